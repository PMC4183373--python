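"""Numba hot loops for the Langevin integrator.

The equations of motion are

    m  d²y_n/dt² = -dE/dy_n - m  gamma  dy_n/dt + xi_n(t)
    m_p d²x/dt²  = -dE/dx  - m_p gamma_p dx/dt + xi_x(t)

with Gaussian white noise of strength 2 m gamma kB T per degree of freedom.
One step of the fourth-order stochastic Runge-Kutta scheme treats the random
force as constant across the step (its impulse carries the exact variance
2 m gamma kB T dt) and propagates the drift with classical RK4 stages, so
the deterministic limit recovers plain RK4 exactly.

Clamped sites are frozen at y = 0; the particle coordinate is wrapped
periodically into [0, N).  An optional reflecting wall at y = y_wall > 0
confines openings for single-site equilibrium studies.
"""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _forces(y, x, is_gc,
            D_AT, D_GC, a_AT, a_GC, G, b, w, k, rho, alpha,
            A_p, sigma, y_sat, f_out):
    """Fill f_out with -dE/dy and return -dE/dx."""
    n = y.shape[0]
    inv2w2 = 0.5 / (w * w)
    for i in range(n):
        if is_gc[i]:
            D = D_GC
            a = a_GC
        else:
            D = D_AT
            a = a_AT
        ey = np.exp(-a * y[i])
        f = 2.0 * a * D * ey * (ey - 1.0)
        if G > 0.0:
            dyb = y[i] - b
            f += G * dyb / (w * w) * np.exp(-dyb * dyb * inv2w2)
        f_out[i] = f
    for i in range(1, n):
        s = y[i] + y[i - 1]
        d = y[i] - y[i - 1]
        ex = rho * np.exp(-alpha * s)
        common = -0.5 * k * alpha * ex * d * d
        lin = k * (1.0 + ex) * d
        f_out[i] -= common + lin
        f_out[i - 1] -= common - lin
    fx = 0.0
    if A_p > 0.0:
        lo = int(np.floor(x - 6.0 * sigma))
        if lo < 0:
            lo = 0
        hi = int(np.ceil(x + 6.0 * sigma)) + 1
        if hi > n:
            hi = n
        inv2s2 = 0.5 / (sigma * sigma)
        invs2 = 1.0 / (sigma * sigma)
        for i in range(lo, hi):
            dx = x - i
            g = np.exp(-dx * dx * inv2s2)
            yi = y[i]
            if yi > 0.0:
                t = np.tanh(yi / y_sat)
                f_out[i] += A_p * (1.0 - t * t) / y_sat * g
                fx -= A_p * t * g * dx * invs2
    return fx


@njit(cache=True)
def _wrap(x, n):
    x = x % n
    if x < 0.0:
        x += n
    return x


@njit(cache=True, fastmath=True)
def run_langevin(y, vy, x, vx, is_gc, free,
                 D_AT, D_GC, a_AT, a_GC, G, b, w, k, rho, alpha,
                 A_p, sigma, y_sat,
                 m, m_p, gamma, gamma_p, kBT, y_wall,
                 dt, n_steps, preheat, stride, seed,
                 frames_y, frames_x):
    """Integrate preheat + n_steps SRK4 steps, storing every stride-th
    production frame into frames_y / frames_x.  Mutates y, vy in place and
    returns the final (x, vx)."""
    n = y.shape[0]
    np.random.seed(seed)
    amp_y = 0.0
    amp_x = 0.0
    if kBT > 0.0:
        amp_y = np.sqrt(2.0 * m * gamma * kBT / dt)
        amp_x = np.sqrt(2.0 * m_p * gamma_p * kBT / dt)

    fr = np.zeros(n)
    f1 = np.empty(n)
    yt = np.empty(n)
    vt = np.empty(n)
    dy = np.empty((4, n))
    dv = np.empty((4, n))
    dxs = np.empty(4)
    dvxs = np.empty(4)
    half = 0.5 * dt
    frame = 0
    total = preheat + n_steps
    for step in range(total):
        if amp_y > 0.0:
            for i in range(n):
                fr[i] = amp_y * np.random.normal() if free[i] else 0.0
            frx = amp_x * np.random.normal()
        else:
            frx = 0.0

        # stage state starts at the current state
        for i in range(n):
            yt[i] = y[i]
            vt[i] = vy[i]
        xt = x
        vxt = vx
        for s in range(4):
            fx = _forces(yt, _wrap(xt, n), is_gc,
                         D_AT, D_GC, a_AT, a_GC, G, b, w, k, rho, alpha,
                         A_p, sigma, y_sat, f1)
            for i in range(n):
                if free[i]:
                    dy[s, i] = vt[i]
                    dv[s, i] = (f1[i] + fr[i] - m * gamma * vt[i]) / m
                else:
                    dy[s, i] = 0.0
                    dv[s, i] = 0.0
            dxs[s] = vxt
            dvxs[s] = (fx + frx - m_p * gamma_p * vxt) / m_p
            if s < 3:
                h = half if s < 2 else dt
                for i in range(n):
                    yt[i] = y[i] + h * dy[s, i]
                    vt[i] = vy[i] + h * dv[s, i]
                xt = x + h * dxs[s]
                vxt = vx + h * dvxs[s]

        sixth = dt / 6.0
        for i in range(n):
            if free[i]:
                y[i] += sixth * (dy[0, i] + 2.0 * dy[1, i] + 2.0 * dy[2, i] + dy[3, i])
                vy[i] += sixth * (dv[0, i] + 2.0 * dv[1, i] + 2.0 * dv[2, i] + dv[3, i])
                if y_wall > 0.0 and y[i] > y_wall:
                    y[i] = 2.0 * y_wall - y[i]
                    vy[i] = -vy[i]
        x = _wrap(x + sixth * (dxs[0] + 2.0 * dxs[1] + 2.0 * dxs[2] + dxs[3]), n)
        vx += sixth * (dvxs[0] + 2.0 * dvxs[1] + 2.0 * dvxs[2] + dvxs[3])

        for i in range(n):
            if not np.isfinite(y[i]):
                return np.nan, np.nan
        if step >= preheat:
            prod = step - preheat + 1
            if prod % stride == 0 and frame < frames_y.shape[0]:
                for i in range(n):
                    frames_y[frame, i] = y[i]
                frames_x[frame] = x
                frame += 1
    return x, vx
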