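"""Hamiltonian of the chain-plus-particle model.

The DNA chain is a one-dimensional lattice of base-pair opening coordinates
y_n (Å).  Each site feels an on-site potential

    V(y) = D_c (e^{-a_c y} - 1)^2 + G e^{-(y-b)^2 / (2 w^2)},

a Morse well (depth D_c, inverse width a_c, with c the pair class: A-T or
the stiffer G-C) plus a Gaussian solvent barrier that penalizes the
intermediate openings where the strands are apart but not yet solvated;
this sharpens denaturation and stabilizes open bubbles.  Neighboring sites
are coupled by the anharmonic stacking potential

    W(y_n, y_{n-1}) = (k/2) (1 + rho e^{-alpha (y_n + y_{n-1})}) (y_n - y_{n-1})^2,

whose effective spring constant drops from k(1+rho) to k when either pair
opens — the source of melting cooperativity.

A Brownian particle with continuous coordinate x (in base-pair index units)
slides along the chain and couples to open regions through a field of
Gaussian wells, one per site:

    V_p(x, {y}) = -A Σ_n f(y_n) exp(-(x - n)^2 / (2 sigma^2)),

with a saturating amplitude f(y) = tanh(y / y_sat) for y > 0 and 0
otherwise, so the attraction grows linearly with small openings and
saturates for wide-open pairs (no self-trapping), and closed or compressed
pairs do not attract at all.  The well sum is truncated at |x - n| <= 6 sigma
and the wells are not wrapped across the periodic particle boundary (the
G-C clamps keep the chain ends closed, so the field vanishes there anyway).

Units: energies in eV, chain lengths in Å, particle coordinate in base-pair
index units, mass in amu; the derived time unit is sqrt(amu Å²/eV) ≈ 10 fs.
All numeric defaults come from the standard mesoscopic-DNA literature and
are overridable through configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Optional

import numpy as np

from .sequence_io import EncodedChain

__all__ = [
    "KB_EV",
    "ModelParameters",
    "ChainState",
    "onsite_potential",
    "stacking_potential",
    "particle_potential",
    "total_energy",
    "kinetic_energy",
    "forces",
]

#: Boltzmann constant in eV/K.
KB_EV = 8.617333262e-5


@dataclass
class ModelParameters:
    """All Hamiltonian, coupling and thermal constants.

    Chain defaults are the widely used mesoscopic-DNA values (Morse depths
    0.05/0.075 eV, inverse widths 4.2/6.9 Å⁻¹, stacking k = 0.025 eV/Å²,
    rho = 2, alpha = 0.35 Å⁻¹) plus a solvent barrier of 0.03 eV centered at
    2 Å.  The particle coupling (A_p, sigma_p, y_sat) is calibrated so that
    particle-stabilized bubbles span of order ten base pairs and the
    interaction saturates at openings of a few Å; see docs/methods.md.
    """

    # Morse on-site
    D_AT: float = 0.05          # eV
    D_GC: float = 0.075         # eV
    a_AT: float = 4.2           # 1/Å
    a_GC: float = 6.9           # 1/Å
    # Gaussian solvent barrier
    G_bar: float = 0.03         # eV
    b_pos: float = 2.0          # Å
    b_w: float = 0.5            # Å
    # stacking
    k_stack: float = 0.025      # eV/Å²
    rho: float = 2.0
    alpha: float = 0.35         # 1/Å
    # particle coupling
    A_p: float = 0.055          # eV
    sigma_p: float = 5.0        # base pairs
    y_sat: float = 2.5          # Å
    # masses / thermostat
    m: float = 300.0            # amu per base pair
    m_p: float = 1.0            # particle mass, eV·(time unit)²/bp²
    gamma: float = 0.05         # chain friction, 1/time unit
    gamma_p: float = 0.01       # particle friction, 1/time unit
    kB: float = KB_EV
    T: float = 290.0            # K
    # optional reflecting wall on y (None/<=0 disables); used for confined
    # single-site equilibrium studies, not in production scans
    y_wall: float = 0.0

    def __post_init__(self):
        if not (self.D_GC > self.D_AT > 0):
            raise ValueError("require D_GC > D_AT > 0")
        for name in ("a_AT", "a_GC", "k_stack", "rho", "alpha", "sigma_p",
                     "y_sat", "m", "m_p", "T", "kB"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.G_bar < 0 or self.A_p < 0 or self.gamma < 0 or self.gamma_p < 0:
            raise ValueError("G_bar, A_p and frictions must be >= 0")

    @property
    def kBT(self) -> float:
        return self.kB * self.T

    def with_(self, **kw) -> "ModelParameters":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**d)


@dataclass
class ChainState:
    """Instantaneous configuration: openings y (Å), particle position x
    (base-pair units, in [0, N)), and optional velocities."""

    y: np.ndarray
    x: float
    v: Optional[np.ndarray] = None
    vx: float = 0.0

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite opening in state")
        if self.v is None:
            self.v = np.zeros_like(self.y)
        else:
            self.v = np.asarray(self.v, dtype=float)
        n = len(self.y)
        if not (0.0 <= self.x < n):
            raise ValueError(f"particle coordinate {self.x} outside [0, {n})")


def _d_class(pair_class, p: ModelParameters):
    pc = np.asarray(pair_class)
    D = np.where(pc == 0, p.D_AT, p.D_GC)
    a = np.where(pc == 0, p.a_AT, p.a_GC)
    return D, a


def onsite_potential(y, pair_class, p: ModelParameters):
    """Morse + solvent-barrier on-site potential; vectorized over y."""
    y = np.asarray(y, dtype=float)
    D, a = _d_class(pair_class, p)
    morse = D * (np.exp(-a * y) - 1.0) ** 2
    barrier = p.G_bar * np.exp(-((y - p.b_pos) ** 2) / (2.0 * p.b_w**2))
    return morse + barrier


def stacking_potential(y_n, y_prev, p: ModelParameters):
    """Anharmonic nearest-neighbor stacking energy."""
    y_n = np.asarray(y_n, dtype=float)
    y_prev = np.asarray(y_prev, dtype=float)
    eff = 1.0 + p.rho * np.exp(-p.alpha * (y_n + y_prev))
    return 0.5 * p.k_stack * eff * (y_n - y_prev) ** 2


def _saturation(y, y_sat):
    y = np.asarray(y, dtype=float)
    return np.where(y > 0.0, np.tanh(np.maximum(y, 0.0) / y_sat), 0.0)


def particle_potential(x: float, y, p: ModelParameters) -> float:
    """Particle-chain interaction energy at particle position x."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if not (0.0 <= x < n):
        raise ValueError(f"particle coordinate {x} outside [0, {n})")
    lo = max(0, int(np.floor(x - 6.0 * p.sigma_p)))
    hi = min(n, int(np.ceil(x + 6.0 * p.sigma_p)) + 1)
    sites = np.arange(lo, hi)
    g = np.exp(-((x - sites) ** 2) / (2.0 * p.sigma_p**2))
    return float(-p.A_p * np.sum(_saturation(y[lo:hi], p.y_sat) * g))


def total_energy(state: ChainState, chain: EncodedChain, p: ModelParameters) -> float:
    """Total potential energy (on-site + stacking + particle coupling)."""
    y = state.y
    if len(y) != chain.n_sites:
        raise ValueError(
            f"state has {len(y)} sites but chain has {chain.n_sites}"
        )
    e = float(np.sum(onsite_potential(y, chain.pair_class, p)))
    e += float(np.sum(stacking_potential(y[1:], y[:-1], p)))
    if p.A_p > 0:
        e += particle_potential(state.x, y, p)
    return e


def kinetic_energy(state: ChainState, p: ModelParameters) -> float:
    return float(0.5 * p.m * np.sum(state.v**2) + 0.5 * p.m_p * state.vx**2)


def forces(state: ChainState, chain: EncodedChain, p: ModelParameters):
    """Exact negative gradients of :func:`total_energy`.

    Returns ``(f_y, f_x)`` where ``f_y[n] = -dE/dy_n`` (including the
    particle's back-reaction on the chain) and ``f_x = -dE/dx``.
    """
    y = state.y
    n = len(y)
    if n != chain.n_sites:
        raise ValueError(
            f"state has {n} sites but chain has {chain.n_sites}"
        )
    D, a = _d_class(chain.pair_class, p)

    # on-site
    ey = np.exp(-a * y)
    dV = -2.0 * a * D * ey * (ey - 1.0)
    if p.G_bar > 0:
        dV += p.G_bar * (-(y - p.b_pos) / p.b_w**2) * np.exp(
            -((y - p.b_pos) ** 2) / (2.0 * p.b_w**2)
        )
    f = -dV

    # stacking: bonds (n, n-1)
    s = y[1:] + y[:-1]
    d = y[1:] - y[:-1]
    ex = p.rho * np.exp(-p.alpha * s)
    # dW/dy_n (upper site of the bond) and dW/dy_{n-1}
    common = -0.5 * p.k_stack * p.alpha * ex * d**2
    lin = p.k_stack * (1.0 + ex) * d
    f[1:] -= common + lin
    f[:-1] -= common - lin

    # particle coupling
    fx = 0.0
    if p.A_p > 0:
        x = state.x
        lo = max(0, int(np.floor(x - 6.0 * p.sigma_p)))
        hi = min(n, int(np.ceil(x + 6.0 * p.sigma_p)) + 1)
        sites = np.arange(lo, hi)
        g = np.exp(-((x - sites) ** 2) / (2.0 * p.sigma_p**2))
        ys = y[lo:hi]
        fsat = _saturation(ys, p.y_sat)
        dfsat = np.where(ys > 0.0, (1.0 - np.tanh(ys / p.y_sat) ** 2) / p.y_sat, 0.0)
        # -dV_p/dy_n = A f'(y_n) g_n(x)
        f[lo:hi] += p.A_p * dfsat * g
        # -dV_p/dx = -A Σ f(y_n) g_n (x-n)/sigma²
        fx = float(-p.A_p * np.sum(fsat * g * (x - sites)) / p.sigma_p**2)
    return f, fx
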