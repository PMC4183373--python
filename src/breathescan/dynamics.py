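"""Langevin dynamics of the chain-plus-particle system.

Each promoter is simulated in several independent realizations.  Every
realization starts from the closed chain (all y = 0) with the particle at a
random position, discards a preheating stretch, then samples frames at a
fixed stride.  Observables are the per-site mean opening and the particle's
site-visit histogram, both restricted to non-clamp sites.

Reproducibility contract: a realization is a pure function of
(master seed, realization_id); the per-realization RNG streams are derived
with ``numpy.random.SeedSequence`` so ensembles are identical regardless of
how realizations are scheduled.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Optional, Sequence

import h5py
import numpy as np

from . import _kernels
from .energetics import ChainState, ModelParameters
from .sequence_io import EncodedChain

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "OpeningProfile",
    "srk4_step",
    "euler_maruyama_step",
    "run_realization",
    "run_ensemble",
    "save_trajectories",
    "load_trajectories",
]


@dataclass
class SimulationConfig:
    """Integration and sampling schedule.

    Defaults correspond to a production-scale scan (1e6 time units per
    realization, 1e4 of preheating, five realizations); tests and the worked
    examples run at much shorter, documented scales.
    """

    dt: float = 0.05
    n_steps: int = 20_000_000
    preheat_steps: int = 200_000
    n_realizations: int = 5
    sample_stride: int = 200
    seed: int = 0
    temperature: Optional[float] = None  # overrides ModelParameters.T

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_steps < 1 or self.n_realizations < 1:
            raise ValueError("n_steps and n_realizations must be >= 1")
        if self.sample_stride < 1:
            raise ValueError("sample_stride must be >= 1")
        if self.preheat_steps < 0:
            raise ValueError("preheat_steps must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.n_steps // self.sample_stride

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


@dataclass
class Trajectory:
    """Sampled frames of one realization: openings y (frames x N, float32),
    particle coordinate x (frames), and sample times."""

    y: np.ndarray
    x: np.ndarray
    times: np.ndarray
    realization_id: int
    seed: int

    @property
    def n_frames(self) -> int:
        return self.y.shape[0]

    @property
    def n_sites(self) -> int:
        return self.y.shape[1]


@dataclass
class OpeningProfile:
    """Ensemble observables on non-clamp sites: mean opening <y_n> and the
    particle visit fraction per site (renormalized after dropping clamps)."""

    sites: np.ndarray           # simulated-site indices (non-clamp)
    labels: np.ndarray          # genomic labels of those sites
    mean_opening: np.ndarray
    particle_histogram: np.ndarray

    @property
    def modal_site(self) -> int:
        """Simulated-site index the particle visits most."""
        return int(self.sites[int(np.argmax(self.particle_histogram))])

    @property
    def modal_label(self) -> int:
        return int(self.labels[int(np.argmax(self.particle_histogram))])


def _effective_params(params: ModelParameters, config: SimulationConfig) -> ModelParameters:
    if config.temperature is not None:
        return params.with_(T=config.temperature)
    return params


def _kernel_args(chain: EncodedChain, p: ModelParameters):
    is_gc = np.ascontiguousarray(chain.pair_class, dtype=np.uint8)
    free = np.ascontiguousarray(chain.analysis_mask, dtype=np.uint8)
    return is_gc, free


def srk4_step(state: ChainState, chain: EncodedChain, params: ModelParameters,
              dt: float, noise_seed: Optional[int] = None) -> ChainState:
    """Advance one stochastic-RK4 step; ``noise_seed=None`` disables noise
    (deterministic RK4 limit).  Mainly a test/inspection surface; long runs
    go through :func:`run_realization`."""
    p = params
    is_gc, free = _kernel_args(chain, p)
    y = state.y.copy()
    vy = state.v.copy()
    frames_y = np.empty((0, len(y)), dtype=np.float32)
    frames_x = np.empty(0, dtype=np.float64)
    kBT = p.kBT if noise_seed is not None else 0.0
    seed = 0 if noise_seed is None else int(noise_seed)
    x, vx = _kernels.run_langevin(
        y, vy, float(state.x), float(state.vx), is_gc, free,
        p.D_AT, p.D_GC, p.a_AT, p.a_GC, p.G_bar, p.b_pos, p.b_w,
        p.k_stack, p.rho, p.alpha, p.A_p, p.sigma_p, p.y_sat,
        p.m, p.m_p, p.gamma, p.gamma_p, kBT, p.y_wall,
        dt, 1, 0, 2, seed, frames_y, frames_x)
    if not np.isfinite(x):
        raise FloatingPointError(
            "non-finite state after integration step (dt too large?)")
    return ChainState(y=y, x=x, v=vy, vx=vx)


def euler_maruyama_step(state: ChainState, chain: EncodedChain,
                        params: ModelParameters, dt: float,
                        rng: np.random.Generator) -> ChainState:
    """First-order reference integrator (cross-check oracle for stationary
    statistics; never used in production runs)."""
    from .energetics import forces
    p = params
    f, fx = forces(state, chain, p)
    free = chain.analysis_mask
    kBT = p.kBT
    y = state.y.copy()
    vy = state.v.copy()
    noise_y = rng.normal(size=len(y)) * np.sqrt(2.0 * p.m * p.gamma * kBT * dt)
    noise_x = rng.normal() * np.sqrt(2.0 * p.m_p * p.gamma_p * kBT * dt)
    vy[free] += (dt * (f[free] - p.m * p.gamma * vy[free]) + noise_y[free]) / p.m
    y[free] += dt * vy[free]
    if p.y_wall > 0:
        over = free & (y > p.y_wall)
        y[over] = 2.0 * p.y_wall - y[over]
        vy[over] *= -1.0
    vx = state.vx + (dt * (fx - p.m_p * p.gamma_p * state.vx) + noise_x) / p.m_p
    x = (state.x + dt * vx) % len(y)
    return ChainState(y=y, x=x, v=vy, vx=vx)


def _realization_seed(master_seed: int, realization_id: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(realization_id)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_realization(chain: EncodedChain, params: ModelParameters,
                    config: SimulationConfig, realization_id: int = 0) -> Trajectory:
    """Simulate one realization and return its sampled trajectory."""
    p = _effective_params(params, config)
    is_gc, free = _kernel_args(chain, p)
    n = chain.n_sites
    seed = _realization_seed(config.seed, realization_id)
    rng = np.random.default_rng(seed)
    y = np.zeros(n)
    vy = np.zeros(n)
    x0 = float(rng.uniform(0, n))
    n_frames = config.n_frames
    frames_y = np.empty((n_frames, n), dtype=np.float32)
    frames_x = np.empty(n_frames, dtype=np.float64)
    x, vx = _kernels.run_langevin(
        y, vy, x0, 0.0, is_gc, free,
        p.D_AT, p.D_GC, p.a_AT, p.a_GC, p.G_bar, p.b_pos, p.b_w,
        p.k_stack, p.rho, p.alpha, p.A_p, p.sigma_p, p.y_sat,
        p.m, p.m_p, p.gamma, p.gamma_p, p.kBT, p.y_wall,
        config.dt, config.n_steps, config.preheat_steps,
        config.sample_stride, seed, frames_y, frames_x)
    if not np.isfinite(x):
        raise FloatingPointError(
            f"realization {realization_id}: non-finite state during "
            "integration (dt too large?)")
    times = (np.arange(1, n_frames + 1) * config.sample_stride) * config.dt
    return Trajectory(y=frames_y, x=frames_x, times=times,
                      realization_id=realization_id, seed=seed)


def compute_profile(trajectories: Sequence[Trajectory],
                    chain: EncodedChain) -> OpeningProfile:
    """Pool frames of all realizations into the mean-opening profile and the
    particle site-visit histogram (clamps dropped, histogram renormalized)."""
    if not trajectories:
        raise ValueError("no trajectories")
    n = chain.n_sites
    mask = chain.analysis_mask
    sites = np.flatnonzero(mask)
    total = np.zeros(n)
    counts = np.zeros(n)
    n_frames = 0
    for t in trajectories:
        total += t.y.sum(axis=0, dtype=np.float64)
        occ = np.rint(t.x).astype(np.int64) % n
        counts += np.bincount(occ, minlength=n)
        n_frames += t.n_frames
    mean_opening = (total / n_frames)[mask]
    hist = counts[mask]
    s = hist.sum()
    hist = hist / s if s > 0 else hist
    return OpeningProfile(sites=sites, labels=chain.position_labels[mask],
                          mean_opening=mean_opening, particle_histogram=hist)


def run_ensemble(chain: EncodedChain, params: ModelParameters,
                 config: SimulationConfig) -> tuple[list[Trajectory], OpeningProfile]:
    """Simulate ``config.n_realizations`` realizations and pool their
    observables."""
    if config.n_realizations < 1:
        raise ValueError("need at least one realization")
    trajs = [run_realization(chain, params, config, rid)
             for rid in range(config.n_realizations)]
    return trajs, compute_profile(trajs, chain)


def save_trajectories(path, trajectories: Sequence[Trajectory],
                      chain: EncodedChain, params: ModelParameters,
                      config: SimulationConfig) -> None:
    """Persist an ensemble in HDF5 (one group per realization; parameters
    and schedule stored as attributes)."""
    with h5py.File(path, "w") as f:
        f.attrs["seq_id"] = chain.seq_id
        f.attrs["clamp_len"] = chain.clamp_len
        f.create_dataset("pair_class", data=chain.pair_class)
        f.create_dataset("analysis_mask", data=chain.analysis_mask)
        f.create_dataset("position_labels", data=chain.position_labels)
        for k, v in params.to_dict().items():
            f.attrs[f"param_{k}"] = v
        for k, v in config.to_dict().items():
            f.attrs[f"config_{k}"] = -1 if v is None else v
        for t in trajectories:
            g = f.create_group(f"realization_{t.realization_id}")
            g.create_dataset("y", data=t.y, chunks=True)
            g.create_dataset("x", data=t.x)
            g.create_dataset("times", data=t.times)
            g.attrs["realization_id"] = t.realization_id
            g.attrs["seed"] = t.seed


def load_trajectories(path) -> tuple[list[Trajectory], EncodedChain]:
    with h5py.File(path, "r") as f:
        chain = EncodedChain(
            seq_id=str(f.attrs["seq_id"]),
            pair_class=f["pair_class"][:],
            analysis_mask=f["analysis_mask"][:],
            position_labels=f["position_labels"][:],
            clamp_len=int(f.attrs["clamp_len"]),
        )
        trajs = []
        for name in sorted(k for k in f.keys() if k.startswith("realization_")):
            g = f[name]
            trajs.append(Trajectory(
                y=g["y"][:], x=g["x"][:], times=g["times"][:],
                realization_id=int(g.attrs["realization_id"]),
                seed=int(g.attrs["seed"])))
    trajs.sort(key=lambda t: t.realization_id)
    return trajs, chain
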