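"""PCA of chain-opening trajectories and eigenvector localization.

The covariance matrix of the masked opening coordinates, pooled over all
realizations of a promoter, is diagonalized; the leading eigenvectors are
the collective opening modes and their eigenvalues the variance each mode
carries.  Trajectories are then projected onto the first few components
(default five), which together with the particle coordinate form the
reduced description handed to the Markov-network stage.

Localization of an eigenvector v (orthonormal) is quantified by the
participation ratio PR = 1 / sum_n v_n^4 — the effective number of sites the
mode spans (N for a uniform vector, 1 for a single-site one) — and by the
squared-amplitude share falling into user-labeled sequence regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dynamics import Trajectory

__all__ = [
    "PCAResult",
    "ProjectedTrajectory",
    "fit_pca",
    "project",
    "explained_by",
    "participation_ratio",
    "eigenvector_localization",
]


@dataclass
class PCAResult:
    mean: np.ndarray              # per masked site
    eigenvalues: np.ndarray       # descending, >= 0
    eigenvectors: np.ndarray      # columns, orthonormal
    explained_fraction: np.ndarray
    mask_sites: np.ndarray        # simulated-site index per row of mean

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


@dataclass
class ProjectedTrajectory:
    coords: np.ndarray            # frames x n_pc
    x: np.ndarray                 # particle coordinate per frame
    realization_id: int

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


def _pooled(trajectories: Sequence[Trajectory], mask: np.ndarray) -> np.ndarray:
    return np.concatenate([t.y[:, mask].astype(np.float64) for t in trajectories])


def fit_pca(trajectories: Sequence[Trajectory], mask: np.ndarray,
            center: bool = True) -> PCAResult:
    """Diagonalize the pooled covariance of masked openings.

    Components are ordered by decreasing eigenvalue; each eigenvector's sign
    is fixed so its largest-magnitude entry is positive (deterministic
    downstream binning).

    With ``center=False`` the second moment is taken about the closed state
    (y = 0) instead of the sampled mean — the breathing-coordinate
    convention used for whole-gene mode analysis, where the first component
    then captures the mean breathing profile of the entire sequence and the
    localized fluctuation modes follow it.
    """
    mask = np.asarray(mask, dtype=bool)
    data = _pooled(trajectories, mask)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 frames for PCA")
    if center:
        mean = data.mean(axis=0)
        cov = np.cov(data, rowvar=False, bias=False)
    else:
        mean = np.zeros(data.shape[1])
        cov = (data.T @ data) / (data.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] *= -1.0
    tot = evals.sum()
    frac = evals / tot if tot > 0 else np.zeros_like(evals)
    return PCAResult(mean=mean, eigenvalues=evals, eigenvectors=evecs,
                     explained_fraction=frac,
                     mask_sites=np.flatnonzero(mask))


def project(traj: Trajectory, pca: PCAResult, n_pc: int = 5) -> ProjectedTrajectory:
    """Project a trajectory onto the first ``n_pc`` components; the particle
    coordinate is carried alongside, never mixed into the covariance."""
    if not 0 < n_pc <= pca.n_components:
        raise ValueError(f"n_pc={n_pc} outside 1..{pca.n_components}")
    data = traj.y[:, pca.mask_sites].astype(np.float64) - pca.mean
    coords = data @ pca.eigenvectors[:, :n_pc]
    return ProjectedTrajectory(coords=coords, x=traj.x.copy(),
                               realization_id=traj.realization_id)


def reconstruct(proj: ProjectedTrajectory, pca: PCAResult) -> np.ndarray:
    """Inverse of :func:`project` (lossless at full rank)."""
    n_pc = proj.coords.shape[1]
    return proj.coords @ pca.eigenvectors[:, :n_pc].T + pca.mean


def explained_by(pca: PCAResult, n_pc: int) -> float:
    """Cumulative variance fraction captured by the first n_pc components."""
    if not 0 <= n_pc <= pca.n_components:
        raise ValueError(f"n_pc={n_pc} outside 0..{pca.n_components}")
    return float(pca.explained_fraction[:n_pc].sum())


def participation_ratio(v: np.ndarray) -> float:
    v = np.asarray(v, dtype=float)
    v = v / np.linalg.norm(v)
    return float(1.0 / np.sum(v**4))


def eigenvector_localization(
    pca: PCAResult,
    regions: Mapping[str, tuple[int, int]],
    n_components: int = 4,
) -> dict:
    """Region-resolved squared amplitude and participation ratio of the
    leading eigenvectors.

    ``regions`` maps a name to a half-open (start, stop) range of
    simulated-site indices; the ranges must not overlap.  Returns, per
    component, the squared-amplitude share in each region plus its
    participation ratio.
    """
    items = sorted(regions.items(), key=lambda kv: kv[1][0])
    for (na, (a0, a1)), (nb, (b0, b1)) in zip(items, items[1:]):
        if b0 < a1:
            raise ValueError(f"overlapping regions {na!r} and {nb!r}")
    n_components = min(n_components, pca.n_components)
    out = {}
    for c in range(n_components):
        v = pca.eigenvectors[:, c]
        v2 = v**2 / np.sum(v**2)
        shares = {}
        for name, (start, stop) in regions.items():
            in_region = (pca.mask_sites >= start) & (pca.mask_sites < stop)
            shares[name] = float(v2[in_region].sum())
        out[c + 1] = {"shares": shares,
                      "participation_ratio": participation_ratio(v)}
    return out
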