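"""Conformational Markov Network built from discretized trajectories.

A microstate is the pair (particle site, PC bin vector): the particle's
nearest integer position along the chain together with the bin index of
each retained principal component.  Nodes of the network are the visited
microstates, weighted by the fraction of pooled frames spent in them; the
directed edges count the frame-to-frame transitions observed within each
realization (never across the seam between realizations).  Self-loops are
retained.  The sampling stride is therefore the effective lag time of the
network.

Bin edges span the pooled [min, max] of each component (values at the
boundary, and any out-of-range value, are clipped into the end bins), which
keeps the discretization robust to parameter changes; the edges are
recorded for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .dimreduce import ProjectedTrajectory

__all__ = ["MicrostateKey", "CMNetwork", "discretize", "build_network"]

# A microstate key is (particle_site, pc_bin_0, ..., pc_bin_{n_pc-1}).
MicrostateKey = tuple


@dataclass
class CMNetwork:
    """Weighted directed microstate network."""

    weights: dict                 # MicrostateKey -> occupancy P_i
    edges: dict                   # (key_i, key_j) -> transition count
    frame_total: int
    bin_edges: np.ndarray = None  # (n_pc, n_bins+1), recorded for provenance

    @property
    def n_nodes(self) -> int:
        return len(self.weights)

    def neighbors(self, key) -> set:
        """Nodes linked to ``key`` by an edge in either direction (excluding
        the self-loop)."""
        out = set()
        for (i, j) in self.edges:
            if i == key and j != key:
                out.add(j)
            elif j == key and i != key:
                out.add(i)
        return out

    def adjacency(self) -> dict:
        """Undirected neighbor sets for every node (self-loops dropped)."""
        adj = {k: set() for k in self.weights}
        for (i, j) in self.edges:
            if i != j:
                adj[i].add(j)
                adj[j].add(i)
        return adj

    def transition_matrix(self):
        """Row-stochastic transition matrix over nodes with outgoing edges;
        returns (keys, matrix)."""
        keys = sorted(self.weights)
        index = {k: n for n, k in enumerate(keys)}
        mat = np.zeros((len(keys), len(keys)))
        for (i, j), c in self.edges.items():
            mat[index[i], index[j]] = c
        rows = mat.sum(axis=1, keepdims=True)
        np.divide(mat, rows, out=mat, where=rows > 0)
        return keys, mat

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for k, w in self.weights.items():
            g.add_node(str(k), weight=float(w))
        for (i, j), c in self.edges.items():
            g.add_edge(str(i), str(j), count=int(c))
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))

    def write_tsv(self, node_path, edge_path) -> None:
        with open(node_path, "w") as f:
            f.write("key\tP\n")
            for k in sorted(self.weights):
                f.write(f"{k}\t{self.weights[k]:.8g}\n")
        with open(edge_path, "w") as f:
            f.write("source\ttarget\tcount\n")
            for (i, j) in sorted(self.edges):
                f.write(f"{i}\t{j}\t{self.edges[(i, j)]}\n")


def pooled_bin_edges(projs: Sequence[ProjectedTrajectory], n_bins: int) -> np.ndarray:
    """Equal-width bin edges per PC spanning the pooled data range."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    coords = np.concatenate([p.coords for p in projs])
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    # degenerate (constant) components get a token nonzero width
    span = np.where(hi > lo, hi - lo, 1.0)
    return np.stack([np.linspace(l, l + s, n_bins + 1)
                     for l, s in zip(lo, span)])


def discretize(proj: ProjectedTrajectory, n_bins: int,
               bin_edges: np.ndarray, n_sites: int) -> list:
    """Map each frame to its microstate key.

    ``bin_edges`` normally comes from :func:`pooled_bin_edges` over all
    realizations, so that every realization shares one discretization.
    """
    if proj.n_frames == 0:
        raise ValueError("empty trajectory")
    sites = np.rint(proj.x).astype(np.int64) % n_sites
    n_pc = proj.coords.shape[1]
    bins = np.empty((proj.n_frames, n_pc), dtype=np.int64)
    for c in range(n_pc):
        b = np.searchsorted(bin_edges[c], proj.coords[:, c], side="right") - 1
        bins[:, c] = np.clip(b, 0, n_bins - 1)
    return [tuple((int(s), *row)) for s, row in zip(sites, bins)]


def build_network(key_sequences: Sequence[Sequence[MicrostateKey]],
                  bin_edges: np.ndarray = None) -> CMNetwork:
    """Count node occupancies and directed frame-to-frame transitions.

    Each inner sequence is one realization; transitions are only counted
    within a realization, never across the concatenation seam.
    """
    seqs = [list(s) for s in key_sequences if len(s) > 0]
    if not seqs:
        raise ValueError("no nonempty key sequences")
    weights: dict = {}
    edges: dict = {}
    total = 0
    for seq in seqs:
        for k in seq:
            weights[k] = weights.get(k, 0) + 1
        for a, b in zip(seq, seq[1:]):
            edges[(a, b)] = edges.get((a, b), 0) + 1
        total += len(seq)
    weights = {k: c / total for k, c in weights.items()}
    return CMNetwork(weights=weights, edges=edges, frame_total=total,
                     bin_edges=bin_edges)
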