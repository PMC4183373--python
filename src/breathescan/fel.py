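"""Free-energy-landscape analysis of the microstate network.

The network is first partitioned into basins of attraction by steepest
ascent in occupancy: from every node, hop to the linked neighbor with the
largest weight among those heavier than the current node, until a node with
no heavier neighbor (the attractor) is reached.  Each basin gets a free
energy from its pooled weight,

    F_b = -kB T ln(P_b / P_max),

with P_max the weight of the heaviest basin, so the dominant basin sits at
F = 0.  Sweeping a threshold upward through the basin free energies and
watching when groups of active basins become mutually linked yields the
disconnectivity dendrogram; basins separated by effective barriers below a
cut (default 1 kB T) are clustered into macrostates.  Low-occupancy basins
— short-lived transitional states in which the particle diffuses between
targets — are pooled into the nonspecific reference with total weight P_NS,
and each macrostate is characterized by

    dF = ln(P_alpha / P_NS)   [kB T]
    S  = -sum_b q_b ln q_b,   q_b = P_b / P_alpha,

the free energy relative to nonspecific binding and the Shannon
multiplicity over its member basins.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cmn import CMNetwork, MicrostateKey

__all__ = [
    "Basin",
    "Dendrogram",
    "Macrostate",
    "PromoterReport",
    "find_basins",
    "basin_free_energy",
    "build_dendrogram",
    "cluster_macrostates",
    "split_nonspecific",
    "free_energy_difference",
    "macrostate_entropy",
    "promoter_report",
]


@dataclass
class Basin:
    attractor: MicrostateKey
    members: frozenset
    weight: float
    free_energy: float = math.nan

    @property
    def particle_site(self) -> int:
        return int(self.attractor[0])


@dataclass
class Dendrogram:
    """Disconnectivity tree over basins.

    ``bottom_F`` holds each basin's depth (free energy of its attractor
    microstate); ``merges`` are (group, group, barrier) events with barriers
    non-decreasing, the barrier being the free energy of the ridge
    microstate whose activation first connects the two groups.
    """

    leaves: list                        # basin indices sorted by depth
    merges: list                        # (frozenset, frozenset, barrier)
    bottom_F: dict                      # basin index -> attractor-node F

    def to_json(self) -> str:
        return json.dumps({
            "leaves": [int(i) for i in self.leaves],
            "bottom_F": {str(int(i)): float(f)
                         for i, f in self.bottom_F.items()},
            "merges": [
                {"group_a": sorted(int(i) for i in a),
                 "group_b": sorted(int(i) for i in b),
                 "barrier": float(h)}
                for a, b, h in self.merges
            ],
        }, indent=1)

    def to_newick(self) -> str:
        """Newick with branch lengths = barrier minus child height.

        Merge events touching more than two current clusters become
        multifurcations; a disconnected landscape renders as one tree per
        component, concatenated.
        """
        cluster = {i: frozenset([i]) for i in self.leaves}
        node = {frozenset([i]): str(i) for i in self.leaves}
        height = {frozenset([i]): float(self.bottom_F[i])
                  for i in self.leaves}
        for ga, gb, h in self.merges:
            comps = sorted({cluster[i] for i in ga | gb}, key=min)
            if len(comps) < 2:
                continue
            parts = [f"{node.pop(c)}:{max(h - height.pop(c), 0.0):.6g}"
                     for c in comps]
            merged = frozenset().union(*comps)
            node[merged] = "(" + ",".join(parts) + ")"
            height[merged] = h
            for i in merged:
                cluster[i] = merged
        return ";".join(node[c] for c in sorted(node, key=min)) + ";"


@dataclass
class Macrostate:
    basins: list                        # member Basin objects
    weight: float
    entropy: float
    particle_site: int                  # modal site of the heaviest basin
    label: Optional[int] = None         # genomic position label
    delta_F: float = math.nan           # kB T, relative to nonspecific states
    tss_match: Optional[int] = None     # matched known-TSS label, if any


def _steepest_target(key, weights, adj):
    """Heaviest strictly-heavier linked neighbor (ties -> lowest key)."""
    best = None
    w0 = weights[key]
    for nb in adj[key]:
        w = weights[nb]
        if w > w0:
            if best is None or w > weights[best] or (w == weights[best] and nb < best):
                best = nb
    return best


def find_basins(net: CMNetwork, stochastic: bool = False,
                seed: Optional[int] = None) -> list[Basin]:
    """Partition the network into basins of attraction.

    The default is the deterministic rule above (reproducible).  With
    ``stochastic=True`` each node instead hops to a heavier neighbor with
    probability proportional to the connecting edge flux (counts in either
    direction), closer in spirit to a stochastic descent on the flux
    network; a seed is then required.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    adj = net.adjacency()
    weights = net.weights
    rng = np.random.default_rng(seed) if stochastic else None

    target = {}
    for key in weights:
        if stochastic:
            heavier = [nb for nb in adj[key] if weights[nb] > weights[key]]
            if not heavier:
                target[key] = None
                continue
            flux = np.array([net.edges.get((key, nb), 0)
                             + net.edges.get((nb, key), 0)
                             for nb in heavier], dtype=float)
            if flux.sum() == 0:
                flux[:] = 1.0
            target[key] = heavier[int(rng.choice(len(heavier),
                                                 p=flux / flux.sum()))]
        else:
            target[key] = _steepest_target(key, weights, adj)

    # path-compressed attractor assignment
    attractor_of = {}

    def resolve(key):
        path = []
        k = key
        while k not in attractor_of and target[k] is not None:
            path.append(k)
            k = target[k]
        root = attractor_of.get(k, k)
        for p in path:
            attractor_of[p] = root
        attractor_of[key] = root
        return root

    members: dict = {}
    for key in weights:
        root = resolve(key)
        members.setdefault(root, set()).add(key)
    basins = [
        Basin(attractor=root, members=frozenset(ms),
              weight=float(sum(weights[k] for k in ms)))
        for root, ms in members.items()
    ]
    basins.sort(key=lambda b: (-b.weight, b.attractor))
    return basins


def basin_free_energy(weights: Sequence[float], kBT: float = 1.0) -> np.ndarray:
    """F_b = -kBT ln(P_b / P_max); the heaviest basin sits at F = 0."""
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("basin weights must be > 0")
    return -kBT * np.log(w / w.max())


def build_dendrogram(basins: Sequence[Basin], net: CMNetwork,
                     kBT: float = 1.0) -> Dendrogram:
    """Disconnectivity dendrogram over basins, built at microstate level.

    Every member microstate gets a free energy -kBT ln(P_i / P_max) from
    its own occupancy; microstates are activated in order of increasing
    free energy, each connecting to its already-active network neighbors.
    Because steepest-ascent paths only climb in weight, an active node is
    always connected to its attractor, so growing components are unions of
    partial basins; a merge event is recorded at the activating node's free
    energy whenever two components holding different basins join.  (Pooled
    basin free energies from :func:`basin_free_energy` are also attached to
    the basins for reporting.)
    """
    pooled_F = basin_free_energy([b.weight for b in basins], kBT)
    for b, f in zip(basins, pooled_F):
        b.free_energy = float(f)

    owner = {}
    for idx, b in enumerate(basins):
        for k in b.members:
            owner[k] = idx
    weights = {k: net.weights[k] for k in owner}
    wmax = max(weights.values())
    node_F = {k: -kBT * math.log(w / wmax) for k, w in weights.items()}
    attractors = {b.attractor for b in basins}
    order = sorted(weights, key=lambda k: (node_F[k], k not in attractors, k))
    adj = net.adjacency()

    bottom_F = {i: float(node_F[b.attractor]) for i, b in enumerate(basins)}

    parent = {}

    def find(k):
        root = k
        while parent[root] != root:
            root = parent[root]
        while parent[k] != root:
            parent[k], k = root, parent[k]
        return root

    comp_basins = {}
    merges = []
    active = set()
    for k in order:
        parent[k] = k
        comp_basins[k] = frozenset([owner[k]])
        active.add(k)
        for nb in adj.get(k, ()):
            if nb not in active:
                continue
            ra, rb = find(k), find(nb)
            if ra == rb:
                continue
            ga, gb = comp_basins.pop(ra), comp_basins.pop(rb)
            parent[rb] = ra
            comp_basins[ra] = ga | gb
            if ga != gb and not (ga <= gb or gb <= ga):
                merges.append((ga, gb, float(node_F[k])))

    leaves = sorted(range(len(basins)), key=lambda i: (bottom_F[i],
                                                       basins[i].attractor))
    return Dendrogram(leaves=leaves, merges=merges, bottom_F=bottom_F)


def cluster_macrostates(dend: Dendrogram, basins: Sequence[Basin],
                        barrier_cut: float = 1.0) -> list[Macrostate]:
    """Cluster basins separated by effective barriers below ``barrier_cut``.

    A merge event is accepted when its ridge free energy minus the
    shallower merging group's depth (the cost for that group to escape) is
    below the cut; macrostates are the connected clusters of accepted
    merges.
    """
    F = dend.bottom_F
    cluster_of = {i: frozenset([i]) for i in dend.leaves}
    for ga, gb, barrier in dend.merges:
        eff = barrier - max(min(F[i] for i in ga), min(F[i] for i in gb))
        if eff < barrier_cut:
            merged = frozenset().union(*(cluster_of[i] for i in ga | gb))
            for m in merged:
                cluster_of[m] = merged
    out = []
    for cluster in {id(c): c for c in cluster_of.values()}.values():
        member = sorted(cluster, key=lambda i: -basins[i].weight)
        bs = [basins[i] for i in member]
        weight = float(sum(b.weight for b in bs))
        out.append(Macrostate(
            basins=bs, weight=weight,
            entropy=macrostate_entropy([b.weight for b in bs]),
            particle_site=bs[0].particle_site))
    out.sort(key=lambda m: -m.weight)
    return out


def macrostate_modal_site(macro: Macrostate, net: CMNetwork) -> int:
    """Position of a macrostate: the occupancy-weighted modal particle site
    of its heaviest member basin — where the particle sits in the state's
    dominant configurations.  (The full macrostate can lump in shallow
    diffusive microstates, whose pooled positions are not representative.)"""
    by_site: dict = {}
    for k in macro.basins[0].members:
        by_site[k[0]] = by_site.get(k[0], 0.0) + net.weights[k]
    return int(max(sorted(by_site), key=lambda s: by_site[s]))


def split_nonspecific(basins: Sequence[Basin],
                      ns_threshold: float = 0.005) -> tuple[list[Basin], float]:
    """Separate low-occupancy (nonspecific) basins from the specific ones.

    Returns the specific basins and P_NS, the pooled weight of all basins
    with occupancy below the threshold.
    """
    if not 0.0 <= ns_threshold < 1.0:
        raise ValueError("ns_threshold must be in [0, 1)")
    specific = [b for b in basins if b.weight >= ns_threshold]
    p_ns = float(sum(b.weight for b in basins if b.weight < ns_threshold))
    if not specific:
        raise ValueError(
            "all basins fall below the nonspecific threshold; "
            "landscape unresolved (lower ns_threshold or sample longer)")
    return specific, p_ns


def free_energy_difference(P_state: float, P_NS: float) -> float:
    """Free energy of a specific state relative to the pooled nonspecific
    states, dF = ln(P_state / P_NS), in kB T units."""
    if P_state <= 0 or P_NS <= 0:
        raise ValueError("occupancies must be > 0")
    return math.log(P_state / P_NS)


def macrostate_entropy(member_weights: Sequence[float]) -> float:
    """Shannon multiplicity over member basins: S = -sum q ln q with
    q = P_b / P_alpha.  0 for a single basin, ln m for m equal basins."""
    w = np.asarray(member_weights, dtype=float)
    if w.size == 0 or np.any(w <= 0):
        raise ValueError("member weights must be nonempty and > 0")
    q = w / w.sum()
    return float(-np.sum(q * np.log(q)))


@dataclass
class PromoterReport:
    """Per-macrostate summary of a promoter scan."""

    seq_id: str
    macrostates: list
    p_ns: float
    metadata: dict = field(default_factory=dict)

    def rows(self) -> list[dict]:
        out = []
        for m in self.macrostates:
            out.append({
                "label": m.label,
                "site": m.particle_site,
                "P": round(m.weight, 6),
                "dF_kBT": None if math.isnan(m.delta_F) else round(m.delta_F, 4),
                "S": abs(round(m.entropy, 4)),
                "n_basins": len(m.basins),
                "tss_match": m.tss_match,
            })
        return out

    def to_json(self) -> str:
        return json.dumps({
            "seq_id": self.seq_id,
            "P_NS": round(self.p_ns, 6),
            "macrostates": self.rows(),
            "metadata": self.metadata,
        }, indent=1)

    def to_tsv(self) -> str:
        lines = ["label\tsite\tP\tdF_kBT\tS\tn_basins\ttss_match"]
        for r in self.rows():
            lines.append("\t".join("" if r[c] is None else str(r[c])
                                   for c in ("label", "site", "P", "dF_kBT",
                                             "S", "n_basins", "tss_match")))
        lines.append(f"# NS\tP={self.p_ns:.6f}")
        return "\n".join(lines) + "\n"


def promoter_report(macrostates: Sequence[Macrostate], p_ns: float,
                    seq_id: str = "", known_tss: Sequence[int] = (),
                    metadata: Optional[dict] = None) -> PromoterReport:
    """Assemble the final report: macrostates sorted by weight with dF
    relative to the nonspecific states, annotated against known TSS labels
    (match window ±10 bp)."""
    ms = sorted(macrostates, key=lambda m: -m.weight)
    for m in ms:
        m.delta_F = (free_energy_difference(m.weight, p_ns)
                     if p_ns > 0 else math.nan)
        if m.label is not None:
            for tss in known_tss:
                if abs(m.label - tss) <= 10:
                    m.tss_match = int(tss)
                    break
    return PromoterReport(seq_id=seq_id, macrostates=ms, p_ns=p_ns,
                          metadata=metadata or {})
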