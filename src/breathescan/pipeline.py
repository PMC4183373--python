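"""End-to-end promoter analysis: FASTA -> dynamics -> PCA -> network -> FEL.

Every promoter is analyzed independently.  A run is a pure function of
(sequence, RunConfig, seed): all stochastic stages derive their streams from
the master seed, and every persisted artifact embeds the resolved
configuration.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .sequence_io import PromoterSequence, EncodedChain, encode
from .energetics import ModelParameters
from .dynamics import (SimulationConfig, run_ensemble, compute_profile,
                       save_trajectories, OpeningProfile)
from .dimreduce import fit_pca, project, explained_by, eigenvector_localization
from .cmn import pooled_bin_edges, discretize, build_network
from .fel import (find_basins, build_dendrogram, cluster_macrostates,
                  split_nonspecific, promoter_report, PromoterReport,
                  macrostate_modal_site)

__all__ = ["RunConfig", "AnalysisResult", "analyze_promoter",
           "analyze_gene_chain_only"]

log = logging.getLogger("breathescan")


@dataclass
class RunConfig:
    """Everything needed to reproduce a scan."""

    params: ModelParameters = field(default_factory=ModelParameters)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    clamp_len: int = 10
    n_pc: int = 5
    n_bins: int = 10
    barrier_cut: float = 1.0          # kB T
    ns_threshold: float = 0.005       # basin occupancy below which = nonspecific
    known_tss: list = field(default_factory=list)   # genomic labels

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["params"] = ModelParameters.from_dict(d.get("params", {}))
        d["sim"] = SimulationConfig.from_dict(d.get("sim", {}))
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s


@dataclass
class AnalysisResult:
    report: PromoterReport
    profile: OpeningProfile
    chain: EncodedChain
    pca: "object"
    network: "object"
    basins: list
    dendrogram: "object"


def _stage(name, t0, **sizes):
    extra = " ".join(f"{k}={v}" for k, v in sizes.items())
    log.info("stage=%s wall=%.2fs %s", name, time.perf_counter() - t0, extra)


def analyze_promoter(seq: PromoterSequence, config: RunConfig,
                     out_dir: Optional[Path] = None) -> AnalysisResult:
    """Run the full scan of one promoter and build its macrostate report.

    With ``out_dir`` given, persists trajectories (HDF5), the network
    (GraphML + TSV), the dendrogram (JSON/Newick) and the report (TSV/JSON).
    """
    chain = encode(seq, clamp_len=config.clamp_len)
    t0 = time.perf_counter()
    trajs, profile = run_ensemble(chain, config.params, config.sim)
    _stage("simulate", t0, n_sites=chain.n_sites, n_real=len(trajs),
           frames=sum(t.n_frames for t in trajs))

    t0 = time.perf_counter()
    pca = fit_pca(trajs, chain.analysis_mask)
    n_pc = min(config.n_pc, pca.n_components)
    projs = [project(t, pca, n_pc) for t in trajs]
    _stage("pca", t0, n_pc=n_pc, kept=f"{explained_by(pca, n_pc):.3f}")

    t0 = time.perf_counter()
    edges = pooled_bin_edges(projs, config.n_bins)
    keys = [discretize(p, config.n_bins, edges, chain.n_sites) for p in projs]
    net = build_network(keys, bin_edges=edges)
    _stage("cmn", t0, nodes=net.n_nodes, edges=len(net.edges))

    t0 = time.perf_counter()
    basins = find_basins(net)
    specific, p_ns = split_nonspecific(basins, config.ns_threshold)
    dend = build_dendrogram(specific, net)
    macro = cluster_macrostates(dend, specific, config.barrier_cut)
    for m in macro:
        m.particle_site = macrostate_modal_site(m, net)
        m.label = chain.label_of_site(m.particle_site)
    report = promoter_report(
        macro, p_ns, seq_id=seq.id, known_tss=config.known_tss,
        metadata={"version": __version__, "seed": config.sim.seed,
                  "n_nodes": net.n_nodes, "n_basins": len(basins),
                  "n_specific": len(specific)})
    _stage("fel", t0, basins=len(basins), specific=len(specific),
           macrostates=len(macro))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_trajectories(out_dir / "run.h5", trajs, chain,
                          config.params, config.sim)
        net.write_graphml(out_dir / "network.graphml")
        net.write_tsv(out_dir / "nodes.tsv", out_dir / "edges.tsv")
        (out_dir / "dendrogram.json").write_text(dend.to_json())
        (out_dir / "dendrogram.nwk").write_text(dend.to_newick())
        (out_dir / "report.tsv").write_text(report.to_tsv())
        (out_dir / "report.json").write_text(report.to_json())
        config.to_json(out_dir / "config.json")
    return AnalysisResult(report=report, profile=profile, chain=chain,
                          pca=pca, network=net, basins=basins,
                          dendrogram=dend)


def analyze_gene_chain_only(seq: PromoterSequence, config: RunConfig,
                            regions: dict,
                            n_components: int = 4) -> dict:
    """Chain-only (no particle) analysis of a whole gene: simulate the bare
    breathing dynamics and report where the leading PCA eigenvectors
    localize over the labeled regions.

    ``regions`` maps region names (e.g. "promoter", "coding") to half-open
    (start, stop) ranges in sequence coordinates; any particle-coupling
    override in the config is ignored — the coupling is always off here.
    """
    if not regions:
        raise ValueError("region labels required (e.g. promoter/coding ranges)")
    params = config.params.with_(A_p=0.0)
    chain = encode(seq, clamp_len=config.clamp_len)
    trajs, _ = run_ensemble(chain, params, config.sim)
    # second moment about the closed state: the first mode is then the mean
    # breathing profile of the gene, and localized modes follow it
    pca = fit_pca(trajs, chain.analysis_mask, center=False)
    shifted = {name: (start + config.clamp_len, stop + config.clamp_len)
               for name, (start, stop) in regions.items()}
    loc = eigenvector_localization(pca, shifted, n_components=n_components)
    return {"localization": loc, "pca": pca, "chain": chain,
            "explained_first": [float(f) for f in
                                pca.explained_fraction[:n_components]]}


def localization_table(loc: dict) -> str:
    """TSV rendering of an eigenvector-localization result."""
    regions = sorted(next(iter(loc.values()))["shares"])
    lines = ["component\tparticipation_ratio\t" + "\t".join(regions)]
    for c, row in sorted(loc.items()):
        shares = "\t".join(f"{row['shares'][r]:.4f}" for r in regions)
        lines.append(f"{c}\t{row['participation_ratio']:.2f}\t{shares}")
    return "\n".join(lines) + "\n"
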