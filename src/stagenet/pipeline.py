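"""Per-stage orchestration: screen -> build network -> centrality -> modules
-> enrichment, with TSV/GraphML artifact export and table verification.

`run_stage` / `run_all` are the library entry points; the command-line
interface wraps them thinly.  `verify_tables` recomputes consensus hubs and
hub drivers from externally transcribed top-15 ranking columns, which is how
published centrality tables are checked without rebuilding their networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import __version__
from .centrality import CentralityReport, centrality_report, consensus_hubs, hub_drivers
from .driver_screen import ScreeningFunnel, StagePredictions, run_funnel
from .enrichment import EnrichmentRecord, enrich
from .io_formats import GeneSetCollection, Graph, write_graphml
from .module_decomposition import ModuleDecomposition, decompose
from .network_builder import (DegreeFit, StageNetwork, TopologySummary,
                              build_stage_network, degree_distribution,
                              fit_power_law, topology_summary)

__all__ = [
    "PipelineConfig",
    "StageReport",
    "run_stage",
    "run_all",
    "verify_tables",
    "EXIT_OK",
    "EXIT_CONFIG_ERROR",
    "EXIT_DATA_ERROR",
    "EXIT_DEGENERATE",
]

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3
EXIT_DEGENERATE = 4


@dataclass
class PipelineConfig:
    """Everything a full run needs; numeric defaults match the modules."""

    min_tools: int = 3
    subtract_mode: str = "previous"
    n_partners: int = 20
    interaction_types: tuple | None = None
    top_k: int = 15
    membership_threshold: float = 0.3
    restart: float = 0.15
    q_threshold: float = 0.05
    seed: int = 0
    outdir: Path | None = None


@dataclass
class StageReport:
    """All artifacts of one stage's analysis."""

    stage: str
    novel_drivers: set[str]
    network: StageNetwork | None = None
    degree_fit: DegreeFit | None = None
    topology: TopologySummary | None = None
    centrality: CentralityReport | None = None
    modules: ModuleDecomposition | None = None
    enrichment: list[EnrichmentRecord] = field(default_factory=list)
    status: str = "ok"
    log: dict = field(default_factory=dict)

    @property
    def hub_driver_genes(self) -> set[str]:
        return self.centrality.hub_driver_genes if self.centrality else set()


def run_stage(stage: str, novel_drivers: set[str], interactome: Graph,
              annotations: Mapping[str, set[str]] | None = None,
              config: PipelineConfig | None = None) -> StageReport:
    """Analyze one stage from its novel driver seeds.

    An empty seed set yields a report with ``status="no seeds"`` rather than
    an error — a stage can legitimately contribute no novel drivers.
    """
    config = config or PipelineConfig()
    report = StageReport(stage=stage, novel_drivers=set(novel_drivers))
    report.log = {"stage": stage, "version": __version__,
                  "params": {"n_partners": config.n_partners,
                             "top_k": config.top_k,
                             "restart": config.restart,
                             "membership_threshold": config.membership_threshold,
                             "q_threshold": config.q_threshold,
                             "seed": config.seed}}
    if not novel_drivers:
        report.status = "no seeds"
        return report

    network = build_stage_network(
        novel_drivers, interactome, n_partners=config.n_partners,
        interaction_types=config.interaction_types, stage=stage)
    report.network = network
    graph = network.graph

    hist = degree_distribution(graph)
    if sum(1 for k, c in hist.items() if k > 0 and c > 0) >= 2:
        report.degree_fit = fit_power_law(hist)
    report.topology = topology_summary(graph)
    report.centrality = centrality_report(
        graph, driver_seeds=network.seeds, k=config.top_k)
    report.modules = decompose(
        graph, driver_seeds=network.seeds, hubs=report.centrality.hubs,
        restart=config.restart, threshold=config.membership_threshold)
    if annotations:
        report.enrichment = enrich(
            graph.nodes, annotations, q_threshold=config.q_threshold,
            hubs=report.centrality.hubs)
    if config.outdir is not None:
        _write_stage_artifacts(report, Path(config.outdir))
    return report


def run_all(predictions: StagePredictions, interactome: Graph,
            background: set[str] | None = None,
            census: set[str] | None = None,
            annotations: Mapping[str, set[str]] | None = None,
            config: PipelineConfig | None = None,
            skip_first_stage: bool = True
            ) -> tuple[ScreeningFunnel, dict[str, StageReport]]:
    """Screen all stages, then analyze each stage after the first.

    The first stage anchors the subtraction and, as in the staging design,
    is not itself analyzed unless ``skip_first_stage=False``.
    """
    config = config or PipelineConfig()
    funnel = run_funnel(predictions, background=background, census=census,
                        min_tools=config.min_tools,
                        subtract_mode=config.subtract_mode)
    reports: dict[str, StageReport] = {}
    stages = predictions.stages[1:] if skip_first_stage else predictions.stages
    for stage in stages:
        reports[stage] = run_stage(
            stage, funnel.novel_drivers(stage), interactome,
            annotations=annotations, config=config)
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        funnel.to_frame().to_csv(outdir / "funnel.tsv", sep="\t", index=False)
    return funnel, reports


def _write_stage_artifacts(report: StageReport, outdir: Path) -> None:
    outdir = outdir / f"stage_{report.stage}"
    outdir.mkdir(parents=True, exist_ok=True)
    if report.network is not None:
        write_graphml(report.network.graph, outdir / "network.graphml")
        with open(outdir / "nodes.tsv", "w") as fh:
            fh.write("gene\tis_seed\n")
            for n in report.network.graph.sorted_nodes():
                fh.write(f"{n}\t{int(n in report.network.seeds)}\n")
    if report.centrality is not None:
        rep = report.centrality
        rows = []
        hubs_sorted = sorted(rep.hubs)
        hd_sorted = sorted(rep.hub_driver_genes)
        for i in range(rep.k):
            rows.append({
                "rank": i + 1,
                "betweenness": _at(rep.top["betweenness"], i),
                "closeness": _at(rep.top["closeness"], i),
                "bottleneck": _at(rep.top["bottleneck"], i),
                "consensus_hubs": _at(hubs_sorted, i),
                "hub_drivers": _at(hd_sorted, i),
            })
        pd.DataFrame(rows).to_csv(outdir / "centrality.tsv", sep="\t",
                                  index=False)
    if report.modules is not None:
        rows = [{"centre": m.center,
                 "effective_size": round(m.effective_size, 2),
                 "driver_members": ",".join(m.driver_members),
                 "hub_members": ",".join(m.hub_members)}
                for m in report.modules.modules]
        pd.DataFrame(rows).to_csv(outdir / "modules.tsv", sep="\t", index=False)
    if report.enrichment:
        rows = [{"term": r.term, "q_value": r.q_value,
                 "coverage_gt_20pct": r.coverage_flag,
                 "description": r.description,
                 "hub_genes": ",".join(r.hub_members),
                 "other_genes": ",".join(r.other_members)}
                for r in report.enrichment]
        pd.DataFrame(rows).to_csv(outdir / "enrichment.tsv", sep="\t",
                                  index=False)


def _at(seq, i):
    return seq[i] if i < len(seq) else ""


@dataclass
class TableVerification:
    """Consensus hubs recomputed from transcribed top-k ranking columns."""

    hubs: set[str]
    hub_driver_genes: set[str]
    non_driver_hubs: set[str]
    warnings: list[str] = field(default_factory=list)

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.hubs), len(self.hub_driver_genes),
                len(self.non_driver_hubs))


def verify_tables(rankings: Mapping[str, Iterable[str]] | str | Path,
                  drivers: Iterable[str] | str | Path | None = None,
                  expect_k: int = 15) -> TableVerification:
    """Recompute hub calls from transcribed ranking columns.

    ``rankings`` is either a mapping metric -> ranked gene list or a TSV path
    with columns ``betweenness``, ``closeness``, ``bottleneck``; ``drivers``
    is a gene collection or one-gene-per-line file.  Columns whose length is
    not ``expect_k`` produce a warning, not an error.
    """
    if isinstance(rankings, (str, Path)):
        frame = pd.read_csv(rankings, sep="\t")
        cols = {}
        for metric in ("betweenness", "closeness", "bottleneck"):
            if metric not in frame.columns:
                raise ValueError(f"rankings file lacks column {metric!r}")
            cols[metric] = [str(g).strip().upper()
                            for g in frame[metric].dropna() if str(g).strip()]
    else:
        cols = {m: [str(g).strip().upper() for g in lst]
                for m, lst in rankings.items()}

    warns = [f"column {m!r} has {len(lst)} entries, expected {expect_k}"
             for m, lst in cols.items() if len(lst) != expect_k]
    hubs = consensus_hubs(*cols.values())

    driver_set: set[str] = set()
    if drivers is not None:
        if isinstance(drivers, (str, Path)):
            from .io_formats import read_gene_list
            driver_set = read_gene_list(drivers)
        else:
            driver_set = {str(g).strip().upper() for g in drivers}
    hd = hub_drivers(hubs, driver_set)
    return TableVerification(hubs=hubs, hub_driver_genes=hd,
                             non_driver_hubs=hubs - hd, warnings=warns)
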