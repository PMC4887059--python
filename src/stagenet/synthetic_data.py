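"""Synthetic input bundles with known ground truth.

The generator emulates the study conditions the pipeline was designed for:
a four-stage tumour cohort in which eight driver-prediction tools emit
per-stage gene calls, a scale-free interactome, and flattened GO-style
annotations.  Planted structure gives every downstream step a recoverable
truth:

* per-stage true driver sets with a pan-stage "common driver" core (callable
  from the pooled cohort, hence screened out as background), partial
  carryover of drivers between consecutive stages (removed by stage
  subtraction), and stage-specific novel drivers;
* designated **hub driver** genes per stage — planted module centers wired
  to a dense neighbourhood inside the interactome, the genes the end-to-end
  pipeline should re-discover as hubs;
* one planted annotation term per stage concentrated on that stage's module
  genes, which the enrichment step should flag.

Tool error is modelled as independent per-gene sensitivity plus uniform
false positives; the pooled-cohort background run sees stage-specific
drivers at a diluted sensitivity, emulating the signal loss when a stage's
samples are a minority of the pooled cohort.  Everything is deterministic
given the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .driver_screen import StagePredictions
from .io_formats import (GeneSetCollection, Graph, write_edge_list, write_gmt,
                         write_gene_list)

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "make_truth",
    "simulate_interactome",
    "simulate_tool_calls",
    "simulate_pooled_calls",
    "simulate_annotations",
    "make_census",
    "generate_scenario",
    "STAGE_LABELS",
]

STAGE_LABELS = ("I", "II", "III", "IV")


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic scenario; defaults are the study conditions
    the generator emulates (4 stages, 8 tools, tens of drivers per stage)."""

    n_genes: int = 1000
    n_stages: int = 4
    n_tools: int = 8
    n_common_drivers: int = 20          # pan-stage drivers -> background
    stage_driver_counts: tuple = (30, 25, 25, 25)  # new specific per stage
    stage_overlap_fraction: float = 0.25  # carryover from previous stage
    tool_sensitivity: float = 0.9
    tool_fpr: float = 0.005             # expected FPs per tool = fpr*n_genes
    pooled_dilution: float = 0.1        # sensitivity factor in the pooled run
    n_census: int = 40
    census_overlaps_truth: bool = False  # adversarial switch for the filter
    interactome_edges_per_node: int = 2
    n_planted_modules: int = 3           # per stage after the first
    planted_module_size: int = 12
    module_density: float = 0.8
    center_extra_links: int = 18         # fringe genes per center
    n_partners: int = 80                 # stage-network expansion size
    n_go_terms: int = 50
    enriched_term_overlap: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stages < 2:
            raise ValueError("n_stages must be >= 2")
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if len(self.stage_driver_counts) != self.n_stages:
            raise ValueError("stage_driver_counts must have n_stages entries")
        for p in (self.stage_overlap_fraction, self.tool_sensitivity,
                  self.tool_fpr, self.pooled_dilution, self.module_density):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if max(self.stage_driver_counts) > self.n_genes:
            raise ValueError("more drivers than genes")

    @property
    def stages(self) -> list[str]:
        return list(STAGE_LABELS[:self.n_stages]) if self.n_stages <= 4 else \
            [f"S{i+1}" for i in range(self.n_stages)]

    @property
    def tools(self) -> list[str]:
        return [f"tool{i+1}" for i in range(self.n_tools)]


@dataclass
class GroundTruth:
    """Planted structure of a scenario."""

    genes: list[str]
    common_drivers: set[str]
    stage_drivers: dict[str, set[str]]          # full truth per stage
    stage_new_drivers: dict[str, set[str]]      # stage-specific novel part
    hub_drivers: dict[str, list[str]]           # planted module centers
    module_members: dict[str, list[str]]        # center -> member genes
    planted_terms: dict[str, str]               # stage -> term name
    census: set[str] = field(default_factory=set)

    def all_planted_hub_drivers(self) -> set[str]:
        out: set[str] = set()
        for centers in self.hub_drivers.values():
            out.update(centers)
        return out


def _rng(config: ScenarioConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng((config.seed * 1_000_003 + salt) % (2**31))


def make_truth(config: ScenarioConfig) -> GroundTruth:
    """Draw per-stage driver sets, planted centers and module members."""
    rng = _rng(config, 1)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    # drivers are drawn from the peripheral part of the attachment order:
    # early (hub, housekeeping-like) interactome genes are not plausible
    # novel stage drivers, and the planted modules must not collide with
    # the scale-free core
    n_core = config.n_genes // 10
    pool = list(rng.permutation(genes[n_core:]))

    def take(k: int) -> list[str]:
        if k > len(pool):
            raise ValueError(
                "gene pool exhausted: reduce driver/module counts or "
                "increase n_genes")
        out, rest = pool[:k], pool[k:]
        pool[:] = rest
        return out

    common = set(take(config.n_common_drivers))
    stages = config.stages

    stage_new: dict[str, set[str]] = {}
    stage_full: dict[str, set[str]] = {}
    prev_specific: set[str] = set()
    for stage, k in zip(stages, config.stage_driver_counts):
        carry_n = int(round(config.stage_overlap_fraction * len(prev_specific)))
        carry = set(rng.choice(sorted(prev_specific), size=carry_n,
                               replace=False)) if carry_n else set()
        new = set(take(k))
        stage_new[stage] = new
        stage_full[stage] = common | carry | new
        prev_specific = new | carry

    hub_drivers: dict[str, list[str]] = {}
    module_members: dict[str, list[str]] = {}
    for stage in stages[1:]:
        new_sorted = sorted(stage_new[stage])
        centers = [str(c) for c in rng.choice(
            new_sorted, size=min(config.n_planted_modules, len(new_sorted)),
            replace=False)]
        hub_drivers[stage] = centers
        # members: a few co-driver genes from the same stage, rest from the
        # untouched pool, so partner expansion pulls the module together
        # driver members are disjoint across the stage's modules, so no
        # member accumulates the degree of several dense neighbourhoods
        others = list(rng.permutation([g for g in new_sorted
                                       if g not in centers]))
        for center in centers:
            n_drv = min(4, len(others))
            drv_members = [str(others.pop()) for _ in range(n_drv)]
            non_drv = take(config.planted_module_size - len(drv_members))
            module_members[center] = drv_members + non_drv

    planted_terms = {stage: f"PLANTED_{stage}" for stage in stages[1:]}
    return GroundTruth(
        genes=genes, common_drivers=common, stage_drivers=stage_full,
        stage_new_drivers=stage_new, hub_drivers=hub_drivers,
        module_members=module_members, planted_terms=planted_terms)


def simulate_interactome(config: ScenarioConfig,
                         truth: GroundTruth | None = None) -> Graph:
    """Preferential-attachment interactome with planted dense neighbourhoods.

    The scale-free backbone grows one node at a time, each new node
    attaching to ``interactome_edges_per_node`` distinct degree-weighted
    targets.  Each planted center is then wired to all of its module members
    and to ``center_extra_links`` peripheral genes (a hub interacts beyond
    its dense neighbourhood), and members are interlinked with probability
    ``module_density``.
    """
    if truth is None:
        truth = make_truth(config)
    rng = _rng(config, 2)
    m = config.interactome_edges_per_node
    genes = truth.genes
    g = Graph()

    # connected core, then preferential attachment via the repeated-nodes trick
    core = genes[:m + 1]
    for i in range(len(core)):
        for j in range(i + 1, len(core)):
            g.add_edge(core[i], core[j], 1.0, "ppi")
    repeated: list[str] = [n for i, n in enumerate(core)
                           for _ in range(m)]
    for node in genes[m + 1:]:
        targets: set[str] = set()
        while len(targets) < m:
            targets.add(repeated[rng.integers(len(repeated))])
        for t in sorted(targets):
            g.add_edge(node, t, 1.0, "ppi")
            repeated.append(t)
            repeated.append(node)

    etypes = ("physical", "ppi", "predicted")
    all_module_genes: set[str] = set()
    for members in truth.module_members.values():
        all_module_genes.update(members)
    all_drivers: set[str] = set(truth.common_drivers)
    for s in truth.stage_drivers.values():
        all_drivers |= s
    # peripheral, non-driver genes available as extra center partners
    periphery_pool = sorted(set(genes[len(genes) // 2:])
                            - all_drivers - all_module_genes)
    for stage, centers in truth.hub_drivers.items():
        for center in centers:
            # planted interactions carry confidence weight 2.0: a curated
            # module's edges rest on more evidence than background links
            members = truth.module_members[center]
            for mem in members:
                g.add_edge(center, mem, 2.0, "physical")
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    if rng.random() < config.module_density:
                        g.add_edge(members[i], members[j], 2.0,
                                   str(rng.choice(etypes)))
            # a planted hub driver interacts beyond its dense core: a fringe
            # of peripheral genes, each touching the center and one member,
            # gives the center the degree excess and subtended neighbourhood
            # of a real hub
            if config.center_extra_links and periphery_pool:
                extra = rng.choice(periphery_pool,
                                   size=min(config.center_extra_links,
                                            len(periphery_pool)),
                                   replace=False)
                for p in extra:
                    g.add_edge(center, str(p), 2.0, "predicted")
                    # geometric number of member contacts: most fringe genes
                    # touch the center only, a few reach deeper, giving the
                    # low-degree tail a smooth decay
                    n_mem = int(rng.geometric(0.5)) - 1
                    for mem in rng.choice(members,
                                          size=min(n_mem, len(members)),
                                          replace=False):
                        g.add_edge(str(p), str(mem), 2.0, "predicted")

    comps = g.connected_components()
    if len(comps) > 1:  # pragma: no cover - construction keeps it connected
        import warnings
        warnings.warn("interactome disconnected; returning largest component")
        g = g.subgraph(comps[0])
    return g


def _tool_call(rng: np.random.Generator, truth_set: set[str],
               non_drivers: list[str], sensitivity: float,
               fpr: float, n_genes: int) -> set[str]:
    called = {g for g in sorted(truth_set) if rng.random() < sensitivity}
    n_fp = rng.binomial(n_genes, fpr)
    n_fp = min(n_fp, len(non_drivers))
    if n_fp:
        called |= {str(g) for g in rng.choice(non_drivers, size=n_fp,
                                              replace=False)}
    return called


def simulate_tool_calls(config: ScenarioConfig,
                        truth: GroundTruth) -> StagePredictions:
    """Per-stage, per-tool driver calls: true drivers kept with
    ``tool_sensitivity``, false positives uniform over non-drivers with
    expected count ``tool_fpr * n_genes`` per tool."""
    rng = _rng(config, 3)
    stages = list(truth.stage_drivers)
    calls: dict[str, dict[str, set[str]]] = {}
    for stage in stages:
        truth_set = truth.stage_drivers[stage]
        non_drivers = sorted(set(truth.genes) - truth_set)
        calls[stage] = {
            tool: _tool_call(rng, truth_set, non_drivers,
                             config.tool_sensitivity, config.tool_fpr,
                             config.n_genes)
            for tool in config.tools
        }
    return StagePredictions(stages=stages, calls=calls)


def simulate_pooled_calls(config: ScenarioConfig,
                          truth: GroundTruth) -> dict[str, set[str]]:
    """Tool calls on the pooled cohort (all stages together).

    Common drivers are seen at full sensitivity; stage-specific drivers are
    diluted by ``pooled_dilution`` because any one stage's samples are a
    minority of the pool.
    """
    rng = _rng(config, 4)
    specific = set()
    for s in truth.stage_drivers.values():
        specific |= s
    specific -= truth.common_drivers
    non_drivers = sorted(set(truth.genes) - truth.common_drivers - specific)
    diluted = config.tool_sensitivity * config.pooled_dilution
    out: dict[str, set[str]] = {}
    for tool in config.tools:
        called = {g for g in sorted(truth.common_drivers)
                  if rng.random() < config.tool_sensitivity}
        called |= {g for g in sorted(specific) if rng.random() < diluted}
        n_fp = min(rng.binomial(config.n_genes, config.tool_fpr),
                   len(non_drivers))
        if n_fp:
            called |= {str(g) for g in rng.choice(non_drivers, size=n_fp,
                                                  replace=False)}
        out[tool] = called
    return out


def make_census(config: ScenarioConfig, truth: GroundTruth) -> set[str]:
    """Known-cancer-gene exclusion list.

    Drawn from genes outside every planted truth set by default so the
    census screen cannot destroy planted structure; the adversarial switch
    lets it swallow half of each stage's novel drivers instead, for testing
    the filter itself.
    """
    rng = _rng(config, 5)
    all_truth = set(truth.common_drivers)
    for s in truth.stage_drivers.values():
        all_truth |= s
    free = sorted(set(truth.genes) - all_truth)
    census = {str(g) for g in rng.choice(
        free, size=min(config.n_census, len(free)), replace=False)}
    if config.census_overlaps_truth:
        for stage, new in truth.stage_new_drivers.items():
            hit = sorted(set(new) - truth.all_planted_hub_drivers())
            census |= set(hit[: len(hit) // 2])
    truth.census = census
    return census


def simulate_annotations(config: ScenarioConfig, truth: GroundTruth,
                         interactome: Graph) -> GeneSetCollection:
    """Random annotation terms plus one planted enriched term per stage.

    The planted term holds ``enriched_term_overlap`` genes of the stage's
    first planted module plus random padding, so the module's network is
    strongly over-represented for it.
    """
    rng = _rng(config, 6)
    genes = truth.genes
    coll = GeneSetCollection()
    for i in range(config.n_go_terms):
        size = int(rng.integers(10, 41))
        coll[f"TERM{i:03d}"] = {str(g) for g in rng.choice(
            genes, size=size, replace=False)}
    for stage, term in truth.planted_terms.items():
        center = truth.hub_drivers[stage][0]
        module = [center] + truth.module_members[center]
        picked = [str(g) for g in rng.choice(
            module, size=min(config.enriched_term_overlap, len(module)),
            replace=False)]
        pad = [str(g) for g in rng.choice(
            sorted(set(genes) - set(module)), size=7, replace=False)]
        coll[term] = set(picked) | set(pad)
    return coll


def generate_scenario(config: ScenarioConfig, outdir: str | Path,
                      force: bool = False) -> GroundTruth:
    """Write a complete scenario bundle and return its ground truth.

    Files: per-stage tool-call GMTs, interactome edge list, annotation GMT,
    census and background gene lists, a truth TSV and the config as a plain
    key-value file.  Refuses to write into a non-empty directory unless
    ``force`` is given.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"output directory {outdir} is not empty "
                              "(pass force=True to overwrite)")
    outdir.mkdir(parents=True, exist_ok=True)

    truth = make_truth(config)
    interactome = simulate_interactome(config, truth)
    predictions = simulate_tool_calls(config, truth)
    pooled = simulate_pooled_calls(config, truth)
    census = make_census(config, truth)
    annotations = simulate_annotations(config, truth, interactome)

    from .driver_screen import consensus_drivers
    background = consensus_drivers(pooled, min_tools=3)

    for stage in predictions.stages:
        write_gmt(predictions.calls[stage],
                  outdir / f"calls_stage_{stage}.gmt")
    write_edge_list(interactome, outdir / "interactome.tsv")
    write_gmt(annotations, outdir / "annotations.gmt")
    write_gene_list(census, outdir / "census.txt")
    write_gene_list(background, outdir / "background.txt")

    with open(outdir / "truth.tsv", "w") as fh:
        for stage, drivers in truth.stage_drivers.items():
            fh.write(f"stage_drivers\t{stage}\t" + ",".join(sorted(drivers)) + "\n")
        for stage, centers in truth.hub_drivers.items():
            fh.write(f"hub_drivers\t{stage}\t" + ",".join(centers) + "\n")
        for center, members in truth.module_members.items():
            fh.write(f"module\t{center}\t" + ",".join(members) + "\n")
        for stage, term in truth.planted_terms.items():
            fh.write(f"planted_term\t{stage}\t{term}\n")
    with open(outdir / "config.txt", "w") as fh:
        for key, value in asdict(config).items():
            fh.write(f"{key}: {value}\n")
    return truth
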