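"""Consensus-and-screening funnel from per-tool driver calls to novel drivers.

The funnel, applied per tumour stage in order:

1. **consensus** — keep genes called by at least ``min_tools`` of the
   driver-prediction tools for that stage;
2. **stage subtraction** — remove the consensus drivers of the immediately
   preceding stage, isolating drivers specific to the progression step;
3. **background screen** — remove drivers found when the whole cohort is
   pooled regardless of stage (non-specific drivers);
4. **census screen** — remove previously catalogued cancer genes, leaving
   novel stage-specific candidates.

Every step is a set operation, so later sets are always subsets of earlier
ones and the per-stage cardinalities are non-increasing along the funnel.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "StagePredictions",
    "StageFunnelRow",
    "ScreeningFunnel",
    "consensus_drivers",
    "stage_subtract",
    "background_screen",
    "census_screen",
    "pooled_background",
    "run_funnel",
]


@dataclass
class StagePredictions:
    """Ordered stage label -> tool name -> called gene set."""

    stages: list[str]
    calls: dict[str, dict[str, set[str]]]

    def __post_init__(self) -> None:
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stage labels must be unique")
        missing = [s for s in self.stages if s not in self.calls]
        if missing:
            raise ValueError(f"no calls for stages: {missing}")

    def tools(self, stage: str) -> list[str]:
        return sorted(self.calls[stage])


@dataclass
class StageFunnelRow:
    stage: str
    consensus: set[str]
    after_subtraction: set[str]
    after_background: set[str]
    after_census: set[str]

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (len(self.consensus), len(self.after_subtraction),
                len(self.after_background), len(self.after_census))


@dataclass
class ScreeningFunnel:
    """Gene-set snapshots after each screening step, one row per stage."""

    rows: dict[str, StageFunnelRow] = field(default_factory=dict)

    def novel_drivers(self, stage: str) -> set[str]:
        return self.rows[stage].after_census

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for stage, row in self.rows.items():
            c = row.counts
            recs.append({"stage": stage, "consensus": c[0],
                         "after_subtraction": c[1], "after_background": c[2],
                         "after_census": c[3]})
        return pd.DataFrame(recs)


def consensus_drivers(calls: Mapping[str, Iterable[str]],
                      min_tools: int = 3) -> set[str]:
    """Genes called by at least ``min_tools`` of the supplied tools."""
    if min_tools < 1:
        raise ValueError("min_tools must be >= 1")
    if len(calls) < min_tools:
        raise ValueError(
            f"need >= {min_tools} tools, got {len(calls)}")
    counts: Counter[str] = Counter()
    for genes in calls.values():
        counts.update(set(genes))
    return {g for g, c in counts.items() if c >= min_tools}


def stage_subtract(consensus_by_stage: Mapping[str, set[str]],
                   order: Sequence[str] | None = None,
                   mode: str = "previous") -> dict[str, set[str]]:
    """Per-stage set minus the reference stage's consensus set.

    ``mode="previous"`` (default) subtracts the immediately preceding stage;
    ``mode="stage1"`` subtracts the first stage from every later stage.  The
    first stage passes through unchanged.
    """
    if mode not in ("previous", "stage1"):
        raise ValueError(f"unknown subtract mode {mode!r}")
    stages = list(order) if order is not None else list(consensus_by_stage)
    if not stages:
        return {}
    out: dict[str, set[str]] = {stages[0]: set(consensus_by_stage[stages[0]])}
    for i, stage in enumerate(stages[1:], start=1):
        ref = stages[i - 1] if mode == "previous" else stages[0]
        out[stage] = set(consensus_by_stage[stage]) - set(consensus_by_stage[ref])
    return out


def background_screen(stage_set: set[str], background: set[str]) -> set[str]:
    """Remove drivers also found in the pooled-cohort background."""
    return set(stage_set) - set(background)


def census_screen(stage_set: set[str], census: set[str]) -> set[str]:
    """Remove known cancer genes (Cancer Gene Census style exclusion list)."""
    return set(stage_set) - set(census)


def pooled_background(predictions: StagePredictions,
                      min_tools: int = 3) -> set[str]:
    """Background driver set from pooling all stages: per tool, the union of
    its calls over every stage, then the usual >= ``min_tools`` consensus."""
    pooled: dict[str, set[str]] = {}
    for stage in predictions.stages:
        for tool, genes in predictions.calls[stage].items():
            pooled.setdefault(tool, set()).update(genes)
    return consensus_drivers(pooled, min_tools=min_tools)


def run_funnel(predictions: StagePredictions,
               background: set[str] | None = None,
               census: set[str] | None = None,
               min_tools: int = 3,
               subtract_mode: str = "previous") -> ScreeningFunnel:
    """Run the full screening funnel over all stages in order.

    If ``background`` is not supplied it is computed from the pooled
    predictions via :func:`pooled_background`.
    """
    census = census or set()
    consensus = {s: consensus_drivers(predictions.calls[s], min_tools)
                 for s in predictions.stages}
    if background is None:
        background = pooled_background(predictions, min_tools)
    subtracted = stage_subtract(consensus, order=predictions.stages,
                                mode=subtract_mode)
    funnel = ScreeningFunnel()
    for stage in predictions.stages:
        after_bg = background_screen(subtracted[stage], background)
        after_census = census_screen(after_bg, census)
        funnel.rows[stage] = StageFunnelRow(
            stage=stage,
            consensus=consensus[stage],
            after_subtraction=subtracted[stage],
            after_background=after_bg,
            after_census=after_census,
        )
    return funnel
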