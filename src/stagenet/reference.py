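"""Bundled reference tables for the colorectal-cancer worked examples.

Small transcriptions of the published per-stage centrality rankings
(top-15 genes by betweenness, closeness and bottleneck centrality for the
stage II/III/IV colon-adenocarcinoma networks) and the novel driver genes
among their consensus hubs.  They let the hub-calling logic be exercised as
a worked example: intersecting the three ranking columns must reproduce the
published consensus-hub and hub-driver gene sets.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["REFERENCE_STAGES", "load_rankings", "load_driver_hubs"]

REFERENCE_STAGES = ("II", "III", "IV")


def _data_path(name: str) -> Path:
    return Path(resources.files("stagenet").joinpath("data", name))


def load_rankings(stage: str) -> dict[str, list[str]]:
    """Top-15 ranking columns for one stage: metric -> ranked gene list."""
    if stage not in REFERENCE_STAGES:
        raise ValueError(f"no reference rankings for stage {stage!r}")
    frame = pd.read_csv(_data_path(f"stage_{stage}_rankings.tsv"), sep="\t")
    return {m: frame[m].tolist()
            for m in ("betweenness", "closeness", "bottleneck")}


def load_driver_hubs(stage: str) -> set[str]:
    """Published novel driver genes among the stage's consensus hubs."""
    if stage not in REFERENCE_STAGES:
        raise ValueError(f"no reference driver list for stage {stage!r}")
    with open(_data_path(f"stage_{stage}_drivers.txt")) as fh:
        return {line.strip() for line in fh if line.strip()}
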