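"""Consensus driver screening: from per-tool calls to novel stage drivers.

Four stages, three mock tools.  A gene must be called by at least three
tools to reach consensus; each stage then loses the previous stage's
drivers, the pooled-cohort background and the known-cancer-gene census.
"""

from stagenet import StagePredictions, run_funnel

calls = {
    "I":   {"toolA": {"APC", "KRAS"}, "toolB": {"APC", "KRAS"},
            "toolC": {"APC", "KRAS", "XPO1"}},
    "II":  {"toolA": {"APC", "GRM1", "DYNC1H1"},
            "toolB": {"APC", "GRM1", "DYNC1H1", "TTN"},
            "toolC": {"APC", "GRM1", "DYNC1H1"}},
    "III": {"toolA": {"GRM1", "IGF1R", "CPS1"},
            "toolB": {"GRM1", "IGF1R", "CPS1"},
            "toolC": {"IGF1R", "CPS1", "MUC16"}},
    "IV":  {"toolA": {"GSK3B"}, "toolB": {"GSK3B"}, "toolC": {"GSK3B"}},
}
predictions = StagePredictions(stages=["I", "II", "III", "IV"], calls=calls)

funnel = run_funnel(predictions,
                    background={"TTN", "MUC16"},   # pooled-cohort drivers
                    census={"APC", "KRAS"})        # known cancer genes

print(funnel.to_frame().to_string(index=False))
print()
for stage in ("II", "III", "IV"):
    print(f"novel stage-{stage} drivers:",
          ", ".join(sorted(funnel.novel_drivers(stage))) or "(none)")

# The counts shrink monotonically along each row: consensus calling, then
# subtraction of the previous stage, background and census screening.  The
# surviving genes are the stage-specific novel driver candidates that seed
# the network reconstruction.
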