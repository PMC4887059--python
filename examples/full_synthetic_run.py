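"""End-to-end run on the default synthetic scenario with planted truth.

Generates four stages of tool calls over a 1000-gene scale-free
interactome with planted hub-driver modules, runs screening, network
construction, centrality, module decomposition and enrichment, and
compares the output against the planted ground truth.
"""

import warnings

from stagenet import PipelineConfig, consensus_drivers, run_all
from stagenet.synthetic_data import (ScenarioConfig, make_census, make_truth,
                                     simulate_annotations,
                                     simulate_interactome,
                                     simulate_pooled_calls,
                                     simulate_tool_calls)

config = ScenarioConfig(seed=0)
truth = make_truth(config)
interactome = simulate_interactome(config, truth)
predictions = simulate_tool_calls(config, truth)
background = consensus_drivers(simulate_pooled_calls(config, truth))
census = make_census(config, truth)
annotations = simulate_annotations(config, truth, interactome)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    funnel, reports = run_all(
        predictions, interactome, background=background, census=census,
        annotations=annotations,
        config=PipelineConfig(n_partners=config.n_partners))

print(funnel.to_frame().to_string(index=False))
planted = truth.all_planted_hub_drivers()
recovered = set()
for stage, rep in reports.items():
    recovered |= rep.hub_driver_genes
    fit = rep.degree_fit
    print(f"\nstage {stage}: network {rep.network.graph.number_of_nodes()} "
          f"nodes / {rep.network.graph.number_of_edges()} edges; "
          f"power-law R2={fit.r_squared:.2f} vs linear {fit.linear_r_squared:.2f}")
    print(f"  hub drivers found: {', '.join(sorted(rep.hub_driver_genes))}")
    print(f"  planted:           {', '.join(sorted(truth.hub_drivers[stage]))}")
    best = rep.enrichment[0]
    print(f"  top enriched term: {best.term} (q={best.q_value:.2e})")

pct = 100 * len(recovered & planted) / len(planted)
print(f"\nplanted hub-driver recovery: {len(recovered & planted)}/"
      f"{len(planted)} ({pct:.0f}%)")

# Every stage's degree distribution prefers the power law over the linear
# fit, the planted enrichment term tops each stage's GO table, and the
# pipeline recovers (nearly) all planted hub-driver genes.
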