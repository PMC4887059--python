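import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from stagenet.driver_screen import consensus_drivers
from stagenet.io_formats import Graph
from stagenet.pipeline import PipelineConfig, run_all
from stagenet.synthetic_data import (ScenarioConfig, make_census, make_truth,
                                     simulate_annotations,
                                     simulate_interactome,
                                     simulate_pooled_calls,
                                     simulate_tool_calls)


def build_graph(edges, isolated=()):
    g = Graph()
    for n in isolated:
        g.add_node(n)
    for e in edges:
        g.add_edge(*e)
    return g


@pytest.fixture(scope="session")
def default_scenario():
    """Default synthetic scenario (seed 0) with full pipeline output."""
    config = ScenarioConfig(seed=0)
    truth = make_truth(config)
    interactome = simulate_interactome(config, truth)
    predictions = simulate_tool_calls(config, truth)
    background = consensus_drivers(simulate_pooled_calls(config, truth))
    census = make_census(config, truth)
    annotations = simulate_annotations(config, truth, interactome)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        funnel, reports = run_all(
            predictions, interactome, background=background, census=census,
            annotations=annotations,
            config=PipelineConfig(n_partners=config.n_partners))
    return {
        "config": config, "truth": truth, "interactome": interactome,
        "predictions": predictions, "background": background,
        "census": census, "annotations": annotations,
        "funnel": funnel, "reports": reports,
    }
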