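"""Scenario generator: determinism, planted structure, error models."""

import filecmp

import numpy as np
import pytest
from scipy import stats

from stagenet.driver_screen import consensus_drivers
from stagenet.io_formats import read_edge_list, read_gene_list, read_gmt
from stagenet.network_builder import degree_distribution, fit_power_law
from stagenet.synthetic_data import (ScenarioConfig, generate_scenario,
                                     make_census, make_truth,
                                     simulate_annotations,
                                     simulate_interactome,
                                     simulate_tool_calls)

SMALL = dict(n_genes=300, n_common_drivers=8,
             stage_driver_counts=(10, 8, 8, 8), n_planted_modules=2,
             planted_module_size=6, center_extra_links=4, n_go_terms=10)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            ScenarioConfig(n_stages=1, stage_driver_counts=(5,))
        with pytest.raises(ValueError):
            ScenarioConfig(tool_sensitivity=1.4)
        with pytest.raises(ValueError):
            ScenarioConfig(stage_driver_counts=(5, 5))

    def test_stage_labels(self):
        assert ScenarioConfig().stages == ["I", "II", "III", "IV"]


class TestTruth:
    def test_planted_centers_are_stage_drivers(self):
        truth = make_truth(ScenarioConfig(seed=5))
        for stage, centers in truth.hub_drivers.items():
            assert set(centers) <= truth.stage_drivers[stage]
            assert set(centers) <= truth.stage_new_drivers[stage]

    def test_stage_overlap_carries_previous_drivers(self):
        config = ScenarioConfig(seed=2, stage_overlap_fraction=0.5)
        truth = make_truth(config)
        stages = config.stages
        for prev, cur in zip(stages, stages[1:]):
            carried = (truth.stage_drivers[cur] - truth.common_drivers
                       - truth.stage_new_drivers[cur])
            assert carried <= truth.stage_drivers[prev]
            assert carried  # 0.5 of 25+ previous specific drivers is > 0

    def test_census_disjoint_from_all_planted_truth(self):
        config = ScenarioConfig(seed=4)
        truth = make_truth(config)
        census = make_census(config, truth)
        for drivers in truth.stage_drivers.values():
            assert not census & drivers

    def test_adversarial_census_hits_novel_drivers_but_not_centers(self):
        config = ScenarioConfig(seed=4, census_overlaps_truth=True)
        truth = make_truth(config)
        census = make_census(config, truth)
        hit = set()
        for new in truth.stage_new_drivers.values():
            hit |= new & census
        assert hit
        assert not census & truth.all_planted_hub_drivers()


class TestInteractome:
    def test_deterministic_given_seed(self):
        config = ScenarioConfig(seed=42, **SMALL)
        g1 = simulate_interactome(config)
        g2 = simulate_interactome(config)
        assert g1 == g2

    def test_different_seeds_differ(self):
        g1 = simulate_interactome(ScenarioConfig(seed=1, **SMALL))
        g2 = simulate_interactome(ScenarioConfig(seed=2, **SMALL))
        assert g1 != g2

    def test_connected(self):
        g = simulate_interactome(ScenarioConfig(seed=3, **SMALL))
        assert len(g.connected_components()) == 1

    def test_scale_free_tail_on_large_run(self):
        config = ScenarioConfig(seed=7, n_genes=2000)
        fit = fit_power_law(degree_distribution(simulate_interactome(config)))
        assert fit.r_squared >= 0.7
        assert fit.exponent < -1.0

    def test_planted_center_degree_at_least_module_size(self):
        config = ScenarioConfig(seed=9)
        truth = make_truth(config)
        g = simulate_interactome(config, truth)
        for centers in truth.hub_drivers.values():
            for c in centers:
                assert g.degree(c) >= config.planted_module_size


class TestToolCalls:
    def test_perfect_sensitivity_no_fp_equals_truth(self):
        config = ScenarioConfig(seed=1, tool_sensitivity=1.0, tool_fpr=0.0)
        truth = make_truth(config)
        preds = simulate_tool_calls(config, truth)
        for stage in preds.stages:
            for tool_set in preds.calls[stage].values():
                assert tool_set == truth.stage_drivers[stage]

    def test_zero_sensitivity_no_fp_all_empty(self):
        config = ScenarioConfig(seed=1, tool_sensitivity=0.0, tool_fpr=0.0)
        truth = make_truth(config)
        preds = simulate_tool_calls(config, truth)
        assert all(not s for stage in preds.stages
                   for s in preds.calls[stage].values())

    def test_consensus_fraction_matches_binomial_tail(self):
        """With sensitivity 0.8 and 8 tools the fraction of true drivers
        called by >=3 tools matches the exact binomial tail P(X>=3)."""
        config = ScenarioConfig(
            seed=8, n_genes=2000, n_common_drivers=0,
            stage_driver_counts=(500, 1, 1, 1), stage_overlap_fraction=0.0,
            tool_sensitivity=0.8, tool_fpr=0.0, n_planted_modules=1,
            planted_module_size=4, center_extra_links=0, n_go_terms=1)
        truth = make_truth(config)
        preds = simulate_tool_calls(config, truth)
        stage = preds.stages[0]
        consensus = consensus_drivers(preds.calls[stage], min_tools=3)
        frac = len(consensus & truth.stage_drivers[stage]) / 500
        expected = 1.0 - stats.binom.cdf(2, 8, 0.8)   # ~0.9988
        assert frac == pytest.approx(expected, abs=3 * np.sqrt(
            expected * (1 - expected) / 500) + 1e-9)

    def test_two_seeds_give_different_false_positives(self):
        fps = []
        for seed in (1, 2):
            config = ScenarioConfig(seed=seed, tool_sensitivity=1.0,
                                    tool_fpr=0.02)
            truth = make_truth(ScenarioConfig(seed=1, tool_sensitivity=1.0,
                                              tool_fpr=0.02))
            preds = simulate_tool_calls(config, truth)
            stage = preds.stages[0]
            fps.append(frozenset(
                g for s in preds.calls[stage].values()
                for g in s - truth.stage_drivers[stage]))
        # ~20 FP draws from ~900 genes: collision probability is negligible
        assert fps[0] != fps[1]


class TestAnnotations:
    def test_planted_term_overlaps_module(self):
        config = ScenarioConfig(seed=5)
        truth = make_truth(config)
        inter = simulate_interactome(config, truth)
        ann = simulate_annotations(config, truth, inter)
        for stage, term in truth.planted_terms.items():
            center = truth.hub_drivers[stage][0]
            module = {center} | set(truth.module_members[center])
            assert len(ann[term] & module) >= config.enriched_term_overlap

    def test_deterministic(self):
        config = ScenarioConfig(seed=5)
        truth = make_truth(config)
        inter = simulate_interactome(config, truth)
        assert simulate_annotations(config, truth, inter) == \
            simulate_annotations(config, truth, inter)

    def test_planted_term_hypergeometric_p_below_1e4(self, default_scenario):
        """Against the stage network, the planted term's raw hypergeometric
        p-value is far below 1e-4 under the default scenario."""
        for stage, rep in default_scenario["reports"].items():
            term = default_scenario["truth"].planted_terms[stage]
            rec = next(r for r in rep.enrichment if r.term == term)
            assert rec.p_value < 1e-4


class TestScenarioBundle:
    def test_bundle_round_trips_and_is_byte_deterministic(self, tmp_path):
        config = ScenarioConfig(seed=11, **SMALL)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        t1 = generate_scenario(config, d1)
        generate_scenario(config, d2)
        for name in ("interactome.tsv", "annotations.gmt", "census.txt",
                     "background.txt", "truth.tsv", "config.txt",
                     "calls_stage_I.gmt", "calls_stage_IV.gmt"):
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name
        g = read_edge_list(d1 / "interactome.tsv")
        assert g == simulate_interactome(config, t1)
        assert read_gene_list(d1 / "census.txt") == t1.census
        calls = read_gmt(d1 / "calls_stage_II.gmt")
        assert set(calls) == {f"tool{i+1}" for i in range(config.n_tools)}

    def test_refuses_non_empty_directory(self, tmp_path):
        (tmp_path / "junk.txt").write_text("x")
        with pytest.raises(FileExistsError):
            generate_scenario(ScenarioConfig(seed=1, **SMALL), tmp_path)
        generate_scenario(ScenarioConfig(seed=1, **SMALL), tmp_path,
                          force=True)

    def test_planted_hub_drivers_appear_in_stage_calls(self, tmp_path):
        config = ScenarioConfig(seed=13, **SMALL)
        truth = generate_scenario(config, tmp_path / "s")
        for stage, centers in truth.hub_drivers.items():
            calls = read_gmt(tmp_path / "s" / f"calls_stage_{stage}.gmt")
            called = set().union(*calls.values())
            # sensitivity 0.9 over 8 tools: a center is all but surely called
            assert set(centers) <= called
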