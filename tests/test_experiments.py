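"""Environments, genotype experiments, ranking, dose-response."""

import numpy as np
import pandas as pd
import pytest

from cav1net.engine import SimulationConfig
from cav1net.environments import (CATEGORY_RANGES, CONDITIONS,
                                  build_environment, fixed_environment,
                                  sample_environment)
from cav1net.experiments import (DoseResponseCurve, ExperimentResult,
                                 GenotypeCondition, dose_response,
                                 monotonicity_score, rank_most_affected,
                                 run_experiment)
from cav1net.network import parse_rules_text


class TestEnvironmentTable:
    def test_wild_type_categories(self):
        spec = build_environment("Tissue_WT")
        assert spec.categories["ECM"] == "High"
        assert spec.categories["GP130"] == "Zero"
        assert spec.categories["IL4"] == "Low"
        assert spec.categories["IL10"] == "Med"

    def test_disease_b_il10_full_range(self):
        assert build_environment("Tissue_DiseaseB").categories["IL10"] == "FullRange"

    def test_disease_a_il2_high(self):
        assert build_environment("Tissue_DiseaseA").categories["IL2"] == "High"

    def test_ecm_high_everywhere_gp130_zero_everywhere(self):
        for cond in CONDITIONS:
            spec = build_environment(cond)
            assert spec.categories["ECM"] == "High"
            assert spec.categories["GP130"] == "Zero"

    def test_all_29_stimuli_present(self):
        spec = build_environment("Tissue_WT")
        assert len(spec.categories) == 29
        assert "Alpha_13L" in spec.categories and "TGFB" in spec.categories

    def test_unknown_condition_names_valid_ones(self):
        with pytest.raises(ValueError, match="Tissue_WT"):
            build_environment("Blood_WT")


class TestSampling:
    def test_zero_category_always_zero(self, rng):
        spec = build_environment("Tissue_WT")
        for _ in range(50):
            assert sample_environment(spec, rng)["GP130"] == 0.0

    def test_full_range_mean_near_fifty(self):
        spec = build_environment("Tissue_DiseaseB")
        rng = np.random.default_rng(0)
        draws = [sample_environment(spec, rng)["IL10"] for _ in range(10000)]
        assert abs(np.mean(draws) - 50.0) < 2.0

    def test_category_range_containment(self, rng):
        spec = build_environment("Tissue_WT")
        for _ in range(200):
            levels = sample_environment(spec, rng)
            for stim, cat in spec.categories.items():
                lo, hi = CATEGORY_RANGES[cat]
                assert lo <= levels[stim] <= hi

    def test_fixed_mode_pins_levels(self, rng):
        spec = build_environment("Tissue_WT")
        levels = sample_environment(spec, rng, mode="fixed")
        assert levels["ECM"] == 90.0 and levels["IL10"] == 50.0
        assert levels["IL4"] == 25.0 and levels["GP130"] == 0.0

    def test_fixed_environment_draw_free(self):
        assert fixed_environment("Tissue_WT")["ECM"] == 90.0


SMALL = SimulationConfig(total_iterations=200, window=100, seed=17)


class TestRunExperiment:
    def test_ko_target_exactly_zero(self, compiled_reference):
        res = run_experiment(compiled_reference, build_environment("Tissue_WT"),
                             GenotypeCondition("KO"), SMALL, n_simulations=50)
        assert (res.activities["CAV1"] == 0.0).all()

    def test_het50_target_near_fifty(self, compiled_reference):
        res = run_experiment(compiled_reference, build_environment("Tissue_WT"),
                             GenotypeCondition("Het50"),
                             SimulationConfig(seed=18), n_simulations=300)
        assert abs(res.summary().loc["CAV1", "mean"] - 50.0) < 1.0

    def test_same_seed_identical_summaries(self, compiled_reference):
        spec = build_environment("Tissue_WT")
        a = run_experiment(compiled_reference, spec, GenotypeCondition("WT"),
                           SMALL, n_simulations=20)
        b = run_experiment(compiled_reference, spec, GenotypeCondition("WT"),
                           SMALL, n_simulations=20)
        pd.testing.assert_frame_equal(a.summary(), b.summary())

    def test_too_few_simulations_rejected(self, compiled_reference):
        with pytest.raises(ValueError):
            run_experiment(compiled_reference, build_environment("Tissue_WT"),
                           GenotypeCondition("WT"), SMALL, n_simulations=1)

    def test_random_activation_levels_vary(self, compiled_reference):
        res = run_experiment(compiled_reference, build_environment("Tissue_WT"),
                             GenotypeCondition("RandomActivation"), SMALL,
                             n_simulations=40)
        cav1 = res.activities["CAV1"]
        assert cav1.std() > 10.0  # per-simulation forced levels spread widely

    def test_unknown_genotype_rejected(self):
        with pytest.raises(ValueError):
            GenotypeCondition("Hemi")


def _result(means, n=10):
    """Fabricate an ExperimentResult with exact mean activities."""
    df = pd.DataFrame({k: np.full(n, v, dtype=float) for k, v in means.items()})
    return ExperimentResult("cond", "WT", df, seed=0)


class TestRanking:
    def test_single_shifted_node_ranks_first(self):
        base = _result({"X": 50.0, "Y": 50.0, "Z": 50.0})
        cond = _result({"X": 90.0, "Y": 50.0, "Z": 50.0})
        table = rank_most_affected(cond, base)
        assert table.iloc[0]["node"] == "X"
        assert table.iloc[0]["delta"] == pytest.approx(40.0)

    def test_all_ties_ordered_lexicographically(self):
        base = _result({"B": 10.0, "A": 20.0, "C": 30.0})
        table = rank_most_affected(base, base)
        assert list(table["node"]) == ["A", "B", "C"]
        assert (table["delta"] == 0.0).all()

    def test_top_k_by_absolute_delta_signed_preserved(self):
        base = _result({"A": 50.0, "B": 50.0, "C": 50.0})
        cond = _result({"A": 60.0, "B": 20.0, "C": 70.0})
        table = rank_most_affected(cond, base, k=2)
        assert list(table["node"]) == ["B", "C"]
        assert table.iloc[0]["delta"] == pytest.approx(-30.0)
        assert table.iloc[1]["delta"] == pytest.approx(20.0)

    def test_mismatched_node_sets_rejected(self):
        with pytest.raises(ValueError):
            rank_most_affected(_result({"A": 1.0}), _result({"B": 1.0}))


class TestDoseResponse:
    def test_identity_chain_tracks_input(self, tiny_chain):
        cfg = SimulationConfig(seed=19)
        curve = dose_response(tiny_chain, "E", "A",
                              grid=[0.0, 25.0, 50.0, 75.0, 100.0],
                              reps=30, config=cfg, background={})
        for level, resp in zip(curve.grid, curve.responses):
            p = level / 100.0
            se4 = 4 * 100 * np.sqrt(p * (1 - p) / (300 * 30))
            assert abs(resp - level) <= se4 + 1e-9

    def test_zero_input_pure_activation_zero_output(self, tiny_chain):
        curve = dose_response(tiny_chain, "E", "B", grid=[0.0, 100.0],
                              reps=5, config=SimulationConfig(seed=20),
                              background={})
        assert curve.responses[0] == 0.0

    def test_non_external_input_rejected(self, tiny_chain):
        with pytest.raises(ValueError, match="external"):
            dose_response(tiny_chain, "A", "B")

    def test_same_seed_same_curve(self, tiny_chain):
        cfg = SimulationConfig(seed=21)
        c1 = dose_response(tiny_chain, "E", "A", grid=[0, 50, 100], reps=5,
                           config=cfg, background={})
        c2 = dose_response(tiny_chain, "E", "A", grid=[0, 50, 100], reps=5,
                           config=cfg, background={})
        assert (c1.responses == c2.responses).all()

    def test_grid_must_increase(self):
        with pytest.raises(ValueError):
            DoseResponseCurve("E", "A", np.array([0.0, 0.0, 10.0]),
                              np.zeros(3), np.zeros(3), 5)


def _spearman_avg_rank(x, y):
    """Brute-force Spearman: Pearson of average ranks."""
    def ranks(v):
        v = np.asarray(v, dtype=float)
        r = np.empty(len(v))
        for i, vi in enumerate(v):
            less = (v < vi).sum()
            equal = (v == vi).sum()
            r[i] = less + (equal + 1) / 2.0
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


class TestMonotonicityScore:
    def test_strictly_increasing_is_one(self):
        assert monotonicity_score(([0, 50, 100], [10, 40, 80])) == pytest.approx(1.0)

    def test_strictly_decreasing_is_minus_one(self):
        assert monotonicity_score(([0, 50, 100], [80, 40, 10])) == pytest.approx(-1.0)

    def test_tied_responses_match_rank_formula(self):
        grid, resp = [0, 50, 100], [10, 10, 80]
        expected = _spearman_avg_rank(grid, resp)  # = sqrt(3)/2
        assert monotonicity_score((grid, resp)) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(np.sqrt(3) / 2, abs=1e-12)

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError):
            monotonicity_score(([0, 100], [0, 100]))
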