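"""Scenario transforms, paired replicates, and replicate summaries."""

import numpy as np
import pandas as pd
import pytest

from vpop.experiments import ScenarioSpec, apply_disparity_reduction, grid_table, \
    prepare_baseline, replicate_deltas, run_counterfactual, run_experiment_grid, \
    run_replicate, summarize, with_nonpa_minutes


class TestScenarioTransform:
    def test_elimination_lifts_female_days_to_male_levels(self, params):
        out = apply_disparity_reduction(params, ScenarioSpec(("pa_days",), 1.0))
        assert out.activity.active_days["female"]["12-17"].mean == 3.68
        assert out.activity.active_days["female"]["6-11"].mean == 4.16
        # male values and female spread untouched
        assert out.activity.active_days["male"]["12-17"].mean == 3.68
        assert out.activity.active_days["female"]["12-17"].sd == 0.07

    def test_zero_fraction_is_identity(self, params):
        out = apply_disparity_reduction(params, ScenarioSpec(("pa_days",), 0.0))
        assert out.to_dict() == params.to_dict()

    def test_half_fraction_is_midpoint(self, params):
        out = apply_disparity_reduction(params, ScenarioSpec(("pa_days",), 0.5))
        assert out.activity.active_days["female"]["12-17"].mean == pytest.approx(3.375)

    def test_sports_participation_elimination_matches_male_level(self, params):
        out = apply_disparity_reduction(params,
                                        ScenarioSpec(("sports_participation",), 1.0))
        assert out.sports.participation["female"] == pytest.approx(0.402)

    def test_intensity_dimension_moves_met_mean(self, params):
        out = apply_disparity_reduction(params, ScenarioSpec(("pa_intensity",), 1.0))
        assert out.activity.intensity_met["female"].mean == pytest.approx(5.3)

    def test_input_params_never_mutated(self, params):
        before = params.to_dict()
        apply_disparity_reduction(params, ScenarioSpec(("pa_days", "pa_intensity"), 1.0))
        assert params.to_dict() == before

    def test_unknown_dimension_rejected(self):
        with pytest.raises(ValueError, match="unknown dimensions"):
            ScenarioSpec(("pa_dayz",), 1.0)

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            ScenarioSpec(("pa_days",), 1.5)

    def test_nonpa_override_applies_to_both_sexes(self, params):
        out = with_nonpa_minutes(params, 0.0)
        assert out.activity.nonactive_day_minutes == {"male": 0.0, "female": 0.0}


class TestPairedReplicates:
    def test_null_scenario_gives_exactly_zero_deltas(self, params):
        paired = run_replicate(params, params, scale=5e-5, seed=13)
        deltas = replicate_deltas(paired)
        assert np.all(deltas["value"].to_numpy() == 0.0)

    def test_deltas_reproduce_bit_identically(self, params):
        scen = apply_disparity_reduction(params, ScenarioSpec(("pa_days",), 1.0))
        a = replicate_deltas(run_replicate(params, scen, 1e-4, seed=14,
                                           include_adult=False))
        b = replicate_deltas(run_replicate(params, scen, 1e-4, seed=14,
                                           include_adult=False))
        assert a.equals(b)

    def test_total_row_is_sum_of_age_groups(self, params):
        scen = apply_disparity_reduction(params, ScenarioSpec(("pa_days",), 1.0))
        d = replicate_deltas(run_replicate(params, scen, 2e-4, seed=15))
        for outcome, sub in d.groupby("outcome"):
            by = dict(zip(sub["age_group"], sub["value"]))
            if outcome == "prevalence_change_pp":
                continue
            assert by["total"] == pytest.approx(by["6-11"] + by["12-17"], abs=1e-9)

    def test_common_random_numbers_shrink_paired_variance(self, params):
        # paired (same cohort, same streams) vs unpaired (cross-seed) contrasts
        # of the female mean BMI at 18; CRN removes the cohort-sampling noise
        scen = apply_disparity_reduction(params, ScenarioSpec(("pa_days",), 1.0))
        seeds = [31, 32, 33, 34, 35, 36]
        base_means, scen_means, paired_deltas = [], [], []
        for s in seeds:
            prep = prepare_baseline(params, 2e-4, s, include_adult=False)
            paired = run_counterfactual(prep, scen, s)
            female = (prep.cohort.df["sex"] == "female").to_numpy()
            b = prep.base_child.bmi[female].mean()
            c = paired.scen_child.bmi[female].mean()
            base_means.append(b)
            scen_means.append(c)
            paired_deltas.append(b - c)
        unpaired = [base_means[i] - scen_means[(i + 1) % len(seeds)]
                    for i in range(len(seeds))]
        assert np.var(paired_deltas) < np.var(unpaired)


class TestSummaries:
    @staticmethod
    def _rep(value):
        return pd.DataFrame([{"outcome": "x", "age_group": "total", "value": value}])

    def test_identical_replicates_give_zero_width_ci(self):
        s = summarize([self._rep(50.0)] * 5, scale=0.01)
        row = s.table.iloc[0]
        assert row["mean"] == row["ci_lo"] == row["ci_hi"] == pytest.approx(5000.0)

    def test_counts_scale_linearly_to_national_size(self):
        s = summarize([self._rep(50.0), self._rep(50.0)], scale=0.01)
        assert s.value("x") == pytest.approx(5000.0)

    def test_rates_are_not_scaled(self):
        rep = pd.DataFrame([{"outcome": "prevalence_change_pp", "age_group": "total",
                             "value": 0.4}])
        s = summarize([rep, rep], scale=0.01)
        assert s.value("prevalence_change_pp") == pytest.approx(0.4)

    def test_fewer_than_two_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            summarize([self._rep(1.0)], scale=0.1)

    def test_percentile_ci_covers_the_truth_at_nominal_rate(self):
        rng = np.random.default_rng(99)
        mu, sigma, n_rep = 10.0, 3.0, 25
        covered = 0
        trials = 200
        for _ in range(trials):
            reps = [self._rep(rng.normal(mu, sigma)) for _ in range(n_rep)]
            s = summarize(reps, scale=1.0)
            row = s.table.iloc[0]
            covered += row["ci_lo"] <= mu <= row["ci_hi"]
        assert 0.85 <= covered / trials <= 0.995

    def test_grid_table_flattens_fraction_axis(self, params):
        scen = {0.5: summarize([self._rep(1.0), self._rep(3.0)], 1.0),
                1.0: summarize([self._rep(2.0), self._rep(6.0)], 1.0)}
        t = grid_table(scen)
        assert set(t["fraction"]) == {0.5, 1.0}
        assert {"outcome", "mean", "ci_lo", "ci_hi"} <= set(t.columns)


class TestGrid:
    def test_small_grid_runs_and_orders_effects(self, params):
        summaries = run_experiment_grid(
            params, dimensions=("pa_days",), fractions=(0.0, 1.0), scale=2e-4,
            n_replicates=3, base_seed=17, include_adult=False)
        zero = summaries[0.0].value("overweight_obesity_cases_averted")
        full = summaries[1.0].value("overweight_obesity_cases_averted")
        assert zero == 0.0
        assert full >= 0.0
        assert full >= zero
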