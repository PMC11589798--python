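"""Cohort synthesis: apportionment, body-composition marginals, calibration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vpop.population import CalibrationError, build_cohort, calibrate_to_prevalence, \
    measured_prevalence, sample_body_composition, stratum_counts
from vpop.params import STRATA


class TestApportionment:
    def test_full_scale_reproduces_national_counts(self, params):
        counts = stratum_counts(params, 1.0)
        assert counts == {("male", "6-11"): 2078664, ("female", "6-11"): 1992402,
                          ("male", "12-17"): 2161455, ("female", "12-17"): 2066832}

    def test_one_per_mille_hand_derived(self, params):
        # floors 2078+1992+2161+2066 = 8297; the two leftover units go to the
        # largest fractional remainders (.832 then .664)
        counts = stratum_counts(params, 1e-3)
        assert counts == {("male", "6-11"): 2079, ("female", "6-11"): 1992,
                          ("male", "12-17"): 2161, ("female", "12-17"): 2067}
        assert sum(counts.values()) == 8299

    @given(st.floats(min_value=1e-6, max_value=1.0))
    def test_totals_conserved_for_any_scale(self, scale):
        import vpop
        params = vpop.load_params()
        counts = stratum_counts(params, scale)
        assert abs(sum(counts.values()) - scale * params.demography.total) <= 1.0
        assert all(c >= 0 for c in counts.values())

    @pytest.mark.parametrize("scale", [0.0, -0.5, 1.5])
    def test_invalid_scale_rejected(self, params, scale):
        with pytest.raises(ValueError, match="scale"):
            stratum_counts(params, scale)


class TestBodyComposition:
    def test_stratum_marginal_mean_matches_published_value(self, params, ref):
        rng = np.random.default_rng(0)
        ffm, _ = sample_body_composition("male", "12-17", params.body_composition,
                                         rng, n=100_000, growth_ref=ref)
        assert ffm.mean() == pytest.approx(52.94, abs=0.2)

    def test_zero_sd_returns_the_mean_exactly(self, params):
        bc = params.copy().body_composition
        bc.fat_free_mass_kg["male"]["6-11"].sd = 0.0
        bc.age_scaling = False
        rng = np.random.default_rng(1)
        ffm, _ = sample_body_composition("male", "6-11", bc, rng, n=500)
        assert np.all(ffm == 26.12)

    def test_all_draws_strictly_positive(self, params, ref):
        rng = np.random.default_rng(2)
        for sex, group in STRATA:
            ffm, fm = sample_body_composition(sex, group, params.body_composition,
                                              rng, n=200_000, growth_ref=ref)
            assert np.all(ffm > 0) and np.all(fm > 0)

    def test_negative_sd_rejected(self, params):
        bc = params.copy().body_composition
        bc.fat_mass["female"]["6-11"].sd = -1.0
        with pytest.raises(ValueError, match="SD"):
            sample_body_composition("female", "6-11", bc, np.random.default_rng(0), n=10)


class TestCohortBuild:
    def test_same_seed_gives_bit_identical_cohort(self, params):
        a = build_cohort(params, 2e-4, seed=5)
        b = build_cohort(params, 2e-4, seed=5)
        assert a.df.equals(b.df)

    def test_different_seed_gives_different_cohort(self, params):
        a = build_cohort(params, 2e-4, seed=5)
        b = build_cohort(params, 2e-4, seed=6)
        assert not a.df["fm_kg"].equals(b.df["fm_kg"])

    def test_cohort_round_trips_through_csv(self, params, tmp_path):
        from vpop.population import Cohort
        a = build_cohort(params, 1e-4, seed=5)
        path = tmp_path / "cohort.csv"
        a.to_csv(path)
        b = Cohort.from_csv(path, scale=1e-4, seed=5)
        assert len(b) == len(a)
        assert np.allclose(b.df["fm_kg"], a.df["fm_kg"])


class TestCalibration:
    def test_classified_prevalence_matches_targets(self, params):
        cohort = build_cohort(params, 2e-3, seed=3)
        prev = measured_prevalence(cohort)
        for _, row in prev.iterrows():
            t_ow = params.prevalence_targets.overweight_pct[row.sex][row.age_group].mean
            t_ob = params.prevalence_targets.obesity_pct[row.sex][row.age_group].mean
            assert row.overweight_pct == pytest.approx(t_ow, abs=1.0)
            assert row.obesity_pct == pytest.approx(t_ob, abs=1.0)

    def test_zero_targets_leave_no_one_overweight(self, params, ref):
        p = params.copy()
        for s, g in STRATA:
            p.prevalence_targets.overweight_pct[s][g].mean = 0.0
            p.prevalence_targets.overweight_pct[s][g].lo = 0.0
            p.prevalence_targets.obesity_pct[s][g].mean = 0.0
            p.prevalence_targets.obesity_pct[s][g].lo = 0.0
        cohort = build_cohort(p, 2e-4, seed=3)
        assert np.all(cohort.df["weight_category"].to_numpy() == 0)

    def test_infeasible_targets_raise(self, params, ref):
        cohort = build_cohort(params, 1e-4, seed=3, calibrate=False)
        t = params.copy().prevalence_targets
        t.overweight_pct["male"]["6-11"].mean = 60.0
        t.obesity_pct["male"]["6-11"].mean = 50.0
        with pytest.raises(CalibrationError, match="infeasible"):
            calibrate_to_prevalence(cohort, t, ref)

    def test_calibration_is_idempotent(self, params, ref):
        cohort = build_cohort(params, 1e-3, seed=4)
        again = calibrate_to_prevalence(cohort, params.prevalence_targets, ref,
                                        metabolic=params.metabolic)
        dz = np.abs(again.df["zscore"].to_numpy() - cohort.df["zscore"].to_numpy())
        assert np.quantile(dz, 0.99) < 0.05

    def test_calibration_preserves_rank_order_of_body_mass(self, params, ref):
        raw = build_cohort(params, 1e-3, seed=4, calibrate=False)
        cal = calibrate_to_prevalence(raw, params.prevalence_targets, ref,
                                      metabolic=params.metabolic)
        fm_floor = params.metabolic.fat_mass_floor_kg
        ffm_floor = params.metabolic.fat_free_mass_floor_kg
        for sex, group in STRATA:
            mask = cal.stratum_mask(sex, group)
            unfloored = mask & (cal.df["fm_kg"] > fm_floor + 1e-9).to_numpy() \
                & (cal.df["ffm_kg"] > ffm_floor + 1e-9).to_numpy()
            before = raw.df.loc[unfloored, "zscore"].to_numpy()
            after = cal.df.loc[unfloored, "zscore"].to_numpy()
            # sorted by the pre-calibration z order, the calibrated z must be
            # non-decreasing wherever the physiologic mass floors did not bind
            assert np.all(np.diff(after[np.argsort(before)]) >= -1e-12)
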