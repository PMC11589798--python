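"""Adult Markov progression: onsets, complications, mortality, coupling."""

import numpy as np
import pytest

from vpop.disease import DiseaseParameterError, HealthState, annual_transition, \
    annual_transition_kernel, compile_disease, simulate_adult_cohort, \
    simulate_adult_life


def _zeroed_disease(params):
    """Copy of the disease parameters with every rate set to zero."""
    q = params.copy().disease
    for c in q.conditions.values():
        for s in ("male", "female"):
            for band in c.incidence[s]:
                c.incidence[s][band] = 0.0
        c.excess_mortality = 0.0
    q.gompertz_a = 1e-300
    return q


def _single_hazard(params, condition="diabetes", h=0.05, rr=1.0):
    q = _zeroed_disease(params)
    for s in ("male", "female"):
        for band in q.conditions[condition].incidence[s]:
            q.conditions[condition].incidence[s][band] = h
    q.conditions[condition].rr = {"healthy": 1.0, "overweight": rr, "obesity": rr}
    return q


class TestAnnualTransition:
    def test_zero_rates_change_nothing_but_age(self, params):
        dis = _zeroed_disease(params)
        state = HealthState(age=40, active={})
        out = annual_transition(state, 2, "female", dis, np.random.default_rng(0))
        assert out.age == 41 and out.alive
        assert not any(out.active.values())

    def test_certain_incidence_fires_in_one_step(self, params):
        dis = _single_hazard(params, "diabetes", 1.0)
        out = annual_transition(HealthState(age=30, active={}), 0, "male", dis,
                                np.random.default_rng(0))
        assert out.active["diabetes"]

    def test_dead_agents_are_rejected(self, params):
        with pytest.raises(ValueError, match="living"):
            annual_transition(HealthState(age=30, active={}, alive=False), 0,
                              "male", params.disease, np.random.default_rng(0))

    def test_onset_frequency_matches_incidence_times_rr(self, params):
        dis = _single_hazard(params, "diabetes", 0.02, rr=2.0)
        tables = compile_disease(dis)
        n = 100_000
        active = np.zeros((n, tables.n_conditions), bool)
        alive = np.ones(n, bool)
        u = np.random.default_rng(11).random((n, tables.draws_per_year))
        new, _, _ = annual_transition_kernel(
            30, active, alive, np.zeros(n, int), np.full(n, 2), tables, u)
        i = tables.names.index("diabetes")
        assert new[:, i].mean() == pytest.approx(0.04, abs=0.002)

    def test_complications_require_active_diabetes(self, params):
        dis = _zeroed_disease(params)
        for s in ("male", "female"):
            for band in dis.conditions["neuropathy"].incidence[s]:
                dis.conditions["neuropathy"].incidence[s][band] = 1.0
        out = annual_transition(HealthState(age=30, active={}), 0, "male", dis,
                                np.random.default_rng(0))
        assert not out.active["neuropathy"]
        out2 = annual_transition(HealthState(age=30, active={"diabetes": True}), 0,
                                 "male", dis, np.random.default_rng(0))
        assert out2.active["neuropathy"]

    def test_incidence_times_rr_above_one_rejected(self, params):
        dis = _single_hazard(params, "diabetes", 0.6)
        dis.conditions["diabetes"].rr["obesity"] = 2.0
        with pytest.raises(DiseaseParameterError, match="exceeds 1"):
            compile_disease(dis)


class TestLifetime:
    def test_background_only_death_at_max_age(self, params):
        dis = _zeroed_disease(params)
        hist = simulate_adult_life(0, "female", dis, 5)
        assert hist.death_age == dis.max_age
        assert hist.cause == "background"
        assert hist.onset_age == {}

    def test_onsets_never_after_death(self, params):
        res = simulate_adult_cohort(np.zeros(5000, int),
                                    np.random.default_rng(1).integers(0, 3, 5000),
                                    params.disease, seed=8)
        with np.errstate(invalid="ignore"):
            assert not np.any(res.onset_age > res.death_age[:, None])

    def test_unit_relative_risks_make_category_irrelevant(self, params):
        dis = params.copy().disease
        for c in dis.conditions.values():
            c.rr = {"healthy": 1.0, "overweight": 1.0, "obesity": 1.0}
        a = simulate_adult_cohort(np.zeros(2000, int), np.zeros(2000, int), dis, seed=9)
        b = simulate_adult_cohort(np.zeros(2000, int), np.full(2000, 2), dis, seed=9)
        assert np.array_equal(a.death_age, b.death_age)
        assert np.array_equal(a.onset_age, b.onset_age, equal_nan=True)

    def test_higher_relative_risk_adds_onsets_agent_by_agent(self, params):
        dis = params.copy().disease
        for c in dis.conditions.values():
            c.excess_mortality = 0.0   # keep lifespans identical across arms
        healthy = simulate_adult_cohort(np.zeros(5000, int), np.zeros(5000, int),
                                        dis, seed=10)
        obese = simulate_adult_cohort(np.zeros(5000, int), np.full(5000, 2),
                                      dis, seed=10)
        assert np.all(obese.onsets() >= healthy.onsets())
        assert obese.onsets().sum() > healthy.onsets().sum()

    def test_obese_cohort_accumulates_more_lifetime_onsets(self, params):
        healthy = simulate_adult_cohort(np.zeros(10_000, int), np.zeros(10_000, int),
                                        params.disease, seed=12)
        obese = simulate_adult_cohort(np.zeros(10_000, int), np.full(10_000, 2),
                                      params.disease, seed=12)
        assert obese.onsets().sum() > healthy.onsets().sum()

    def test_constant_hazard_onset_ages_follow_truncated_geometric(self, params):
        h = 0.05
        dis = _single_hazard(params, "diabetes", h)
        n = 20_000
        res = simulate_adult_cohort(np.zeros(n, int), np.zeros(n, int), dis, seed=3)
        onset = res.onset_age[:, list(res.names).index("diabetes")]
        k = (onset[~np.isnan(onset)] - 18).astype(int)
        years = dis.max_age - 18
        kk = np.arange(years)
        cdf_geom = (1 - (1 - h) ** (kk + 1)) / (1 - (1 - h) ** years)
        cdf_emp = np.searchsorted(np.sort(k), kk, side="right") / len(k)
        assert np.abs(cdf_emp - cdf_geom).max() < 0.015
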