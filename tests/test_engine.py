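"""Simulation engine: discounting, DALY arithmetic, competing-risk
allocation against the closed-form oracle, determinism, totals consistency,
and agreement between the Monte-Carlo and expectation modes."""

import numpy as np
import pandas as pd
import pytest

from ncdsim.engine import (
    DALYParameters,
    HealthState,
    SimulationConfig,
    competing_death_draw,
    compute_dalys,
    discounted_annuity,
    run_simulation,
    step_individual,
)
from ncdsim.errors import SimulationError


class TestAnnuity:
    @pytest.mark.parametrize("rate", [0.0, 0.03, 0.1])
    def test_single_year_is_one(self, rate):
        assert discounted_annuity(1, rate) == 1.0

    def test_zero_rate_counts_years(self):
        assert discounted_annuity(10, 0.0) == 10.0

    def test_three_percent_ten_years(self):
        assert np.isclose(discounted_annuity(10, 0.03), 8.7861, atol=5e-5)

    def test_fractional_years(self):
        assert np.isclose(
            discounted_annuity(2.5, 0.03), 1 + 1 / 1.03 + 0.5 / 1.03**2
        )

    def test_negative_inputs_rejected(self):
        with pytest.raises(SimulationError):
            discounted_annuity(-1, 0.03)
        with pytest.raises(SimulationError):
            discounted_annuity(5, -0.01)


class TestComputeDalys:
    def test_yld_closed_form(self, daly_params):
        """One person with onset in the first year, alive throughout, weight
        0.2 at 3%: YLD = 0.2 x annuity(10, 3%) ~ 1.7572."""
        dp = DALYParameters(
            disability_weights={"cvd": 0.2}, case_fatality={"cvd": 0.0},
            life_table=daly_params.life_table,
        )
        tallies = pd.DataFrame([
            {"condition": "cvd", "age_at_entry": 50, "onset_year": 0,
             "death_year": np.nan, "death_cause": np.nan}
        ])
        out = compute_dalys(tallies, dp, 0.03)
        assert np.isclose(out["cvd"], 0.2 * 8.7861, atol=1e-3)

    def test_zero_rate_equals_person_years(self, daly_params):
        tallies = pd.DataFrame([
            {"condition": "diabetes", "age_at_entry": 60, "onset_year": 3,
             "death_year": np.nan, "death_cause": np.nan}
        ])
        out = compute_dalys(tallies, daly_params, 0.0)
        assert np.isclose(out["diabetes"], daly_params.disability_weights["diabetes"] * 7)

    def test_empty_tallies_zero(self, daly_params):
        tallies = pd.DataFrame([
            {"condition": "cvd", "age_at_entry": 50, "onset_year": np.nan,
             "death_year": np.nan, "death_cause": np.nan}
        ])
        assert compute_dalys(tallies, daly_params, 0.03)["cvd"] == 0.0

    def test_death_adds_discounted_yll(self, daly_params):
        tallies = pd.DataFrame([
            {"condition": "cvd", "age_at_entry": 60, "onset_year": 1,
             "death_year": 4, "death_cause": "cvd"}
        ])
        out = compute_dalys(tallies, daly_params, 0.03)
        le = float(daly_params.life_expectancy(64))
        expected_yll = discounted_annuity(le, 0.03) * 1.03**-4
        expected_yld = daly_params.disability_weights["cvd"] * sum(
            1.03**-t for t in range(1, 4)
        )
        assert np.isclose(out["cvd"], expected_yll + expected_yld)

    def test_negative_years_rejected(self, daly_params):
        tallies = pd.DataFrame([
            {"condition": "cvd", "age_at_entry": 60, "onset_year": 0,
             "death_year": -2, "death_cause": "cvd"}
        ])
        with pytest.raises(SimulationError):
            compute_dalys(tallies, daly_params, 0.03)


class TestCompetingRisks:
    def test_allocation_matches_closed_form_at_1e6(self, rng):
        """Two causes at annual probability 0.5 each: over 10^6 draws the
        allocation fractions match h_i/sum(h) x (1 - e^-sum(h)) within three
        binomial standard errors."""
        n = 1_000_000
        h = -np.log1p(-0.5)
        hazards = np.full((n, 2), h)
        died, cause = competing_death_draw(hazards, rng.random(n), rng.random(n))
        total = 2 * h
        p_each = h / total * -np.expm1(-total)
        for k in (0, 1):
            frac = np.mean(died & (cause == k))
            se = np.sqrt(p_each * (1 - p_each) / n)
            assert abs(frac - p_each) < 3 * se

    def test_asymmetric_hazards(self, rng):
        n = 500_000
        hazards = np.column_stack([np.full(n, 0.3), np.full(n, 0.1)])
        died, cause = competing_death_draw(hazards, rng.random(n), rng.random(n))
        p0 = 0.3 / 0.4 * -np.expm1(-0.4)
        frac0 = np.mean(died & (cause == 0))
        assert abs(frac0 - p0) < 3 * np.sqrt(p0 * (1 - p0) / n)

    def test_negative_hazard_rejected(self, rng):
        with pytest.raises(SimulationError):
            competing_death_draw(np.array([[-0.1]]), rng.random(1), rng.random(1))


class TestStepIndividual:
    def test_null_hazards_leave_state_unchanged(self, rng):
        s = HealthState(active={"cvd": 0})
        out = step_individual(s, {"other_cause": 0.0, "incidence": {"diabetes": 0.0},
                                  "mortality": {"cvd": 0.0}}, rng)
        assert out.alive and out.active == {"cvd": 0}

    def test_certain_other_cause_death(self, rng):
        out = step_individual(HealthState(), {"other_cause": 1.0, "incidence": {},
                                              "mortality": {}}, rng)
        assert not out.alive and out.cause_of_death == "other"

    def test_dead_individual_unchanged(self, rng):
        dead = HealthState(alive=False, cause_of_death="cvd")
        assert step_individual(dead, {"other_cause": 1.0}, rng) is dead

    def test_incidence_only_for_inactive_conditions(self, rng):
        s = HealthState(active={"cvd": 0})
        out = step_individual(
            s, {"other_cause": 0.0, "incidence": {"cvd": 1.0, "diabetes": 1.0},
                "mortality": {"cvd": 0.0}}, rng, year=3)
        assert out.active["cvd"] == 0          # onset year not overwritten
        assert out.active["diabetes"] == 3

    def test_probability_out_of_bounds(self, rng):
        with pytest.raises(SimulationError):
            step_individual(HealthState(), {"other_cause": 1.5}, rng)


class TestRunSimulation:
    def test_null_model_produces_nothing(self, pop_small, models, daly_params):
        """With hazards and case fatality forced to zero, and no prevalent
        disease, there is no incidence, no NCD death and no DALY."""
        pop = pop_small.copy()
        pop["dx_diabetes"] = False
        pop["dx_asthma_copd"] = False
        zeroed = {c: m.with_scale(calibration_scale=0.0, fatality_scale=0.0)
                  for c, m in models.items()}
        cfg = SimulationConfig(seed=1, population_size=len(pop))
        res = run_simulation(pop, zeroed, daly_params, cfg)
        assert (res.data.to_numpy() == 0).all()

    def test_bit_identical_reruns(self, pop_small, calibrated, daly_params):
        cfg = SimulationConfig(seed=99, population_size=2000)
        a = run_simulation(pop_small, calibrated, daly_params, cfg)
        b = run_simulation(pop_small, calibrated, daly_params, cfg)
        pd.testing.assert_frame_equal(a.data, b.data)
        assert a.other_cause_deaths_per_10k == b.other_cause_deaths_per_10k

    def test_totals_row_is_exact_sum(self, pop_small, calibrated, daly_params):
        cfg = SimulationConfig(seed=4, population_size=2000)
        res = run_simulation(pop_small, calibrated, daly_params, cfg)
        table = res.to_table()
        for q in res.data.columns:
            assert table.loc["total", q] == res.data[q].sum()

    def test_expectation_matches_mc_mean(self, pop_small, calibrated, daly_params):
        """Dual route: the closed-form expectation recursion and a large
        Monte-Carlo run agree within sampling error."""
        cfg = SimulationConfig(seed=31, population_size=20_000)
        exp = run_simulation(pop_small, calibrated, daly_params, cfg, mode="expectation")
        mc = run_simulation(pop_small, calibrated, daly_params, cfg, mode="mc")
        n = 20_000
        for cond in exp.data.index:
            for q in ("incidence_per_10k", "deaths_per_10k"):
                e = exp.data.loc[cond, q]
                m = mc.data.loc[cond, q]
                p = e / 10_000
                se = np.sqrt(max(p * (1 - p), 1e-9) / n) * 10_000
                assert abs(m - e) < 4 * se + 1e-6, (cond, q)

    def test_disability_weight_monotonicity(self, pop_small, calibrated, daly_params):
        """Raising a disability weight cannot decrease total DALYs under
        common random numbers."""
        cfg = SimulationConfig(seed=8, population_size=2000)
        low = run_simulation(pop_small, calibrated, daly_params, cfg)
        heavier = DALYParameters(
            disability_weights={**daly_params.disability_weights, "cvd": 0.3},
            case_fatality=daly_params.case_fatality,
            life_table=daly_params.life_table,
            sex_multiplier=daly_params.sex_multiplier,
        )
        high = run_simulation(pop_small, calibrated, heavier, cfg)
        assert high.totals()["dalys_per_10k"] >= low.totals()["dalys_per_10k"]

    def test_mc_intervals_from_replicates(self, pop_small, calibrated, daly_params):
        cfg = SimulationConfig(seed=2, population_size=1000, replicates=3)
        res = run_simulation(pop_small, calibrated, daly_params, cfg)
        assert res.intervals is not None
        assert (res.intervals["incidence_per_10k_lo"]
                <= res.intervals["incidence_per_10k_hi"]).all()

    def test_empty_population_rejected(self, calibrated, daly_params, pop_small):
        with pytest.raises(SimulationError):
            run_simulation(pop_small.iloc[:0], calibrated, daly_params,
                           SimulationConfig(seed=1))

    def test_unknown_scenario_condition_rejected(self, pop_small, calibrated, daly_params):
        from ncdsim.interventions import InterventionSpec

        bad = InterventionSpec(who_id="x", effects=[])
        bad_models = {c: m for c, m in calibrated.items() if c != "cvd"}
        from ncdsim.interventions import Effect
        bad.effects = [Effect("cvd", "incidence_rr", 0.9)]
        with pytest.raises(SimulationError, match="unknown condition"):
            run_simulation(pop_small, bad_models, daly_params,
                           SimulationConfig(seed=1, population_size=500), scenario=bad)


def test_baseline_reproduces_published_intervals(pop_small, models, daly_params):
    """Tightly calibrated, a Monte-Carlo baseline lands inside the published
    95% interval for each condition's incidence and mortality in at least 4
    of 5 seeds."""
    from ncdsim import calibration
    from ncdsim.population import PopulationSpec, generate_population
    from ncdsim.results import baseline_panel_result

    # a population the size of the agent pool, so every seed simulates the
    # exact individuals the calibration centered on
    pop = generate_population(PopulationSpec.default(), 20_000, seed=700)
    cfg = SimulationConfig(seed=70, population_size=20_000)
    tight = calibration.calibrate_all(
        pop, models, calibration.default_targets(tolerance=0.002), cfg, daly_params
    )
    published = baseline_panel_result().intervals
    passes = {(c, q): 0 for c in published.index
              for q in ("incidence_per_10k", "deaths_per_10k")}
    n_seeds = 5
    for i in range(n_seeds):
        res = run_simulation(pop, tight, daly_params,
                             SimulationConfig(seed=70 + i, population_size=20_000))
        for cond in published.index:
            for q in ("incidence_per_10k", "deaths_per_10k"):
                v = res.data.loc[cond, q]
                if published.loc[cond, f"{q}_lo"] <= v <= published.loc[cond, f"{q}_hi"]:
                    passes[(cond, q)] += 1
    for key, k in passes.items():
        assert k >= 4, (key, k)
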