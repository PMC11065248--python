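"""Intervention library, reach curves, hazard adjustment, and the
scenario-level invariants (null invariance, mechanism locality, reach
linearity with ICER invariance)."""

import numpy as np
import pytest

from ncdsim.economics import icer
from ncdsim.engine import SimulationConfig, run_simulation
from ncdsim.errors import ConfigurationError, SimulationError
from ncdsim.interventions import (
    InterventionSpec,
    ReachCurve,
    apply_intervention,
    eligibility_mask,
    intervention_library,
    reach,
)
from ncdsim.uncertainty import reach_sweep


class TestLibrary:
    def test_nine_interventions(self):
        lib = intervention_library()
        assert len(lib) == 9
        assert set(lib) == {"1.4", "2.11", "2.13", "3.1", "3.2", "6.2", "6.3", "6.4", "7.3"}

    @pytest.mark.parametrize("who_id,key,value", [
        ("1.4", "per_person_year", 0.20),
        ("2.11", "per_person_year", 4.00),
        ("2.13", "per_person_year", 0.30),
        ("3.1", "per_person_year", 19.00),
        ("3.2", "per_person_year", 110.00),
        ("6.2", "per_person_year", 20.00),
        ("6.3", "per_incident_case", 14_736.00),
        ("6.4", "per_incident_case", 1_423.00),
        ("7.3", "per_eligible_person_year", 24.00),
    ])
    def test_published_unit_costs(self, who_id, key, value):
        assert intervention_library()[who_id].cost_model[key] == value

    def test_default_reach_is_64_percent_linear(self):
        for spec in intervention_library().values():
            assert spec.reach.final_reach == 0.64
            assert spec.reach.ramp == "linear_over_horizon"

    def test_eligibility_masks(self, pop_small):
        lib = intervention_library()
        mam = eligibility_mask(lib["6.2"], pop_small)
        expected = ((pop_small["sex"] == "female")
                    & pop_small["age"].between(50, 69)).to_numpy()
        assert (mam == expected).all()
        asthma = eligibility_mask(lib["7.3"], pop_small)
        assert (asthma == pop_small["dx_asthma_copd"].to_numpy()).all()
        assert eligibility_mask(lib["1.4"], pop_small).all()


class TestReach:
    def test_linear_ramp_reaches_final(self):
        c = ReachCurve(final_reach=0.64, ramp="linear_over_horizon")
        assert np.isclose(reach(c, 9, 10), 0.64)
        assert np.isclose(reach(c, 4, 10), 0.32)
        assert np.isclose(reach(c, 0, 10), 0.064)

    def test_zero_reach_everywhere(self):
        c = ReachCurve(final_reach=0.0)
        assert all(reach(c, t, 10) == 0.0 for t in range(10))

    def test_immediate_ramp(self):
        c = ReachCurve(final_reach=0.64, ramp="immediate")
        assert reach(c, 0, 10) == 0.64

    def test_custom_schedule(self):
        c = ReachCurve(final_reach=0.5, ramp=[0.1, 0.2, 0.5])
        assert reach(c, 1, 3) == 0.2
        with pytest.raises(ConfigurationError):
            reach(ReachCurve(final_reach=0.5, ramp=[0.5, 0.2]), 1, 2)

    def test_year_out_of_range(self):
        with pytest.raises(SimulationError):
            reach(ReachCurve(), 10, 10)

    def test_reach_bounds_validated(self):
        with pytest.raises(ConfigurationError):
            ReachCurve(final_reach=1.2)


class TestApplyIntervention:
    def probs(self):
        return {"other_cause": 0.01, "incidence": {"cvd": 0.05, "diabetes": 0.02},
                "mortality": {"cvd": 0.01}}

    def test_null_intervention_changes_nothing(self):
        spec = InterventionSpec(
            who_id="x", effects=[{"target": "cvd", "channel": "incidence_rr",
                                  "magnitude": 1.0}],
            reach=ReachCurve(final_reach=1.0, ramp="immediate"), cost_model={})
        out, cost = apply_intervention(self.probs(), spec, 0, eligible=True)
        assert cost == 0.0
        assert out["incidence"] == self.probs()["incidence"]

    def test_rate_ratio_passthrough_at_full_reach(self):
        """incidence_rr 0.9 at reach 1 multiplies the hazard by exactly 0.9."""
        spec = InterventionSpec(
            who_id="x", effects=[{"target": "cvd", "channel": "incidence_rr",
                                  "magnitude": 0.9}],
            reach=ReachCurve(final_reach=1.0, ramp="immediate"))
        out, _ = apply_intervention(self.probs(), spec, 0, eligible=True)
        h0 = -np.log1p(-0.05)
        assert np.isclose(-np.log1p(-out["incidence"]["cvd"]), 0.9 * h0, rtol=1e-12)

    def test_mixture_expectation_at_half_reach(self):
        """incidence_rr 0.9 at reach 0.5 gives the hazard multiplier 0.95."""
        spec = InterventionSpec(
            who_id="x", effects=[{"target": "cvd", "channel": "incidence_rr",
                                  "magnitude": 0.9}],
            reach=ReachCurve(final_reach=0.5, ramp="immediate"))
        out, _ = apply_intervention(self.probs(), spec, 0, eligible=True)
        h0 = -np.log1p(-0.05)
        assert np.isclose(-np.log1p(-out["incidence"]["cvd"]), 0.95 * h0, rtol=1e-12)

    def test_ineligible_gets_no_effect(self):
        spec = InterventionSpec(
            who_id="x", effects=[{"target": "cvd", "channel": "incidence_rr",
                                  "magnitude": 0.5}],
            reach=ReachCurve(final_reach=1.0, ramp="immediate"),
            cost_model={"per_person_year": 2.0})
        out, cost = apply_intervention(self.probs(), spec, 0, eligible=False)
        assert out["incidence"] == self.probs()["incidence"]
        assert cost == 2.0  # population-wide cost still accrues

    def test_nonpositive_rate_ratio_rejected(self):
        with pytest.raises(ConfigurationError):
            InterventionSpec(who_id="x", effects=[
                {"target": "cvd", "channel": "incidence_rr", "magnitude": 0.0}])

    def test_unknown_channel_rejected(self):
        with pytest.raises(ConfigurationError):
            InterventionSpec(who_id="x", effects=[
                {"target": "cvd", "channel": "bogus", "magnitude": 0.9}])


class TestScenarioInvariants:
    def test_null_intervention_exact_zero_deltas(self, pop_small, calibrated, daly_params):
        """All rate ratios 1 and zero costs: scenario deltas are exactly zero
        under common random numbers."""
        cfg = SimulationConfig(seed=6, population_size=2000)
        base = run_simulation(pop_small, calibrated, daly_params, cfg)
        null = InterventionSpec(
            who_id="null",
            effects=[{"target": c, "channel": ch, "magnitude": 1.0}
                     for c in calibrated for ch in ("incidence_rr", "mortality_rr")],
        )
        scen = run_simulation(pop_small, calibrated, daly_params, cfg, scenario=null)
        assert (scen.deltas(base).to_numpy() == 0).all()
        assert scen.cost.discounted_total == 0.0

    def test_mechanism_locality(self, pop_small, calibrated, daly_params):
        """An intervention touching only CVD leaves every other condition's
        row exactly unchanged under common random numbers."""
        cfg = SimulationConfig(seed=6, population_size=2000)
        base = run_simulation(pop_small, calibrated, daly_params, cfg)
        spec = InterventionSpec(
            who_id="cvd-only",
            effects=[{"target": "cvd", "channel": "incidence_rr", "magnitude": 0.7}],
        )
        scen = run_simulation(pop_small, calibrated, daly_params, cfg, scenario=spec)
        d = scen.deltas(base)
        others = [c for c in d.index if c != "cvd"]
        assert (d.loc[others].to_numpy() == 0).all()
        assert d.loc["cvd", "incidence_per_10k"] < 0

    def test_reach_linearity_preserves_icer(self, pop_small, calibrated, daly_params):
        """Halving final reach halves DALYs averted and reach-proportional
        costs, leaving the ICER unchanged within tolerance."""
        cfg = SimulationConfig(seed=12, population_size=2000)
        spec = InterventionSpec(
            who_id="asthma-tx",
            effects=[{"target": "asthma_copd", "channel": "mortality_rr", "magnitude": 0.6}],
            eligibility={"requires_dx": "dx_asthma_copd"},
            cost_model={"per_eligible_person_year": 24.0},
        )
        sweep = reach_sweep(pop_small, calibrated, daly_params, cfg, spec,
                            [0.32, 0.64], mode="expectation")
        averted = sweep["dalys_averted"].to_numpy()
        costs = sweep["delta_cost"].to_numpy()
        assert np.isclose(averted[1] / averted[0], 2.0, rtol=0.07)
        assert np.isclose(costs[1] / costs[0], 2.0, rtol=0.02)
        icers = sweep["icer"].to_numpy(float)
        assert np.isclose(icers[0], icers[1], rtol=0.05)

    def test_zero_reach_nullifies_effects_and_variable_costs(
        self, pop_small, calibrated, daly_params
    ):
        cfg = SimulationConfig(seed=12, population_size=1000)
        spec = InterventionSpec(
            who_id="asthma-tx",
            effects=[{"target": "asthma_copd", "channel": "incidence_rr", "magnitude": 0.5}],
            eligibility={"requires_dx": "dx_asthma_copd"},
            cost_model={"per_eligible_person_year": 24.0},
        )
        sweep = reach_sweep(pop_small, calibrated, daly_params, cfg, spec, [0.0])
        assert sweep.loc[0, "dalys_averted"] == 0.0
        assert sweep.loc[0, "delta_cost"] == 0.0
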