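"""Cost discounting, incremental cost-effectiveness ratios, willingness-to-
pay classification, and cost-effectiveness-plane export.

All monetary quantities are 2023 international dollars.  The
willingness-to-pay ceiling is three times the GDP per capita of Palestine
per DALY averted; the shipped GDP constant is set so that ceiling equals
$10,992.  ICERs compare each intervention to the status quo: discounted
incremental cost divided by discounted DALYs averted, with the usual
dominance labels when either difference changes sign.

``league_table`` supports two delta sources: scenario simulation results,
or the published burden panel (the scenario's per-condition DALY reductions
configured directly from the published change-from-baseline block, with
costs accrued from the printed unit costs over 10,000 adults).
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .engine import discounted_annuity
from .errors import ConfigurationError, NcdsimError
from .interventions import InterventionSpec, intervention_library
from .results import baseline_panel_result, load_burden_panel, panel_delta_result

__all__ = [
    "ICERResult",
    "ce_plane_export",
    "classify",
    "icer",
    "league_table",
    "panel_icer",
    "ppp_adjust",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


@functools.lru_cache(maxsize=1)
def economics_constants() -> dict:
    with resources.files("ncdsim.data").joinpath("economics.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass
class ICERResult:
    who_id: str
    delta_cost: float                 # discounted $, per 10,000 adults
    delta_dalys_averted: float        # discounted DALYs averted, per 10,000
    icer: object                      # $ per DALY averted, or a dominance label
    classification: str = ""
    ci_low: float | None = None
    ci_high: float | None = None


def icer(delta_cost: float, delta_dalys_averted: float):
    """$ per DALY averted, or a dominance label.

    Positive cost with positive aversion gives the ratio; cost <= 0 with
    aversion > 0 is ``dominant`` (saves money while averting DALYs);
    aversion <= 0 with cost > 0 is ``dominated``; 0/0 is ``undefined``.
    """
    if not (math.isfinite(delta_cost) and math.isfinite(delta_dalys_averted)):
        raise NcdsimError("icer: inputs must be finite")
    if delta_dalys_averted > 0:
        return DOMINANT if delta_cost <= 0 else delta_cost / delta_dalys_averted
    if delta_cost > 0:
        return DOMINATED
    if delta_cost == 0 and delta_dalys_averted == 0:
        return UNDEFINED
    return DOMINANT if delta_cost < 0 else UNDEFINED


def classify(icer_value, gdp_per_capita: float | None = None) -> str:
    """Band an ICER against 1x and 3x GDP per capita per DALY averted;
    boundary values fall in the lower band."""
    if gdp_per_capita is None:
        gdp_per_capita = economics_constants()["gdp_per_capita"]
    if gdp_per_capita <= 0:
        raise ConfigurationError("gdp_per_capita must be positive")
    if icer_value == DOMINANT:
        return "below_1xGDP"
    if icer_value in (DOMINATED, UNDEFINED):
        return "above_3xGDP"
    if icer_value <= gdp_per_capita:
        return "below_1xGDP"
    if icer_value <= 3 * gdp_per_capita:
        return "below_3xGDP"
    return "above_3xGDP"


def ppp_adjust(cost_foreign: float, ppp_ratio: float) -> float:
    """Convert a cost quoted in another economy by the GDP purchasing-power-
    parity per-capita ratio to Palestine."""
    if ppp_ratio <= 0:
        raise ConfigurationError("ppp_ratio must be positive")
    return cost_foreign * ppp_ratio


def _sort_key(value):
    if value == DOMINANT:
        return -math.inf
    if value in (DOMINATED, UNDEFINED):
        return math.inf
    return value


def _panel_cost(spec: InterventionSpec, horizon: int, rate: float,
                population: float = 10_000.0) -> float:
    """Discounted intervention cost per 10,000 adults from the printed unit
    costs, for delta-configured (panel) runs.

    Whole-population per-person-year costs accrue for all 10,000 adults
    every year; per-eligible costs accrue over the eligible fraction;
    per-incident-case costs accrue once per baseline incident case of the
    target condition, spread evenly over the horizon for discounting.
    """
    ann = discounted_annuity(horizon, rate)
    cm = spec.cost_model
    cost = cm.get("program_fixed", 0.0) * ann
    if "per_person_year" in cm:
        cost += cm["per_person_year"] * population * ann
    if "per_eligible_person_year" in cm:
        frac = spec.eligible_fraction
        if frac is None:
            raise ConfigurationError(
                f"{spec.who_id}: per-eligible costing needs eligible_fraction"
            )
        cost += cm["per_eligible_person_year"] * population * frac * ann
    if "per_incident_case" in cm:
        cond = spec.eligibility.get("incident_condition") or next(iter(sorted(spec.targets())))
        cases = float(load_burden_panel()["baseline"][cond]["incidence"][0])
        cost += cm["per_incident_case"] * cases * ann / horizon
    return cost


def panel_icer(spec: InterventionSpec, horizon: int = 10, rate: float = 0.03) -> ICERResult:
    """ICER for one intervention with its DALY deltas configured from the
    published burden panel and costs from the printed unit costs."""
    base = baseline_panel_result()
    scen = panel_delta_result(spec.who_id)
    averted = scen.dalys_averted(base)
    cost = _panel_cost(spec, horizon, rate)
    value = icer(cost, averted)
    # interval from the published delta interval at the configured cost
    lo = hi = None
    if scen.intervals is not None and averted > 0:
        d_lo = -float(scen.intervals["dalys_per_10k_hi"].sum())
        d_hi = -float(scen.intervals["dalys_per_10k_lo"].sum())
        if d_lo > 0 and d_hi > 0:
            lo, hi = sorted((cost / d_hi, cost / d_lo))
    return ICERResult(
        who_id=spec.who_id, delta_cost=cost, delta_dalys_averted=averted,
        icer=value, classification=classify(value), ci_low=lo, ci_high=hi,
    )


def league_table(
    interventions: dict[str, InterventionSpec] | None = None,
    results: dict | None = None,
    baseline=None,
    horizon: int = 10,
    rate: float = 0.03,
) -> list[ICERResult]:
    """ICERs for a set of interventions, sorted from the lowest incremental
    cost per DALY averted to the highest.

    Without ``results``, deltas come from the published burden panel
    (delta-configured mode).  With ``results`` (who_id -> scenario
    :class:`~ncdsim.results.SimulationResult` carrying a cost ledger) and a
    ``baseline`` result, deltas and costs come from the simulation.
    """
    interventions = interventions or intervention_library()
    rows = []
    for who_id, spec in interventions.items():
        if results is None:
            rows.append(panel_icer(spec, horizon, rate))
        else:
            scen = results[who_id]
            averted = scen.dalys_averted(baseline)
            cost = scen.cost.discounted_total if scen.cost is not None else 0.0
            value = icer(cost, averted)
            rows.append(ICERResult(who_id=who_id, delta_cost=cost,
                                   delta_dalys_averted=averted, icer=value,
                                   classification=classify(value)))
    rows.sort(key=lambda r: _sort_key(r.icer))
    return rows


def ce_plane_export(results: list[ICERResult]) -> pd.DataFrame:
    """Cost-effectiveness-plane table: one row per intervention, discounted
    (DALYs averted, incremental cost) with the ICER and threshold band,
    sorted by ICER ascending."""
    if not results:
        raise ConfigurationError("ce_plane_export: empty result list")
    rows = sorted(results, key=lambda r: _sort_key(r.icer))
    return pd.DataFrame(
        {
            "who_id": [r.who_id for r in rows],
            "delta_dalys_averted": [r.delta_dalys_averted for r in rows],
            "delta_cost": [r.delta_cost for r in rows],
            "icer": [r.icer for r in rows],
            "classification": [r.classification for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
        }
    )


def discount_costs(yearly_costs, rate: float) -> float:
    """Present value of a per-year cost stream (year 0 undiscounted)."""
    yearly = np.asarray(yearly_costs, dtype=float)
    t = np.arange(len(yearly))
    return float(np.sum(yearly * (1.0 + rate) ** -t))
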