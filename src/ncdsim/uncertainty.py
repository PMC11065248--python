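"""Probabilistic sensitivity analysis and the reach sensitivity sweep.

PSA propagates input-parameter uncertainty by parametric resampling:
each parameter gets a (truncated) normal distribution — rate ratios are
sampled on the log scale by default so draws stay positive — and the
cost-effectiveness computation is re-run per draw with common random
numbers shared between baseline and scenario.  The summary per intervention
is the mean and the 2.5th/97.5th percentiles across draws.

The reach sweep re-runs a scenario at several final coverage fractions with
a shared seed; DALYs averted and reach-proportional costs scale linearly in
coverage, leaving the ICER unchanged for interventions whose variable costs
follow the reached population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .economics import icer
from .engine import run_simulation
from .errors import ConfigurationError
from .interventions import ReachCurve
from .results import load_burden_panel

__all__ = [
    "PSADistributionSpec",
    "PSAResult",
    "default_psa_distributions",
    "reach_sweep",
    "run_psa",
    "sample_parameters",
]


@dataclass
class PSADistributionSpec:
    """Sampling distributions, one entry per parameter name:
    ``{mean, sd, lo, hi, transform}`` with ``transform`` in
    ``{"identity", "log"}`` (log for rate ratios and other positive-only
    parameters)."""

    params: dict = field(default_factory=dict)

    def validate(self):
        bad = []
        for name, p in self.params.items():
            if p.get("sd", 0.0) < 0:
                bad.append(f"{name}.sd negative")
            if p.get("transform", "identity") not in ("identity", "log"):
                bad.append(f"{name}.transform unknown")
            if p.get("transform") == "log" and p["mean"] <= 0:
                bad.append(f"{name}: log transform needs a positive mean")
            lo, hi = p.get("lo", -np.inf), p.get("hi", np.inf)
            if lo >= hi:
                bad.append(f"{name}: empty truncation interval")
        if bad:
            raise ConfigurationError("invalid PSA distribution spec: " + "; ".join(bad),
                                     fields=bad)


@dataclass
class PSAResult:
    """Per-intervention mean and 95% credible bounds (2.5th/97.5th
    percentiles of the same draw set) for DALYs averted, incremental cost
    and ICER."""

    summary: pd.DataFrame       # index: who_id; columns: quantity_mean/lo/hi
    n_draws: int
    seed: int
    draws: pd.DataFrame | None = None


def sample_parameters(dist_spec: PSADistributionSpec, n_draws: int, rng) -> pd.DataFrame:
    """Truncated-(log)normal parameter draws, one row per draw.  Truncation
    is by rejection with a deterministic fallback to the nearest bound."""
    dist_spec.validate()
    out = {}
    for name, p in dist_spec.params.items():
        mean, sd = float(p["mean"]), float(p.get("sd", 0.0))
        lo, hi = float(p.get("lo", -np.inf)), float(p.get("hi", np.inf))
        if p.get("transform", "identity") == "log":
            sd_log = sd / mean if mean else 0.0
            x = np.exp(rng.normal(np.log(mean) if mean else 0.0, sd_log, size=n_draws))
        else:
            x = rng.normal(mean, sd, size=n_draws)
        for _ in range(100):
            bad = (x < lo) | (x > hi)
            if not bad.any():
                break
            if p.get("transform", "identity") == "log":
                x[bad] = np.exp(rng.normal(np.log(mean), sd_log, size=int(bad.sum())))
            else:
                x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        out[name] = np.clip(x, lo, hi)
    return pd.DataFrame(out)


def default_psa_distributions(cost_cv: float = 0.2) -> PSADistributionSpec:
    """Distributions for delta-configured cost-effectiveness: per-intervention
    total DALYs averted (normal, sd from the published interval width / 3.92,
    truncated at zero) and unit-cost multipliers (lognormal around 1 with the
    given coefficient of variation)."""
    panel = load_burden_panel()
    params = {}
    for who_id, block in panel["interventions"].items():
        point = -sum(block[c]["dalys"][0] for c in block)
        lo = -sum(block[c]["dalys"][2] for c in block)
        hi = -sum(block[c]["dalys"][1] for c in block)
        sd = max((hi - lo) / 3.92, 0.025 * max(point, 1.0))
        params[f"dalys_averted:{who_id}"] = {
            "mean": max(point, 1e-9), "sd": sd, "lo": 0.0, "hi": np.inf,
        }
        params[f"cost_multiplier:{who_id}"] = {
            "mean": 1.0, "sd": cost_cv, "lo": 0.0, "hi": np.inf, "transform": "log",
        }
    return PSADistributionSpec(params)


def run_psa(
    evaluate,
    dist_spec: PSADistributionSpec,
    n_draws: int,
    seed: int,
    keep_draws: bool = False,
) -> PSAResult:
    """Re-run a cost-effectiveness evaluation over parameter draws.

    ``evaluate(params: dict) -> dict`` maps one parameter draw to
    per-intervention ``{who_id: (dalys_averted, delta_cost)}``.  Draws are
    deterministic for a fixed seed; the evaluation itself must use common
    random numbers internally so that between-draw variation reflects the
    parameters, not simulation noise.
    """
    if n_draws < 1:
        raise ConfigurationError("n_draws must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9A5]))
    samples = sample_parameters(dist_spec, n_draws, rng)
    records = []
    for _, row in samples.iterrows():
        res = evaluate(row.to_dict())
        for who_id, (averted, cost) in res.items():
            value = icer(cost, averted)
            records.append({
                "who_id": who_id, "dalys_averted": averted, "delta_cost": cost,
                "icer": value if isinstance(value, float) else np.nan,
            })
    draws = pd.DataFrame(records)
    rows = {}
    for who_id, g in draws.groupby("who_id", sort=False):
        r = {}
        for q in ("dalys_averted", "delta_cost", "icer"):
            vals = g[q].to_numpy(float)
            r[f"{q}_mean"] = float(np.nanmean(vals))
            r[f"{q}_lo"] = float(np.nanpercentile(vals, 2.5))
            r[f"{q}_hi"] = float(np.nanpercentile(vals, 97.5))
        rows[who_id] = r
    return PSAResult(summary=pd.DataFrame.from_dict(rows, orient="index"),
                     n_draws=n_draws, seed=seed,
                     draws=draws if keep_draws else None)


def panel_psa_evaluator(interventions, horizon: int = 10, rate: float = 0.03):
    """Evaluator for :func:`run_psa` over the delta-configured pipeline:
    resampled total DALYs averted and unit-cost multipliers feed the printed
    cost arithmetic."""
    from .economics import _panel_cost

    base_costs = {w: _panel_cost(s, horizon, rate) for w, s in interventions.items()}

    def evaluate(params):
        out = {}
        for who_id in interventions:
            averted = params[f"dalys_averted:{who_id}"]
            cost = base_costs[who_id] * params[f"cost_multiplier:{who_id}"]
            out[who_id] = (averted, cost)
        return out

    return evaluate


def reach_sweep(
    pop,
    models,
    daly_params,
    config,
    spec,
    reach_values,
    mode: str = "expectation",
) -> pd.DataFrame:
    """Re-run baseline and scenario at several final coverage fractions with
    a shared seed; one row per reach value with DALYs averted, discounted
    cost and ICER."""
    for r in reach_values:
        if not 0.0 <= r <= 1.0:
            raise ConfigurationError(f"reach value {r} outside [0, 1]")
    baseline = run_simulation(pop, models, daly_params, config, mode=mode)
    rows = []
    for r in reach_values:
        spec_r = replace(spec, reach=ReachCurve(final_reach=r, ramp=spec.reach.ramp))
        scen = run_simulation(pop, models, daly_params, config, scenario=spec_r, mode=mode)
        averted = scen.dalys_averted(baseline)
        cost = scen.cost.discounted_total if scen.cost is not None else 0.0
        rows.append({"final_reach": r, "dalys_averted": averted,
                     "delta_cost": cost, "icer": icer(cost, averted)})
    return pd.DataFrame(rows)
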