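"""Hazard-scale calibration to external burden targets.

Each condition's risk score fixes the *relative* risk gradient across
individuals; calibration fixes the *level* by solving for a single
multiplicative hazard scale such that the expected cumulative incidence per
10,000 over the horizon matches an external target (age/sex gradients are
carried by the risk scores themselves).  A second, subsequent bisection
fits a case-fatality scale to the mortality target while holding the
incidence scale fixed.

The objective is the engine's expectation-mode recursion (state
probabilities propagated exactly, so the objective is smooth, deterministic
and strictly monotone in the scale until saturation); a Monte-Carlo run at
the calibrated scales therefore centers on the target up to sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import BASELINE_DX, DALYParameters, SimulationConfig, _prepare_agents, hazard_matrices
from .errors import CalibrationError
from .results import load_burden_panel
from .risk import ConditionModel

__all__ = ["CalibrationTarget", "calibrate", "calibrate_all", "default_targets"]


@dataclass
class CalibrationTarget:
    """Cumulative 10-year incidence and mortality per 10,000 to reproduce.

    Mortality may exceed what incident cases alone could produce (deaths can
    arise from prevalent disease) but never the population size."""

    condition: str
    target_incidence_per_10k: float
    target_mortality_per_10k: float | None = None
    tolerance: float = 0.02

    def __post_init__(self):
        if self.target_incidence_per_10k < 0:
            raise CalibrationError(f"{self.condition}: negative incidence target")
        for v in (self.target_incidence_per_10k, self.target_mortality_per_10k):
            if v is not None and v > 10_000:
                raise CalibrationError(
                    f"{self.condition}: target {v} exceeds the population of 10,000"
                )


def default_targets(tolerance: float = 0.02) -> dict[str, CalibrationTarget]:
    """Targets transcribed from the published baseline burden panel."""
    panel = load_burden_panel()["baseline"]
    return {
        cond: CalibrationTarget(
            cond,
            target_incidence_per_10k=float(block["incidence"][0]),
            target_mortality_per_10k=float(block["mortality"][0]),
            tolerance=tolerance,
        )
        for cond, block in panel.items()
    }


def _expected_outcomes(H_c, inc_scale, h_fat, other_p, dx0):
    """Expected cumulative (incidence, own-cause deaths) counts for one
    condition; mirrors the engine's expectation recursion exactly."""
    A = dx0.astype(float)
    F = (~dx0).astype(float)
    h_other = -np.log1p(-other_p)
    e_inc = 0.0
    e_dead = 0.0
    for t in range(H_c.shape[1]):
        h_total = h_other[:, t] + h_fat
        p_death_a = -np.expm1(-h_total)
        share = h_fat / np.where(h_total == 0, 1.0, h_total)
        e_dead += float((A * p_death_a * share).sum())
        A = A * (1.0 - p_death_a)
        F = F * (1.0 - other_p[:, t])
        new = F * -np.expm1(-H_c[:, t] * inc_scale)
        e_inc += float(new.sum())
        F = F - new
        A = A + new
    return e_inc, e_dead


def _bisect(f, target, tol, max_iter, what):
    """Log-scale bisection of a nondecreasing function; converges to
    relative tolerance and asserts bracket shrinkage each iteration."""
    lo, hi = 1e-6, 1.0
    f_hi = f(hi)
    grow = 0
    while f_hi < target and grow < 40:
        hi *= 4.0
        f_hi = f(hi)
        grow += 1
    if f_hi < target * (1 - tol):
        raise CalibrationError(
            f"{what}: target {target:.6g} unreachable (maximum attainable ~{f_hi:.6g})"
        )
    if f(lo) > target:
        raise CalibrationError(
            f"{what}: target {target:.6g} below the minimum attainable at near-zero scale"
        )
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        val = f(mid)
        if target > 0 and abs(val - target) / target <= tol:
            return mid
        new_lo, new_hi = (mid, hi) if val < target else (lo, mid)
        if not (new_hi - new_lo < hi - lo):
            raise CalibrationError(f"{what}: bracket failed to shrink")
        lo, hi = new_lo, new_hi
    raise CalibrationError(
        f"{what}: no convergence after {max_iter} iterations; last bracket "
        f"[{lo:.6g}, {hi:.6g}]"
    )


def calibrate(
    pop: pd.DataFrame,
    model: ConditionModel,
    target: CalibrationTarget,
    sim_config: SimulationConfig | None = None,
    daly_params: DALYParameters | None = None,
    max_iter: int = 50,
) -> ConditionModel:
    """Return a copy of ``model`` with ``calibration_scale`` (and, when the
    target carries mortality, ``fatality_scale``) fitted to the target.

    The expected incidence is strictly increasing in the hazard scale (more
    hazard, more cases) until everyone at risk is a case, so bisection on
    the log scale converges; an unreachable target raises
    :class:`CalibrationError` naming the attainable maximum.
    """
    sim_config = sim_config or SimulationConfig()
    daly_params = daly_params or DALYParameters.default()
    agents = _prepare_agents(pop, sim_config)
    n, T = len(agents), sim_config.horizon_years
    per10k = 10_000.0 / n
    is_male = (agents["sex"] == "male").to_numpy()
    ages0 = agents["age"].to_numpy(float)
    other_p = np.column_stack(
        [daly_params.other_cause_prob(ages0 + t, is_male) for t in range(T)]
    )
    H, _ = hazard_matrices(agents, {model.condition: model}, T)
    H_c = H[model.condition]
    dx0 = (
        agents[BASELINE_DX[model.condition]].to_numpy(bool)
        if model.condition in BASELINE_DX else np.zeros(n, dtype=bool)
    )
    cf = daly_params.case_fatality[model.condition]
    h_cf = -np.log1p(-min(cf, 1 - 1e-15))

    if (H_c > 0).sum() == 0 and target.target_incidence_per_10k > 0:
        raise CalibrationError(
            f"{model.condition}: uncalibrated model assigns zero risk to everyone; "
            "incidence target unreachable"
        )

    def f_inc(scale):
        inc, _ = _expected_outcomes(H_c, scale, h_cf * model.fatality_scale, other_p, dx0)
        return inc * per10k

    inc_scale = _bisect(f_inc, target.target_incidence_per_10k, target.tolerance,
                        max_iter, f"{model.condition} incidence")
    out = model.with_scale(calibration_scale=inc_scale)

    if target.target_mortality_per_10k is not None:
        def f_mort(fs):
            _, dead = _expected_outcomes(H_c, inc_scale, h_cf * fs, other_p, dx0)
            return dead * per10k

        fat_scale = _bisect(f_mort, target.target_mortality_per_10k, target.tolerance,
                            max_iter, f"{model.condition} mortality")
        out = out.with_scale(fatality_scale=fat_scale)
    return out


def calibrate_all(
    pop: pd.DataFrame,
    models: dict[str, ConditionModel],
    targets: dict[str, CalibrationTarget] | None = None,
    sim_config: SimulationConfig | None = None,
    daly_params: DALYParameters | None = None,
) -> dict[str, ConditionModel]:
    """Calibrate every condition model to its target (defaults: the shipped
    baseline burden panel)."""
    targets = targets or default_targets()
    return {
        cond: calibrate(pop, model, targets[cond], sim_config, daly_params)
        for cond, model in models.items()
    }
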