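"""The nine modeled WHO NCD interventions: mechanisms, eligibility, reach
ramps and cost models.

Each intervention acts through rate ratios on condition-specific incidence
and/or case-fatality hazards (or through additive risk-factor shifts) among
the reached, eligible subpopulation.  Reach ramps linearly from zero to a
final coverage fraction (default 64%) over the policy horizon; individuals
enroll progressively and stay enrolled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, SimulationError
from .risk import CONDITIONS

__all__ = [
    "CHANNELS",
    "InterventionSpec",
    "ReachCurve",
    "apply_intervention",
    "eligibility_mask",
    "intervention_library",
    "reach",
]

CHANNELS = ("incidence_rr", "mortality_rr", "factor_shift")


@dataclass(frozen=True)
class ReachCurve:
    """Population coverage by program year.

    ``linear_over_horizon`` ramps as ``final_reach * (t + 1) / horizon`` so
    the final year reaches ``final_reach``; ``immediate`` holds coverage at
    ``final_reach`` from year 0.  A list gives an explicit nondecreasing
    schedule."""

    final_reach: float = 0.64
    ramp: object = "linear_over_horizon"

    def __post_init__(self):
        if not 0.0 <= self.final_reach <= 1.0:
            raise ConfigurationError(f"final_reach={self.final_reach} outside [0, 1]")


def reach(curve: ReachCurve, year: int, horizon: int = 10) -> float:
    """Coverage fraction in program year ``year`` (0-based)."""
    if not 0 <= year < horizon:
        raise SimulationError(f"year {year} outside horizon 0..{horizon - 1}")
    if isinstance(curve.ramp, (list, tuple)):
        sched = list(curve.ramp)
        if any(b < a for a, b in zip(sched, sched[1:])):
            raise ConfigurationError("custom reach schedule must be nondecreasing")
        return float(np.clip(sched[year], 0.0, 1.0))
    if curve.ramp == "immediate":
        return curve.final_reach
    if curve.ramp == "linear_over_horizon":
        return curve.final_reach * (year + 1) / horizon
    raise ConfigurationError(f"unknown reach ramp {curve.ramp!r}")


@dataclass
class Effect:
    target: str
    channel: str
    magnitude: float
    field: str | None = None   # risk-factor name for factor_shift

    def __post_init__(self):
        if self.target not in CONDITIONS:
            raise ConfigurationError(f"effect targets unknown condition {self.target!r}")
        if self.channel not in CHANNELS:
            raise ConfigurationError(f"unknown effect channel {self.channel!r}")
        if self.channel.endswith("_rr") and self.magnitude <= 0:
            raise ConfigurationError(
                f"{self.target}.{self.channel}: rate ratio must be positive"
            )


@dataclass
class InterventionSpec:
    """One modeled intervention: WHO list id, mechanism, eligibility,
    reach curve and cost model.

    ``eligibility`` keys: ``sex``, ``age_min``, ``age_max``, ``requires_dx``
    (a diagnosis column), ``incident_condition`` (eligible once incident with
    that condition); an empty dict means the whole population.  ``cost_model``
    keys: ``per_person_year``, ``per_eligible_person_year``,
    ``per_incident_case``, ``program_fixed`` (all $; >= 0).
    """

    who_id: str
    name: str = ""
    effects: list = field(default_factory=list)
    eligibility: dict = field(default_factory=dict)
    reach: ReachCurve = field(default_factory=ReachCurve)
    cost_model: dict = field(default_factory=dict)
    eligible_fraction: float | None = None

    def __post_init__(self):
        self.effects = [e if isinstance(e, Effect) else Effect(**e) for e in self.effects]
        for k, v in self.cost_model.items():
            if v < 0:
                raise ConfigurationError(f"{self.who_id}: cost_model.{k}={v} negative")

    def rate_ratio(self, condition: str, channel: str) -> float:
        rr = 1.0
        for e in self.effects:
            if e.target == condition and e.channel == channel:
                rr *= e.magnitude
        return rr

    def targets(self) -> set:
        return {e.target for e in self.effects}


def intervention_library() -> dict[str, InterventionSpec]:
    """The nine shipped intervention defaults, keyed by WHO list id."""
    with resources.files("ncdsim.data").joinpath("interventions.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    default_curve = ReachCurve(**raw["default_reach"])
    lib = {}
    for item in raw["interventions"]:
        item = dict(item)
        item.setdefault("reach", default_curve)
        spec = InterventionSpec(**item)
        lib[spec.who_id] = spec
    return lib


def eligibility_mask(spec: InterventionSpec, pop: pd.DataFrame) -> np.ndarray:
    """Vectorized eligibility predicate (total: defined for every record).

    ``incident_condition`` eligibility is handled dynamically inside the
    simulation (a record becomes eligible at onset); here such records count
    as eligible so cost and effect hooks can see them."""
    mask = np.ones(len(pop), dtype=bool)
    e = spec.eligibility
    if "sex" in e:
        mask &= (pop["sex"] == e["sex"]).to_numpy()
    if "age_min" in e:
        mask &= pop["age"].to_numpy() >= e["age_min"]
    if "age_max" in e:
        mask &= pop["age"].to_numpy() <= e["age_max"]
    if "requires_dx" in e:
        mask &= pop[e["requires_dx"]].to_numpy(bool)
    return mask


def apply_intervention(
    annual_probs: dict,
    spec: InterventionSpec,
    year: int,
    eligible: bool,
    rng=None,
    horizon: int = 10,
):
    """Adjust one individual's annual probabilities for one cycle.

    ``annual_probs`` has ``incidence`` and ``mortality`` dicts of
    per-condition probabilities.  With an rng, reach is a Bernoulli draw;
    without one (expectation mode) hazards are scaled by the mixture
    multiplier ``1 - r + r * rr``.  Returns ``(adjusted_probs, cost)`` where
    the cost is this cycle's accrual for this individual (population-wide
    program costs are accounted at the population level, not here).
    """
    r = reach(spec.reach, year, horizon)
    out = {k: dict(v) for k, v in annual_probs.items() if isinstance(v, dict)}
    out.update({k: v for k, v in annual_probs.items() if not isinstance(v, dict)})
    cost = 0.0
    if "per_person_year" in spec.cost_model:
        cost += spec.cost_model["per_person_year"]
    if not eligible:
        return out, cost
    reached_w = r if rng is None else float(rng.random() < r)
    if reached_w > 0 and "per_eligible_person_year" in spec.cost_model:
        cost += spec.cost_model["per_eligible_person_year"] * reached_w
    for e in spec.effects:
        if e.channel == "factor_shift":
            continue  # factor shifts act on the profile, upstream of hazards
        block = "incidence" if e.channel == "incidence_rr" else "mortality"
        p = out[block].get(e.target)
        if p is None:
            raise ConfigurationError(
                f"{spec.who_id}: no {block} probability for condition {e.target!r}"
            )
        mult = 1.0 - reached_w + reached_w * e.magnitude
        if mult != 1.0:
            h = -np.log1p(-min(p, 1.0 - 1e-15))
            out[block][e.target] = 1.0 - np.exp(-h * mult)
    return out, cost
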