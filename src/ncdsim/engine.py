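"""Annual-cycle individual-level simulation with competing risks and DALY
accounting.

Each simulated person is followed over the policy horizon (default 10
years) in one-year cycles.  Within a cycle, mortality is resolved first —
active cases face their condition's case fatality competing with
other-cause (demographic) mortality, with the cause of death allocated in
proportion to cause-specific hazards — and disease incidence is then drawn
among survivors still free of the condition.  Other-cause mortality follows
a Gompertz curve fitted to a shipped synthetic reference life table, with
sex multipliers.

Conditions evolve as parallel cause-specific threads that share the same
demographic mortality stream and the same underlying random numbers.  This
cause-deleted convention means an intervention acting on one condition
leaves every other condition's tallies exactly unchanged under common
random numbers, and it makes each condition's expected outcome computable
in closed form: ``mode="expectation"`` runs the identical recursion on
state probabilities instead of sampled states (no Monte-Carlo noise), and
is what calibration bisects on.  The price is that cross-condition
survivorship feedback — e.g. averted CVD deaths slightly inflating later
diabetes incidence — is deliberately excluded; see the methods note.

DALYs = YLD + YLL.  YLD accrues the disability weight for every year lived
with the condition from the onset year onward (the onset-year weight is
configurable; the death year accrues nothing); YLL discounts the remaining
life expectancy at the age of a condition-attributed death back to the
start of the simulation.  Both use discrete annual discounting.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import SimulationError
from .interventions import InterventionSpec, eligibility_mask, reach
from .results import QUANTITIES, SimulationResult
from .risk import annual_hazard

__all__ = [
    "CostLedger",
    "DALYParameters",
    "HealthState",
    "SimulationConfig",
    "competing_death_draw",
    "compute_dalys",
    "discounted_annuity",
    "run_simulation",
    "step_individual",
]


def discounted_annuity(years, rate: float):
    """Present value of one unit per year over ``years`` years, first year
    undiscounted: ``sum_{t=0}^{years-1} (1+rate)^-t``, with a fractional
    final year.  Accepts scalars or arrays."""
    years = np.asarray(years, dtype=float)
    if np.any(years < 0):
        raise SimulationError("years must be nonnegative")
    if rate < 0:
        raise SimulationError("rate must be nonnegative")
    if rate == 0:
        out = years
    else:
        v = 1.0 / (1.0 + rate)
        full = np.floor(years)
        out = (1.0 - v**full) / (1.0 - v) + (years - full) * v**full
    return float(out) if out.ndim == 0 else out


@dataclass
class SimulationConfig:
    horizon_years: int = 10
    population_size: int = 10_000
    discount_rate: float = 0.03
    seed: int = 0
    replicates: int = 1
    onset_weight: float = 1.0   # YLD weight of the onset year (0.5 = half-cycle)

    def __post_init__(self):
        if self.horizon_years < 1:
            raise SimulationError("horizon_years must be >= 1")
        if self.population_size < 1:
            raise SimulationError("population_size must be >= 1")
        if self.discount_rate < 0:
            raise SimulationError("discount_rate must be >= 0")


@functools.lru_cache(maxsize=1)
def _daly_fixture() -> dict:
    with resources.files("ncdsim.data").joinpath("daly_parameters.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass
class DALYParameters:
    """Disability weights, case fatality, life table and other-cause
    mortality (a Gompertz fit to the life table's qx column)."""

    disability_weights: dict
    case_fatality: dict
    life_table: dict
    sex_multiplier: dict = field(default_factory=lambda: {"male": 1.0, "female": 1.0})

    def __post_init__(self):
        bad = [c for c, w in self.disability_weights.items() if not 0 <= w <= 1]
        if bad:
            raise SimulationError(f"disability weights outside [0,1]: {bad}")
        bad = [c for c, p in self.case_fatality.items() if not 0 <= p <= 1]
        if bad:
            raise SimulationError(f"case-fatality probabilities outside [0,1]: {bad}")
        ages = np.array(sorted(self.life_table), dtype=float)
        ex = np.array([self.life_table[int(a)]["ex"] for a in ages])
        if np.any(np.diff(ex) > 0):
            raise SimulationError("life expectancy must be nonincreasing in age")
        qx = np.array([self.life_table[int(a)]["qx"] for a in ages])
        b, log_a = np.polyfit(ages, np.log(-np.log1p(-qx)), 1)
        self._gompertz = (float(np.exp(log_a)), float(b))
        self._ages, self._ex = ages, ex

    @classmethod
    def default(cls) -> "DALYParameters":
        raw = _daly_fixture()
        return cls(
            disability_weights=raw["disability_weights"],
            case_fatality=raw["case_fatality"],
            life_table=raw["life_table"],
            sex_multiplier=raw["other_cause_sex_multiplier"],
        )

    def other_cause_prob(self, age, is_male) -> np.ndarray:
        """Annual other-cause death probability by age and sex."""
        a, b = self._gompertz
        m = a * np.exp(b * np.asarray(age, dtype=float))
        mult = np.where(np.asarray(is_male), self.sex_multiplier["male"],
                        self.sex_multiplier["female"])
        return 1.0 - np.exp(-m * mult)

    def life_expectancy(self, age) -> np.ndarray:
        return np.interp(np.asarray(age, dtype=float), self._ages, self._ex)


# -- single-individual primitive -------------------------------------------

@dataclass
class HealthState:
    """One individual's state: alive flag, active conditions with onset
    years, and at most one cause of death."""

    alive: bool = True
    active: dict = field(default_factory=dict)     # condition -> onset year
    cause_of_death: str | None = None


def competing_death_draw(hazards: np.ndarray, u_death: np.ndarray, u_cause: np.ndarray):
    """Vectorized competing-risk death allocation.

    ``hazards`` has shape (n, k): cause-specific annual hazards.  Death
    occurs with probability ``1 - exp(-sum h)`` and the cause is allocated
    in proportion to the cause-specific hazards, so over many draws cause
    ``i`` claims the fraction ``h_i / sum(h) * (1 - exp(-sum h))``.
    Returns ``(died, cause_index)`` with cause -1 where no death occurred.
    """
    hazards = np.asarray(hazards, dtype=float)
    if np.any(hazards < 0):
        raise SimulationError("cause-specific hazards must be nonnegative")
    total = hazards.sum(axis=1)
    died = u_death < -np.expm1(-total)
    safe_total = np.where(total == 0, 1.0, total)
    shares = hazards / safe_total[:, None]
    cum = np.cumsum(shares, axis=1)
    cause = (u_cause[:, None] >= cum).sum(axis=1)
    cause = np.minimum(cause, hazards.shape[1] - 1)
    return died, np.where(died, cause, -1)


def step_individual(state: HealthState, annual_probs: dict, rng, year: int = 0) -> HealthState:
    """Advance one individual by one annual cycle.

    ``annual_probs`` carries ``other_cause`` (a probability) plus
    ``incidence`` and ``mortality`` per-condition probability dicts.
    Mortality is resolved first, competing other-cause against the case
    fatalities of currently active conditions; incidence is then drawn only
    for conditions not yet active.  A dead individual is returned unchanged.
    """
    flat = [annual_probs.get("other_cause", 0.0)]
    flat += list(annual_probs.get("incidence", {}).values())
    flat += list(annual_probs.get("mortality", {}).values())
    if any(not 0.0 <= p <= 1.0 for p in flat):
        raise SimulationError("annual probabilities must lie in [0, 1]")
    if not state.alive:
        return state
    causes = ["other"] + [c for c in state.active if c in annual_probs.get("mortality", {})]
    hazards = np.array([
        [-np.log1p(-min(annual_probs.get("other_cause", 0.0), 1 - 1e-15))]
        + [-np.log1p(-min(annual_probs["mortality"][c], 1 - 1e-15)) for c in causes[1:]]
    ])
    died, cause = competing_death_draw(hazards, rng.random(1), rng.random(1))
    if died[0]:
        return HealthState(alive=False, active=dict(state.active),
                           cause_of_death=causes[int(cause[0])])
    new_active = dict(state.active)
    for cond, p in annual_probs.get("incidence", {}).items():
        if cond not in new_active and rng.random() < p:
            new_active[cond] = year
    return HealthState(alive=True, active=new_active, cause_of_death=None)


# -- population-level engine ------------------------------------------------

@dataclass
class CostLedger:
    """Per-year undiscounted intervention costs (dollars per 10,000
    population) by category, and their discounted total."""

    individual_level: np.ndarray
    program_level: np.ndarray
    discount_rate: float = 0.03

    def yearly_total(self) -> np.ndarray:
        return self.individual_level + self.program_level

    @property
    def discounted_total(self) -> float:
        t = np.arange(len(self.individual_level))
        return float(np.sum(self.yearly_total() * (1 + self.discount_rate) ** -t))

    @property
    def undiscounted_total(self) -> float:
        return float(self.yearly_total().sum())


#: conditions whose surveyed diagnosis marks a prevalent case at entry
BASELINE_DX = {"diabetes": "dx_diabetes", "asthma_copd": "dx_asthma_copd"}


def _prepare_agents(pop: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    if len(pop) == 0:
        raise SimulationError("population is empty")
    if len(pop) == config.population_size:
        return pop.reset_index(drop=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA6E7]))
    idx = rng.integers(0, len(pop), size=config.population_size)
    return pop.iloc[idx].reset_index(drop=True)


def hazard_matrices(agents, models, horizon, spec=None):
    """Per-condition (n, T) annual hazard matrices at calibration scale 1,
    ages advanced cycle by cycle.  Returns ``(base, shifted)`` where the
    shifted set has the scenario's factor shifts applied (identical to base
    when the scenario has none)."""
    shifts = {}
    if spec is not None:
        for e in spec.effects:
            if e.channel == "factor_shift":
                shifts.setdefault(e.target, []).append((e.field, e.magnitude))
    base, shifted = {}, {}
    for cond, model in models.items():
        cols, cols_s = [], []
        for t in range(horizon):
            prof = agents.copy()
            prof["age"] = prof["age"] + t
            cols.append(annual_hazard(model, prof))
            if cond in shifts:
                for fld, delta in shifts[cond]:
                    prof[fld] = prof[fld] + delta
                cols_s.append(annual_hazard(model, prof))
        base[cond] = np.column_stack(cols)
        shifted[cond] = np.column_stack(cols_s) if cond in shifts else base[cond]
    return base, shifted


def _replicate_runs(pop, models, daly_params, config, scenario, mode):
    reps = []
    for i in range(config.replicates):
        cfg = SimulationConfig(**{**config.__dict__, "seed": config.seed + 7919 * i,
                                  "replicates": 1})
        reps.append(run_simulation(pop, models, daly_params, cfg, scenario, mode))
    data = sum(r.data for r in reps) / len(reps)
    stack = np.stack([r.data.to_numpy() for r in reps])
    sd = stack.std(axis=0, ddof=1)
    intervals = pd.concat(
        [pd.DataFrame(data.to_numpy() - 1.96 * sd, index=data.index,
                      columns=[f"{q}_lo" for q in QUANTITIES]),
         pd.DataFrame(data.to_numpy() + 1.96 * sd, index=data.index,
                      columns=[f"{q}_hi" for q in QUANTITIES])], axis=1)
    first = reps[0]
    return SimulationResult(
        scenario=first.scenario, data=data, intervals=intervals,
        other_cause_deaths_per_10k=float(np.mean([r.other_cause_deaths_per_10k for r in reps])),
        cost=first.cost, meta={**first.meta, "replicates": config.replicates},
    )


def run_simulation(
    pop: pd.DataFrame,
    models: dict,
    daly_params: DALYParameters,
    config: SimulationConfig,
    scenario: InterventionSpec | None = None,
    mode: str = "mc",
) -> SimulationResult:
    """Simulate the population over the horizon; ``scenario`` attaches an
    intervention (effects, reach enrollment and cost accrual).

    ``mode="mc"`` samples trajectories; the run is bit-deterministic for a
    fixed config seed, and any two runs at the same seed share every
    underlying uniform draw (the common-random-numbers contract, which makes
    scenario-minus-baseline deltas free of between-run noise).
    ``mode="expectation"`` propagates state probabilities through the same
    recursion, yielding the exact expected outcome; reach enrollment is then
    applied as a per-year coverage weight.
    """
    if mode not in ("mc", "expectation"):
        raise SimulationError(f"unknown mode {mode!r}")
    if scenario is not None and not scenario.targets() <= set(models):
        unknown = sorted(scenario.targets() - set(models))
        raise SimulationError(f"scenario references unknown condition(s): {unknown}")
    if config.replicates > 1 and mode == "mc":
        return _replicate_runs(pop, models, daly_params, config, scenario, mode)

    agents = _prepare_agents(pop, config)
    n, T = len(agents), config.horizon_years
    per10k = 10_000.0 / n
    disc = (1 + config.discount_rate) ** -np.arange(T)
    is_male = (agents["sex"] == "male").to_numpy()
    ages0 = agents["age"].to_numpy(float)
    other_p = np.column_stack(
        [daly_params.other_cause_prob(ages0 + t, is_male) for t in range(T)]
    )
    h_other = -np.log1p(-other_p)
    # YLL of a condition-attributed death in year t, discounted to t=0
    yll_unit = np.column_stack(
        [discounted_annuity(daly_params.life_expectancy(ages0 + t), config.discount_rate)
         * disc[t] for t in range(T)]
    )

    H, H_shift = hazard_matrices(agents, models, T, scenario)

    mc = mode == "mc"
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    U_death = rng.random((n, T))
    U_cause = rng.random((n, T))
    U_inc = rng.random((n, T, len(models)))
    U_reach = rng.random(n)

    if scenario is not None:
        elig = eligibility_mask(scenario, agents)
        r_t = np.array([reach(scenario.reach, t, T) for t in range(T)])
    else:
        elig = np.zeros(n, dtype=bool)
        r_t = np.zeros(T)

    cost_target = None
    if scenario is not None and "per_incident_case" in scenario.cost_model:
        cost_target = scenario.eligibility.get("incident_condition") or next(
            iter(sorted(scenario.targets()))
        )
    incident_reached = np.zeros(T)

    rows = {}
    for ci, (cond, model) in enumerate(models.items()):
        cf = daly_params.case_fatality[cond]
        h_fat_base = -np.log1p(-min(cf, 1 - 1e-15)) * model.fatality_scale
        inc_rr = scenario.rate_ratio(cond, "incidence_rr") if scenario is not None else 1.0
        mort_rr = scenario.rate_ratio(cond, "mortality_rr") if scenario is not None else 1.0

        dx0 = (
            agents[BASELINE_DX[cond]].to_numpy(bool)
            if cond in BASELINE_DX else np.zeros(n, dtype=bool)
        )
        if mc:
            A = dx0.copy()
            F = ~dx0
            onset = np.where(dx0, -1, -2)          # -1 prevalent, -2 never
            died_own = np.zeros(n, dtype=bool)
        else:
            A = dx0.astype(float)
            F = (~dx0).astype(float)
            e_inc = 0.0
            e_dead_own = 0.0
        inc_count = 0.0
        yld_c = 0.0
        yll_c = 0.0

        for t in range(T):
            if mc:
                w = (elig & (U_reach < r_t[t])).astype(float)
            else:
                w = elig.astype(float) * r_t[t]
            h_fat = h_fat_base * (1.0 - w + w * mort_rr)
            h_inc = ((1.0 - w) * H[cond][:, t]
                     + w * H_shift[cond][:, t] * inc_rr) * model.calibration_scale
            p_inc = -np.expm1(-h_inc)

            if mc:
                h_total = h_other[:, t] + np.where(A, h_fat, 0.0)
                p_death = -np.expm1(-h_total)
                die = (A | F) & (U_death[:, t] < p_death)
                safe = np.where(h_total == 0, 1.0, h_total)
                share_own = np.where(A, h_fat / safe, 0.0)
                new_own = die & (U_cause[:, t] < share_own)
                died_own |= new_own
                yll_c += float(yll_unit[new_own, t].sum())
                A &= ~die
                F &= ~die
                new = F & (U_inc[:, t, ci] < p_inc)
                inc_count += float(new.sum())
                onset = np.where(new, t, onset)
                A |= new
                F &= ~new
                yld_c += disc[t] * (float(A.sum()) - (1 - config.onset_weight) * float(new.sum()))
                if cost_target == cond:
                    incident_reached[t] += float((new & elig & (U_reach < r_t[t])).sum())
            else:
                h_total = h_other[:, t] + h_fat
                p_death_a = -np.expm1(-h_total)
                share_own = h_fat / np.where(h_total == 0, 1.0, h_total)
                d_own = A * p_death_a * share_own
                e_dead_own += float(d_own.sum())
                yll_c += float((d_own * yll_unit[:, t]).sum())
                A = A * (1.0 - p_death_a)
                F = F * (1.0 - other_p[:, t])
                new = F * p_inc
                e_inc += float(new.sum())
                F = F - new
                yld_c += disc[t] * (float(A.sum()) + config.onset_weight * float(new.sum()))
                A = A + new
                if cost_target == cond:
                    incident_reached[t] += float((new * w).sum())

        if mc:
            inc_total = inc_count
            dead_own_total = float(died_own.sum())
        else:
            inc_total = e_inc
            dead_own_total = e_dead_own
        w_c = daly_params.disability_weights[cond]
        rows[cond] = {
            "incidence_per_10k": inc_total * per10k,
            "deaths_per_10k": dead_own_total * per10k,
            "dalys_per_10k": (w_c * yld_c + yll_c) * per10k,
        }

    # demographic (other-cause-only) thread, counted once: population
    # alive-years for cost accrual, and other-cause deaths
    alive_years = np.zeros(T)
    reached_elig_alive = np.zeros(T)
    if mc:
        alive_demo = np.ones(n, dtype=bool)
        other_deaths = 0.0
        for t in range(T):
            die = alive_demo & (U_death[:, t] < other_p[:, t])
            other_deaths += float(die.sum())
            alive_demo &= ~die
            alive_years[t] = float(alive_demo.sum())
            reached_elig_alive[t] = float((alive_demo & elig & (U_reach < r_t[t])).sum())
    else:
        S = np.ones(n)
        other_deaths = 0.0
        for t in range(T):
            other_deaths += float((S * other_p[:, t]).sum())
            S = S * (1.0 - other_p[:, t])
            alive_years[t] = float(S.sum())
            reached_elig_alive[t] = float((S * elig * r_t[t]).sum())

    cost = None
    if scenario is not None:
        cm = scenario.cost_model
        indiv = np.zeros(T)
        if "per_person_year" in cm:
            indiv += cm["per_person_year"] * alive_years
        if "per_eligible_person_year" in cm:
            indiv += cm["per_eligible_person_year"] * reached_elig_alive
        if "per_incident_case" in cm:
            indiv += cm["per_incident_case"] * incident_reached
        prog = np.full(T, float(cm.get("program_fixed", 0.0)))
        cost = CostLedger(individual_level=indiv * per10k, program_level=prog,
                          discount_rate=config.discount_rate)

    data = pd.DataFrame.from_dict(rows, orient="index")[QUANTITIES].loc[list(models)]
    return SimulationResult(
        scenario=scenario.who_id if scenario is not None else "baseline",
        data=data,
        other_cause_deaths_per_10k=other_deaths * per10k,
        cost=cost,
        meta={"mode": mode, "seed": config.seed, "n_agents": n,
              "horizon_years": T, "discount_rate": config.discount_rate},
    )


def compute_dalys(tallies: pd.DataFrame, daly_params: DALYParameters,
                  discount_rate: float, horizon: int = 10,
                  onset_weight: float = 1.0) -> dict:
    """DALYs per condition from explicit onset/death tallies (additive over
    individuals).

    ``tallies`` rows: ``condition``; ``age_at_entry``; ``onset_year``
    (0-based, -1 for prevalent at entry, NaN if never incident);
    ``death_year`` (NaN if alive at horizon); ``death_cause`` (a condition
    name, ``"other"``, or NaN).  YLD = disability weight x discounted years
    lived with the condition (onset year weighted by ``onset_weight``, death
    year accruing nothing); YLL = discounted remaining life expectancy at a
    condition-attributed death.
    """
    if discount_rate < 0:
        raise SimulationError("discount_rate must be nonnegative")
    out: dict = {}
    for _, row in tallies.iterrows():
        cond = row["condition"]
        out.setdefault(cond, 0.0)
        w = daly_params.disability_weights[cond]
        onset = row.get("onset_year")
        death = row.get("death_year")
        if not pd.isna(death) and death < 0:
            raise SimulationError("negative death year in tallies")
        end = horizon if pd.isna(death) else int(death)
        if not pd.isna(onset):
            if onset < -1:
                raise SimulationError("onset year below -1 in tallies")
            for t in range(max(int(onset), 0), min(end, horizon)):
                weight = onset_weight if t == onset else 1.0
                out[cond] += w * weight * (1 + discount_rate) ** -t
        if not pd.isna(death) and row.get("death_cause") == cond:
            le = float(daly_params.life_expectancy(row["age_at_entry"] + int(death)))
            out[cond] += discounted_annuity(le, discount_rate) * (1 + discount_rate) ** -int(death)
    return out
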