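"""Synthetic survey population generator.

Generates individual records that emulate the joint structure of a 2020
household survey of adults aged 40+ in Gaza: sex-stratified marginal
distributions for demographics, diagnoses, treatments, exam values and
laboratory values, tied together by a latent Gaussian rank-dependence
(copula) construction.  Booleans are thresholded latent normals; continuous
variables are transformed through moment-matched truncated-normal (or
lognormal) marginals so the realized mean/SD match the survey values despite
range truncation.

The laboratory block can be masked for a random subset of records (the survey
linked labs for only a fraction of respondents) and re-completed with a
chained-equations multiple-imputation scheme.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .errors import ConfigurationError, ImputationError

__all__ = [
    "LAB_FIELDS",
    "PopulationSpec",
    "generate_population",
    "induce_lab_missingness",
    "impute_missing",
    "read_population_csv",
    "write_population_csv",
]

LAB_FIELDS = ["total_chol", "ldl", "hdl", "triglycerides", "creatinine", "hba1c"]

#: continuous variables driven by the latent copula, in latent-matrix order
_COPULA_CONTINUOUS = [
    "age", "bmi", "sbp", "total_chol", "triglycerides", "ldl", "hdl",
    "creatinine", "hba1c",
]
_COPULA_BOOLEAN = [
    "dx_diabetes", "dx_hypertension", "dx_dyslipidemia", "dx_asthma_copd",
    "smoker", "waterpipe",
]
_COPULA_VARS = _COPULA_CONTINUOUS + _COPULA_BOOLEAN

_RX_TO_DX = {
    "rx_diabetes": "dx_diabetes",
    "rx_hypertension": "dx_hypertension",
    "rx_statin": "dx_dyslipidemia",
}

COLUMNS = (
    ["id", "age", "sex", "refugee"]
    + _COPULA_BOOLEAN[:4]
    + list(_RX_TO_DX)
    + ["smoker", "waterpipe", "sbp", "bmi"]
    + LAB_FIELDS
)


def _default_spec_dict():
    with resources.files("ncdsim.data").joinpath("survey_marginals.yaml").open() as fh:
        return yaml.safe_load(fh)


@functools.lru_cache(maxsize=256)
def _truncnorm_params(mean, sd, lo, hi):
    """Latent (mu, sigma) such that the [lo, hi]-truncated normal has the
    requested mean and SD.  Falls back to the naive parameters if the
    truncation is immaterial or the moment equations cannot be solved."""

    def moments(x):
        mu, sigma = x
        sigma = abs(sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    # cheap exit: truncation beyond ~5 sigma never moves the moments
    if lo < mean - 5 * sd and hi > mean + 5 * sd:
        return mean, sd
    sol = optimize.root(moments, x0=[mean, sd], method="hybr")
    if not sol.success:
        return mean, sd
    mu, sigma = sol.x
    return float(mu), float(abs(sigma))


def _truncnorm_ppf(u, mean, sd, lo, hi):
    mu, sigma = _truncnorm_params(mean, sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.ppf(u, a, b, loc=mu, scale=sigma)


def _lognorm_ppf(u, mean, sd, lo, hi):
    """Lognormal quantile matched to the requested mean/SD, clipped to bounds.
    Used for strongly right-skewed labs (triglycerides, creatinine)."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    x = stats.lognorm.ppf(u, np.sqrt(sigma2), scale=np.exp(mu))
    return np.clip(x, lo, hi)


@dataclass
class PopulationSpec:
    """Sex-stratified marginals plus latent dependence for the generator.

    ``sex_params`` maps ``"male"``/``"female"`` to dicts with continuous
    marginal blocks (mean/sd/lo/hi, optional ``dist: lognormal``), a
    ``prevalence`` dict for the booleans and a ``treated_given_dx`` dict of
    conditional treatment rates.  ``dependence`` is a list of
    ``[var_a, var_b, rho]`` latent correlations.
    """

    sex_params: dict
    female_fraction: float
    refugee_fraction: float
    lab_observed_fraction: float
    n_default: int
    dependence: list = field(default_factory=list)

    @classmethod
    def default(cls) -> "PopulationSpec":
        raw = _default_spec_dict()
        return cls(
            sex_params={s: raw[s] for s in ("male", "female")},
            female_fraction=raw["female_fraction"],
            refugee_fraction=raw["refugee_fraction"],
            lab_observed_fraction=raw["lab_observed_fraction"],
            n_default=raw["n_default"],
            dependence=raw["dependence"],
        )

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        bad = []
        for frac_name in ("female_fraction", "refugee_fraction", "lab_observed_fraction"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                bad.append(f"{frac_name}={v} outside [0, 1]")
        for sex, params in self.sex_params.items():
            for name, p in params["prevalence"].items():
                if not 0.0 <= p <= 1.0:
                    bad.append(f"{sex}.prevalence.{name}={p} outside [0, 1]")
            for name, p in params["treated_given_dx"].items():
                if not 0.0 <= p <= 1.0:
                    bad.append(f"{sex}.treated_given_dx.{name}={p} outside [0, 1]")
            for name, blk in params.items():
                if isinstance(blk, dict) and "sd" in blk and blk["sd"] <= 0:
                    bad.append(f"{sex}.{name}.sd={blk['sd']} not positive")
        R = self.dependence_matrix()
        if not np.allclose(R, R.T):
            bad.append("dependence matrix not symmetric")
        elif np.linalg.eigvalsh(R).min() < -1e-10:
            bad.append("dependence matrix not positive semidefinite")
        if bad:
            raise ConfigurationError(
                "invalid population specification: " + "; ".join(bad), fields=bad
            )

    def dependence_matrix(self) -> np.ndarray:
        idx = {v: i for i, v in enumerate(_COPULA_VARS)}
        R = np.eye(len(_COPULA_VARS))
        for a, b, rho in self.dependence:
            if a not in idx or b not in idx:
                raise ConfigurationError(f"dependence entry names unknown variable: {a!r}/{b!r}")
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = float(rho)
        return R


def _generate_stratum(params, n, refugee_fraction, chol_factor, rng):
    """Generate one sex stratum from latent multivariate normals."""
    z = rng.standard_normal((n, len(_COPULA_VARS))) @ chol_factor.T
    u = stats.norm.cdf(z)
    out = {}
    for j, name in enumerate(_COPULA_CONTINUOUS):
        if name == "hba1c":
            continue  # filled after diagnoses are known
        blk = params[name]
        if blk.get("dist") == "lognormal":
            out[name] = _lognorm_ppf(u[:, j], blk["mean"], blk["sd"], blk["lo"], blk["hi"])
        else:
            out[name] = _truncnorm_ppf(u[:, j], blk["mean"], blk["sd"], blk["lo"], blk["hi"])
    ncont = len(_COPULA_CONTINUOUS)
    for j, name in enumerate(_COPULA_BOOLEAN):
        p = params["prevalence"][name]
        # high latent value -> trait present, so positive latent correlation
        # with a continuous variable implies positive association
        out[name] = z[:, ncont + j] > stats.norm.ppf(1.0 - p)

    # HbA1c conditional on diabetes diagnosis (the survey measured it almost
    # only among the diagnosed); the latent hba1c coordinate supplies the rank
    u_hba1c = u[:, _COPULA_CONTINUOUS.index("hba1c")]
    dia = out["dx_diabetes"]
    hba1c = np.empty(n)
    for mask, key in ((dia, "hba1c_diabetic"), (~dia, "hba1c_normal")):
        if mask.any():
            blk = params[key]
            hba1c[mask] = _truncnorm_ppf(u_hba1c[mask], blk["mean"], blk["sd"], blk["lo"], blk["hi"])
    out["hba1c"] = hba1c

    out["age"] = np.clip(np.rint(out["age"]), params["age"]["lo"], params["age"]["hi"]).astype(int)
    for rx, dx in _RX_TO_DX.items():
        rate = params["treated_given_dx"][rx]
        out[rx] = out[dx] & (rng.random(n) < rate)
    out["refugee"] = rng.random(n) < refugee_fraction
    return out


def generate_population(spec: PopulationSpec, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` synthetic survey records.

    Deterministic for fixed ``(spec, n, seed)``.  Returns a DataFrame with one
    row per individual; laboratory columns are fully populated (mask them with
    :func:`induce_lab_missingness` to emulate the survey's lab subset).
    """
    if n < 0:
        raise ConfigurationError(f"population size n={n} must be nonnegative")
    spec.validate()
    rng = np.random.default_rng(seed)
    chol_factor = np.linalg.cholesky(
        spec.dependence_matrix() + 1e-12 * np.eye(len(_COPULA_VARS))
    )
    n_female = rng.binomial(n, spec.female_fraction) if n else 0
    frames = []
    for sex, n_sex in (("male", n - n_female), ("female", n_female)):
        stratum = _generate_stratum(
            spec.sex_params[sex], n_sex, spec.refugee_fraction, chol_factor, rng
        )
        stratum["sex"] = np.repeat(sex, n_sex)
        frames.append(pd.DataFrame(stratum))
    pop = pd.concat(frames, ignore_index=True)
    pop.insert(0, "id", [f"p{i:06d}" for i in range(len(pop))])
    return pop[COLUMNS]


def induce_lab_missingness(pop: pd.DataFrame, observed_fraction: float, seed: int) -> pd.DataFrame:
    """Blank the full laboratory block for a random subset of records.

    Each record keeps its labs independently with probability
    ``observed_fraction`` (the lab block is all-or-none, as in the survey
    linkage)."""
    if not 0.0 <= observed_fraction <= 1.0:
        raise ConfigurationError(
            f"observed_fraction={observed_fraction} outside [0, 1]"
        )
    out = pop.copy()
    rng = np.random.default_rng(seed)
    missing = rng.random(len(out)) >= observed_fraction
    out.loc[missing, LAB_FIELDS] = np.nan
    return out


def _pmm_impute(y_obs, yhat_obs, yhat_mis, rng, k=5):
    """Predictive-mean matching with rank standardization: missing cases are
    matched to observed cases by the rank of their predicted value within
    their own set, and one of a k-wide donor window contributes its observed
    value.  Rank matching absorbs the scale/variance mismatch between the
    two prediction sets (missing rows predict from partially imputed
    covariates), so the observed marginal is preserved under
    missing-completely-at-random; donated values are always inside the
    observed range."""
    n_obs, n_mis = len(y_obs), len(yhat_mis)
    order = np.argsort(yhat_obs, kind="stable")
    ranks = np.empty(n_mis)
    ranks[np.argsort(yhat_mis, kind="stable")] = np.arange(n_mis)
    pos = ((ranks + rng.random(n_mis)) / n_mis * n_obs).astype(int)
    lo = np.clip(pos - k // 2, 0, max(n_obs - k, 0))
    offsets = rng.integers(0, min(k, n_obs), size=n_mis)
    donors = order[np.minimum(lo + offsets, n_obs - 1)]
    return y_obs[donors]


def impute_missing(
    pop: pd.DataFrame,
    seed: int,
    n_chains: int = 5,
    strategy: str = "pmm",
    n_sweeps: int = 3,
) -> pd.DataFrame:
    """Complete missing laboratory values by chained-equations imputation.

    Each chain runs ``n_sweeps`` rounds of per-variable regression sweeps with
    predictive-mean matching; ``strategy="cart"`` replaces the linear
    regression with a regression tree (the classification-and-regression-tree
    flavour of chained equations).  Chains are pooled by averaging, which
    keeps every imputed value inside the observed per-variable range.
    Observed records are returned bit-exactly unchanged.
    """
    if strategy not in ("pmm", "cart"):
        raise ConfigurationError(f"unknown imputation strategy {strategy!r}")
    targets = [c for c in LAB_FIELDS if pop[c].isna().any()]
    if not targets:
        return pop.copy()
    for c in targets:
        if pop[c].notna().sum() == 0:
            raise ImputationError(f"variable {c!r} has no observed values to impute from")

    predictors = pd.DataFrame(
        {
            "age": pop["age"].astype(float),
            "female": (pop["sex"] == "female").astype(float),
            "bmi": pop["bmi"].astype(float),
            "sbp": pop["sbp"].astype(float),
            "dx_diabetes": pop["dx_diabetes"].astype(float),
            "dx_hypertension": pop["dx_hypertension"].astype(float),
            "dx_dyslipidemia": pop["dx_dyslipidemia"].astype(float),
            "smoker": pop["smoker"].astype(float),
        }
    )
    if strategy == "cart":
        from sklearn.tree import DecisionTreeRegressor

    ss = np.random.SeedSequence(seed)
    chain_sums = {c: np.zeros(int(pop[c].isna().sum())) for c in targets}
    for chain_seed in ss.spawn(n_chains):
        rng = np.random.default_rng(chain_seed)
        work = pop[LAB_FIELDS].copy()
        for c in targets:  # initial fill: observed mean
            work[c] = work[c].fillna(work[c].mean())
        for _ in range(n_sweeps):
            for c in targets:
                mis = pop[c].isna().to_numpy()
                others = [o for o in LAB_FIELDS if o != c]
                X = pd.concat([predictors, work[others]], axis=1).to_numpy()
                y_obs = pop[c].to_numpy()[~mis]
                if strategy == "cart":
                    model = DecisionTreeRegressor(
                        max_depth=6, min_samples_leaf=10,
                        random_state=int(rng.integers(2**31)),
                    ).fit(X[~mis], y_obs)
                    yhat_obs, yhat_mis = model.predict(X[~mis]), model.predict(X[mis])
                else:
                    A = np.column_stack([np.ones(len(X)), X])
                    coef, *_ = np.linalg.lstsq(A[~mis], y_obs, rcond=None)
                    yhat_obs, yhat_mis = A[~mis] @ coef, A[mis] @ coef
                work.loc[mis, c] = _pmm_impute(y_obs, yhat_obs, yhat_mis, rng)
        for c in targets:
            chain_sums[c] += work.loc[pop[c].isna(), c].to_numpy()

    out = pop.copy()
    for c in targets:
        out.loc[pop[c].isna(), c] = chain_sums[c] / n_chains
    return out


def write_population_csv(pop: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write records as CSV (missing labs as empty cells); the generating seed
    is recorded in a header comment for reproducibility."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# ncdsim population; seed={seed}\n")
        pop.to_csv(fh, index=False)


def read_population_csv(path) -> pd.DataFrame:
    pop = pd.read_csv(path, comment="#")
    for c in _COPULA_BOOLEAN + list(_RX_TO_DX) + ["refugee"]:
        pop[c] = pop[c].astype(bool)
    return pop
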