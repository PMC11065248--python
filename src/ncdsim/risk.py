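"""Per-condition annual incidence risk models.

Each of the five modeled conditions (CVD, type 2 diabetes, asthma/COPD,
breast cancer, colorectal cancer) gets an annual hazard function in the
style of a published risk-score family:

* ``globorisk_lab_mean3`` — a Globorisk-style laboratory model whose 10-year
  risk is the arithmetic mean of three country-specific risks (Jordan,
  Lebanon, Syria) computed on the same profile;
* ``findrisc`` — the FINDRISC additive point score mapped to a 10-year
  diabetes probability (waist-circumference points are carried by the BMI
  category because waist was not surveyed);
* ``rr_multiplicative`` — age-trended baseline hazard times prior-diagnosis
  and smoke-exposure rate ratios (asthma/COPD);
* ``gail_style`` — age-band baseline incidence for women times configurable
  relative-risk multipliers (breast cancer; zero for men);
* ``crcpro_style`` — age-trended baseline hazard with sex, smoking and BMI
  multipliers (colorectal cancer).

Ten-year risks are converted to annual hazards under a constant-hazard
assumption, ``h = -ln(1 - p10) / 10``.  The annual incidence probability is
``1 - exp(-calibration_scale * h)``; the calibration scale is fitted
downstream so the simulated population reproduces external incidence
targets, which makes burden outputs insensitive to modest differences
between these shipped coefficients and any particular published table.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ModelInputError

__all__ = [
    "CONDITIONS",
    "ConditionModel",
    "annual_hazard",
    "annual_risk",
    "default_models",
    "findrisc_points",
    "smoke_exposure_rr",
]

CONDITIONS = ["cvd", "diabetes", "asthma_copd", "breast_cancer", "colorectal_cancer"]

_REQUIRED_FIELDS = {
    "globorisk_lab_mean3": ["age", "sex", "sbp", "total_chol", "dx_diabetes", "smoker"],
    "findrisc": ["age", "bmi", "rx_hypertension"],
    "rr_multiplicative": ["age", "dx_asthma_copd", "smoker"],
    "gail_style": ["age", "sex"],
    "crcpro_style": ["age", "sex", "smoker", "bmi"],
}


@dataclass
class ConditionModel:
    """A per-condition annual-risk function plus its calibration scales.

    ``calibration_scale`` multiplies the incidence hazard; ``fatality_scale``
    multiplies the annual case-fatality hazard among prevalent cases.  Both
    default to 1 (uncalibrated).
    """

    condition: str
    score_family: str
    params: dict = field(default_factory=dict)
    calibration_scale: float = 1.0
    fatality_scale: float = 1.0

    def __post_init__(self):
        if self.calibration_scale < 0:
            raise ConfigurationError(
                f"{self.condition}: calibration_scale must be nonnegative"
            )
        if self.score_family not in _REQUIRED_FIELDS:
            raise ConfigurationError(
                f"{self.condition}: unknown score_family {self.score_family!r}"
            )

    def with_scale(self, calibration_scale=None, fatality_scale=None) -> "ConditionModel":
        kw = {}
        if calibration_scale is not None:
            kw["calibration_scale"] = calibration_scale
        if fatality_scale is not None:
            kw["fatality_scale"] = fatality_scale
        return replace(self, **kw)


@functools.lru_cache(maxsize=1)
def _coefficient_fixture() -> dict:
    with resources.files("ncdsim.data").joinpath("risk_coefficients.yaml").open() as fh:
        return yaml.safe_load(fh)


def default_models() -> dict[str, ConditionModel]:
    """The shipped coefficient fixture as a registry keyed by condition."""
    raw = _coefficient_fixture()
    return {
        cond: ConditionModel(cond, raw[cond]["score_family"], raw[cond]["params"])
        for cond in CONDITIONS
    }


def _as_frame(profile) -> pd.DataFrame:
    if isinstance(profile, pd.DataFrame):
        return profile
    if isinstance(profile, pd.Series):
        return profile.to_frame().T
    return pd.DataFrame([profile])


def _require(df: pd.DataFrame, fields, family: str):
    for f in fields:
        if f not in df.columns:
            raise ModelInputError(f"{family}: required field {f!r} missing from profile")
        if pd.isna(df[f]).any():
            raise ModelInputError(f"{family}: required field {f!r} contains missing values")


def _ten_year_to_annual(p10: np.ndarray, horizon: float = 10.0) -> np.ndarray:
    p10 = np.clip(p10, 0.0, 1.0 - 1e-12)
    return -np.log1p(-p10) / horizon


# -- score families ---------------------------------------------------------

def _hazard_globorisk(df, params):
    c = params["centers"]
    lp = (
        params["beta_age"] * (df["age"].to_numpy(float) - c["age"])
        + params["beta_male"] * (df["sex"] == "male").to_numpy(float)
        + params["beta_sbp"] * (df["sbp"].to_numpy(float) - c["sbp"])
        + params["beta_tchol"] * (df["total_chol"].to_numpy(float) - c["total_chol"])
        + params["beta_diabetes"] * df["dx_diabetes"].to_numpy(float)
        + params["beta_smoker"] * df["smoker"].to_numpy(float)
    )
    risks = [
        1.0 - np.exp(-h0 * np.exp(lp)) for h0 in params["country_h0_10yr"].values()
    ]
    p10 = np.mean(risks, axis=0)
    return _ten_year_to_annual(p10, params.get("horizon_years", 10))


def _points_from_bands(x, bands):
    pts = np.zeros(len(x))
    for lo, hi, p in bands:
        pts = np.where((x >= lo) & (x < hi), p, pts)
    return pts


def findrisc_points(profile) -> np.ndarray:
    """FINDRISC additive point score (integer, >= 0).

    Monotone nondecreasing in age category and BMI category; the
    antihypertensive-medication item uses the surveyed treatment flag.
    """
    df = _as_frame(profile)
    _require(df, _REQUIRED_FIELDS["findrisc"], "findrisc")
    params = default_models()["diabetes"].params
    pts = (
        _points_from_bands(df["age"].to_numpy(float), params["age_points"])
        + _points_from_bands(df["bmi"].to_numpy(float), params["bmi_points"])
        + params["antihypertensive_points"] * df["rx_hypertension"].to_numpy(float)
        + params["inactivity_points"]
    )
    return pts.astype(int)


def _hazard_findrisc(df, params):
    pts = (
        _points_from_bands(df["age"].to_numpy(float), params["age_points"])
        + _points_from_bands(df["bmi"].to_numpy(float), params["bmi_points"])
        + params["antihypertensive_points"] * df["rx_hypertension"].to_numpy(float)
        + params["inactivity_points"]
    )
    p10 = _points_from_bands(pts, params["risk_table"])
    return _ten_year_to_annual(p10, params.get("horizon_years", 10))


def smoke_exposure_rr(profile, context=None, params=None) -> np.ndarray:
    """Multiplicative rate ratio for tobacco-smoke exposure.

    ``context={"secondhand_exposed": bool}`` adds the second-hand component;
    active smoking and second-hand exposure combine as a product of their
    rate ratios.  Equals 1 where neither applies.
    """
    df = _as_frame(profile)
    _require(df, ["smoker"], "smoke_exposure_rr")
    if params is None:
        params = default_models()["asthma_copd"].params
    active = params["active_smoking_rr"]
    second = params["secondhand_rr"]
    if active <= 0 or second <= 0:
        raise ConfigurationError("smoke-exposure rate ratios must be positive")
    rr = np.where(df["smoker"].to_numpy(bool), active, 1.0)
    if context and context.get("secondhand_exposed"):
        rr = rr * second
    return rr


def _hazard_rr_multiplicative(df, params):
    h = params["baseline_annual_hazard"] * np.exp(
        params["beta_age"] * (df["age"].to_numpy(float) - params["center_age"])
    )
    h = h * np.where(df["dx_asthma_copd"].to_numpy(bool), params["prior_dx_rr"], 1.0)
    h = h * smoke_exposure_rr(df, params=params)
    return h


def _hazard_gail(df, params):
    h = _points_from_bands(df["age"].to_numpy(float), params["age_hazard"])
    h = h * params.get("rr_family_history", 1.0)
    return np.where((df["sex"] == "female").to_numpy(), h, 0.0)


def _hazard_crcpro(df, params):
    h = params["baseline_annual_hazard"] * np.exp(
        params["beta_age"] * (df["age"].to_numpy(float) - params["center_age"])
    )
    h = h * np.where((df["sex"] == "male").to_numpy(), params["male_rr"], 1.0)
    h = h * np.where(df["smoker"].to_numpy(bool), params["smoker_rr"], 1.0)
    bmi_excess = np.clip((df["bmi"].to_numpy(float) - 25.0) / 5.0, 0.0, None)
    h = h * params["bmi_rr_per_5"] ** bmi_excess
    return h


_FAMILIES = {
    "globorisk_lab_mean3": _hazard_globorisk,
    "findrisc": _hazard_findrisc,
    "rr_multiplicative": _hazard_rr_multiplicative,
    "gail_style": _hazard_gail,
    "crcpro_style": _hazard_crcpro,
}


def annual_hazard(model: ConditionModel, profile) -> np.ndarray:
    """Uncalibrated annual hazard of the model's score family on a profile
    (DataFrame, Series or mapping).  Vectorized over rows."""
    df = _as_frame(profile)
    _require(df, _REQUIRED_FIELDS[model.score_family], model.score_family)
    return np.asarray(_FAMILIES[model.score_family](df, model.params), dtype=float)


def annual_risk(model: ConditionModel, profile) -> np.ndarray:
    """Calibrated annual incidence probability, ``1 - exp(-scale * h)``.

    Always in [0, 1]; monotone nondecreasing in every adverse factor the
    score family uses, and exactly linear in ``calibration_scale`` on the
    cumulative-hazard scale.
    """
    h = annual_hazard(model, profile)
    return 1.0 - np.exp(-model.calibration_scale * h)
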