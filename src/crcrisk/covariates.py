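"""Derivation of binary risk indicators from raw variables, and imputation.

The raw interview/FFQ variables are dichotomised at the study cut-offs:

* alcohol: high if >4 standard units/day (men) or >2 (women), averaged
  over ages 30-40;
* BMI (at age 45): obese if >= 30 kg/m2 (inclusive);
* leisure-time physical activity: none if exactly 0 MET h/week;
* vegetables: low intake if <= 200 g/day (inclusive);
* red meat: high intake if > 65 g/day (strict);
* NSAID/ASA: risk category is non-use or sporadic use;
* smoking: ever (former or current) vs never — derived but excluded from
  the environmental score;
* family history: any first/second/third-degree relative, one flag.

Missing values pass through dichotomisation as missing and are handled by
:func:`impute_missing`: continuous variables get the expected value from an
ordinary least-squares model fitted on complete cases (default predictors:
age, sex, case status); categorical and binary variables get the modal
category among complete cases.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .scores import ERS_FACTORS

__all__ = [
    "ALCOHOL_CUTOFF_SUA",
    "CONTINUOUS_VARS",
    "derive_profile",
    "impute_missing",
]

#: Sex-specific high-consumption thresholds, standard units of alcohol/day.
ALCOHOL_CUTOFF_SUA = {"male": 4.0, "female": 2.0}

BMI_OBESE = 30.0  # kg/m2, inclusive
VEGETABLES_LOW = 200.0  # g/day, inclusive
RED_MEAT_HIGH = 65.0  # g/day, strict

#: Raw variables imputed by regression rather than by mode.
CONTINUOUS_VARS = (
    "alcohol_sua_day",
    "bmi",
    "met_h_week",
    "red_meat_g_day",
    "vegetables_g_day",
)

RAW_VARS = CONTINUOUS_VARS + ("nsaid_regular_use", "smoking_status", "family_history")

#: Indicator column derived from each raw variable (masking cascades).
RAW_DERIVED = {
    "alcohol_sua_day": "alcohol_high",
    "bmi": "obese",
    "met_h_week": "no_physical_activity",
    "vegetables_g_day": "low_vegetables",
    "red_meat_g_day": "high_red_meat",
    "nsaid_regular_use": "no_nsaid_asa",
    "smoking_status": "smoker_ever",
}


def _risk_flag(condition: pd.Series, observed: pd.Series) -> pd.Series:
    """Binary indicator with missingness propagated from the raw variable."""
    out = condition.astype("float")
    out[observed.isna()] = np.nan
    return out


def derive_profile(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append the binary risk-indicator columns to a cohort table.

    Idempotent: indicator columns are recomputed from the raw variables each
    call.  Negative intakes or BMI are rejected; missing raw values yield
    missing indicators (impute afterwards).
    """
    required = {"sex", "alcohol_sua_day", "bmi", "met_h_week",
                "red_meat_g_day", "vegetables_g_day", "nsaid_regular_use"}
    missing_cols = required - set(cohort.columns)
    if missing_cols:
        raise ValueError(f"cohort lacks raw variables: {sorted(missing_cols)}")
    for col in CONTINUOUS_VARS:
        if (cohort[col].dropna() < 0).any():
            raise ValueError(f"negative values in {col}")

    out = cohort.copy()
    cutoff = out["sex"].map(ALCOHOL_CUTOFF_SUA)
    if cutoff.isna().any():
        bad = sorted(out.loc[cutoff.isna(), "sex"].unique())
        raise ValueError(f"unrecognised sex labels: {bad}")
    out["alcohol_high"] = _risk_flag(out["alcohol_sua_day"] > cutoff,
                                     out["alcohol_sua_day"])
    out["obese"] = _risk_flag(out["bmi"] >= BMI_OBESE, out["bmi"])
    out["no_physical_activity"] = _risk_flag(out["met_h_week"] == 0.0,
                                             out["met_h_week"])
    out["low_vegetables"] = _risk_flag(out["vegetables_g_day"] <= VEGETABLES_LOW,
                                       out["vegetables_g_day"])
    out["high_red_meat"] = _risk_flag(out["red_meat_g_day"] > RED_MEAT_HIGH,
                                      out["red_meat_g_day"])
    out["no_nsaid_asa"] = _risk_flag(out["nsaid_regular_use"] == 0,
                                     out["nsaid_regular_use"])
    if "smoking_status" in out.columns:
        out["smoker_ever"] = _risk_flag(
            out["smoking_status"].isin(["former", "current"]),
            out["smoking_status"],
        )
    return out


def _impute_continuous(
    cohort: pd.DataFrame, col: str, predictors: tuple[str, ...]
) -> pd.Series:
    """OLS expected value from complete cases; falls back to the mean when
    no predictors are available."""
    target = cohort[col]
    mask = target.isna()
    preds = [p for p in predictors if p in cohort.columns]
    X = pd.DataFrame(index=cohort.index)
    X["const"] = 1.0
    for p in preds:
        v = cohort[p]
        X[p] = v.map({"male": 1.0, "female": 0.0}) if p == "sex" else v.astype(float)
    complete = ~mask & X.notna().all(axis=1)
    if not complete.any():
        raise ValueError(f"variable {col!r} has no complete cases to impute from")
    beta, *_ = np.linalg.lstsq(
        X[complete].to_numpy(float), target[complete].to_numpy(float), rcond=None
    )
    filled = target.copy()
    filled[mask] = X[mask].to_numpy(float) @ beta
    return filled


def impute_missing(
    cohort: pd.DataFrame,
    predictors: tuple[str, ...] = ("age", "sex", "case_status"),
) -> pd.DataFrame:
    """Deterministically fill every missing cell in a cohort table.

    Continuous variables (``CONTINUOUS_VARS``) are imputed with the fitted
    expected value of an OLS regression on ``predictors`` among complete
    cases; all other columns with missing values get the modal value among
    complete cases.  Observed cells are never altered.
    """
    out = cohort.copy()
    if not out.isna().any().any():
        return out
    for col in out.columns:
        n_missing = out[col].isna().sum()
        if n_missing == 0:
            continue
        if n_missing == len(out):
            raise ValueError(f"variable {col!r} is missing for all subjects")
        if col in CONTINUOUS_VARS:
            out[col] = _impute_continuous(out, col, predictors)
        else:
            mode = out[col].mode(dropna=True)
            out[col] = out[col].fillna(mode.iloc[0])
    # re-derive indicators so imputed raw values propagate consistently;
    # observed cells are unaffected because dichotomisation is deterministic
    raw_needed = {"sex", "alcohol_sua_day", "bmi", "met_h_week",
                  "red_meat_g_day", "vegetables_g_day", "nsaid_regular_use"}
    if raw_needed <= set(out.columns) and set(ERS_FACTORS) & set(out.columns):
        out = derive_profile(out)
        if "ers" in out.columns and set(ERS_FACTORS) <= set(out.columns):
            from .scores import compute_ers

            out["ers"] = compute_ers(out)
    return out
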