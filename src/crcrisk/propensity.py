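"""Propensity score for the frequency-matched case-control design.

Because controls are frequency-matched to cases on age, sex and region,
those variables cannot enter the risk model as ordinary predictors.
Instead, case/control status is regressed on the design and matching
variables — age, sex, education, recruiting centre, three genetic-ancestry
components, plus age x sex and centre x sex interactions — and each
subject's logit-scale prediction is carried into every downstream risk
model as one continuous adjustment covariate (``ps``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = ["PropensityFit", "fit_propensity", "attach_propensity"]

DEFAULT_FORMULA = (
    "age + C(sex) + C(education) + C(region) + pc1 + pc2 + pc3"
    " + age:C(sex) + C(region):C(sex)"
)
BANDED_FORMULA = (
    "C(age_band) + C(sex) + C(education) + C(region) + pc1 + pc2 + pc3"
    " + C(age_band):C(sex) + C(region):C(sex)"
)


class SeparationError(RuntimeError):
    """The propensity design perfectly separates cases from controls."""


@dataclass
class PropensityFit:
    """Fitted propensity model: coefficients over the identifiable design
    columns plus the training-sample linear predictors (logit scale)."""

    params: pd.Series
    linear_predictor: pd.Series
    design_info: "patsy.DesignInfo"
    kept_columns: np.ndarray
    dropped_columns: list[str]

    def predict(self, cohort: pd.DataFrame) -> pd.Series:
        """Logit-scale predictions for new subjects.

        Raises if the cohort carries factor levels unseen at fit time
        (e.g. a new recruiting centre).
        """
        try:
            (X,) = patsy.build_design_matrices(
                [self.design_info], cohort, return_type="dataframe"
            )
        except patsy.PatsyError as err:
            raise ValueError(f"cohort incompatible with propensity design: {err}")
        lp = np.asarray(X)[:, self.kept_columns] @ self.params.to_numpy()
        return pd.Series(lp, index=cohort.index, name="ps")


def _prune_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Indices of a maximal linearly independent column subset (pivoted QR)."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    dropped = [names[i] for i in sorted(set(range(X.shape[1])) - set(keep))]
    return keep, dropped


def fit_propensity(
    cohort: pd.DataFrame,
    formula: str | None = None,
    age_in_bands: bool = False,
) -> PropensityFit:
    """Logistic regression of case status on the matching/design variables.

    Age enters linearly by default; ``age_in_bands=True`` switches to
    5-year-band indicators.  Columns that make the design rank-deficient
    (e.g. a centre recruiting one sex only, which leaves centre x sex
    collinear) are dropped with a logged warning.  Perfect separation is
    reported as an explicit error.
    """
    if formula is None:
        formula = BANDED_FORMULA if age_in_bands else DEFAULT_FORMULA
    data = cohort.copy()
    if age_in_bands and "age_band" not in data.columns:
        data["age_band"] = (data["age"] // 5 * 5).astype(int)
    y = data["case_status"].to_numpy(float)
    X = patsy.dmatrix(formula, data, return_type="dataframe")
    design_info = X.design_info
    names = list(X.columns)
    Xv = np.asarray(X)

    keep, dropped = _prune_collinear(Xv, names)
    if dropped:
        logger.warning("propensity design rank-deficient; dropping %s", dropped)
    Xk = Xv[:, keep]

    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation is re-raised below
            fit = sm.GLM(y, Xk, family=sm.families.Binomial()).fit(maxiter=200)
    except Exception as err:  # statsmodels raises PerfectSeparationError et al.
        raise SeparationError(f"propensity fit failed: {err}") from err
    if not np.all(np.isfinite(fit.params)) or np.abs(fit.params).max() > 30:
        raise SeparationError(
            "propensity model shows complete or quasi-complete separation"
        )

    lp = Xk @ fit.params
    return PropensityFit(
        params=pd.Series(fit.params, index=[names[i] for i in keep]),
        linear_predictor=pd.Series(lp, index=cohort.index, name="ps"),
        design_info=design_info,
        kept_columns=keep,
        dropped_columns=dropped,
    )


def attach_propensity(cohort: pd.DataFrame, fit: PropensityFit) -> pd.DataFrame:
    """Return the cohort with a ``ps`` column of logit-scale predictions."""
    out = cohort.copy()
    out["ps"] = fit.predict(cohort)
    return out
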