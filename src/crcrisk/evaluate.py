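"""Risk-model fitting and propensity-stratified predictive evaluation.

The multivariate risk model is a propensity-adjusted logistic regression of
case status on either the six environmental indicators plus family history
and GRS (factor-level) or on the ERS count plus family history and GRS
(score-level).

Discrimination is summarised with an AUROC adapted to the matched design:
subjects are split into propensity-score quintiles, the AUROC is computed
within each quintile, and the quintile AUROCs are averaged with weights
proportional to the number of cases per quintile.  A 5-fold
cross-validated variant refits the model on held-out folds, and bootstrap
resampling of subjects (CV re-run per resample) yields percentile
confidence intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .scores import ERS_FACTORS

logger = logging.getLogger(__name__)

__all__ = [
    "TwoByTwo",
    "RiskModelFit",
    "AurocEstimate",
    "FACTOR_MODEL_TERMS",
    "SCORE_MODEL_TERMS",
    "fit_risk_model",
    "crude_or",
    "plain_auroc",
    "ps_stratified_auroc",
    "cv_auroc",
    "apparent_auroc",
    "cumulative_auroc_curve",
    "screening_performance",
]

Z95 = 1.959963984540054

FACTOR_MODEL_TERMS = list(ERS_FACTORS) + ["family_history", "grs"]
SCORE_MODEL_TERMS = ["ers", "family_history", "grs"]


class DegenerateStratumError(ValueError):
    """A propensity stratum has cases but no controls (AUROC undefined)."""


class ModelFitError(RuntimeError):
    """Risk-model maximum likelihood failed (separation or non-convergence)."""


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure-by-outcome counts: (cases, controls) x (exposed, unexposed)."""

    exposed_cases: int
    exposed_controls: int
    unexposed_cases: int
    unexposed_controls: int

    def __post_init__(self) -> None:
        for v in (self.exposed_cases, self.exposed_controls,
                  self.unexposed_cases, self.unexposed_controls):
            if v < 0 or v != int(v):
                raise ValueError("counts must be non-negative integers")


@dataclass
class RiskModelFit:
    """Fitted propensity-adjusted logistic risk model."""

    table: pd.DataFrame  # index: term; columns: or_, ci_low, ci_high, beta, se
    loglik: float
    terms: list[str]

    @property
    def odds_ratios(self) -> pd.Series:
        return self.table["or_"]

    def linear_predictor(self, cohort: pd.DataFrame) -> np.ndarray:
        cols = ["const"] + self.terms + ["ps"]
        X = np.column_stack(
            [np.ones(len(cohort))]
            + [cohort[t].to_numpy(float) for t in self.terms]
            + [cohort["ps"].to_numpy(float)]
        )
        return X @ self.table.loc[cols, "beta"].to_numpy()


@dataclass
class AurocEstimate:
    estimate: float
    ci_low: float | None = None
    ci_high: float | None = None
    method: str = "plain"
    stratum_aurocs: np.ndarray | None = field(default=None, repr=False)


def fit_risk_model(cohort: pd.DataFrame, terms: list[str] | None = None) -> RiskModelFit:
    """Propensity-adjusted logistic fit of case status on ``terms``.

    ``terms`` defaults to the score-level model (ERS count, family history,
    GRS).  The ``ps`` column is always appended as a continuous covariate.
    Odds ratios are exponentiated coefficients with 95% Wald intervals.
    """
    terms = list(terms) if terms is not None else list(SCORE_MODEL_TERMS)
    missing = [t for t in terms + ["ps", "case_status"] if t not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks columns {missing}")
    y = cohort["case_status"].to_numpy(float)
    X = np.column_stack(
        [np.ones(len(cohort))]
        + [cohort[t].to_numpy(float) for t in terms]
        + [cohort["ps"].to_numpy(float)]
    )
    if np.isnan(X).any():
        raise ValueError("missing covariate values: impute first")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    except Exception as err:
        raise ModelFitError(f"logistic fit failed: {err}") from err
    if not np.all(np.isfinite(fit.params)) or np.abs(fit.params[1:]).max() > 30:
        raise ModelFitError(
            "risk model did not converge to finite estimates (separation?)"
        )
    names = ["const"] + terms + ["ps"]
    beta, se = np.asarray(fit.params), np.asarray(fit.bse)
    table = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "or_": np.exp(beta),
            "ci_low": np.exp(beta - Z95 * se),
            "ci_high": np.exp(beta + Z95 * se),
        },
        index=names,
    )
    return RiskModelFit(table=table, loglik=float(fit.llf), terms=terms)


def crude_or(table: TwoByTwo) -> dict[str, float]:
    """Woolf crude odds ratio with a 95% log-scale interval.

    No continuity correction: a zero cell is an explicit error.
    """
    a, b = table.exposed_cases, table.exposed_controls
    c, d = table.unexposed_cases, table.unexposed_controls
    if min(a, b, c, d) == 0:
        raise ValueError("zero cell in 2x2 table; odds ratio undefined")
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return {
        "or_": or_,
        "ci_low": float(np.exp(np.log(or_) - Z95 * se)),
        "ci_high": float(np.exp(np.log(or_) + Z95 * se)),
    }


def plain_auroc(scores, labels) -> float:
    """Rank (Mann-Whitney) AUROC; tied scores count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("need both cases and controls")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _strata(ps: np.ndarray, n_strata: int) -> np.ndarray:
    """Quantile stratum index per subject; ties on a boundary fall to the
    lower stratum."""
    edges = np.quantile(ps, np.linspace(0, 1, n_strata + 1)[1:-1])
    return np.searchsorted(edges, ps, side="left")


def ps_stratified_auroc(
    scores, labels, ps, n_strata: int = 5
) -> AurocEstimate:
    """Case-weighted mean AUROC over propensity-score quantile strata.

    Strata are quantiles of ``ps`` over the pooled sample; the stratum
    AUROCs are averaged with weights proportional to each stratum's case
    count.  A stratum without cases gets weight zero (logged); a stratum
    with cases but no controls is an error.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    ps = np.asarray(ps, dtype=float)
    strata = _strata(ps, n_strata)
    aurocs, weights = [], []
    for s in range(n_strata):
        m = strata == s
        n_cases = int(labels[m].sum())
        n_controls = int(m.sum() - n_cases)
        if n_cases == 0:
            logger.warning("propensity stratum %d has no cases; weight 0", s)
            continue
        if n_controls == 0:
            raise DegenerateStratumError(
                f"propensity stratum {s} has cases but no controls"
            )
        aurocs.append(plain_auroc(scores[m], labels[m]))
        weights.append(n_cases)
    w = np.asarray(weights, dtype=float)
    a = np.asarray(aurocs)
    return AurocEstimate(
        estimate=float((w * a).sum() / w.sum()),
        method="ps_stratified",
        stratum_aurocs=a,
    )


def _cv_scores(
    cohort: pd.DataFrame, terms: list[str], k: int, rng: np.random.Generator
) -> np.ndarray:
    """Held-out linear predictors from k-fold CV stratified by case status."""
    y = cohort["case_status"].to_numpy(int)
    skf = StratifiedKFold(
        n_splits=k, shuffle=True, random_state=int(rng.integers(2**31))
    )
    out = np.empty(len(cohort))
    for train, test in skf.split(np.zeros(len(y)), y):
        fit = fit_risk_model(cohort.iloc[train], terms)
        out[test] = fit.linear_predictor(cohort.iloc[test])
    return out


def cv_auroc(
    cohort: pd.DataFrame,
    terms: list[str] | None = None,
    k: int = 5,
    n_boot: int = 200,
    seed: int | np.random.Generator = 0,
    n_strata: int = 5,
) -> AurocEstimate:
    """Propensity-stratified AUROC under k-fold cross-validation.

    The model is refit on each set of k-1 folds and scored on the held-out
    fold; the pooled held-out scores enter the stratified AUROC.  The 95%
    CI is a percentile bootstrap over subject resamples, repeating the full
    CV per resample (``n_boot=0`` skips the interval).
    """
    terms = list(terms) if terms is not None else list(SCORE_MODEL_TERMS)
    if k < 2:
        raise ValueError("k must be >= 2")
    if cohort["case_status"].sum() < k:
        raise ValueError("too few cases to populate every fold")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scores = _cv_scores(cohort, terms, k, rng)
    point = ps_stratified_auroc(
        scores, cohort["case_status"].to_numpy(int), cohort["ps"].to_numpy(), n_strata
    )
    ci_low = ci_high = None
    if n_boot > 0:
        estimates = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(cohort), len(cohort))
            boot = cohort.iloc[idx].reset_index(drop=True)
            if boot["case_status"].sum() < k or boot["case_status"].sum() == len(boot):
                continue
            try:
                s = _cv_scores(boot, terms, k, rng)
                est = ps_stratified_auroc(
                    s, boot["case_status"].to_numpy(int),
                    boot["ps"].to_numpy(), n_strata,
                )
            except (DegenerateStratumError, ModelFitError, ValueError):
                continue
            estimates.append(est.estimate)
        if len(estimates) < 0.8 * n_boot:
            raise RuntimeError(
                f"bootstrap unstable: only {len(estimates)}/{n_boot} resamples usable"
            )
        ci_low, ci_high = np.percentile(estimates, [2.5, 97.5])
    return AurocEstimate(
        estimate=point.estimate,
        ci_low=None if ci_low is None else float(ci_low),
        ci_high=None if ci_high is None else float(ci_high),
        method="cv_ps_stratified",
    )


def apparent_auroc(
    cohort: pd.DataFrame, terms: list[str] | None = None, n_strata: int = 5
) -> AurocEstimate:
    """Resubstitution (no cross-validation) stratified AUROC."""
    terms = list(terms) if terms is not None else list(SCORE_MODEL_TERMS)
    fit = fit_risk_model(cohort, terms)
    return ps_stratified_auroc(
        fit.linear_predictor(cohort),
        cohort["case_status"].to_numpy(int),
        cohort["ps"].to_numpy(),
        n_strata,
    )


def cumulative_auroc_curve(
    cohort: pd.DataFrame,
    variables: list[str],
    k: int = 5,
    seed: int = 0,
    cross_validated: bool = True,
) -> pd.DataFrame:
    """Individual and cumulative model AUROC, one row per added variable.

    Variables are sorted by their individual AUROC (ascending) and added to
    the model one at a time; the cumulative column therefore ends at the
    full-model AUROC.
    """
    def one(terms: list[str]) -> float:
        if cross_validated:
            # same seed, hence same folds, for every model in the curve
            return cv_auroc(cohort, terms, k=k, n_boot=0, seed=seed).estimate
        return apparent_auroc(cohort, terms).estimate

    individual = {v: one([v]) for v in variables}
    order = sorted(variables, key=individual.get)
    rows = []
    for i in range(len(order)):
        rows.append(
            {
                "variable": order[i],
                "individual_auroc": individual[order[i]],
                "cumulative_auroc": one(order[: i + 1]),
            }
        )
    return pd.DataFrame(rows)


def likelihood_ratios(sens: float, spec: float) -> tuple[float, float]:
    """Positive and negative likelihood ratios from percent sens/spec.

    PLR = sens/(100-spec), NLR = (100-sens)/spec; a vanishing denominator
    yields ``inf``.
    """
    if not (0.0 <= sens <= 100.0 and 0.0 <= spec <= 100.0):
        raise ValueError("sensitivity and specificity must be in [0, 100]")
    plr = sens / (100.0 - spec) if spec < 100.0 else np.inf
    nlr = (100.0 - sens) / spec if spec > 0.0 else np.inf
    return plr, nlr


def screening_performance(rs, labels, cutoffs) -> pd.DataFrame:
    """Sensitivity, specificity and likelihood ratios at each RS cut-off.

    ``RS >= cutoff`` is test-positive.  Sensitivity and specificity are in
    percent; PLR = sens/(100-spec) and NLR = (100-sens)/spec, reported as
    ``inf`` with a flag where the denominator vanishes.
    """
    rs = np.asarray(rs, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(rs)):
        raise ValueError("non-finite risk scores")
    cases, controls = rs[labels == 1], rs[labels == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("need both cases and controls")
    rows = []
    for cut in np.atleast_1d(np.asarray(cutoffs, dtype=float)):
        sens = 100.0 * (cases >= cut).mean()
        spec = 100.0 * (controls < cut).mean()
        plr, nlr = likelihood_ratios(sens, spec)
        rows.append(
            {
                "cutoff": cut,
                "sensitivity": sens,
                "specificity": spec,
                "positive_lr": plr,
                "negative_lr": nlr,
                "plr_undefined": spec >= 100.0,
                "nlr_undefined": spec <= 0.0,
            }
        )
    return pd.DataFrame(rows)
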