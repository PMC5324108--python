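"""Environmental, genetic, and combined risk scores.

Three scores summarise a subject's risk profile:

* **ERS** — environmental risk score: the count (0-6) of modifiable binary
  risk indicators (high alcohol, obesity, no leisure-time physical
  activity, low vegetable intake, high red-meat intake, NSAID/ASA
  non-use).  Family history and smoking are deliberately excluded.
* **GRS** — genetic risk score: the count of risk alleles over a SNP
  panel.  Autosomal genotypes contribute 0, 1 or 2; the X-linked SNP is
  coded 0, 0.5, 1 so its contribution is on a comparable scale in both
  sexes (males, hemizygous, contribute 0 or 0.5).  A weighted variant
  multiplies the coded allele counts by per-SNP log-odds weights.
* **RS** — relative risk score: the multiplicative combination

      RS = OR_E^(ERS - e_ref) * OR_F^FH * OR_G^(GRS - g_ref)

  normalised so that the population-average profile (ERS = e_ref, no
  family history, GRS = g_ref) has RS = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import SnpPanel

__all__ = [
    "ERS_FACTORS",
    "RiskScoreParams",
    "GrsWeights",
    "compute_grs",
    "compute_ers",
    "compute_rs",
    "grs_group_contrast",
    "refit_weights",
]

#: The six modifiable binary indicators entering the ERS, in canonical order.
ERS_FACTORS = (
    "alcohol_high",
    "obese",
    "no_physical_activity",
    "low_vegetables",
    "high_red_meat",
    "no_nsaid_asa",
)


@dataclass(frozen=True)
class RiskScoreParams:
    """Odds ratios and reference values for the combined risk score.

    Defaults are the fitted multivariate score-level odds ratios (per
    environmental factor 1.36, family history 2.25, per risk allele 1.07)
    with population-average references ERS = 3 and GRS = 22.
    """

    or_per_factor: float = 1.36
    or_fh: float = 2.25
    or_per_allele: float = 1.07
    ers_reference: float = 3.0
    grs_reference: float = 22.0

    def __post_init__(self) -> None:
        for name in ("or_per_factor", "or_fh", "or_per_allele"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GrsWeights:
    """Per-SNP log-odds weights aligned with a panel's SNP order."""

    values: np.ndarray
    source: str = "unweighted"  # {unweighted, published, refitted}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("GRS weights must be finite")

    @classmethod
    def unweighted(cls, panel: SnpPanel) -> "GrsWeights":
        return cls(np.ones(len(panel)), source="unweighted")

    @classmethod
    def published(cls, panel: SnpPanel) -> "GrsWeights":
        """Weights from the discovery-GWAS odds ratios: ln(published OR)."""
        return cls(panel.published_log_or.to_numpy(), source="published")


def _coded_genotypes(genotypes: pd.DataFrame, panel: SnpPanel) -> pd.DataFrame:
    """Validate genotypes against a panel and apply the X-chromosome coding.

    Returns allele counts with the X-linked column halved, so autosomes are
    0/1/2 and X is 0/0.5/1 (0/0.5 for hemizygous males).
    """
    missing_cols = [r for r in panel.rsids if r not in genotypes.columns]
    if missing_cols:
        raise ValueError(f"genotype table lacks panel SNPs: {missing_cols}")
    g = genotypes[panel.rsids].astype(float)
    if g.isna().any().any():
        raise ValueError("missing genotypes: impute or drop subjects upstream")
    if not g.isin([0.0, 1.0, 2.0]).all().all():
        bad = g.columns[~g.isin([0.0, 1.0, 2.0]).all()].tolist()
        raise ValueError(f"genotypes outside {{0,1,2}} in columns {bad}")
    coded = g.copy()
    x = panel.x_mask
    if x.any():
        coded.loc[:, x[x].index] *= 0.5
    return coded


def compute_grs(
    genotypes: pd.DataFrame,
    panel: SnpPanel,
    weights: GrsWeights | None = None,
) -> pd.Series:
    """Per-subject genetic risk score.

    Unweighted (the default): the count of risk alleles, with the X SNP
    contributing 0/0.5/1.  Weighted: the inner product of the coded allele
    counts with ``weights``.
    """
    coded = _coded_genotypes(genotypes, panel)
    if weights is None:
        weights = GrsWeights.unweighted(panel)
    if len(weights.values) != len(panel):
        raise ValueError("weights length does not match panel size")
    return pd.Series(
        coded.to_numpy() @ weights.values, index=genotypes.index, name="grs"
    )


def compute_ers(profile: pd.DataFrame) -> pd.Series:
    """Count of the six modifiable risk indicators equal to 1.

    Family history and smoking are excluded by construction.  The profile
    must be complete (imputed) — missing indicators are an error.
    """
    missing_cols = [c for c in ERS_FACTORS if c not in profile.columns]
    if missing_cols:
        raise ValueError(f"profile lacks factor columns: {missing_cols}")
    block = profile[list(ERS_FACTORS)]
    if block.isna().any().any():
        raise ValueError("profile has missing factors: impute first")
    if not block.isin([0, 1]).all().all():
        raise ValueError("factor indicators must be 0/1")
    return block.sum(axis=1).rename("ers")


def compute_rs(ers, fh, grs, params: RiskScoreParams | None = None):
    """Combined relative risk score OR_E^(ERS-e) * OR_F^FH * OR_G^(GRS-g).

    Accepts scalars or aligned array-likes; returns a float or ndarray.
    The population-average profile maps to exactly 1.
    """
    if params is None:
        params = RiskScoreParams()
    ers = np.asarray(ers, dtype=float)
    fh = np.asarray(fh, dtype=float)
    grs = np.asarray(grs, dtype=float)
    if not (np.all(np.isfinite(ers)) and np.all(np.isfinite(fh)) and np.all(np.isfinite(grs))):
        raise ValueError("risk-score inputs must be finite")
    rs = (
        params.or_per_factor ** (ers - params.ers_reference)
        * params.or_fh**fh
        * params.or_per_allele ** (grs - params.grs_reference)
    )
    return float(rs) if rs.ndim == 0 else rs


def refit_weights(cohort: pd.DataFrame, panel: SnpPanel) -> GrsWeights:
    """Per-SNP weights refitted on a cohort: joint propensity-adjusted logistic
    regression of case status on all coded allele counts."""
    import statsmodels.api as sm

    coded = _coded_genotypes(cohort[panel.rsids], panel)
    X = sm.add_constant(coded.to_numpy())
    if "ps" in cohort.columns:
        X = np.column_stack([X, cohort["ps"].to_numpy()])
    fit = sm.GLM(
        cohort["case_status"].to_numpy(), X, family=sm.families.Binomial()
    ).fit()
    return GrsWeights(fit.params[1 : 1 + len(panel)], source="refitted")


def grs_group_contrast(
    cohort: pd.DataFrame, low_cut: float, high_cut: float
) -> dict[str, float]:
    """Odds ratio contrasting high-GRS vs low-GRS subjects.

    Subjects with GRS <= ``low_cut`` form the reference group and those with
    GRS >= ``high_cut`` the exposed group; the rest are dropped.  The OR is
    from a logistic model of case status on group membership, adjusted by
    the propensity score if a ``ps`` column is present.  Returns a dict with
    keys ``or_``, ``ci_low``, ``ci_high``.
    """
    import statsmodels.api as sm

    if not {"grs", "case_status"} <= set(cohort.columns):
        raise ValueError("cohort needs 'grs' and 'case_status' columns")
    low = cohort[cohort["grs"] <= low_cut]
    high = cohort[cohort["grs"] >= high_cut]
    for name, grp in (("low", low), ("high", high)):
        if grp.empty or grp["case_status"].nunique() < 2:
            raise ValueError(
                f"{name}-GRS group is empty or lacks both cases and controls"
            )
    sub = pd.concat([low, high])
    x = (sub["grs"] >= high_cut).astype(float).to_numpy()
    X = sm.add_constant(x)
    if "ps" in sub.columns:
        X = np.column_stack([X, sub["ps"].to_numpy()])
    fit = sm.GLM(
        sub["case_status"].to_numpy(), X, family=sm.families.Binomial()
    ).fit()
    beta, se = fit.params[1], fit.bse[1]
    return {
        "or_": float(np.exp(beta)),
        "ci_low": float(np.exp(beta - 1.959963984540054 * se)),
        "ci_high": float(np.exp(beta + 1.959963984540054 * se)),
    }
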