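"""Synthetic frequency-matched case-control cohort generator.

Emulates the statistical structure of a population-based colorectal-cancer
case-control study: binary lifestyle risk factors drawn at control-arm
prevalences, family history, Hardy-Weinberg genotypes for a SNP panel
(hemizygous X handling for males), ancestry covariates, and a logistic
outcome model

    P(case) = expit(b0 + ln(OR_E) * ERS + ln(OR_F) * FH + ln(OR_G) * GRS)

whose coefficients default to the fitted score-level odds ratios
(1.36 per factor, 2.25 for family history, 1.07 per allele).  Controls are
frequency-matched to cases on sex, region, and 5-year age band.  Age, sex
and region do not enter the outcome model by default — they act only
through matching and the propensity adjustment.

Factors are generated mutually independent, and missingness (optional) is
missing-completely-at-random; see the package methods note for what this
does and does not emulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .covariates import ALCOHOL_CUTOFF_SUA
from .panel import SnpPanel, default_panel
from .scores import ERS_FACTORS, compute_grs

__all__ = [
    "GeneratorConfig",
    "InsufficientPoolError",
    "simulate_genotypes",
    "simulate_risk_factors",
    "assign_outcomes",
    "frequency_match",
    "inject_missing",
    "generate_cohort",
]

EDUCATION_LEVELS = ("primary", "secondary", "university")
SMOKING_LEVELS = ("never", "former", "current")

#: Design variables that may never be masked by missingness injection.
PROTECTED_VARS = frozenset({"subject_id", "case_status", "age", "sex", "region"})


class InsufficientPoolError(RuntimeError):
    """A matching stratum (or the pool overall) cannot supply the controls
    or cases requested."""


def _default_age_distribution() -> dict[int, float]:
    cfg = GeneratorConfig.default()
    return dict(cfg.age_distribution)


@dataclass
class GeneratorConfig:
    """True parameters and design of the synthetic study.

    ``true_or_*`` are the odds ratios of the generating logistic model;
    ``factor_prevalences`` are the marginal prevalences of the six
    modifiable risk indicators in the source population; ``age_distribution``
    maps 5-year band starts (25..80) to sampling weights.
    """

    n_cases: int = 1336
    n_controls: int = 2744
    factor_prevalences: dict[str, float] = field(
        default_factory=lambda: {
            "alcohol_high": 0.1556,
            "obese": 0.0685,
            "no_physical_activity": 0.3852,
            "low_vegetables": 0.6917,
            "high_red_meat": 0.4093,
            "no_nsaid_asa": 0.2730,
        }
    )
    fh_prevalence: float = 0.1214
    smoking_prevalence: float = 0.5645
    true_or_per_factor: float = 1.36
    true_or_fh: float = 2.25
    true_or_per_allele: float = 1.07
    baseline_logit: float = -3.0
    age_distribution: dict[int, float] = field(
        default_factory=lambda: {
            25: 0.010, 30: 0.015, 35: 0.025, 40: 0.040, 45: 0.060,
            50: 0.100, 55: 0.125, 60: 0.140, 65: 0.150, 70: 0.140,
            75: 0.110, 80: 0.085,
        }
    )
    sex_ratio: float = 0.55
    n_regions: int = 12
    missing_rates: dict[str, float] = field(default_factory=dict)
    seed: int = 20170224

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case and control counts must be positive")
        if set(self.factor_prevalences) != set(ERS_FACTORS):
            raise ValueError(
                f"factor_prevalences must cover exactly {list(ERS_FACTORS)}"
            )
        props = [*self.factor_prevalences.values(), self.fh_prevalence,
                 self.smoking_prevalence, self.sex_ratio,
                 *self.missing_rates.values()]
        if any(not 0.0 <= p <= 1.0 for p in props):
            raise ValueError("all proportions must lie in [0, 1]")
        for name in ("true_or_per_factor", "true_or_fh", "true_or_per_allele"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.age_distribution = {int(k): float(v)
                                 for k, v in self.age_distribution.items()}
        if any(w < 0 for w in self.age_distribution.values()):
            raise ValueError("age-band weights must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "GeneratorConfig":
        """The packaged default calibration."""
        with resources.files("crcrisk.data").joinpath("default_config.yaml").open() as fh:
            return cls(**yaml.safe_load(fh))


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_genotypes(
    panel: SnpPanel, n: int, sexes, seed
) -> pd.DataFrame:
    """Hardy-Weinberg genotypes for ``n`` subjects, one column per rsid.

    Autosomal SNPs: Binomial(2, p) allele counts.  The X-linked SNP:
    Binomial(2, p) for females, Binomial(1, p) for males (hemizygous, so
    values 0/1).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    sexes = np.asarray(sexes)
    if len(sexes) != n:
        raise ValueError("sexes must have length n")
    rng = _as_rng(seed)
    male = sexes == "male"
    out = {}
    for snp in panel:
        p = snp.risk_allele_freq
        if snp.is_x_linked:
            g = np.empty(n, dtype=np.int64)
            g[male] = rng.binomial(1, p, male.sum())
            g[~male] = rng.binomial(2, p, (~male).sum())
        else:
            g = rng.binomial(2, p, n)
        out[snp.rsid] = g
    return pd.DataFrame(out)


def simulate_risk_factors(config: GeneratorConfig, n: int, seed) -> pd.DataFrame:
    """Independent Bernoulli draws of the six binary factors plus family
    history, at the configured prevalences."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = _as_rng(seed)
    out = {
        name: rng.binomial(1, config.factor_prevalences[name], n)
        for name in ERS_FACTORS
    }
    out["family_history"] = rng.binomial(1, config.fh_prevalence, n)
    return pd.DataFrame(out)


def _raw_lifestyle(
    factors: pd.DataFrame, sexes: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Raw continuous variables consistent with the binary indicators.

    Values are drawn uniformly within the risk / non-risk range of each
    study cut-off, so dichotomising the raw variables recovers the
    indicators exactly.
    """
    n = len(factors)
    cut = pd.Series(sexes).map(ALCOHOL_CUTOFF_SUA).to_numpy()
    high = factors["alcohol_high"].to_numpy().astype(bool)
    alcohol = np.where(high, cut + rng.uniform(0.5, 6.0, n), rng.uniform(0, 1, n) * cut)
    obese = factors["obese"].to_numpy().astype(bool)
    bmi = np.where(obese, rng.uniform(30.0, 40.0, n), rng.uniform(19.0, 29.5, n))
    inactive = factors["no_physical_activity"].to_numpy().astype(bool)
    met = np.where(inactive, 0.0, rng.uniform(1.0, 40.0, n))
    low_veg = factors["low_vegetables"].to_numpy().astype(bool)
    veg = np.where(low_veg, rng.uniform(0.0, 200.0, n), rng.uniform(201.0, 500.0, n))
    high_meat = factors["high_red_meat"].to_numpy().astype(bool)
    meat = np.where(high_meat, rng.uniform(66.0, 200.0, n), rng.uniform(0.0, 65.0, n))
    return pd.DataFrame({
        "alcohol_sua_day": np.round(alcohol, 2),
        "bmi": np.round(bmi, 1),
        "met_h_week": np.round(met, 1),
        "vegetables_g_day": np.round(veg, 1),
        "red_meat_g_day": np.round(meat, 1),
        "nsaid_regular_use": 1 - factors["no_nsaid_asa"].to_numpy(),
    })


def case_probability(pool: pd.DataFrame, config: GeneratorConfig) -> np.ndarray:
    """P(case) under the generating logistic model, per subject.

    Requires ``ers``, ``family_history`` and ``grs`` columns on the pool
    (GRS already on the 0/0.5/1 X coding).
    """
    from scipy.special import expit

    eta = (
        config.baseline_logit
        + math.log(config.true_or_per_factor) * pool["ers"].to_numpy(float)
        + math.log(config.true_or_fh) * pool["family_history"].to_numpy(float)
        + math.log(config.true_or_per_allele) * pool["grs"].to_numpy(float)
    )
    return expit(eta)


def assign_outcomes(pool: pd.DataFrame, config: GeneratorConfig, seed) -> np.ndarray:
    """Bernoulli case/control labels from the generating logistic model."""
    rng = _as_rng(seed)
    return rng.binomial(1, case_probability(pool, config))


def _stratum_key(df: pd.DataFrame) -> pd.Series:
    band = (df["age"] // 5 * 5).astype(int)
    return pd.Series(list(zip(df["sex"], df["region"], band)), index=df.index)


def frequency_match(
    cases: pd.DataFrame,
    control_pool: pd.DataFrame,
    n_controls: int,
    seed,
) -> pd.DataFrame:
    """Sample controls so their sex x region x 5-year-age-band distribution
    mirrors the cases'.

    Each stratum containing cases receives at least one control; stratum
    quotas are proportional to case counts (largest-remainder rounding),
    capped by availability, with any shortfall redistributed to strata that
    still have spare controls.  Sampling is without replacement.
    """
    rng = _as_rng(seed)
    case_strata = _stratum_key(cases).value_counts()
    pool_by_stratum = control_pool.groupby(_stratum_key(control_pool)).groups
    n_cases = len(cases)

    alloc: dict = {}
    for stratum, n_case_s in case_strata.items():
        avail = len(pool_by_stratum.get(stratum, ()))
        if avail == 0:
            sex, region, band = stratum
            raise InsufficientPoolError(
                f"no eligible controls in stratum sex={sex}, region={region}, "
                f"age band {band}-{band + 4} ({n_case_s} cases)"
            )
        raw = n_controls * n_case_s / n_cases
        alloc[stratum] = {"raw": raw, "take": min(avail, max(1, int(raw))),
                          "avail": avail}

    def total() -> int:
        return sum(a["take"] for a in alloc.values())

    # top up towards the target, preferring the largest unmet remainder
    while total() < n_controls:
        open_strata = [s for s, a in alloc.items() if a["take"] < a["avail"]]
        if not open_strata:
            raise InsufficientPoolError(
                f"control pool exhausted: {total()} of {n_controls} controls "
                "available across case strata"
            )
        s = max(open_strata, key=lambda s: alloc[s]["raw"] - alloc[s]["take"])
        alloc[s]["take"] += 1
    while total() > n_controls:
        shrinkable = [s for s, a in alloc.items() if a["take"] > 1]
        if not shrinkable:
            break
        s = min(shrinkable, key=lambda s: alloc[s]["raw"] - alloc[s]["take"])
        alloc[s]["take"] -= 1

    chosen = []
    for stratum, a in alloc.items():
        idx = np.asarray(pool_by_stratum[stratum])
        chosen.append(rng.choice(idx, size=a["take"], replace=False))
    return control_pool.loc[np.concatenate(chosen)]


def inject_missing(cohort: pd.DataFrame, missing_rates: dict[str, float], seed) -> pd.DataFrame:
    """Mask targeted fields missing-completely-at-random at per-variable rates.

    Case status, age, sex and region are design variables and may not be
    masked.
    """
    from .covariates import RAW_DERIVED

    rng = _as_rng(seed)
    out = cohort.copy()

    def mask_column(col: str, mask: np.ndarray) -> None:
        if out[col].dtype != object:
            out[col] = out[col].astype(float)
        out.loc[mask, col] = np.nan

    for col, rate in missing_rates.items():
        if col in PROTECTED_VARS:
            raise ValueError(f"refusing to mask design variable {col!r}")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missing rate for {col!r} outside [0, 1]")
        if col not in out.columns:
            raise KeyError(f"no column {col!r} in cohort")
        if rate == 0.0:
            continue
        mask = rng.random(len(out)) < rate
        mask_column(col, mask)
        # a masked raw variable takes its derived indicator (and the ERS,
        # which counts that indicator) with it
        derived = RAW_DERIVED.get(col)
        if derived and derived in out.columns:
            mask_column(derived, mask)
            if derived in ERS_FACTORS and "ers" in out.columns:
                mask_column("ers", mask)
    return out


def _simulate_pool(
    config: GeneratorConfig, panel: SnpPanel, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    bands = np.array(sorted(config.age_distribution))
    w = np.array([config.age_distribution[b] for b in bands], dtype=float)
    band = rng.choice(bands, size=n, p=w / w.sum())
    age = band + rng.integers(0, 5, n)
    sex = np.where(rng.random(n) < config.sex_ratio, "male", "female")
    region = np.array([f"R{i:02d}" for i in rng.integers(1, config.n_regions + 1, n)])
    education = rng.choice(EDUCATION_LEVELS, size=n, p=[0.45, 0.35, 0.20])

    factors = simulate_risk_factors(config, n, rng)
    raw = _raw_lifestyle(factors, sex, rng)
    smoker = rng.binomial(1, config.smoking_prevalence, n)
    former = rng.random(n) < 0.5
    smoking = np.where(smoker == 0, "never", np.where(former, "former", "current"))
    genotypes = simulate_genotypes(panel, n, sex, rng)

    pool = pd.concat(
        [
            pd.DataFrame({
                "age": age, "sex": sex, "region": region,
                "education": education,
                "pc1": rng.standard_normal(n),
                "pc2": rng.standard_normal(n),
                "pc3": rng.standard_normal(n),
                "smoking_status": smoking,
            }),
            raw,
            factors,
            genotypes,
        ],
        axis=1,
    )
    pool["ers"] = factors[list(ERS_FACTORS)].sum(axis=1)
    pool["grs"] = compute_grs(genotypes, panel)
    pool["case_status"] = assign_outcomes(pool, config, rng)
    return pool


def generate_cohort(
    config: GeneratorConfig | None = None,
    panel: SnpPanel | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate a complete frequency-matched case-control cohort.

    Simulates a source population, labels outcomes with the generating
    logistic model, takes the first ``n_cases`` cases, and frequency-matches
    ``n_controls`` controls on sex, region and 5-year age band.  The
    returned table carries raw variables, binary indicators, genotypes,
    ``ers``/``grs`` (true coded values), and ``case_status``; rows are
    cases first, then controls, with a fresh ``subject_id``.

    Missingness (``config.missing_rates``) is injected after matching, and
    the indicator/score columns derived from maskable raw variables are
    recomputed downstream after imputation.
    """
    config = config or GeneratorConfig.default()
    panel = panel or default_panel()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    pilot = _simulate_pool(config, panel, 2000, rng)
    p_hat = min(max(pilot["case_status"].mean(), 0.02), 0.98)
    n_pool = int(1.6 * max(config.n_cases / p_hat, config.n_controls / (1 - p_hat)))
    pool = _simulate_pool(config, panel, n_pool, rng)

    for _attempt in range(9):
        cases = pool[pool["case_status"] == 1]
        controls = pool[pool["case_status"] == 0]
        if len(cases) >= config.n_cases:
            cases = cases.iloc[: config.n_cases]
            try:
                matched = frequency_match(cases, controls, config.n_controls, rng)
                break
            except InsufficientPoolError:
                pass
        # double the pool: sparse strata (rare age bands) fill geometrically
        extra = _simulate_pool(config, panel, max(len(pool), 2000), rng)
        pool = pd.concat([pool, extra], ignore_index=True)
    else:
        raise InsufficientPoolError(
            "could not assemble the requested cohort; check baseline_logit "
            "and stratum granularity against the pool size"
        )

    cohort = pd.concat([cases, matched], ignore_index=True)
    cohort.insert(0, "subject_id", [f"S{i:06d}" for i in range(len(cohort))])
    if config.missing_rates:
        cohort = inject_missing(cohort, config.missing_rates, rng)
    return cohort
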