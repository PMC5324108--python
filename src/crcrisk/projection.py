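"""Absolute-risk projection and screening-policy quantities.

Registry cumulative incidence (per 100 persons, by sex and age) is scaled
by the relative risk score RS to obtain individual cumulative-risk curves:
projected CR = min(CR x RS, 100).  Multiplying cumulative risks (rather
than hazards) by an odds ratio is a first-order approximation that is only
accurate while risks are small; a hazard-scale alternative is available
for sensitivity analysis.

From the projected curves the module derives:

* the risk-advancement period — how many years earlier a subject with
  RS > 1 reaches the cumulative risk of an average subject at a reference
  age;
* PPV/NPV of an RS cut-off via Bayes' theorem, with the prior taken as
  the cumulative risk accrued over an age decade.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "IncidenceTable",
    "load_incidence",
    "synthetic_incidence",
    "project_cumulative_risk",
    "risk_advancement_age",
    "ppv_npv",
    "ppv_by_age",
]


@dataclass
class IncidenceTable:
    """Cumulative risk per 100 persons on a monotone age grid, per sex."""

    data: pd.DataFrame  # columns: sex, age, cum_risk_per100

    def __post_init__(self) -> None:
        required = {"sex", "age", "cum_risk_per100"}
        if not required <= set(self.data.columns):
            raise ValueError(f"incidence table needs columns {sorted(required)}")
        if ((self.data["cum_risk_per100"] < 0) | (self.data["cum_risk_per100"] > 100)).any():
            raise ValueError("cumulative risks must lie in [0, 100]")
        self.data = self.data.sort_values(["sex", "age"]).reset_index(drop=True)
        for sex, grp in self.data.groupby("sex"):
            if grp["cum_risk_per100"].diff().dropna().lt(0).any():
                raise ValueError(f"cumulative risk not monotone for sex={sex!r}")

    @property
    def sexes(self) -> list[str]:
        return sorted(self.data["sex"].unique())

    def curve(self, sex: str) -> pd.DataFrame:
        grp = self.data[self.data["sex"] == sex]
        if grp.empty:
            raise KeyError(f"no incidence rows for sex={sex!r}")
        return grp

    def cumulative_risk(self, sex: str, age) -> np.ndarray | float:
        """Piecewise-linear interpolation of CR(age) within the grid."""
        grp = self.curve(sex)
        ages = grp["age"].to_numpy(float)
        cr = grp["cum_risk_per100"].to_numpy(float)
        age = np.asarray(age, dtype=float)
        if np.any(age < ages[0]) or np.any(age > ages[-1]):
            raise ValueError(
                f"age outside tabulated range [{ages[0]}, {ages[-1]}]"
            )
        out = np.interp(age, ages, cr)
        return float(out) if out.ndim == 0 else out


def load_incidence(path: str | Path) -> IncidenceTable:
    """Read a comma-separated incidence table (sex, age, cum_risk_per100)."""
    return IncidenceTable(pd.read_csv(path))


def synthetic_incidence() -> IncidenceTable:
    """Packaged synthetic incidence fixture.

    Shaped like Spanish registry colorectal-cancer curves — near-zero
    before 40, exponential rise from age 50, male lifetime risk about
    10 per 100 and female about 5 — but not extracted from any registry
    publication.
    """
    with resources.files("crcrisk.data").joinpath(
        "incidence_synthetic_spain.csv"
    ).open() as fh:
        return IncidenceTable(pd.read_csv(fh))


def project_cumulative_risk(table: IncidenceTable, rs_values) -> pd.DataFrame:
    """Scale each sex's cumulative-risk curve by each RS value.

    Returns long-format rows (sex, age, rs, cum_risk_per100, capped); the
    projection is capped at 100 per 100 with the cap flagged.  RS = 1
    reproduces the input curve.
    """
    rs_values = np.atleast_1d(np.asarray(rs_values, dtype=float))
    if np.any(rs_values <= 0) or not np.all(np.isfinite(rs_values)):
        raise ValueError("risk scores must be positive and finite")
    rows = []
    for sex in table.sexes:
        grp = table.curve(sex)
        for rs in rs_values:
            raw = grp["cum_risk_per100"].to_numpy() * rs
            rows.append(
                pd.DataFrame(
                    {
                        "sex": sex,
                        "age": grp["age"].to_numpy(),
                        "rs": rs,
                        "cum_risk_per100": np.minimum(raw, 100.0),
                        "capped": raw > 100.0,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def risk_advancement_age(
    table: IncidenceTable, rs: float, reference_age: float, sex: str
) -> float:
    """Years of risk advancement for a subject with relative risk ``rs``.

    Finds the age ``a`` at which ``rs x CR(a)`` equals the average-risk
    cumulative risk at ``reference_age`` (monotone piecewise-linear
    inversion) and returns ``reference_age - a``.  On an exponential curve
    CR(a) = c e^{ka} this equals ln(rs)/k.
    """
    if rs <= 0:
        raise ValueError("rs must be positive")
    grp = table.curve(sex)
    ages = grp["age"].to_numpy(float)
    cr = grp["cum_risk_per100"].to_numpy(float)
    target = table.cumulative_risk(sex, reference_age) / rs
    if target < cr[0] or target > cr[-1]:
        raise ValueError(
            f"target cumulative risk {target:.4g} outside the projected "
            f"curve's range [{cr[0]:.4g}, {cr[-1]:.4g}]"
        )
    # invert the monotone curve; on flat segments take the earliest age
    idx = np.searchsorted(cr, target, side="left")
    if idx == 0 or cr[idx] == target:
        a = ages[idx]
    else:
        lo, hi = idx - 1, idx
        frac = (target - cr[lo]) / (cr[hi] - cr[lo])
        a = ages[lo] + frac * (ages[hi] - ages[lo])
    return float(reference_age - a)


def ppv_npv(sens: float, spec: float, prior: float) -> tuple[float, float]:
    """Bayes-theorem predictive values from percent sens/spec and a prior
    probability.

    Returns (PPV, NPV) as proportions; a vanishing denominator yields nan
    for the affected value.
    """
    if not (0.0 <= sens <= 100.0 and 0.0 <= spec <= 100.0):
        raise ValueError("sensitivity and specificity must be in [0, 100]")
    if not 0.0 <= prior <= 1.0:
        raise ValueError("prior must be a proportion in [0, 1]")
    tp = sens / 100.0 * prior
    fp = (100.0 - spec) / 100.0 * (1.0 - prior)
    tn = spec / 100.0 * (1.0 - prior)
    fn = (100.0 - sens) / 100.0 * prior
    ppv = tp / (tp + fp) if tp + fp > 0 else float("nan")
    npv = tn / (tn + fn) if tn + fn > 0 else float("nan")
    return ppv, npv


def ppv_by_age(
    table: IncidenceTable,
    performance: pd.DataFrame,
    decades: list[tuple[float, float]],
) -> pd.DataFrame:
    """PPV per (cut-off, age range, sex).

    The prior for an age range [a, b) is CR(b) - CR(a), the cumulative risk
    accrued across the range, as a proportion.  ``performance`` is a
    screening-performance table with cutoff/sensitivity/specificity
    columns.  For fixed sensitivity and specificity the PPV is increasing
    in the prior, so PPV rises with age as long as incidence does.
    """
    rows = []
    for sex in table.sexes:
        for start, end in decades:
            prior = (
                table.cumulative_risk(sex, end) - table.cumulative_risk(sex, start)
            ) / 100.0
            for perf in performance.itertuples():
                ppv, npv = ppv_npv(perf.sensitivity, perf.specificity, prior)
                rows.append(
                    {
                        "sex": sex,
                        "age_start": start,
                        "age_end": end,
                        "cutoff": perf.cutoff,
                        "prior": prior,
                        "ppv": ppv,
                        "npv": npv,
                    }
                )
    return pd.DataFrame(rows)
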