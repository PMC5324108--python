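"""Cohort table I/O: tab-separated, one row per subject, missing as empty."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["read_cohort", "write_cohort"]


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated cohort table; empty fields become NaN."""
    return pd.read_csv(path, sep="\t")


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table; missing values are written as empty fields."""
    cohort.to_csv(path, sep="\t", index=False, na_rep="")
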