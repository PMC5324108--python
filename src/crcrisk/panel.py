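"""SNP panel definitions for the genetic risk score.

A panel is an ordered set of susceptibility SNPs, each with a risk allele,
its population frequency, and the per-allele odds ratio reported by the
discovery GWAS.  At most one SNP may be X-linked; its allele counts are
halved when scoring so that its contribution lies on the same 0-0.5-1
scale for both sexes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import pandas as pd

__all__ = ["SnpDefinition", "SnpPanel", "load_panel", "default_panel"]


@dataclass(frozen=True)
class SnpDefinition:
    """One susceptibility SNP: identity, risk allele, frequency, published effect."""

    rsid: str
    chromosome: str
    risk_allele: str
    risk_allele_freq: float
    published_or: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.risk_allele_freq <= 1.0:
            raise ValueError(
                f"{self.rsid}: risk allele frequency {self.risk_allele_freq} "
                "outside [0, 1]"
            )
        if self.published_or <= 0:
            raise ValueError(f"{self.rsid}: published OR must be positive")
        if len(self.risk_allele) != 1 or self.risk_allele not in "ACGT":
            raise ValueError(f"{self.rsid}: risk allele must be a single base")

    @property
    def is_x_linked(self) -> bool:
        return str(self.chromosome).upper() == "X"


@dataclass
class SnpPanel:
    """Ordered collection of SNP definitions with at most one X-linked entry."""

    snps: list[SnpDefinition] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.snps:
            raise ValueError("a SNP panel needs at least one SNP")
        rsids = [s.rsid for s in self.snps]
        if len(set(rsids)) != len(rsids):
            raise ValueError("duplicate rsids in panel")
        if sum(s.is_x_linked for s in self.snps) > 1:
            raise ValueError("at most one X-linked SNP is supported")

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self) -> Iterator[SnpDefinition]:
        return iter(self.snps)

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.snps]

    @property
    def frequencies(self) -> pd.Series:
        return pd.Series(
            [s.risk_allele_freq for s in self.snps], index=self.rsids, name="raf"
        )

    @property
    def x_mask(self) -> pd.Series:
        """Boolean mask over panel order; True for the X-linked SNP."""
        return pd.Series([s.is_x_linked for s in self.snps], index=self.rsids)

    @property
    def published_log_or(self) -> pd.Series:
        import numpy as np

        return pd.Series(
            np.log([s.published_or for s in self.snps]), index=self.rsids
        )

    def with_frequencies(self, raf: dict[str, float] | pd.Series) -> "SnpPanel":
        """Return a copy with overridden risk-allele frequencies.

        Useful to recalibrate the panel to a target population (e.g. when
        the discovery-GWAS frequencies do not reproduce an observed mean
        risk-allele count).
        """
        raf = dict(raf)
        return SnpPanel(
            [
                SnpDefinition(
                    s.rsid,
                    s.chromosome,
                    s.risk_allele,
                    float(raf.get(s.rsid, s.risk_allele_freq)),
                    s.published_or,
                )
                for s in self.snps
            ]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": self.rsids,
                "chromosome": [s.chromosome for s in self.snps],
                "risk_allele": [s.risk_allele for s in self.snps],
                "raf": [s.risk_allele_freq for s in self.snps],
                "published_or": [s.published_or for s in self.snps],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _panel_from_frame(df: pd.DataFrame) -> SnpPanel:
    required = {"rsid", "chromosome", "risk_allele", "raf", "published_or"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel table missing columns: {sorted(missing)}")
    return SnpPanel(
        [
            SnpDefinition(
                str(r.rsid),
                str(r.chromosome),
                str(r.risk_allele),
                float(r.raf),
                float(r.published_or),
            )
            for r in df.itertuples()
        ]
    )


def load_panel(path: str | Path) -> SnpPanel:
    """Read a panel from a tab-separated table with a header row."""
    return _panel_from_frame(pd.read_csv(path, sep="\t"))


def default_panel() -> SnpPanel:
    """The packaged 21-SNP colorectal-cancer susceptibility panel.

    Twenty autosomal SNPs plus rs5934683 on chromosome X, with the risk
    allele frequencies and per-allele odds ratios reported by the discovery
    GWAS publications.
    """
    with resources.files("crcrisk.data").joinpath("snp_panel_mcc21.tsv").open() as fh:
        return _panel_from_frame(pd.read_csv(fh, sep="\t"))
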