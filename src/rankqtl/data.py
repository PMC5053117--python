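"""Core in-memory containers for the eQTL pipeline.

Dosages are stored as a float samples x SNPs array with values in
{0, 1, 2, NaN}: the count of the counted allele (ALT for VCF input, the
minor allele at read time for PLINK text), NaN for a missing call. All ids
are strings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "SnpMap",
    "ExpressionMatrix",
    "CovariateTable",
    "GeneMap",
]


@dataclass
class GenotypeMatrix:
    sample_ids: list[str]
    snp_ids: list[str]
    dosage: np.ndarray  # (n_samples, n_snps), float, NaN = missing

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def sample_missing_fraction(self) -> pd.Series:
        frac = np.isnan(self.dosage).mean(axis=1)
        return pd.Series(frac, index=self.sample_ids, name="missing_fraction")

    def snp_missing_fraction(self) -> pd.Series:
        frac = np.isnan(self.dosage).mean(axis=0)
        return pd.Series(frac, index=self.snp_ids, name="missing_fraction")

    def maf(self) -> pd.Series:
        """Minor allele frequency per SNP over non-missing calls."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosage, axis=0) / 2.0
        maf = np.minimum(p, 1.0 - p)
        return pd.Series(maf, index=self.snp_ids, name="maf")

    def subset(
        self,
        samples: Sequence[str] | None = None,
        snps: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        s_idx = np.arange(self.n_samples)
        v_idx = np.arange(self.n_snps)
        s_ids, v_ids = self.sample_ids, self.snp_ids
        if samples is not None:
            pos = {a: i for i, a in enumerate(self.sample_ids)}
            s_idx = np.array([pos[a] for a in samples], dtype=int)
            s_ids = list(samples)
        if snps is not None:
            pos = {v: i for i, v in enumerate(self.snp_ids)}
            v_idx = np.array([pos[v] for v in snps], dtype=int)
            v_ids = list(snps)
        return GenotypeMatrix(s_ids, v_ids, self.dosage[np.ix_(s_idx, v_idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosage, index=self.sample_ids, columns=self.snp_ids
        )


@dataclass
class SnpMap:
    """Chromosome/position metadata per SNP (1-based bp coordinates).

    ``chromosome`` is a string label ("1".."29", "X", ...) or None when the
    position is unknown; ``position_bp`` is present iff the chromosome is.
    """

    df: pd.DataFrame  # columns: snp_id, chromosome (str|None), position_bp

    def __post_init__(self):
        df = self.df.copy()
        required = {"snp_id", "chromosome", "position_bp"}
        if not required.issubset(df.columns):
            raise ValueError(f"SnpMap needs columns {sorted(required)}")
        chrom_known = df["chromosome"].notna()
        pos_known = df["position_bp"].notna()
        if (chrom_known != pos_known).any():
            raise ValueError(
                "SnpMap: position must be present iff chromosome is"
            )
        df["snp_id"] = df["snp_id"].astype(str)
        self.df = df.reset_index(drop=True)

    def lookup(self, snp_id: str) -> tuple[str | None, int | None]:
        row = self.df.loc[self.df["snp_id"] == snp_id]
        if row.empty:
            raise KeyError(f"SNP {snp_id!r} not in map")
        chrom = row["chromosome"].iloc[0]
        pos = row["position_bp"].iloc[0]
        if pd.isna(chrom):
            return None, None
        return str(chrom), int(pos)

    def as_dict(self) -> dict[str, tuple[str | None, int | None]]:
        out = {}
        for row in self.df.itertuples():
            if pd.isna(row.chromosome):
                out[row.snp_id] = (None, None)
            else:
                out[row.snp_id] = (str(row.chromosome), int(row.position_bp))
        return out


@dataclass
class GeneMap:
    """Transcript -> gene annotation with chromosome and gene start (bp)."""

    df: pd.DataFrame  # columns: transcript_id, gene_id, chromosome, start_bp

    def __post_init__(self):
        required = {"transcript_id", "gene_id", "chromosome", "start_bp"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"GeneMap needs columns {sorted(required)}")
        df = self.df.copy()
        df["transcript_id"] = df["transcript_id"].astype(str)
        self.df = df.reset_index(drop=True)

    def as_dict(self) -> dict[str, tuple[str, str, int]]:
        return {
            row.transcript_id: (str(row.gene_id), str(row.chromosome), int(row.start_bp))
            for row in self.df.itertuples()
        }


@dataclass
class ExpressionMatrix:
    """Samples x transcripts matrix of log2-scale expression values."""

    sample_ids: list[str]
    transcript_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (
            len(self.sample_ids),
            len(self.transcript_ids),
        ):
            raise ValueError("expression shape does not match ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no missing)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.transcript_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            df.to_numpy(dtype=float),
        )


@dataclass
class CovariateTable:
    """Per-sample fixed-effect covariates: year-season class and age (days)."""

    df: pd.DataFrame  # columns: sample_id, season_class, age_days

    def __post_init__(self):
        required = {"sample_id", "season_class", "age_days"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"CovariateTable needs columns {sorted(required)}")
        df = self.df.copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["season_class"] = df["season_class"].astype(str)
        df["age_days"] = df["age_days"].astype(float)
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in covariates")
        self.df = df.reset_index(drop=True)

    def aligned_to(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        out = self.df.set_index("sample_id")
        missing = [s for s in sample_ids if s not in out.index]
        if missing:
            raise ValueError(f"samples without covariates: {missing[:5]}")
        return out.loc[list(sample_ids)]
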