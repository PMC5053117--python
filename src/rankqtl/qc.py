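"""Genotype quality control and pedigree-consistency checks.

Filters follow the study design: samples and SNPs with *more than* 10%
missing genotypes are excluded (strict >), and SNPs with a minor allele
frequency of *less than* 5% are excluded (strict <). The sample filter is
applied first; SNP missingness and MAF are then computed on the surviving
samples' non-missing calls.

Pedigree consistency is checked with per-trio Mendelian incompatibility
tests (opposing homozygotes and impossible trio configurations) rather than
full likelihood-based genotype elimination — at F2-trio pedigree depth the
two coincide for biallelic SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeMatrix
from .pedigree import PedigreeTable

__all__ = [
    "QcReport",
    "filter_samples_and_snps",
    "mendelian_check",
    "intersect_snps",
]


@dataclass
class QcReport:
    """Every exclusion with its reason, plus the thresholds applied."""

    max_missing: float
    min_maf: float
    exclusions: pd.DataFrame  # columns: kind, id, reason, value
    counted_allele_note: str = (
        "dosage counts the ALT allele (VCF) or the minor allele determined "
        "at read time (PLINK text); MAF computed after sample exclusion"
    )

    def to_tsv(self, path) -> None:
        self.exclusions.to_csv(path, sep="\t", index=False)


def filter_samples_and_snps(
    G: GenotypeMatrix,
    max_missing: float = 0.10,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the missingness and MAF filters; return survivors and a report.

    Exclusion rules (boundaries per the study's wording): sample missing
    fraction > ``max_missing``; SNP missing fraction > ``max_missing`` or
    MAF < ``min_maf`` computed on non-missing calls of surviving samples.

    Raises
    ------
    ValueError
        If the thresholds are outside [0, 1] or no SNP survives.
    """
    if not (0 <= max_missing <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must be in [0, 1]")
    rows = []

    sample_miss = G.sample_missing_fraction()
    keep_samples = [
        s for s in G.sample_ids if sample_miss[s] <= max_missing
    ]
    for s in G.sample_ids:
        if sample_miss[s] > max_missing:
            rows.append(
                ("sample", s, f"missing fraction > {max_missing}", sample_miss[s])
            )

    G1 = G.subset(samples=keep_samples)
    snp_miss = G1.snp_missing_fraction()
    maf = G1.maf()
    keep_snps = []
    for v in G1.snp_ids:
        if snp_miss[v] > max_missing:
            rows.append(
                ("snp", v, f"missing fraction > {max_missing}", snp_miss[v])
            )
        elif np.isnan(maf[v]) or maf[v] < min_maf:
            rows.append(("snp", v, f"MAF < {min_maf}", maf[v]))
        else:
            keep_snps.append(v)
    if not keep_snps:
        raise ValueError("all SNPs excluded by QC filters")

    report = QcReport(
        max_missing,
        min_maf,
        pd.DataFrame(rows, columns=["kind", "id", "reason", "value"]),
    )
    return G1.subset(snps=keep_snps), report


def _trio_valid_table() -> np.ndarray:
    """valid[f, m, c] for dosage codes 0/1/2 and 3 = missing parent."""
    gametes = {0: {0}, 1: {0, 1}, 2: {1}, 3: {0, 1}}
    valid = np.zeros((4, 4, 3), dtype=bool)
    for f in range(4):
        for m in range(4):
            possible = {a + b for a in gametes[f] for b in gametes[m]}
            for c in possible:
                valid[f, m, c] = True
    return valid


_VALID = _trio_valid_table()


def mendelian_check(
    G: GenotypeMatrix, ped: PedigreeTable
) -> list[dict]:
    """Flag genotype calls incompatible with Mendelian transmission.

    For every genotyped animal with at least one genotyped parent, each SNP
    is checked against the set of offspring dosages producible from the
    parental genotypes (a missing parent is unconstrained; a missing call at
    the site skips the check). Each flag names the SNP, the animal, its
    checked parents and the observed dosages.
    """
    sample_pos = {s: i for i, s in enumerate(G.sample_ids)}
    # integer codes: 0/1/2 dosage, 3 missing
    codes = np.where(np.isnan(G.dosage), 3, G.dosage).astype(int)
    flags: list[dict] = []
    for row in ped.df.itertuples():
        child = row.animal
        if child not in sample_pos:
            continue
        ci = sample_pos[child]
        fi = sample_pos.get(row.sire) if row.sire is not None else None
        mi = sample_pos.get(row.dam) if row.dam is not None else None
        if fi is None and mi is None:
            continue
        c = codes[ci]
        f = codes[fi] if fi is not None else np.full_like(c, 3)
        m = codes[mi] if mi is not None else np.full_like(c, 3)
        checkable = c != 3
        bad = np.zeros(len(c), dtype=bool)
        bad[checkable] = ~_VALID[f[checkable], m[checkable], c[checkable]]
        for j in np.nonzero(bad)[0]:
            flags.append(
                {
                    "snp_id": G.snp_ids[j],
                    "animal": child,
                    "sire": row.sire if fi is not None else None,
                    "dam": row.dam if mi is not None else None,
                    "animal_dosage": int(c[j]),
                    "sire_dosage": int(f[j]) if f[j] != 3 else None,
                    "dam_dosage": int(m[j]) if m[j] != 3 else None,
                }
            )
    return flags


def intersect_snps(*matrices: GenotypeMatrix) -> list[GenotypeMatrix]:
    """Restrict genotype matrices to their shared SNP ids (chip merging)."""
    shared = set(matrices[0].snp_ids)
    for G in matrices[1:]:
        shared &= set(G.snp_ids)
    order = [v for v in matrices[0].snp_ids if v in shared]
    return [G.subset(snps=order) for G in matrices]
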