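"""Genome-wide SNP x transcript scan, FDR control and cis/trans summaries.

Every SNP-transcript pair with enough genotype-group support is tested with
the adaptive linear rank test on the decorrelated expression (companion
Kruskal-Wallis and one-way ANOVA p-values are carried along). Benjamini-
Hochberg adjustment uses m = the number of tests actually *performed* —
pairs skipped by the group-size rule do not enter m. An association is
called cis when SNP and gene sit on the same chromosome, trans when on
different chromosomes, and unknown when the SNP has no mapped position;
window-based re-classification (e.g. 1 Mb / 5 Mb around the gene start) is
provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GeneMap, GenotypeMatrix, SnpMap
from .ranktest import (
    DEFAULT_DECISION_TABLE,
    DegenerateSampleError,
    adaptive_test,
    anova_f_test,
    kruskal_wallis_test,
    select_test,
    selector_statistics,
)

__all__ = [
    "ScanConfig",
    "ScanResult",
    "run_scan",
    "bh_adjust",
    "classify_association",
    "classify_records",
    "snp_gene_distance",
    "summarize_scan",
    "equivalent_fdr",
    "threshold_from_rejections",
]

RECORD_COLUMNS = [
    "snp_id",
    "snp_chrom",
    "snp_pos",
    "transcript_id",
    "gene_id",
    "gene_chrom",
    "gene_start",
    "chosen_test",
    "n_groups",
    "p_adaptive",
    "p_kw",
    "p_anova",
    "p_bh",
    "significant",
    "assoc_class",
    "distance_bp",
]


@dataclass
class ScanConfig:
    """Scan policy knobs.

    ``alpha_fdr`` is the global BH level (default 0.1). A pair is tested
    only when at least ``min_groups`` genotype classes have at least
    ``min_group_count`` members after dropping missing genotypes; classes
    below the count are dropped from the test. ``selector_scope`` picks
    whether the adaptive selector is evaluated per SNP-transcript pair (on
    the analyzed subsample) or once per transcript.
    """

    alpha_fdr: float = 0.1
    min_group_count: int = 3
    min_groups: int = 2
    selector_scope: str = "per_pair"  # or "per_transcript"
    emit_companion_tests: bool = True
    decision_table: list = field(
        default_factory=lambda: list(DEFAULT_DECISION_TABLE)
    )

    def __post_init__(self):
        if not 0 < self.alpha_fdr < 1:
            raise ValueError("alpha_fdr must be in (0, 1)")
        if self.min_group_count < 1:
            raise ValueError("min_group_count must be >= 1")
        if self.selector_scope not in ("per_pair", "per_transcript"):
            raise ValueError(f"bad selector_scope {self.selector_scope!r}")


@dataclass
class ScanResult:
    records: pd.DataFrame  # one row per performed test (RECORD_COLUMNS)
    m: int  # number of performed tests (the BH denominator)
    n_skipped: int  # pairs skipped by the group-size rule

    @property
    def significant(self) -> pd.DataFrame:
        return self.records.loc[self.records["significant"]]


def bh_adjust(p, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` may exceed ``len(p)`` when the scan is chunked and the full test
    count is known externally: adj_(k) = min_{j>=k} (m * p_(j) / j), capped
    at 1, with the input order restored.
    """
    p = np.asarray(p, dtype=float)
    n = len(p)
    if n == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    if m is None:
        m = n
    if m < n:
        raise ValueError("m must be >= len(p)")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, None, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def classify_association(
    snp_chrom: str | None, gene_chrom: str | None
) -> str:
    """cis (same chromosome), trans (different), unknown (SNP unmapped)."""
    if gene_chrom is None or (isinstance(gene_chrom, float) and np.isnan(gene_chrom)):
        raise ValueError("gene chromosome must be known")
    if snp_chrom is None or (isinstance(snp_chrom, float) and np.isnan(snp_chrom)):
        return "unknown"
    return "cis" if str(snp_chrom) == str(gene_chrom) else "trans"


def snp_gene_distance(
    snp_pos: int | None, gene_start: int, same_chromosome: bool
) -> int | None:
    """|snp_pos - gene_start| in bp on the same chromosome, else undefined."""
    if not same_chromosome or snp_pos is None:
        return None
    return abs(int(snp_pos) - int(gene_start))


def classify_records(records: pd.DataFrame) -> pd.DataFrame:
    """Fill ``assoc_class`` and ``distance_bp`` from the position columns."""
    out = records.copy()
    classes = []
    distances = []
    for row in out.itertuples():
        snp_chrom = None if pd.isna(row.snp_chrom) else str(row.snp_chrom)
        cls = classify_association(snp_chrom, str(row.gene_chrom))
        classes.append(cls)
        if cls == "cis":
            distances.append(
                snp_gene_distance(int(row.snp_pos), int(row.gene_start), True)
            )
        else:
            distances.append(np.nan)
    out["assoc_class"] = classes
    out["distance_bp"] = distances
    return out


def run_scan(
    residuals: pd.DataFrame,
    G: GenotypeMatrix,
    snp_map: SnpMap,
    gene_map: GeneMap,
    cfg: ScanConfig | None = None,
) -> ScanResult:
    """Test every SNP x transcript pair on the shared samples.

    ``residuals`` is the decorrelated expression (samples x transcripts).
    Samples missing the genotype at a SNP are dropped pair-wise; genotype
    classes smaller than ``cfg.min_group_count`` are dropped, and the pair
    is skipped (counted, excluded from the BH denominator m) when fewer
    than ``cfg.min_groups`` classes remain.
    """
    cfg = cfg or ScanConfig()
    shared = [s for s in residuals.index.astype(str) if s in set(G.sample_ids)]
    if not shared:
        raise ValueError("no overlapping samples between residuals and genotypes")
    R = residuals.loc[shared]
    Gs = G.subset(samples=shared)
    snp_info = snp_map.as_dict()
    gene_info = gene_map.as_dict()
    transcripts = [t for t in R.columns.astype(str) if t in gene_info]

    per_transcript_rules = {}
    if cfg.selector_scope == "per_transcript":
        for tid in transcripts:
            try:
                sel = selector_statistics(R[tid].to_numpy())
                chosen = select_test(sel, cfg.decision_table)
            except DegenerateSampleError:
                chosen = "kruskal_wallis"
            # a one-rule table forces the per-transcript choice
            per_transcript_rules[tid] = [{"test": chosen}]

    rows = []
    n_skipped = 0
    resid_values = R.to_numpy(dtype=float)
    col_of = {t: i for i, t in enumerate(R.columns.astype(str))}
    for j, snp in enumerate(Gs.snp_ids):
        dose = Gs.dosage[:, j]
        present = np.isfinite(dose)
        labels_all = dose[present].astype(int)
        uniq, counts = np.unique(labels_all, return_counts=True)
        keep_classes = uniq[counts >= cfg.min_group_count]
        snp_chrom, snp_pos = snp_info.get(snp, (None, None))
        for tid in transcripts:
            if len(keep_classes) < cfg.min_groups:
                n_skipped += 1
                continue
            mask = present.copy()
            mask[present] = np.isin(labels_all, keep_classes)
            y = resid_values[mask, col_of[tid]]
            labels = dose[mask].astype(int)
            rules = per_transcript_rules.get(tid, cfg.decision_table)
            result = adaptive_test(y, labels, rules=rules)
            gene_id, gene_chrom, gene_start = gene_info[tid]
            rows.append(
                {
                    "snp_id": snp,
                    "snp_chrom": snp_chrom,
                    "snp_pos": snp_pos,
                    "transcript_id": tid,
                    "gene_id": gene_id,
                    "gene_chrom": gene_chrom,
                    "gene_start": gene_start,
                    "chosen_test": result.chosen_test,
                    "n_groups": result.n_groups,
                    "p_adaptive": result.p_value,
                    "p_kw": (
                        kruskal_wallis_test(y, labels)
                        if cfg.emit_companion_tests
                        else np.nan
                    ),
                    "p_anova": (
                        anova_f_test(y, labels)
                        if cfg.emit_companion_tests
                        else np.nan
                    ),
                }
            )
    records = pd.DataFrame(rows)
    m = len(records)
    if m:
        records["p_bh"] = bh_adjust(records["p_adaptive"].to_numpy(), m)
        records["significant"] = records["p_bh"] <= cfg.alpha_fdr
        records = classify_records(records)
        records = records[RECORD_COLUMNS]
    else:
        records = pd.DataFrame(columns=RECORD_COLUMNS)
    return ScanResult(records=records, m=m, n_skipped=n_skipped)


def summarize_scan(
    records: pd.DataFrame,
    windows: tuple[int, ...] = (1_000_000, 5_000_000),
) -> dict:
    """Count summaries over (typically significant) classified records.

    Returns totals, unique SNP/transcript counts, cis/trans/unknown under
    the chromosome rule, per-chromosome counts (SNP chromosome; unique SNPs
    too), window-based re-classification (SNP within ``w`` bp of the gene
    start = cis; everything else with a known position = trans; unknown
    positions tallied separately) and the distance list for the same-
    chromosome records.
    """
    if len(records) == 0:
        return {
            "n_associations": 0,
            "n_unique_snps": 0,
            "n_unique_transcripts": 0,
            "by_class": {"cis": 0, "trans": 0, "unknown": 0},
            "per_chromosome": {},
            "snps_per_chromosome": {},
            "windows": {int(w): {"cis": 0, "trans": 0, "unknown": 0} for w in windows},
            "distances_bp": [],
        }
    by_class = records["assoc_class"].value_counts().to_dict()
    known = records.loc[records["assoc_class"] != "unknown"]
    per_chrom: dict[str, dict[str, int]] = {}
    for chrom, grp in known.groupby(known["snp_chrom"].astype(str)):
        per_chrom[chrom] = {
            "cis": int((grp["assoc_class"] == "cis").sum()),
            "trans": int((grp["assoc_class"] == "trans").sum()),
        }
    snps_per_chrom = {
        chrom: int(grp["snp_id"].nunique())
        for chrom, grp in known.groupby(known["snp_chrom"].astype(str))
    }
    window_counts = {}
    dist = records["distance_bp"]
    for w in windows:
        within = (records["assoc_class"] == "cis") & (dist < w)
        unknown = records["assoc_class"] == "unknown"
        window_counts[int(w)] = {
            "cis": int(within.sum()),
            "trans": int((~within & ~unknown).sum()),
            "unknown": int(unknown.sum()),
        }
    return {
        "n_associations": int(len(records)),
        "n_unique_snps": int(records["snp_id"].nunique()),
        "n_unique_transcripts": int(records["transcript_id"].nunique()),
        "by_class": {
            "cis": int(by_class.get("cis", 0)),
            "trans": int(by_class.get("trans", 0)),
            "unknown": int(by_class.get("unknown", 0)),
        },
        "per_chromosome": per_chrom,
        "snps_per_chromosome": snps_per_chrom,
        "windows": window_counts,
        "distances_bp": [int(d) for d in dist.dropna()],
    }


def equivalent_fdr(alpha: float, m_sub: int, m_total: int) -> float:
    """FDR level on a test subset equivalent to BH at ``alpha`` over all tests.

    BH's per-test rejection threshold k*alpha/m_total re-expressed for an
    analysis restricted to ``m_sub`` tests gives alpha * m_sub / m_total
    (the rejection count k cancels).
    """
    if not 0 < m_sub <= m_total:
        raise ValueError("need 0 < m_sub <= m_total")
    return alpha * m_sub / m_total


def threshold_from_rejections(k: int, m: int, alpha: float) -> float:
    """Raw-p threshold k*alpha/m implied by k BH rejections among m tests."""
    if not 1 <= k <= m:
        raise ValueError("need 1 <= k <= m")
    return k * alpha / m
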