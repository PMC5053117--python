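"""Readers and writers for the pipeline's on-disk formats.

Genotypes come in as PLINK text (.ped/.map) or VCF (plain or bgzipped,
parsed with cyvcf2); expression is a TSV with samples in rows, transcripts
in columns; pedigree and covariates are CSV; SNP and gene position maps are
TSV. Coordinates are 1-based throughout.

PLINK .ped files carry no ref/alt designation, so for that format the
counted allele is the minor allele determined at read time (recorded per
SNP); the association tests downstream are invariant to flipping the coding
(0 <-> 2 relabels genotype groups).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CovariateTable, ExpressionMatrix, GeneMap, GenotypeMatrix, SnpMap

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "read_vcf",
    "read_plink_text",
    "write_plink_text",
    "write_vcf",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_covariates_csv",
    "write_covariates_csv",
    "read_snp_map_tsv",
    "write_snp_map_tsv",
    "read_gene_map_tsv",
    "write_gene_map_tsv",
]


def read_genotypes(path, format: str) -> tuple[GenotypeMatrix, SnpMap]:
    """Read genotypes as alt/minor-allele dosage plus the SNP position map.

    ``format`` is ``"vcf"`` or ``"plink_text"`` (for the latter, ``path``
    may be the .ped file or the common prefix).
    """
    if format == "vcf":
        return read_vcf(path)
    if format == "plink_text":
        return read_plink_text(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path) -> tuple[GenotypeMatrix, SnpMap]:
    """Read a biallelic-SNP VCF into ALT-allele dosages.

    Multi-allelic sites are skipped with a logged warning; missing genotypes
    become NaN. Chromosome "0" (or ".") marks an unknown position.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    rows = []
    map_rows = []
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            logger.warning(
                "skipping multi-allelic site %s:%s (%s)",
                var.CHROM,
                var.POS,
                var.ID,
            )
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        dose = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        snp_ids.append(snp_id)
        rows.append(dose)
        chrom = str(var.CHROM)
        if chrom in ("0", "."):
            map_rows.append((snp_id, None, None))
        else:
            map_rows.append((snp_id, chrom, int(var.POS)))
    dosage = (
        np.asarray(rows).T if rows else np.empty((len(samples), 0))
    )
    G = GenotypeMatrix(samples, snp_ids, dosage)
    snp_map = SnpMap(
        pd.DataFrame(map_rows, columns=["snp_id", "chromosome", "position_bp"])
    )
    return G, snp_map


def write_vcf(G: GenotypeMatrix, snp_map: SnpMap, path) -> None:
    """Write dosages as a minimal VCFv4.2 (REF=A, ALT=G placeholder alleles)."""
    info = snp_map.as_dict()
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted(
            {c for c, _ in info.values() if c is not None},
            key=lambda c: (len(c), c),
        )
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        for j, snp in enumerate(G.snp_ids):
            chrom, pos = info.get(snp, (None, None))
            chrom_s = chrom if chrom is not None else "0"
            pos_s = str(pos) if pos is not None else "0"
            calls = [
                code.get(d, "./.") if np.isfinite(d) else "./."
                for d in G.dosage[:, j]
            ]
            fh.write(
                f"{chrom_s}\t{pos_s}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


# ---------------------------------------------------------------------------
# PLINK text


def _plink_paths(path) -> tuple[Path, Path]:
    p = Path(path)
    if p.suffix in (".ped", ".map"):
        p = p.with_suffix("")
    return p.with_suffix(".ped"), p.with_suffix(".map")


def read_plink_text(path) -> tuple[GenotypeMatrix, SnpMap]:
    """Read PLINK .ped/.map; dosage counts the minor allele at read time."""
    ped_path, map_path = _plink_paths(path)
    map_df = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chromosome", "snp_id", "cm", "position_bp"],
        dtype={"chromosome": str, "snp_id": str},
    )
    snp_ids = map_df["snp_id"].tolist()
    n_snps = len(snp_ids)

    samples: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} fields, "
                    f"got {len(fields)}"
                )
            samples.append(fields[1])
            allele_rows.append(np.array(fields[6:], dtype=object))

    alleles = (
        np.vstack(allele_rows)
        if allele_rows
        else np.empty((0, 2 * n_snps), dtype=object)
    )
    a1 = alleles[:, 0::2]
    a2 = alleles[:, 1::2]
    dosage = np.full((len(samples), n_snps), np.nan)
    for j in range(n_snps):
        col = np.concatenate([a1[:, j], a2[:, j]])
        obs = col[col != "0"]
        uniq, counts = np.unique(obs, return_counts=True)
        if len(uniq) > 2:
            raise ValueError(
                f"{ped_path}: SNP {snp_ids[j]} has >2 alleles: {list(uniq)}"
            )
        if len(uniq) == 0:
            continue
        # counted allele = minor (least frequent; deterministic tie-break)
        order = np.lexsort((uniq, counts))
        minor = uniq[order[0]]
        miss = (a1[:, j] == "0") | (a2[:, j] == "0")
        d = (a1[:, j] == minor).astype(float) + (a2[:, j] == minor).astype(float)
        d[miss] = np.nan
        dosage[:, j] = d

    unknown = map_df["chromosome"].isin(["0", "."]) | (
        map_df["position_bp"] <= 0
    )
    map_out = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chromosome": map_df["chromosome"].where(~unknown, None),
            "position_bp": map_df["position_bp"].where(~unknown, np.nan),
        }
    )
    return GenotypeMatrix(samples, snp_ids, dosage), SnpMap(map_out)


def write_plink_text(
    G: GenotypeMatrix,
    snp_map: SnpMap,
    prefix,
    family_ids: dict[str, str] | None = None,
) -> None:
    """Write .ped/.map with alleles A (non-counted) and G (counted)."""
    prefix = Path(prefix)
    info = snp_map.as_dict()
    with open(prefix.with_suffix(".map"), "w") as fh:
        for snp in G.snp_ids:
            chrom, pos = info.get(snp, (None, None))
            chrom_s = chrom if chrom is not None else "0"
            pos_s = str(pos) if pos is not None else "0"
            fh.write(f"{chrom_s}\t{snp}\t0\t{pos_s}\n")
    allele_pairs = {0.0: ("A", "A"), 1.0: ("A", "G"), 2.0: ("G", "G")}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, sample in enumerate(G.sample_ids):
            fid = (family_ids or {}).get(sample, "0")
            fields = [fid, sample, "0", "0", "0", "-9"]
            for d in G.dosage[i]:
                pair = allele_pairs.get(d) if np.isfinite(d) else ("0", "0")
                fields.extend(pair or ("0", "0"))
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# TSV/CSV tables


def read_expression_tsv(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix.from_frame(df)


def write_expression_tsv(E: ExpressionMatrix | pd.DataFrame, path) -> None:
    df = E.to_frame() if isinstance(E, ExpressionMatrix) else E
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_covariates_csv(path) -> CovariateTable:
    return CovariateTable(pd.read_csv(path, dtype={"sample_id": str}))


def write_covariates_csv(cov: CovariateTable, path) -> None:
    cov.df.to_csv(path, index=False)


def read_snp_map_tsv(path) -> SnpMap:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chromosome": str})
    df["chromosome"] = df["chromosome"].where(df["chromosome"].notna(), None)
    return SnpMap(df)


def write_snp_map_tsv(snp_map: SnpMap, path) -> None:
    out = snp_map.df.copy()
    out["position_bp"] = out["position_bp"].astype("Int64")
    out.to_csv(path, sep="\t", index=False)


def read_gene_map_tsv(path) -> GeneMap:
    df = pd.read_csv(
        path, sep="\t", dtype={"transcript_id": str, "gene_id": str, "chromosome": str}
    )
    return GeneMap(df)


def write_gene_map_tsv(gene_map: GeneMap, path) -> None:
    gene_map.df.to_csv(path, sep="\t", index=False)
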