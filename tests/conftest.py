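"""Shared fixtures: small pedigrees, simulated bundles, and a synthetic
reconstruction of the study's published eQTL table."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rankqtl.pedigree import validate_pedigree, build_relationship_matrix
from rankqtl.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def trio_pedigree():
    return validate_pedigree(
        [
            ("S", None, None),
            ("D", None, None),
            ("C", "S", "D"),
        ]
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A small F2-cross bundle reused by QC/decorrelation/scan tests."""
    cfg = SimulationConfig(
        family_sizes=(10, 8, 6, 4, 2),
        n_chromosomes=3,
        snps_per_chromosome=10,
        n_transcripts=12,
        n_cis_eqtl=2,
        n_trans_eqtl=1,
        effect_size_sd=1.5,
        sigma2_a=0.5,
        sigma2_e=0.5,
        seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def study_bundle():
    """Study-sized bundle: 145 F2 cows in the five published family sizes."""
    cfg = SimulationConfig(
        n_chromosomes=3,
        snps_per_chromosome=15,
        n_transcripts=30,
        n_cis_eqtl=3,
        n_trans_eqtl=1,
        effect_size_sd=1.5,
        sigma2_a=1.0,
        sigma2_e=1.0,
        seed=5,
    )
    return simulate_dataset(cfg)


def synthetic_published_table() -> pd.DataFrame:
    """Synthetic stand-in for the study's supplementary eQTL table.

    The real table (the published list of 505 significant associations) is
    not redistributable here, so this constructs a synthetic table whose
    marginal counts match the published ones exactly: 505 associations over
    129 transcripts, 482 cis (SNP and gene on the same chromosome), 17
    trans, 6 with unknown SNP position; 55 unique SNPs on chromosome 23;
    343 of the 482 same-chromosome pairs closer than 5 Mb to the gene
    start, 314 of them closer than 1 Mb. Positions and ids are arbitrary.
    """
    rows = []
    autosomes = [str(c) for c in range(1, 30) if c not in (16, 24, 28)]
    # 482 cis: chromosome 23 carries 55, the rest spread over the others
    cis_chroms = ["23"] * 55
    others = [c for c in autosomes if c != "23"]
    i = 0
    while len(cis_chroms) < 482:
        cis_chroms.append(others[i % len(others)])
        i += 1
    # distances: 314 < 1 Mb, 29 in [1, 5) Mb, 139 >= 5 Mb
    distances = [500_000] * 314 + [3_000_000] * 29 + [20_000_000] * 139
    gene_start = 40_000_000
    for k, (chrom, dist) in enumerate(zip(cis_chroms, distances)):
        rows.append(
            {
                "snp_id": f"cis_snp_{k:04d}",
                "snp_chrom": chrom,
                "snp_pos": gene_start + dist,
                "gene_chrom": chrom,
                "gene_start": gene_start,
            }
        )
    for k in range(17):
        rows.append(
            {
                "snp_id": f"trans_snp_{k:02d}",
                "snp_chrom": autosomes[k % len(autosomes)],
                "snp_pos": 10_000_000,
                "gene_chrom": autosomes[(k + 3) % len(autosomes)],
                "gene_start": gene_start,
            }
        )
    for k in range(6):
        rows.append(
            {
                "snp_id": f"unk_snp_{k}",
                "snp_chrom": None,
                "snp_pos": np.nan,
                "gene_chrom": autosomes[k],
                "gene_start": gene_start,
            }
        )
    df = pd.DataFrame(rows)
    df["transcript_id"] = [f"tx_{k % 129:03d}" for k in range(len(df))]
    df["gene_id"] = df["transcript_id"].str.replace("tx", "gene")
    return df
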