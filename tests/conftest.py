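from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from treesel.io_formats import Dataset

DATA_DIR = Path(__file__).parent / "data"


def make_dataset(genotypes, populations, snp_ids=None, gene_ids=None,
                 climate=None, coverage=None, allele_balance=None,
                 n_alt=None, site_class=None, external_calls=None,
                 gene_sets=None):
    """Assemble a toy Dataset from a SNP x sample genotype matrix and a
    per-sample population list."""
    G = np.asarray(genotypes, dtype=np.int8)
    n_snps, n_samples = G.shape
    samples = [f"s{k + 1}" for k in range(n_samples)]
    popmap = dict(zip(samples, populations))
    snp_ids = snp_ids or [f"snp{i + 1}" for i in range(n_snps)]
    gene_ids = gene_ids or ["geneA"] * n_snps
    meta = pd.DataFrame({
        "snp_id": snp_ids,
        "gene_id": gene_ids,
        "chrom": gene_ids,
        "pos": np.arange(1, n_snps + 1),
        "ref": ["A"] * n_snps,
        "alt": ["T"] * n_snps,
        "minor": ["T"] * n_snps,
        "n_alt": n_alt if n_alt is not None else np.ones(n_snps, dtype=int),
        "coverage": coverage if coverage is not None else np.full(n_snps, 50.0),
        "allele_balance": allele_balance if allele_balance is not None
        else np.full(n_snps, 0.5),
    })
    if site_class is not None:
        meta["site_class"] = site_class
    return Dataset(genotypes=G, snp_meta=meta, samples=samples, popmap=popmap,
                   climate=climate, external_calls=external_calls,
                   gene_sets=gene_sets)


@pytest.fixture
def f1_alignment():
    """Packaged 6-copy fixture alignment (n=6, L=40)."""
    from treesel.io_formats import read_alignment_fasta
    return read_alignment_fasta(DATA_DIR / "f1.fasta", gene_id="F1")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
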