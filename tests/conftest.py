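import numpy as np
import pandas as pd
import pytest

from force_epistasis import GenotypeMatrix, MISSING


def make_gm(genotypes, phenotype, positions=None, chrom=None, ids=None,
            alleles=("a", "A")):
    """Build a GenotypeMatrix from raw arrays with generated metadata."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_snps = genotypes.shape[1]
    meta = pd.DataFrame({
        "id": ids if ids is not None else [f"snp{j + 1}" for j in range(n_snps)],
        "chrom": chrom if chrom is not None else ["1"] * n_snps,
        "pos": positions if positions is not None else
               [1_000_000 * (j + 1) for j in range(n_snps)],
        "allele1": alleles[0],
        "allele2": alleles[1],
    })
    return GenotypeMatrix(genotypes, np.asarray(phenotype, dtype=np.int8), meta)


def random_gm(rng, n_samples=60, n_snps=8, missing_rate=0.05, maf_range=(0.1, 0.5)):
    """Random case-control genotype data, balanced phenotype, optional missing."""
    freqs = rng.uniform(*maf_range, size=n_snps)
    g = rng.binomial(2, freqs, size=(n_samples, n_snps)).astype(np.int8)
    if missing_rate:
        g[rng.random(g.shape) < missing_rate] = MISSING
    phenotype = np.zeros(n_samples, dtype=np.int8)
    phenotype[: n_samples // 2] = 1
    return make_gm(g, phenotype)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_ped(tmp_path):
    """3 samples x 2 SNPs with hand-readable calls.

    SNP rs1 alleles C/T: T copies per sample = 1, 1, 0 (T minor: 2/6).
    SNP rs2 alleles A/G: sample 2 missing; A copies = 0, -, 1 (A minor: 1/4).
    Phenotypes: case, control, case.
    """
    (tmp_path / "toy.map").write_text(
        "1 rs1 0 1000\n"
        "2 rs2 0 5000\n"
    )
    (tmp_path / "toy.ped").write_text(
        "f1 s1 0 0 0 2 C T G G\n"
        "f2 s2 0 0 0 1 C T 0 0\n"
        "f3 s3 0 0 0 2 C C A G\n"
    )
    return tmp_path / "toy"
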