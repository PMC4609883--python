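import numpy as np
import pytest

from dcvar import ExpressionMatrix, GenotypeMatrix, MISSING


@pytest.fixture
def tiny_genotypes() -> GenotypeMatrix:
    """3 SNPs x 4 samples with one missing call."""
    calls = np.array(
        [
            [0, 0, 1, 2],
            [0, 1, 2, MISSING],
            [1, 1, 1, 1],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        snp_ids=["rs1", "rs2", "rs3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        chrom=["1", "1", "2"],
        pos=np.array([100, 200, 300], dtype=np.int64),
        calls=calls,
        alleles=[("A", "T"), ("C", "G"), ("A", "C")],
    )


@pytest.fixture
def tiny_expression() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    return ExpressionMatrix(
        probe_ids=["pA", "pB", "pC"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=rng.standard_normal((3, 4)),
    )


def random_genotype_matrix(
    rng: np.random.Generator, n_snps: int, n_samples: int, missing_rate: float = 0.0
) -> GenotypeMatrix:
    calls = rng.integers(0, 3, size=(n_snps, n_samples)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = MISSING
    # keep the designated-minor invariant per SNP
    for s in range(n_snps):
        nonmissing = calls[s] != MISSING
        if nonmissing.any() and calls[s][nonmissing].sum() > nonmissing.sum():
            calls[s][nonmissing] = 2 - calls[s][nonmissing]
    return GenotypeMatrix(
        snp_ids=[f"rs{s}" for s in range(n_snps)],
        sample_ids=[f"s{i}" for i in range(n_samples)],
        chrom=["1"] * n_snps,
        pos=np.arange(1, n_snps + 1, dtype=np.int64),
        calls=calls,
        alleles=[("A", "T")] * n_snps,
    )


def random_expression_matrix(
    rng: np.random.Generator, n_probes: int, n_samples: int
) -> ExpressionMatrix:
    return ExpressionMatrix(
        probe_ids=[f"p{t:03d}" for t in range(n_probes)],
        sample_ids=[f"s{i}" for i in range(n_samples)],
        values=rng.standard_normal((n_probes, n_samples)),
    )
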