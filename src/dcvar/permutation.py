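"""Permutation-based type-I-error (false-positive-rate) estimation.

The null is generated by permuting each SNP's call vector across samples
while fixing the expression matrix, which severs any genotype-expression
relationship but preserves every per-SNP genotype count (and hence MAF
and group sizes) exactly. Running the full scan on the permuted data and
counting trios that survive the configured threshold gives an empirical
estimate of the scan's family-wise false-positive behavior: at a
Bonferroni threshold alpha / n_tests the expected survivor count per
whole-scan replicate is alpha.

Each SNP draws its permutation from an independent stream derived from
the master seed and a stable hash of the SNP ID, so the result does not
depend on SNP iteration or storage order.
"""

from __future__ import annotations

import zlib
from dataclasses import replace

import numpy as np

from .io_formats import ExpressionMatrix, GenotypeMatrix
from .scan import ScanConfig, ScanSummary, run_scan


def _snp_rng(seed: int, snp_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(snp_id.encode())])
    )


def permute_genotypes(g: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Independently permute each SNP's calls (missing entries included).

    The per-SNP multiset of calls is conserved exactly; only the
    assignment of calls to samples changes. Deterministic in ``seed`` and
    independent of SNP order.
    """
    calls = g.calls.copy()
    n = g.n_samples
    for s, snp_id in enumerate(g.snp_ids):
        perm = _snp_rng(seed, snp_id).permutation(n)
        calls[s] = calls[s][perm]
    return replace(g, calls=calls)


def estimate_fpr(
    g: GenotypeMatrix, e: ExpressionMatrix, cfg: ScanConfig, seed: int
) -> tuple[int, int, float, ScanSummary]:
    """One permutation replicate: scan permuted genotypes, count survivors.

    Returns ``(n_significant, n_tests, fpr, summary)`` where ``n_tests``
    is the full designed trio count (the honest multiple-testing
    denominator, including skipped trios).
    """
    permuted = permute_genotypes(g, seed)
    results, summary = run_scan(permuted, e, cfg)
    n_tests = summary.n_trios
    n_sig = summary.n_significant
    return n_sig, n_tests, n_sig / n_tests, summary
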