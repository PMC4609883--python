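"""Preprocessing filters applied before a scan.

Three steps, in the order a discovery analysis applies them:

1. minor-allele-frequency window on SNPs (default 0.2 -- 0.8 on the
   designated-minor allele scale, i.e. MAF >= 0.2), so that both genotype
   groups are populated;
2. per-transcript quantile normalization onto standard-normal quantiles,
   which removes scale/distributional differences across transcripts and
   tames cross-population expression heterogeneity;
3. a top-N total-variance probe filter computed *after* normalization.

Upstream QC (call-rate, Hardy-Weinberg, LD pruning) is assumed done by
standard genotype tooling and is out of scope here.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import UndefinedMAFError, ValidationError
from .io_formats import MISSING, ExpressionMatrix, GenotypeMatrix


def minor_allele_frequency(calls: np.ndarray) -> float:
    """Frequency of the designated minor allele among non-missing calls.

    Returns (sum of minor-allele copies) / (2 x non-missing count).
    Because calls count the designated minor allele, the result can
    exceed 0.5 only if the designation is stale (e.g. after subsetting
    samples).
    """
    calls = np.asarray(calls)
    nonmissing = calls != MISSING
    n = int(nonmissing.sum())
    if n == 0:
        raise UndefinedMAFError("MAF undefined: all calls missing")
    return float(calls[nonmissing].sum()) / (2 * n)


def filter_snps_by_maf(
    g: GenotypeMatrix, low: float = 0.2, high: float = 0.8
) -> GenotypeMatrix:
    """Keep SNPs whose allele frequencies fall in [low, high] (inclusive).

    With minor-allele coding a SNP with minor frequency f has allele
    frequencies {f, 1 - f}; it is kept iff ``low <= f`` and
    ``1 - f <= high``. All-missing SNPs are dropped.
    """
    if not (0 <= low <= high <= 1):
        raise ValidationError(f"invalid MAF bounds ({low}, {high})")
    keep = []
    for s in range(g.n_snps):
        try:
            f = minor_allele_frequency(g.calls[s])
        except UndefinedMAFError:
            continue
        if low <= f and (1 - f) <= high:
            keep.append(s)
    return g.subset_snps(keep)


def quantile_normalize_transcript(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform of one transcript.

    The value at ascending rank k (1-based) maps to the standard-normal
    quantile of (k - 0.5)/n; ties receive the average of their ranks, so
    a constant vector maps to all zeros. The output depends only on the
    ranks: any strictly monotone transform of the input yields the
    identical result.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 1 or values.size < 2:
        raise ValidationError("quantile normalization needs a 1-D vector, n >= 2")
    if not np.isfinite(values).all():
        raise ValidationError("quantile normalization input has non-finite values")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.5) / values.size)


def quantile_normalize(e: ExpressionMatrix) -> ExpressionMatrix:
    """Apply the inverse-normal transform to every probe independently."""
    out = np.empty_like(e.values)
    for t in range(e.n_probes):
        out[t] = quantile_normalize_transcript(e.values[t])
    return ExpressionMatrix(list(e.probe_ids), list(e.sample_ids), out)


def variance_filter(e: ExpressionMatrix, top_n: int) -> ExpressionMatrix:
    """Keep the ``top_n`` probes by unbiased sample variance (ddof=1).

    Ties at the cutoff are broken by probe-ID lexicographic order, so the
    selected set is deterministic and invariant to the input row order.
    Selected probes keep their original relative order.
    """
    if top_n > e.n_probes:
        raise ValidationError(
            f"top_n={top_n} exceeds probe count {e.n_probes}"
        )
    variances = e.values.var(axis=1, ddof=1)
    order = sorted(range(e.n_probes), key=lambda t: (-variances[t], e.probe_ids[t]))
    keep = sorted(order[:top_n])
    return e.subset_probes(keep)
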