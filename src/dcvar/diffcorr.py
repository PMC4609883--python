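"""The differential-correlation statistic and multiple-testing helpers.

For one SNP and one probe pair, samples fall into genotype groups G1 and
G2 of sizes m1 and m2. Within each group the Pearson correlation r of
the two probes is Fisher z-transformed, z = arctanh(r), whose sampling
variance is approximately 1/(m - 3). The two-sample test statistic is

    Z = |z1 - z2| / sqrt(1/(m1 - 3) + 1/(m2 - 3))

which is approximately standard normal under the null of equal
population correlation; the two-sided p-value is 2 * (1 - Phi(Z)).

The transform is applied *signed*: r = -0.9 and r = +0.9 must be maximally
different, not identical, and the absolute value enters only in the
numerator difference. The denominator carries the square root of the
summed variances, as in the textbook two-sample correlation z-test.

Family-wise control uses a Bonferroni threshold over the full designed
trio count S x T(T-1)/2; a Benjamini-Hochberg FDR option is available
for less stringent control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateCorrelationError,
    InsufficientSamplesError,
    ValidationError,
)

#: |r| is pulled inside the open interval by this amount before arctanh,
#: so a perfectly collinear small group yields an extreme but finite Z.
CLAMP_EPS = 1e-15

#: Smallest reportable p-value; 2*norm.sf underflows to exactly 0 around
#: Z ~ 39 and the contract requires p > 0.
MIN_P = 5e-324

#: m - 3 must be positive in both groups for the variance term.
HARD_MIN_GROUP = 4


@dataclass(frozen=True)
class DiffCorrStat:
    """Within-group correlations and the standardized z-difference."""

    r1: float
    r2: float
    z1: float
    z2: float
    Z: float
    p: float
    m1: int
    m2: int
    clamped: bool = False


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    The divisor convention cancels between numerator and denominator, so
    the result is the same for population or sample covariance.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValidationError("pearson_r needs two equal-length 1-D vectors, n >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        raise DegenerateCorrelationError("constant vector has no defined correlation")
    return float(xc @ yc) / denom


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilizing transform, z = arctanh(r), signed."""
    if not -1.0 < r < 1.0:
        raise ValidationError(f"fisher_z domain is (-1, 1); got r={r}")
    return math.atanh(r)


def clamp_correlation(r: float, eps: float = CLAMP_EPS) -> tuple[float, bool]:
    """Pull |r| = 1 (possible at tiny m) just inside the open interval."""
    if r >= 1.0:
        return 1.0 - eps, True
    if r <= -1.0:
        return -1.0 + eps, True
    return r, False


def z_statistic(
    r1: float, m1: int, r2: float, m2: int, min_group_size: int = HARD_MIN_GROUP
) -> DiffCorrStat:
    """Two-sample Fisher z-test for a difference in correlation.

    Raises :class:`InsufficientSamplesError` when either group is below
    ``min_group_size`` (never below 4: the variance term needs m > 3).
    """
    floor = max(min_group_size, HARD_MIN_GROUP)
    if m1 < floor or m2 < floor:
        raise InsufficientSamplesError(
            f"group sizes ({m1}, {m2}) below minimum {floor}"
        )
    r1c, c1 = clamp_correlation(r1)
    r2c, c2 = clamp_correlation(r2)
    z1 = fisher_z(r1c)
    z2 = fisher_z(r2c)
    se = math.sqrt(1.0 / (m1 - 3) + 1.0 / (m2 - 3))
    Z = abs(z1 - z2) / se
    p = max(2.0 * float(stats.norm.sf(Z)), MIN_P)
    return DiffCorrStat(
        r1=r1, r2=r2, z1=z1, z2=z2, Z=Z, p=min(p, 1.0),
        m1=int(m1), m2=int(m2), clamped=c1 or c2,
    )


def n_trios(n_snps: int, n_probes: int) -> int:
    """Designed test count: every SNP against every unordered probe pair."""
    return n_snps * (n_probes * (n_probes - 1) // 2)


def bonferroni_threshold(alpha: float, n_snps: int, n_probes: int) -> float:
    """Family-wise threshold alpha / (S x T(T-1)/2).

    For the reference genome-wide design (70,716 SNPs x 10,000 probes at
    alpha = 0.05) this is 1.41e-14; restricted to a single variant it is
    about 1e-9.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha {alpha} outside (0, 1)")
    if n_snps < 1 or n_probes < 2:
        raise ValidationError("need n_snps >= 1 and n_probes >= 2")
    return alpha / n_trios(n_snps, n_probes)


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up procedure; returns a boolean mask."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if not ((p > 0) & (p <= 1)).all():
        raise ValidationError("p-values must lie in (0, 1]")
    if not 0 < q < 1:
        raise ValidationError(f"q {q} outside (0, 1)")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject
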