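"""The genome-wide scan engine.

Every SNP is tested against every unordered probe pair. Per SNP, the
samples are split into two genotype groups and the full within-group
probe-probe correlation matrix is computed for each group from the
group-restricted expression block (one centered matrix product per
group), rather than a per-pair loop; the results are identical to the
naive triple loop up to floating-point summation order.

Trios whose preconditions fail — a genotype group below the minimum
size, or a probe constant within a group — are skipped and counted, never
assigned p = 1, so the multiple-testing denominator stays the full
designed count S x T(T-1)/2 and the bookkeeping identity
``evaluated + skipped = designed`` holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .diffcorr import (
    CLAMP_EPS,
    MIN_P,
    bh_fdr,
    bonferroni_threshold,
    n_trios,
)
from .errors import ValidationError
from .genotype_models import MODELS, assign_groups
from .io_formats import ExpressionMatrix, GenotypeMatrix, TrioResult

CORRECTIONS = ("bonferroni", "bh", "none")


@dataclass
class ScanConfig:
    """Configuration for one scan run."""

    model: str = "dominant"
    alpha: float = 0.05
    correction: str = "bonferroni"
    p_threshold: Optional[float] = None  # explicit override of the arithmetic
    min_group_size: int = 4
    chunk_size: int = 4096  # probe-block size hook for very large T
    seed: int = 0  # consumed by the permutation module
    out: Optional[str] = None

    def validate(self) -> None:
        if self.model not in MODELS:
            raise ValidationError(f"unknown model {self.model!r}")
        if self.correction not in CORRECTIONS:
            raise ValidationError(f"unknown correction {self.correction!r}")
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha {self.alpha} outside (0, 1)")
        if self.p_threshold is not None and not 0 < self.p_threshold <= 1:
            raise ValidationError(f"p_threshold {self.p_threshold} outside (0, 1]")
        if self.min_group_size < 4:
            raise ValidationError("min_group_size must be >= 4 (z-test needs m > 3)")
        if self.chunk_size < 1:
            raise ValidationError("chunk_size must be >= 1")


@dataclass
class ScanSummary:
    """Exact bookkeeping for one scan."""

    n_snps: int
    n_probes: int
    n_trios: int  # designed count S x T(T-1)/2
    n_evaluated: int = 0
    n_skipped_small_group: int = 0
    n_skipped_constant: int = 0
    n_significant: int = 0
    threshold: float = 1.0
    correction: str = "bonferroni"
    model: str = "dominant"

    @property
    def n_skipped(self) -> int:
        return self.n_skipped_small_group + self.n_skipped_constant

    def format_lines(self) -> list[str]:
        return [
            f"SNPs tested:        {self.n_snps}",
            f"probes tested:      {self.n_probes}",
            f"designed trios:     {self.n_trios}",
            f"evaluated trios:    {self.n_evaluated}",
            f"skipped (group):    {self.n_skipped_small_group}",
            f"skipped (constant): {self.n_skipped_constant}",
            f"significant trios:  {self.n_significant}",
            f"model:              {self.model}",
            f"correction:         {self.correction}",
            f"threshold:          {self.threshold:.6e}",
        ]


def resolve_threshold(cfg: ScanConfig, n_snps: int, n_probes: int) -> float:
    """Emission threshold implied by the config.

    An explicit ``p_threshold`` wins; otherwise Bonferroni arithmetic over
    the full designed trio count, or alpha uncorrected. BH has no fixed
    per-test threshold, so the scan collects all evaluated trios and
    applies the step-up afterwards.
    """
    if cfg.p_threshold is not None:
        return cfg.p_threshold
    if cfg.correction == "bonferroni":
        return bonferroni_threshold(cfg.alpha, n_snps, n_probes)
    return 1.0 if cfg.correction == "bh" else cfg.alpha


def _group_block_stats(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlation matrix and constant-probe mask for one group's block.

    ``block`` is (T, m). Constant probes (max == min within the group)
    get a zeroed row so the matrix product stays finite; their pairs are
    masked out by the caller.
    """
    constant = block.max(axis=1) == block.min(axis=1)
    centered = block - block.mean(axis=1, keepdims=True)
    centered[constant] = 0.0
    ss = np.einsum("ij,ij->i", centered, centered)
    norm = np.sqrt(np.where(ss > 0, ss, 1.0))
    cross = centered @ centered.T
    corr = cross / np.outer(norm, norm)
    np.clip(corr, -1.0, 1.0, out=corr)
    return corr, constant


def run_scan(
    g: GenotypeMatrix, e: ExpressionMatrix, cfg: ScanConfig
) -> tuple[list[TrioResult], ScanSummary]:
    """Test every SNP x probe-pair trio; return pruned results + summary.

    Results are canonicalized: within a trio ``probe_i < probe_j``
    lexicographically, and the list is sorted by (snp, probe_i, probe_j),
    so output is invariant to SNP and probe input order.
    """
    cfg.validate()
    if g.n_snps < 1 or e.n_probes < 2:
        raise ValidationError(
            f"scan needs >= 1 SNP and >= 2 probes "
            f"(got {g.n_snps} SNPs, {e.n_probes} probes)"
        )
    if g.sample_ids != e.sample_ids:
        raise ValidationError(
            "genotype and expression samples are not aligned; call align_samples first"
        )
    T = e.n_probes
    pairs_per_snp = T * (T - 1) // 2
    summary = ScanSummary(
        n_snps=g.n_snps,
        n_probes=T,
        n_trios=n_trios(g.n_snps, T),
        correction=cfg.correction,
        model=cfg.model,
    )
    threshold = resolve_threshold(cfg, g.n_snps, T)
    summary.threshold = threshold
    iu, ju = np.triu_indices(T, k=1)

    results: list[TrioResult] = []
    for s in range(g.n_snps):
        ga = assign_groups(g.calls[s], cfg.model)
        m1, m2 = ga.m1, ga.m2
        if m1 < cfg.min_group_size or m2 < cfg.min_group_size:
            summary.n_skipped_small_group += pairs_per_snp
            continue
        c1, const1 = _group_block_stats(e.values[:, ga.g1_mask])
        c2, const2 = _group_block_stats(e.values[:, ga.g2_mask])
        bad = const1 | const2
        n_good = T - int(bad.sum())
        n_eval = n_good * (n_good - 1) // 2
        summary.n_skipped_constant += pairs_per_snp - n_eval
        summary.n_evaluated += n_eval
        if n_eval == 0:
            continue

        r1 = c1[iu, ju]
        r2 = c2[iu, ju]
        valid = ~(bad[iu] | bad[ju])
        clamped = (np.abs(r1) >= 1.0) | (np.abs(r2) >= 1.0)
        z1 = np.arctanh(np.clip(r1, -1 + CLAMP_EPS, 1 - CLAMP_EPS))
        z2 = np.arctanh(np.clip(r2, -1 + CLAMP_EPS, 1 - CLAMP_EPS))
        se = np.sqrt(1.0 / (m1 - 3) + 1.0 / (m2 - 3))
        Z = np.abs(z1 - z2) / se
        p = np.minimum(np.maximum(2.0 * stats.norm.sf(Z), MIN_P), 1.0)

        hits = np.flatnonzero(valid & (p <= threshold))
        snp_id = g.snp_ids[s]
        for k in hits:
            i, j = int(iu[k]), int(ju[k])
            pi, pj = e.probe_ids[i], e.probe_ids[j]
            if pj < pi:
                pi, pj = pj, pi
            results.append(
                TrioResult(
                    snp_id=snp_id, probe_i=pi, probe_j=pj,
                    r1=float(r1[k]), r2=float(r2[k]),
                    z1=float(z1[k]), z2=float(z2[k]),
                    Z=float(Z[k]), p=float(p[k]),
                    m1=m1, m2=m2, clamped=bool(clamped[k]),
                )
            )

    if cfg.correction == "bh" and results:
        reject = bh_fdr(np.array([t.p for t in results]), cfg.alpha)
        kept = [t for t, r in zip(results, reject) if r]
        summary.threshold = max((t.p for t in kept), default=0.0) or summary.threshold
        results = kept

    results.sort(key=lambda t: (t.snp_id, t.probe_i, t.probe_j))
    summary.n_significant = len(results)
    return results, summary


def count_unique(results: list[TrioResult]) -> tuple[int, int, int]:
    """Distinct (SNPs, probes, unordered probe pairs) in a result set."""
    snps = {t.snp_id for t in results}
    probes = {p for t in results for p in (t.probe_i, t.probe_j)}
    pairs = {(t.probe_i, t.probe_j) for t in results}
    return len(snps), len(probes), len(pairs)
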