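"""The trio scan engine: block computation, bookkeeping, canonical output."""

import numpy as np
import pytest

from dcvar import (
    PlantSpec,
    ScanConfig,
    assign_groups,
    count_unique,
    generate,
    pearson_r,
    run_scan,
    z_statistic,
)
from dcvar.errors import DegenerateCorrelationError, ValidationError
from dcvar.io_formats import TrioResult

from conftest import random_expression_matrix, random_genotype_matrix


def naive_scan(g, e, cfg):
    """Per-trio reference loop over pearson_r/z_statistic (no blocks)."""
    out = {}
    for s in range(g.n_snps):
        ga = assign_groups(g.calls[s], cfg.model)
        if ga.m1 < cfg.min_group_size or ga.m2 < cfg.min_group_size:
            continue
        x1 = e.values[:, ga.g1_mask]
        x2 = e.values[:, ga.g2_mask]
        for i in range(e.n_probes):
            for j in range(i + 1, e.n_probes):
                try:
                    r1 = pearson_r(x1[i], x1[j])
                    r2 = pearson_r(x2[i], x2[j])
                except DegenerateCorrelationError:
                    continue
                stat = z_statistic(r1, ga.m1, r2, ga.m2, cfg.min_group_size)
                pi, pj = sorted((e.probe_ids[i], e.probe_ids[j]))
                out[(g.snp_ids[s], pi, pj)] = stat
    return out


class TestRunScan:
    def test_block_scan_matches_naive_loop(self):
        rng = np.random.default_rng(11)
        g = random_genotype_matrix(rng, n_snps=5, n_samples=40, missing_rate=0.05)
        e = random_expression_matrix(rng, n_probes=20, n_samples=40)
        cfg = ScanConfig(p_threshold=1.0)  # keep everything
        results, summary = run_scan(g, e, cfg)
        reference = naive_scan(g, e, cfg)
        assert len(results) == len(reference) == summary.n_evaluated
        for t in results:
            ref = reference[(t.snp_id, t.probe_i, t.probe_j)]
            assert t.Z == pytest.approx(ref.Z, rel=1e-12, abs=1e-12)
            assert t.p == pytest.approx(ref.p, rel=1e-12)
            assert (t.m1, t.m2) == (ref.m1, ref.m2)

    def test_pair_counting_one_snp_three_probes(self):
        rng = np.random.default_rng(12)
        g = random_genotype_matrix(rng, n_snps=1, n_samples=30)
        e = random_expression_matrix(rng, n_probes=3, n_samples=30)
        _, summary = run_scan(g, e, ScanConfig(p_threshold=1.0))
        assert summary.n_trios == 3
        assert summary.n_evaluated + summary.n_skipped == 3

    def test_monomorphic_snp_trios_skipped_as_small_group(self):
        rng = np.random.default_rng(13)
        g = random_genotype_matrix(rng, n_snps=1, n_samples=30)
        g.calls[0, :] = 0
        e = random_expression_matrix(rng, n_probes=4, n_samples=30)
        _, summary = run_scan(g, e, ScanConfig(p_threshold=1.0))
        assert summary.n_skipped_small_group == 6
        assert summary.n_evaluated == 0

    def test_constant_probe_within_group_skipped_and_counted(self):
        rng = np.random.default_rng(14)
        g = random_genotype_matrix(rng, n_snps=1, n_samples=30)
        e = random_expression_matrix(rng, n_probes=4, n_samples=30)
        e.values[2, :] = 5.0  # constant everywhere, hence in both groups
        results, summary = run_scan(g, e, ScanConfig(p_threshold=1.0))
        assert summary.n_skipped_constant == 3  # pairs involving probe 2
        assert summary.n_evaluated == 3
        assert all("p002" not in (t.probe_i, t.probe_j) for t in results)

    def test_output_invariant_to_snp_and_probe_order(self):
        rng = np.random.default_rng(15)
        g = random_genotype_matrix(rng, n_snps=4, n_samples=36)
        e = random_expression_matrix(rng, n_probes=8, n_samples=36)
        cfg = ScanConfig(p_threshold=1.0)
        base, _ = run_scan(g, e, cfg)
        g2 = g.subset_snps([2, 0, 3, 1])
        e2 = e.subset_probes([5, 1, 7, 0, 3, 6, 2, 4])
        shuffled, _ = run_scan(g2, e2, cfg)
        keys = [(t.snp_id, t.probe_i, t.probe_j) for t in base]
        assert keys == [(t.snp_id, t.probe_i, t.probe_j) for t in shuffled]
        for a, b in zip(base, shuffled):
            assert a.Z == pytest.approx(b.Z, rel=1e-12)

    def test_bookkeeping_identity_over_random_fixtures(self):
        rng = np.random.default_rng(16)
        for _ in range(10):
            g = random_genotype_matrix(rng, 3, 25, missing_rate=0.2)
            e = random_expression_matrix(rng, 6, 25)
            _, summary = run_scan(
                g, e, ScanConfig(p_threshold=1.0, model="homozygous")
            )
            assert summary.n_evaluated + summary.n_skipped == summary.n_trios

    def test_planted_effect_ranks_first(self):
        g, e, truth = generate(PlantSpec(seed=21))
        results, _ = run_scan(g, e, ScanConfig(p_threshold=1.0))
        best = min(results, key=lambda t: t.p)
        assert (best.snp_id, best.probe_i, best.probe_j) == (
            truth["snp"], truth["probe_i"], truth["probe_j"],
        )

    def test_bh_correction_keeps_step_up_survivors(self):
        g, e, _ = generate(PlantSpec(seed=22))
        results, summary = run_scan(g, e, ScanConfig(correction="bh", alpha=0.05))
        assert summary.n_significant == len(results)
        # planted trio must survive FDR control at q = 0.05
        assert any(t.snp_id == "snp_causal" for t in results)

    def test_unaligned_samples_rejected(self):
        rng = np.random.default_rng(17)
        g = random_genotype_matrix(rng, 2, 10)
        e = random_expression_matrix(rng, 4, 10)
        e.sample_ids = [f"x{i}" for i in range(10)]
        with pytest.raises(ValidationError, match="align"):
            run_scan(g, e, ScanConfig())

    def test_too_few_probes_fatal(self):
        rng = np.random.default_rng(18)
        g = random_genotype_matrix(rng, 2, 10)
        e = random_expression_matrix(rng, 1, 10)
        with pytest.raises(ValidationError):
            run_scan(g, e, ScanConfig())


class TestCountUnique:
    def make(self, snp, a, b):
        return TrioResult(snp, a, b, 0.1, 0.2, 0.1, 0.2, 1.0, 0.3, 10, 10)

    def test_distinct_counts(self):
        trios = [
            self.make("s1", "a", "b"),
            self.make("s1", "a", "c"),
            self.make("s2", "a", "b"),
        ]
        assert count_unique(trios) == (2, 3, 2)

    def test_empty(self):
        assert count_unique([]) == (0, 0, 0)

    def test_scan_emits_each_trio_at_most_once(self):
        rng = np.random.default_rng(19)
        g = random_genotype_matrix(rng, 3, 30)
        e = random_expression_matrix(rng, 6, 30)
        results, _ = run_scan(g, e, ScanConfig(p_threshold=1.0))
        keys = [(t.snp_id, t.probe_i, t.probe_j) for t in results]
        assert len(keys) == len(set(keys))
        assert all(t.probe_i < t.probe_j for t in results)
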