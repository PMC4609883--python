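"""Synthetic genotype + expression fixtures with a planted effect.

The generator emulates the structure of a differential co-expression
variant: one causal SNP drawn at Hardy-Weinberg genotype frequencies for
a given minor-allele frequency, and one probe pair whose within-group
correlation is ``rho1`` in genotype group G1 and ``rho2`` in G2 under the
chosen genetic model. Around it sit independent null SNPs (random MAFs)
and i.i.d. standard-normal null probes, so a scan of the fixture has a
single known ground-truth trio.

All expression margins are standard normal: the bivariate draws use the
2x2 Cholesky factor, so quantile normalization is approximately an
identity on large fixtures and the statistic is exercised in isolation
from normalization effects.

What this does *not* emulate: linkage disequilibrium between SNPs,
population stratification, microarray noise floors, or RNA-Seq count
distributions. Passing tests on these fixtures demonstrate the
correctness and calibration of the statistic, not robustness to those
real-data features.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ValidationError
from .genotype_models import EXCLUDED, G1, G2, MODELS, assign_groups
from .io_formats import (
    ExpressionMatrix,
    GenotypeMatrix,
    write_expression,
    write_genotypes_tped,
)


@dataclass
class PlantSpec:
    """Parameters of one planted-effect fixture.

    ``rho_het`` governs the planted pair's correlation for heterozygotes
    when the homozygous model excludes them from the effect groups;
    ``None`` means they inherit ``rho1``.
    """

    n_samples: int = 200
    maf: float = 0.3
    model: str = "dominant"
    rho1: float = 0.7
    rho2: float = 0.0
    rho_het: Optional[float] = None
    n_null_snps: int = 10
    n_null_probes: int = 20
    min_group_size: int = 4
    regenerate: bool = True  # redraw genotypes if a group comes up short
    max_attempts: int = 50
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValidationError(f"maf {self.maf} outside (0, 0.5]")
        if self.model not in MODELS:
            raise ValidationError(f"unknown model {self.model!r}")
        for name in ("rho1", "rho2", "rho_het"):
            v = getattr(self, name)
            if v is not None and not -1 < v < 1:
                raise ValidationError(f"{name}={v} outside (-1, 1)")
        if self.n_samples < 2 * self.min_group_size:
            raise ValidationError("n_samples too small for two viable groups")


def _hwe_genotypes(rng: np.random.Generator, n: int, maf: float) -> np.ndarray:
    q = maf
    probs = [(1 - q) ** 2, 2 * q * (1 - q), q * q]
    calls = rng.choice(np.array([0, 1, 2], dtype=np.int8), size=n, p=probs)
    # keep the designated-minor invariant: empirical minor frequency <= 0.5
    if calls.sum() > n:  # frequency of coded allele > 0.5
        calls = (2 - calls).astype(np.int8)
    return calls


def _correlated_pair(
    rng: np.random.Generator, n: int, rho: float
) -> tuple[np.ndarray, np.ndarray]:
    u = rng.standard_normal(n)
    v = rng.standard_normal(n)
    return u, rho * u + np.sqrt(1 - rho * rho) * v


def generate(
    spec: PlantSpec,
) -> tuple[GenotypeMatrix, ExpressionMatrix, dict]:
    """Draw one fixture; returns (genotypes, expression, truth record).

    Deterministic in ``spec.seed``: the same spec regenerates the same
    dataset byte for byte.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples

    causal = _hwe_genotypes(rng, n, spec.maf)
    ga = assign_groups(causal, spec.model)
    attempts = 1
    while ga.m1 < spec.min_group_size or ga.m2 < spec.min_group_size:
        if not spec.regenerate or attempts >= spec.max_attempts:
            raise ValidationError(
                f"group sizes ({ga.m1}, {ga.m2}) below {spec.min_group_size} "
                f"after {attempts} draw(s) at maf={spec.maf}, n={n}"
            )
        causal = _hwe_genotypes(rng, n, spec.maf)
        ga = assign_groups(causal, spec.model)
        attempts += 1

    # planted pair: per-group bivariate normal with the group's rho
    rho_het = spec.rho1 if spec.rho_het is None else spec.rho_het
    rho_by_label = {G1: spec.rho1, G2: spec.rho2, EXCLUDED: rho_het}
    e1 = np.empty(n)
    e2 = np.empty(n)
    for label, rho in rho_by_label.items():
        mask = ga.labels == label
        m = int(mask.sum())
        if m == 0:
            continue
        e1[mask], e2[mask] = _correlated_pair(rng, m, rho)

    null_probes = rng.standard_normal((spec.n_null_probes, n))
    null_mafs = rng.uniform(0.2, 0.5, size=spec.n_null_snps)
    null_calls = [
        _hwe_genotypes(rng, n, float(q)) for q in null_mafs
    ]

    sample_ids = [f"sample_{i:04d}" for i in range(n)]
    snp_ids = ["snp_causal"] + [f"snp_null_{k:04d}" for k in range(spec.n_null_snps)]
    probe_ids = ["probe_plant_a", "probe_plant_b"] + [
        f"probe_null_{k:04d}" for k in range(spec.n_null_probes)
    ]
    calls = np.vstack([causal[None, :]] + [c[None, :] for c in null_calls]).astype(
        np.int8
    )
    values = np.vstack([e1[None, :], e2[None, :], null_probes])

    g = GenotypeMatrix(
        snp_ids=snp_ids,
        sample_ids=sample_ids,
        chrom=["1"] * len(snp_ids),
        pos=np.arange(1, len(snp_ids) + 1, dtype=np.int64) * 1000,
        calls=calls,
        alleles=[("A", "T")] * len(snp_ids),
    )
    e = ExpressionMatrix(probe_ids=probe_ids, sample_ids=sample_ids, values=values)
    g.validate()
    e.validate()

    truth = {
        "snp": "snp_causal",
        "probe_i": "probe_plant_a",
        "probe_j": "probe_plant_b",
        "model": spec.model,
        "rho1": spec.rho1,
        "rho2": spec.rho2,
        "rho_het": rho_het,
        "maf": spec.maf,
        "m1": ga.m1,
        "m2": ga.m2,
        "n_samples": n,
        "seed": spec.seed,
    }
    return g, e, truth


def write_fixture(
    g: GenotypeMatrix,
    e: ExpressionMatrix,
    out_dir: str | Path,
    truth: Optional[dict] = None,
) -> dict[str, Path]:
    """Serialize a fixture to .tped/.tfam + expression TSV (+ truth txt)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tped": out_dir / "genotypes.tped",
        "tfam": out_dir / "genotypes.tfam",
        "expr": out_dir / "expression.tsv",
    }
    write_genotypes_tped(g, paths["tped"], paths["tfam"])
    write_expression(e, paths["expr"])
    if truth is not None:
        paths["truth"] = out_dir / "truth.txt"
        with open(paths["truth"], "w") as fh:
            for k, v in truth.items():
                fh.write(f"{k} = {v}\n")
    return paths
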