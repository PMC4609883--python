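"""Text-format IO and the in-memory containers used by every other module.

Genotypes are read from the PLINK text dialects (.ped/.map and the
transposed .tped/.tfam) into a :class:`GenotypeMatrix` that codes each
call as the number of copies of the designated minor allele (0, 1, 2)
with ``MISSING`` (-1) for calls containing a missing allele character.
Expression is a plain tab-delimited probes x samples table read into an
:class:`ExpressionMatrix`. Scan output is written as a TSV of surviving
(SNP, probe, probe) trios.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, MultiAllelicError, ValidationError

#: Sentinel for a missing genotype call in ``GenotypeMatrix.calls``.
MISSING: int = -1

#: Allele characters treated as missing (PLINK text convention).
MISSING_ALLELE_CHARS = frozenset({"0", "N"})

#: Placeholder minor-allele character for a monomorphic SNP (no second
#: allele observed, so none can be designated minor).
ABSENT_ALLELE = "0"


@dataclass
class GenotypeMatrix:
    """Biallelic genotype calls for S SNPs x N samples.

    ``calls[s, n]`` counts copies of the minor allele of SNP ``s`` carried
    by sample ``n`` (0, 1 or 2), or ``MISSING``. ``alleles[s]`` is the
    ``(major, minor)`` character pair; positions are 1-based annotation
    only and never enter any computation.
    """

    snp_ids: list[str]
    sample_ids: list[str]
    chrom: list[str]
    pos: np.ndarray  # (S,) int64, 1-based
    calls: np.ndarray  # (S, N) int8 in {0, 1, 2, MISSING}
    alleles: list[tuple[str, str]]  # per SNP (major, minor)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def validate(self) -> None:
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValidationError("duplicate SNP IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample IDs")
        if self.calls.shape != (self.n_snps, self.n_samples):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{self.n_snps} SNPs x {self.n_samples} samples"
            )
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValidationError("genotype calls outside {0, 1, 2, MISSING}")

    def subset_snps(self, index: Sequence[int]) -> "GenotypeMatrix":
        idx = list(index)
        return GenotypeMatrix(
            snp_ids=[self.snp_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            chrom=[self.chrom[i] for i in idx],
            pos=self.pos[idx].copy(),
            calls=self.calls[idx].copy(),
            alleles=[self.alleles[i] for i in idx],
        )

    def subset_samples(self, index: Sequence[int]) -> "GenotypeMatrix":
        idx = list(index)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            calls=self.calls[:, idx].copy(),
        )


@dataclass
class ExpressionMatrix:
    """Real-valued expression of T probes x N samples, no missing values."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (T, N) float64

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def validate(self) -> None:
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("duplicate probe IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample IDs")
        if self.values.shape != (self.n_probes, self.n_samples):
            raise ValidationError("values shape does not match IDs")
        if not np.isfinite(self.values).all():
            raise ValidationError("expression matrix contains non-finite values")

    def subset_probes(self, index: Sequence[int]) -> "ExpressionMatrix":
        idx = list(index)
        return ExpressionMatrix(
            probe_ids=[self.probe_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            values=self.values[idx].copy(),
        )

    def subset_samples(self, index: Sequence[int]) -> "ExpressionMatrix":
        idx = list(index)
        return ExpressionMatrix(
            probe_ids=list(self.probe_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[:, idx].copy(),
        )


@dataclass(frozen=True)
class TrioResult:
    """One (SNP, probe pair) differential-correlation test result.

    ``probe_i < probe_j`` lexicographically, so each unordered pair
    appears exactly once. ``clamped`` flags a within-group |r| = 1 that
    was pulled inside the open interval before the z-transform.
    """

    snp_id: str
    probe_i: str
    probe_j: str
    r1: float
    r2: float
    z1: float
    z2: float
    Z: float
    p: float
    m1: int
    m2: int
    clamped: bool = False


# ---------------------------------------------------------------------------
# genotype readers
# ---------------------------------------------------------------------------


def _read_map(map_path: Path) -> tuple[list[str], list[str], np.ndarray]:
    chroms: list[str] = []
    snp_ids: list[str] = []
    pos: list[int] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4:
                raise FormatError(
                    f"{map_path}: line {lineno}: expected 4 columns "
                    f"(chrom, snp, cM, pos), got {len(fields)}"
                )
            chroms.append(fields[0])
            snp_ids.append(fields[1])
            try:
                pos.append(int(fields[3]))
            except ValueError as exc:
                raise FormatError(
                    f"{map_path}: line {lineno}: non-integer position {fields[3]!r}"
                ) from exc
    return chroms, snp_ids, np.asarray(pos, dtype=np.int64)


def _encode_snp(
    a1: Sequence[str], a2: Sequence[str], snp_id: str
) -> tuple[np.ndarray, tuple[str, str]]:
    """Turn per-sample allele character pairs into minor-allele counts.

    The allele with the lower frequency among non-missing calls is
    designated minor; at an exact 50/50 tie the lexicographically smaller
    character becomes the major allele.
    """
    n = len(a1)
    calls = np.full(n, MISSING, dtype=np.int8)
    counts: dict[str, int] = {}
    pairs: list[tuple[int, str, str]] = []
    for i in range(n):
        x, y = a1[i], a2[i]
        if x in MISSING_ALLELE_CHARS or y in MISSING_ALLELE_CHARS:
            continue
        counts[x] = counts.get(x, 0) + 1
        counts[y] = counts.get(y, 0) + 1
        pairs.append((i, x, y))
    observed = sorted(counts)
    if len(observed) > 2:
        raise MultiAllelicError(
            f"SNP {snp_id}: {len(observed)} distinct alleles {observed} "
            "(biallelic input required)"
        )
    if not observed:  # all calls missing
        return calls, (ABSENT_ALLELE, ABSENT_ALLELE)
    if len(observed) == 1:
        major, minor = observed[0], ABSENT_ALLELE
    else:
        a, b = observed  # a < b lexicographically
        # minor = strictly less frequent; tie -> smaller char is MAJOR
        if counts[a] < counts[b]:
            major, minor = b, a
        else:  # counts[a] >= counts[b]: b is minor (covers the tie)
            major, minor = a, b
    for i, x, y in pairs:
        calls[i] = (x == minor) + (y == minor)
    return calls, (major, minor)


def read_genotypes_ped(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read a PLINK text .ped/.map pair (one sample per .ped row)."""
    ped_path, map_path = Path(ped_path), Path(map_path)
    chroms, snp_ids, pos = _read_map(map_path)
    n_snps = len(snp_ids)
    sample_ids: list[str] = []
    rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise FormatError(
                    f"{ped_path}: line {lineno}: expected "
                    f"{6 + 2 * n_snps} columns for {n_snps} SNPs, got {len(fields)}"
                )
            sample_ids.append(fields[1])
            rows.append(fields[6:])
    n = len(sample_ids)
    calls = np.full((n_snps, n), MISSING, dtype=np.int8)
    alleles: list[tuple[str, str]] = []
    for s in range(n_snps):
        a1 = [rows[i][2 * s] for i in range(n)]
        a2 = [rows[i][2 * s + 1] for i in range(n)]
        calls[s], lab = _encode_snp(a1, a2, snp_ids[s])
        alleles.append(lab)
    g = GenotypeMatrix(snp_ids, sample_ids, chroms, pos, calls, alleles)
    g.validate()
    return g


def read_genotypes_tped(tped_path: str | Path, tfam_path: str | Path) -> GenotypeMatrix:
    """Read the transposed PLINK text dialect (one SNP per .tped row)."""
    tped_path, tfam_path = Path(tped_path), Path(tfam_path)
    sample_ids: list[str] = []
    with open(tfam_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 2:
                raise FormatError(
                    f"{tfam_path}: line {lineno}: expected >=2 columns"
                )
            sample_ids.append(fields[1])
    n = len(sample_ids)

    chroms: list[str] = []
    snp_ids: list[str] = []
    pos: list[int] = []
    call_rows: list[np.ndarray] = []
    alleles: list[tuple[str, str]] = []
    with open(tped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            allele_fields = fields[4:]
            if len(allele_fields) % 2 or len(allele_fields) != 2 * n:
                raise FormatError(
                    f"{tped_path}: line {lineno}: expected {2 * n} allele "
                    f"columns for {n} samples, got {len(allele_fields)}"
                )
            chroms.append(fields[0])
            snp_ids.append(fields[1])
            try:
                pos.append(int(fields[3]))
            except ValueError as exc:
                raise FormatError(
                    f"{tped_path}: line {lineno}: non-integer position {fields[3]!r}"
                ) from exc
            row, lab = _encode_snp(allele_fields[0::2], allele_fields[1::2], fields[1])
            call_rows.append(row)
            alleles.append(lab)
    calls = (
        np.vstack(call_rows) if call_rows else np.empty((0, n), dtype=np.int8)
    )
    g = GenotypeMatrix(
        snp_ids, sample_ids, chroms, np.asarray(pos, dtype=np.int64), calls, alleles
    )
    g.validate()
    return g


# ---------------------------------------------------------------------------
# genotype writers (fixtures and round-trip tests)
# ---------------------------------------------------------------------------


def _allele_pair(code: int, major: str, minor: str) -> tuple[str, str]:
    if code == MISSING:
        return "0", "0"
    if code == 0:
        return major, major
    if code == 1:
        return major, minor
    return minor, minor


def write_genotypes_ped(g: GenotypeMatrix, ped_path: str | Path, map_path: str | Path) -> None:
    with open(map_path, "w") as fh:
        for s in range(g.n_snps):
            fh.write(f"{g.chrom[s]}\t{g.snp_ids[s]}\t0\t{int(g.pos[s])}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(g.sample_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for s in range(g.n_snps):
                fields.extend(_allele_pair(int(g.calls[s, i]), *g.alleles[s]))
            fh.write(" ".join(fields) + "\n")


def write_genotypes_tped(g: GenotypeMatrix, tped_path: str | Path, tfam_path: str | Path) -> None:
    with open(tfam_path, "w") as fh:
        for sid in g.sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    with open(tped_path, "w") as fh:
        for s in range(g.n_snps):
            fields = [g.chrom[s], g.snp_ids[s], "0", str(int(g.pos[s]))]
            for i in range(g.n_samples):
                fields.extend(_allele_pair(int(g.calls[s, i]), *g.alleles[s]))
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a tab-delimited probes x samples table.

    First column holds probe IDs, header row holds sample IDs. Any
    non-numeric cell (including "NA") is a parse error: imputation must
    be explicit upstream, never silent.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False, na_values=[]
    )
    probe_ids = [str(p) for p in df.index]
    sample_ids = [str(s) for s in df.columns]
    if len(set(probe_ids)) != len(probe_ids):
        dupes = sorted({p for p in probe_ids if probe_ids.count(p) > 1})
        raise ValidationError(f"{path}: duplicate probe IDs: {dupes[:5]}")
    values = np.empty(df.shape, dtype=np.float64)
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.index[numeric.isna()]
        if len(bad):
            row = probe_ids.index(str(bad[0]))
            raise FormatError(
                f"{path}: non-numeric cell {df[col].loc[bad[0]]!r} at "
                f"probe {bad[0]!r} (row {row + 2}), sample {col!r}"
            )
        values[:, j] = numeric.to_numpy()
    e = ExpressionMatrix(probe_ids, sample_ids, values)
    e.validate()
    return e


def write_expression(e: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(e.values, index=e.probe_ids, columns=e.sample_ids)
    df.to_csv(path, sep="\t", index_label="probe_id", float_format="%.10g")


# ---------------------------------------------------------------------------
# alignment & results
# ---------------------------------------------------------------------------


def align_samples(
    g: GenotypeMatrix, e: ExpressionMatrix
) -> tuple[GenotypeMatrix, ExpressionMatrix]:
    """Restrict both matrices to the shared samples, in a common order.

    The final column order is the genotype matrix's sample order
    restricted to the intersection, so the result is deterministic and
    invariant to the expression file's column order.
    """
    expr_set = set(e.sample_ids)
    shared = [sid for sid in g.sample_ids if sid in expr_set]
    if not shared:
        raise ValidationError(
            "no samples shared between genotype and expression inputs"
        )
    g_idx = [g.sample_ids.index(sid) for sid in shared]
    e_idx = [e.sample_ids.index(sid) for sid in shared]
    return g.subset_samples(g_idx), e.subset_samples(e_idx)


RESULT_COLUMNS = ("snp", "probe_i", "probe_j", "r1", "r2", "m1", "m2", "Z", "p")


def write_results(
    results: Iterable[TrioResult], path: str | Path, threshold: float
) -> int:
    """Write trios with p <= threshold as TSV; return the count written.

    p-values use scientific notation with 6 significant digits so that
    genome-scale thresholds (1e-14 and below) survive a text round trip.
    """
    if not 0 < threshold <= 1:
        raise ValidationError(f"threshold {threshold} outside (0, 1]")
    n = 0
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for t in results:
            if t.p > threshold:
                continue
            fh.write(
                f"{t.snp_id}\t{t.probe_i}\t{t.probe_j}\t"
                f"{t.r1:.6f}\t{t.r2:.6f}\t{t.m1}\t{t.m2}\t"
                f"{t.Z:.6f}\t{t.p:.6e}\n"
            )
            n += 1
    return n
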