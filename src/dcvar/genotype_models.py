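"""Genotype dichotomization: map one SNP's calls onto two comparison groups.

Three encodings are supported for a biallelic SNP with major allele A and
minor allele T:

* ``dominant``   — G1 = AA,       G2 = AT or TT (one or more minor alleles)
* ``recessive``  — G1 = AA or AT, G2 = TT
* ``homozygous`` — G1 = AA,       G2 = TT; heterozygotes are excluded

Missing calls are always excluded. The dominant model balances group
sizes best when the minor-allele frequency is high (>= 0.2) and is the
default for discovery scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING

MODELS = ("dominant", "recessive", "homozygous")

#: Per-sample label codes in :attr:`GroupAssignment.labels`.
EXCLUDED, G1, G2 = 0, 1, 2


@dataclass(frozen=True)
class GroupAssignment:
    """Per-sample group labels for one SNP under one genetic model."""

    labels: np.ndarray  # (N,) int8 in {EXCLUDED, G1, G2}
    model: str

    @property
    def g1_mask(self) -> np.ndarray:
        return self.labels == G1

    @property
    def g2_mask(self) -> np.ndarray:
        return self.labels == G2

    @property
    def m1(self) -> int:
        return int(self.g1_mask.sum())

    @property
    def m2(self) -> int:
        return int(self.g2_mask.sum())

    @property
    def n_excluded(self) -> int:
        return int((self.labels == EXCLUDED).sum())


def assign_groups(calls: np.ndarray, model: str) -> GroupAssignment:
    """Assign samples to {G1, G2, excluded} from minor-allele counts.

    Parameters
    ----------
    calls
        Genotype codes in {0, 1, 2, MISSING} for one SNP.
    model
        One of ``dominant``, ``recessive``, ``homozygous``.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    calls = np.asarray(calls)
    labels = np.full(calls.shape, EXCLUDED, dtype=np.int8)
    if model == "dominant":
        labels[calls == 0] = G1
        labels[(calls == 1) | (calls == 2)] = G2
    elif model == "recessive":
        labels[(calls == 0) | (calls == 1)] = G1
        labels[calls == 2] = G2
    else:  # homozygous: heterozygotes stay excluded
        labels[calls == 0] = G1
        labels[calls == 2] = G2
    labels[calls == MISSING] = EXCLUDED
    return GroupAssignment(labels=labels, model=model)
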