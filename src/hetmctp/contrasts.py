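"""Contrast matrices for one-way and crossed two-way layouts.

Each row ``c_l`` of a contrast matrix ``C`` encodes one linear hypothesis
``H0(l): c_l' b = 0`` on the vector of adjusted treatment effects.  The
classical families are many-to-one (Dunnett), all-pairwise (Tukey) and
comparisons to the grand mean (the centering matrix ``P_a = I_a - J_a / a``).
For crossed factors, main-effect and interaction matrices are Kronecker
products of centering matrices and averaging vectors, with cells ordered
first-factor slow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List

import numpy as np


@dataclass
class ContrastMatrix:
    """A ``q x a`` hypothesis matrix with one label per row."""

    C: np.ndarray
    row_labels: List[str]
    family: str

    def __post_init__(self):
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        q = self.C.shape[0]
        if q < 1:
            raise ValueError("contrast matrix needs at least one row")
        if len(self.row_labels) != q:
            raise ValueError("row_labels length does not match the matrix")
        if np.any(np.all(self.C == 0.0, axis=1)):
            raise ValueError("contrast matrix contains an all-zero row")
        if self.family == "custom":
            sums = self.C.sum(axis=1)
            if np.any(np.abs(sums) > 1e-10):
                warnings.warn(
                    "custom hypothesis rows do not all sum to zero; they are "
                    "accepted but are not contrasts",
                    UserWarning,
                )

    @property
    def q(self) -> int:
        return self.C.shape[0]

    @property
    def a(self) -> int:
        return self.C.shape[1]


def centering_matrix(a: int) -> np.ndarray:
    """The centering projection ``P_a = I_a - J_a / a``."""
    return np.eye(a) - np.full((a, a), 1.0 / a)


def build_contrast(family: str, a: int) -> ContrastMatrix:
    """Build a standard one-way contrast family for ``a`` groups.

    ``dunnett``: groups 2..a each compared to group 1 (q = a - 1).
    ``tukey``: all pairwise differences (q = a(a-1)/2).
    ``grandmean``: each group compared to the grand mean; the full ``a x a``
    centering matrix is kept even though its rows are linearly dependent.
    """
    if a < 2:
        raise ValueError(f"need at least 2 groups, got a={a}")
    if family == "dunnett":
        C = np.zeros((a - 1, a))
        C[:, 0] = -1.0
        C[np.arange(a - 1), np.arange(1, a)] = 1.0
        labels = [f"{i + 2} - 1" for i in range(a - 1)]
    elif family == "tukey":
        rows, labels = [], []
        for i in range(a - 1):
            for j in range(i + 1, a):
                row = np.zeros(a)
                row[i], row[j] = -1.0, 1.0
                rows.append(row)
                labels.append(f"{j + 1} - {i + 1}")
        C = np.array(rows)
    elif family == "grandmean":
        C = centering_matrix(a)
        labels = [f"{i + 1} - mean" for i in range(a)]
    else:
        raise ValueError(f"unknown contrast family {family!r}")
    return ContrastMatrix(C=C, row_labels=labels, family=family)


def factorial_contrast(levels, effect: str) -> ContrastMatrix:
    """Main-effect and interaction contrasts for a crossed two-way layout.

    Cells are ordered first factor slow, second factor fast, matching
    :func:`hetmctp.io.read_table`.  With centering matrices ``P_a`` and
    averaging vectors ``1'_a / a``:

    * ``main_first``:  ``P_{a1} (x) 1'_{a2}/a2`` — first-factor levels vs
      their grand mean, averaged over the second factor;
    * ``main_second``: ``1'_{a1}/a1 (x) P_{a2}``;
    * ``interaction``: ``P_{a1} (x) P_{a2}``.
    """
    a1, a2 = levels
    if a1 < 2 or a2 < 2:
        raise ValueError("both factors need at least 2 levels")
    avg1 = np.full((1, a1), 1.0 / a1)
    avg2 = np.full((1, a2), 1.0 / a2)
    if effect == "main_first":
        C = np.kron(centering_matrix(a1), avg2)
        labels = [f"A{i + 1} - mean" for i in range(a1)]
    elif effect == "main_second":
        C = np.kron(avg1, centering_matrix(a2))
        labels = [f"B{j + 1} - mean" for j in range(a2)]
    elif effect == "interaction":
        C = np.kron(centering_matrix(a1), centering_matrix(a2))
        labels = [f"A{i + 1}:B{j + 1}" for i in range(a1) for j in range(a2)]
    else:
        raise ValueError(f"unknown factorial effect {effect!r}")
    return ContrastMatrix(C=C, row_labels=labels, family="factorial")
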