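"""Correspondence analysis of the sequences x codons RSCU matrix.

Standard CA: the matrix is normalised to proportions P with row masses
r and column masses c, standardised residuals
S = D_r^{-1/2} (P - r c^T) D_c^{-1/2} are decomposed by SVD, and
principal coordinates are the mass-scaled singular vectors times the
singular values.  Per-axis inertia is the squared singular value; total
inertia equals the Pearson chi-square statistic divided by the grand
total.  Axis signs are fixed by making the largest-magnitude column
loading on each axis positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["CoaResult", "correspondence_analysis"]


@dataclass(frozen=True)
class CoaResult:
    row_ids: list[str]
    col_ids: list[str]
    row_coords: np.ndarray  # rows x axes, principal coordinates
    col_coords: np.ndarray  # cols x axes, principal coordinates
    inertia: np.ndarray     # sigma^2 per axis
    total_inertia: float

    @property
    def inertia_pct(self) -> np.ndarray:
        if self.total_inertia == 0:
            return np.zeros_like(self.inertia)
        return 100.0 * self.inertia / self.total_inertia


def correspondence_analysis(
    M: np.ndarray,
    row_ids: list[str] | None = None,
    col_ids: list[str] | None = None,
) -> CoaResult:
    """Run CA on a nonnegative matrix (e.g. RSCU values, 59 columns).

    Zero rows/columns are dropped with a warning; with identical row
    profiles the total inertia is 0 and all coordinates vanish.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if (M < 0).any():
        raise ValueError("matrix entries must be nonnegative")
    n_rows, n_cols = M.shape
    row_ids = list(row_ids) if row_ids is not None else [str(i) for i in range(n_rows)]
    col_ids = list(col_ids) if col_ids is not None else [str(j) for j in range(n_cols)]

    keep_r = M.sum(axis=1) > 0
    keep_c = M.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping zero rows/columns from CA input")
        M = M[keep_r][:, keep_c]
        row_ids = [i for i, k in zip(row_ids, keep_r) if k]
        col_ids = [j for j, k in zip(col_ids, keep_c) if k]
    if M.shape[0] < 2:
        raise ValueError("need at least 2 rows with nonzero mass")

    P = M / M.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sig, Vt = np.linalg.svd(S, full_matrices=False)

    # trim trivial/numerically-null axes
    k = min(M.shape[0] - 1, M.shape[1] - 1)
    U, sig, Vt = U[:, :k], sig[:k], Vt[:k, :]

    with np.errstate(invalid="ignore"):
        row_std = U / np.sqrt(r)[:, None]
        col_std = Vt.T / np.sqrt(c)[:, None]
    row_pc = row_std * sig[None, :]
    col_pc = col_std * sig[None, :]

    # sign convention: largest |column loading| positive per axis
    for j in range(k):
        if col_pc.shape[0]:
            i_max = int(np.argmax(np.abs(col_pc[:, j])))
            if col_pc[i_max, j] < 0:
                col_pc[:, j] *= -1.0
                row_pc[:, j] *= -1.0

    inertia = sig ** 2
    return CoaResult(
        row_ids=row_ids,
        col_ids=col_ids,
        row_coords=row_pc,
        col_coords=col_pc,
        inertia=inertia,
        total_inertia=float(inertia.sum()),
    )
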