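"""Rank selection by 4-block bi-cross-validation.

The matrix is split into four random blocks::

    Y = [A B]
        [C D]

D is factorized at each candidate rank; the held-out block A is predicted
from the off-diagonal blocks as A_hat = B @ pinv(H_D) @ pinv(W_D) @ C, and
the rank minimizing the mean per-cell squared prediction error over folds
is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FitConfig, nmf_fit

__all__ = ["BCVPartition", "BCVResult", "bcv_partition", "bcv_heldout_error", "select_rank"]


@dataclass
class BCVPartition:
    """One random 2x2 tiling of a matrix into blocks A, B, C, D."""

    rows_in: np.ndarray   # row indices of A and B (size r)
    rows_out: np.ndarray  # row indices of C and D (size m - r)
    cols_in: np.ndarray   # column indices of A and C (size s)
    cols_out: np.ndarray  # column indices of B and D (size n - s)
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray


@dataclass
class BCVResult:
    k_grid: list[int]
    errors: pd.DataFrame  # columns: k, fold, error
    k_selected: int
    folds: int
    seed: int

    def mean_errors(self) -> pd.Series:
        return self.errors.groupby("k")["error"].mean()


def bcv_partition(Y: np.ndarray, row_frac: float = 0.5, col_frac: float = 0.5,
                  seed: int = 0) -> BCVPartition:
    """Randomly tile Y into four blocks; rows/cols are permuted by the seed."""
    Y = np.asarray(Y, dtype=np.float64)
    m, n = Y.shape
    if not (0.0 < row_frac < 1.0 and 0.0 < col_frac < 1.0):
        raise ValueError("row_frac and col_frac must lie strictly in (0, 1)")
    r = int(round(m * row_frac))
    s = int(round(n * col_frac))
    if not (1 <= r < m and 1 <= s < n):
        raise ValueError(
            f"fractions produce an empty block: r={r} of m={m}, s={s} of n={n}"
        )
    rng = np.random.default_rng(seed)
    row_perm = rng.permutation(m)
    col_perm = rng.permutation(n)
    rows_in, rows_out = np.sort(row_perm[:r]), np.sort(row_perm[r:])
    cols_in, cols_out = np.sort(col_perm[:s]), np.sort(col_perm[s:])
    return BCVPartition(
        rows_in=rows_in, rows_out=rows_out, cols_in=cols_in, cols_out=cols_out,
        A=Y[np.ix_(rows_in, cols_in)],
        B=Y[np.ix_(rows_in, cols_out)],
        C=Y[np.ix_(rows_out, cols_in)],
        D=Y[np.ix_(rows_out, cols_out)],
    )


def bcv_heldout_error(partition: BCVPartition, k: int,
                      fit_config: FitConfig | None = None) -> float:
    """Mean squared error of predicting block A from D (via B and C).

    D is factorized at rank k (NNDSVD init by default, for determinism);
    the prediction is invariant to the scale ambiguity of (W_D, H_D)
    because the pseudo-inverses cancel any invertible diagonal rescaling.
    """
    D = partition.D
    if k > min(D.shape):
        raise ValueError(f"k={k} exceeds the D block's min dimension {min(D.shape)}")
    if fit_config is None:
        fit_config = FitConfig(k=k, init="nndsvd", max_outer_iter=100, rel_tol=1e-5)
    else:
        fit_config = FitConfig(**{**fit_config.__dict__, "k": k})
    model = nmf_fit(D, fit_config)
    W_D = model.W
    H_D = model.H_rna * model.rescale_rna  # undo modality rescaling
    A_hat = partition.B @ np.linalg.pinv(H_D) @ np.linalg.pinv(W_D) @ partition.C
    resid = partition.A - A_hat
    return float(np.sum(resid * resid) / partition.A.size)


def select_rank(
    Y: np.ndarray,
    k_grid,
    folds: int = 5,
    row_frac: float = 0.5,
    col_frac: float = 0.5,
    seed: int = 0,
    fit_config: FitConfig | None = None,
) -> BCVResult:
    """Average the BCV held-out error over independent partitions per rank
    and pick the argmin (ties go to the smaller rank)."""
    k_grid = sorted(int(k) for k in k_grid)
    if not k_grid:
        raise ValueError("k_grid is empty")
    Y = np.asarray(Y, dtype=np.float64)
    fold_seeds = np.random.SeedSequence(seed).generate_state(folds)
    records = []
    for fold, fs in enumerate(fold_seeds):
        part = bcv_partition(Y, row_frac, col_frac, seed=int(fs))
        for k in k_grid:
            err = bcv_heldout_error(part, k, fit_config)
            records.append({"k": k, "fold": fold, "error": err})
    errors = pd.DataFrame.from_records(records)
    means = errors.groupby("k")["error"].mean()
    k_selected = int(means.idxmin())  # idxmin takes the first (smallest) k on ties
    return BCVResult(k_grid=k_grid, errors=errors, k_selected=k_selected,
                     folds=folds, seed=seed)
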