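"""Joint two-block NMF with a shared spot-factor matrix.

Solves::

    min_{W, H_rna, H_img >= 0}
        alpha * ||Y_rna - W @ H_rna||_F^2 + (2 - alpha) * ||Y_img - W @ H_img||_F^2

by accelerated hierarchical alternating least squares (A-HALS): each outer
iteration updates W, then H_rna, then H_img, each by cyclic closed-form
column/row updates repeated in a cheap inner loop while they still make
appreciable progress.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpotExpression",
    "SpotImageFeatures",
    "JointFactorModel",
    "FitConfig",
    "joint_objective",
    "jnmf_fit",
    "nmf_fit",
    "transform",
    "save_model",
    "load_model",
]

_EPS = np.finfo(np.float64).eps


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"duplicate {what}: {dupes[:5]}")
    return ids


def _check_nonneg(values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2:
        raise ValueError(f"{what} must be 2-D, got shape {values.shape}")
    if values.size == 0:
        raise ValueError(f"{what} is empty")
    neg = values < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValueError(f"{what} has negative entry at ({i}, {j}): {values[i, j]}")
    return values


@dataclass
class SpotExpression:
    """Non-negative spot x gene matrix with barcode and gene identifiers."""

    values: np.ndarray
    barcodes: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = _check_nonneg(self.values, "expression matrix")
        self.barcodes = _check_unique(self.barcodes, "barcodes")
        self.gene_ids = _check_unique(self.gene_ids, "gene_ids")
        m, n = self.values.shape
        if len(self.barcodes) != m:
            raise ValueError(
                f"barcode count {len(self.barcodes)} != spot axis length {m}"
            )
        if len(self.gene_ids) != n:
            raise ValueError(
                f"gene_id count {len(self.gene_ids)} != gene axis length {n}"
            )

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class SpotImageFeatures:
    """Non-negative spot x image-feature matrix aligned to an expression matrix."""

    values: np.ndarray
    barcodes: list[str]
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = _check_nonneg(self.values, "image feature matrix")
        self.barcodes = _check_unique(self.barcodes, "barcodes")
        self.feature_names = _check_unique(self.feature_names, "feature_names")
        m, f = self.values.shape
        if len(self.barcodes) != m:
            raise ValueError(
                f"barcode count {len(self.barcodes)} != spot axis length {m}"
            )
        if len(self.feature_names) != f:
            raise ValueError(
                f"feature_name count {len(self.feature_names)} != feature axis "
                f"length {f}"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class FitConfig:
    """Solver settings for :func:`jnmf_fit`.

    ``alpha`` weights the expression block; the image block gets ``2 - alpha``.
    ``inner_tol`` (delta) and ``inner_rho`` control the A-HALS inner loop:
    cyclic updates of a block repeat while the step size exceeds ``inner_tol``
    times the first inner step, capped at ``1 + floor(inner_rho * cost_ratio)``
    repeats, where ``cost_ratio`` is the flop ratio between the block's
    precomputation and one cyclic sweep.
    """

    alpha: float = 1.0
    k: int = 10
    init: str = "random_halfnormal"
    max_outer_iter: int = 200
    rel_tol: float = 1e-6
    inner_tol: float = 0.01
    inner_rho: float = 0.5
    seed: int | None = None
    modality_rescale: bool = True
    init_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 2.0:
            raise ValueError(f"alpha must be in [0, 2], got {self.alpha}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.max_outer_iter < 1:
            raise ValueError("max_outer_iter must be >= 1")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be > 0")
        if self.init not in ("random_halfnormal", "nndsvd"):
            raise ValueError(f"unknown init method {self.init!r}")


@dataclass
class JointFactorModel:
    """Fitted joint factorization: shared ``W`` plus per-modality loadings."""

    W: np.ndarray
    H_rna: np.ndarray
    H_img: np.ndarray
    alpha: float
    k: int
    objective_trace: np.ndarray
    seed: int | None = None
    converged: bool = False
    rescale_rna: float = 1.0
    rescale_img: float = 1.0
    unweighted_blocks: tuple[str, ...] = ()
    barcodes: list[str] | None = None
    gene_ids: list[str] | None = None
    feature_names: list[str] | None = None
    n_outer_iter: int = 0

    def reconstruct_rna(self) -> np.ndarray:
        """Reconstruction of the expression block on the original scale."""
        return (self.W @ self.H_rna) * self.rescale_rna

    def reconstruct_img(self) -> np.ndarray:
        return (self.W @ self.H_img) * self.rescale_img


def _values_of(Y, what: str) -> np.ndarray:
    if isinstance(Y, (SpotExpression, SpotImageFeatures)):
        return Y.values
    return _check_nonneg(np.asarray(Y, dtype=np.float64), what)


def joint_objective(Y_rna, Y_img, model: JointFactorModel) -> float:
    """Weighted sum of squared Frobenius residuals of the two blocks.

    Computed on the matrices the solver actually sees: if the model was fit
    with modality rescaling, the inputs are divided by the stored per-block
    scalars before the residual is taken.
    """
    Yr = np.asarray(_values_of(Y_rna, "Y_rna"), dtype=np.float64) / model.rescale_rna
    Yi = np.asarray(_values_of(Y_img, "Y_img"), dtype=np.float64) / model.rescale_img
    W, Hr, Hi = model.W, model.H_rna, model.H_img
    if Yr.shape[0] != W.shape[0]:
        raise ValueError(
            f"spot axis mismatch: Y_rna has {Yr.shape[0]} rows, W has {W.shape[0]}"
        )
    if Yi.shape[0] != W.shape[0]:
        raise ValueError(
            f"spot axis mismatch: Y_img has {Yi.shape[0]} rows, W has {W.shape[0]}"
        )
    if Yr.shape[1] != Hr.shape[1]:
        raise ValueError(
            f"gene axis mismatch: Y_rna has {Yr.shape[1]} columns, "
            f"H_rna has {Hr.shape[1]}"
        )
    if Yi.shape[1] != Hi.shape[1]:
        raise ValueError(
            f"feature axis mismatch: Y_img has {Yi.shape[1]} columns, "
            f"H_img has {Hi.shape[1]}"
        )
    a = model.alpha
    rr = Yr - W @ Hr
    ri = Yi - W @ Hi
    return float(a * np.sum(rr * rr) + (2.0 - a) * np.sum(ri * ri))


def _block_objective(sq_norm: float, Y: np.ndarray, W: np.ndarray, H: np.ndarray,
                     WtW: np.ndarray | None = None) -> float:
    """||Y - W H||_F^2 via the trace expansion (avoids forming the residual)."""
    if WtW is None:
        WtW = W.T @ W
    WtY = W.T @ Y
    val = sq_norm - 2.0 * float(np.sum(H * WtY)) + float(np.sum(WtW * (H @ H.T)))
    return max(val, 0.0)


def _hals_update_W(W: np.ndarray, A: np.ndarray, B: np.ndarray,
                   inner_tol: float, max_inner: int) -> np.ndarray:
    """Accelerated HALS sweep(s) for W given A = sum_b w_b Y_b H_b^T and
    B = sum_b w_b H_b H_b^T. Updates W in place."""
    k = W.shape[1]
    diag = np.diag(B).copy()
    first_step = None
    for _ in range(max_inner):
        step = 0.0
        for j in range(k):
            if diag[j] < _EPS:
                continue
            wj = W[:, j] + (A[:, j] - W @ B[:, j]) / diag[j]
            np.maximum(wj, 0.0, out=wj)
            d = wj - W[:, j]
            step += float(d @ d)
            W[:, j] = wj
        if first_step is None:
            first_step = step
            if first_step <= 0.0:
                break
        elif step <= inner_tol * first_step:
            break
    return W


def _hals_update_H(H: np.ndarray, WtY: np.ndarray, WtW: np.ndarray,
                   inner_tol: float, max_inner: int) -> np.ndarray:
    """Accelerated HALS sweep(s) for H given precomputed W^T Y and W^T W."""
    k = H.shape[0]
    diag = np.diag(WtW).copy()
    first_step = None
    for _ in range(max_inner):
        step = 0.0
        for j in range(k):
            if diag[j] < _EPS:
                continue
            hj = H[j, :] + (WtY[j, :] - WtW[j, :] @ H) / diag[j]
            np.maximum(hj, 0.0, out=hj)
            d = hj - H[j, :]
            step += float(d @ d)
            H[j, :] = hj
        if first_step is None:
            first_step = step
            if first_step <= 0.0:
                break
        elif step <= inner_tol * first_step:
            break
    return H


def _max_inner(rows: int, cols: int, k: int, rho: float) -> int:
    # flop ratio between the block's precomputation (Y-sized matmuls) and one
    # cyclic HALS sweep (k-sized matmuls)
    ratio = (rows * cols) / max(rows * k + cols * k, 1)
    return max(1, 1 + int(np.floor(rho * ratio)))


def _rescue_dead_factors(W: np.ndarray, Hs: list[np.ndarray],
                         rng: np.random.Generator) -> int:
    """Re-seed W columns whose norm collapsed; zero the paired H rows so the
    current reconstruction (and hence the objective) is unchanged."""
    norms = np.linalg.norm(W, axis=0)
    dead = np.flatnonzero(norms < 1e-12)
    if dead.size == 0:
        return 0
    alive = norms[norms >= 1e-12]
    target = float(alive.mean()) if alive.size else 1.0
    for j in dead:
        col = np.abs(rng.standard_normal(W.shape[0]))
        nrm = np.linalg.norm(col)
        W[:, j] = col * (target / nrm if nrm > 0 else 1.0)
        for H in Hs:
            H[j, :] = 0.0
    return int(dead.size)


def _normalize_columns(W: np.ndarray, Hs: list[np.ndarray]) -> None:
    """Scale W columns to unit Euclidean norm, pushing the scale into every
    H block consistently. Zero columns are left untouched."""
    norms = np.linalg.norm(W, axis=0)
    scale = np.where(norms > 0, norms, 1.0)
    W /= scale
    for H in Hs:
        H *= scale[:, None]


def _run_ahals(
    Yr: np.ndarray,
    Yi: np.ndarray | None,
    wr: float,
    wi: float,
    W: np.ndarray,
    Hr: np.ndarray,
    Hi: np.ndarray | None,
    config: FitConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None, np.ndarray, bool, int]:
    """Core alternating loop. ``Yi``/``Hi`` may be None for a unimodal fit.

    The objective is ``wr * ||Yr - W Hr||^2 + wi * ||Yi - W Hi||^2``; blocks
    with zero weight are skipped entirely inside the loop.
    """
    m, n = Yr.shape
    k = config.k
    f = Yi.shape[1] if Yi is not None else 0
    use_r = wr > 0.0
    use_i = wi > 0.0 and Yi is not None

    sq_r = float(np.sum(Yr * Yr))
    sq_i = float(np.sum(Yi * Yi)) if Yi is not None else 0.0

    cols_W = (n if use_r else 0) + (f if use_i else 0)
    mi_W = _max_inner(m, cols_W, k, config.inner_rho)
    mi_Hr = _max_inner(n, m, k, config.inner_rho)
    mi_Hi = _max_inner(f, m, k, config.inner_rho) if use_i else 1

    def objective() -> float:
        WtW = W.T @ W
        val = 0.0
        if use_r:
            val += wr * _block_objective(sq_r, Yr, W, Hr, WtW)
        if use_i:
            val += wi * _block_objective(sq_i, Yi, W, Hi, WtW)
        return val

    trace = [objective()]
    converged = False
    it = 0
    for it in range(1, config.max_outer_iter + 1):
        # --- W step: gradient pieces accumulate over the weighted blocks
        A = np.zeros((m, k))
        B = np.zeros((k, k))
        if use_r:
            A += wr * (Yr @ Hr.T)
            B += wr * (Hr @ Hr.T)
        if use_i:
            A += wi * (Yi @ Hi.T)
            B += wi * (Hi @ Hi.T)
        _hals_update_W(W, A, B, config.inner_tol, mi_W)

        _rescue_dead_factors(W, [H for H in (Hr, Hi) if H is not None], rng)

        WtW = W.T @ W
        if use_r:
            _hals_update_H(Hr, W.T @ Yr, WtW, config.inner_tol, mi_Hr)
        if use_i:
            _hals_update_H(Hi, W.T @ Yi, WtW, config.inner_tol, mi_Hi)

        trace.append(objective())
        prev, cur = trace[-2], trace[-1]
        denom = prev if prev > 0 else 1.0
        if abs(prev - cur) / denom < config.rel_tol:
            converged = True
            break

    return W, Hr, Hi, np.asarray(trace), converged, it


def _lstsq_nonneg_H(Y: np.ndarray, W: np.ndarray, n_sweeps: int = 200,
                    tol: float = 1e-10) -> np.ndarray:
    """Non-negative least squares for H in Y ~ W H with W fixed (HALS sweeps
    iterated to a fixed point)."""
    k = W.shape[1]
    WtY = W.T @ Y
    WtW = W.T @ W
    H = np.maximum(np.linalg.lstsq(W, Y, rcond=None)[0], 0.0)
    diag = np.diag(WtW).copy()
    for _ in range(n_sweeps):
        step = 0.0
        for j in range(k):
            if diag[j] < _EPS:
                H[j, :] = 0.0
                continue
            hj = H[j, :] + (WtY[j, :] - WtW[j, :] @ H) / diag[j]
            np.maximum(hj, 0.0, out=hj)
            d = hj - H[j, :]
            step += float(d @ d)
            H[j, :] = hj
        if step <= tol * max(float(np.sum(H * H)), 1.0):
            break
    return H


def _initial_factors(
    Yr: np.ndarray, Yi: np.ndarray | None, wr: float, wi: float, config: FitConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    from .initialization import init_nndsvd_joint, init_random_halfnormal

    m, n = Yr.shape
    f = Yi.shape[1] if Yi is not None else 0
    if config.init == "nndsvd":
        W0, Hr0, Hi0 = init_nndsvd_joint(Yr, Yi, wr, wi, config.k)
    else:
        if config.seed is None:
            raise ValueError(
                "random_halfnormal initialization requires a seed "
                "(reproducibility is a contract)"
            )
        total = float(np.sum(Yr)) * wr + (float(np.sum(Yi)) * wi if Yi is not None else 0.0)
        wtot = wr * Yr.size + (wi * Yi.size if Yi is not None else 0)
        data_mean = total / max(wtot, 1)
        W0, Hr0, Hi0 = init_random_halfnormal(
            m, n, f, config.k, seed=config.seed, scale=config.init_scale,
            data_mean=data_mean,
        )
        if Yi is None:
            Hi0 = None
    return W0, Hr0, Hi0


def jnmf_fit(Y_rna, Y_img, config: FitConfig | None = None,
             init_factors: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
             **kwargs) -> JointFactorModel:
    """Fit the joint factorization by accelerated HALS.

    Parameters
    ----------
    Y_rna : SpotExpression or array-like
        Non-negative spot x gene matrix.
    Y_img : SpotImageFeatures or array-like
        Non-negative spot x feature matrix over the same spots, same order.
    config : FitConfig, optional
        Solver settings; keyword arguments override individual fields.
    init_factors : (W0, H_rna0, H_img0), optional
        Explicit starting factors on the solver's (rescaled) scale; overrides
        ``config.init``.

    Returns
    -------
    JointFactorModel
        Factors with unit-norm W columns, the objective trace (one value per
        outer iteration, non-increasing), and fit metadata.
    """
    if config is None:
        config = FitConfig(**kwargs)
    elif kwargs:
        config = FitConfig(**{**config.__dict__, **kwargs})

    Yr = _values_of(Y_rna, "Y_rna")
    Yi = _values_of(Y_img, "Y_img")
    if Yr.shape[0] != Yi.shape[0]:
        raise ValueError(
            f"spot axis mismatch: Y_rna has {Yr.shape[0]} rows, "
            f"Y_img has {Yi.shape[0]}"
        )
    if isinstance(Y_rna, SpotExpression) and isinstance(Y_img, SpotImageFeatures):
        if Y_rna.barcodes != Y_img.barcodes:
            raise ValueError("Y_rna and Y_img barcodes differ (order matters)")
    if not np.any(Yr):
        raise ValueError("Y_rna is all zeros; nothing to factorize")
    if not np.any(Yi):
        raise ValueError("Y_img is all zeros; nothing to factorize")

    m, n = Yr.shape
    if config.k > min(m, n):
        warnings.warn(
            f"rank k={config.k} exceeds min(m, n)={min(m, n)}; the factorization "
            "is over-parameterized", UserWarning, stacklevel=2,
        )

    scale_r = float(np.linalg.norm(Yr)) if config.modality_rescale else 1.0
    scale_i = float(np.linalg.norm(Yi)) if config.modality_rescale else 1.0
    Yr_s = Yr / scale_r
    Yi_s = Yi / scale_i

    wr = config.alpha
    wi = 2.0 - config.alpha

    rng = np.random.default_rng(config.seed)
    if init_factors is not None:
        W0, Hr0, Hi0 = (np.array(x, dtype=np.float64) for x in init_factors)
    else:
        W0, Hr0, Hi0 = _initial_factors(Yr_s, Yi_s, wr, wi, config)

    unweighted: tuple[str, ...] = ()
    if wr == 0.0 and wi == 0.0:  # unreachable given alpha in [0,2]; guard anyway
        raise ValueError("both block weights are zero")

    W, Hr, Hi, trace, converged, n_iter = _run_ahals(
        Yr_s, Yi_s, wr, wi, W0, Hr0, Hi0, config, rng
    )

    # zero-weight blocks never entered the objective: fit their loadings post
    # hoc against the final W and flag them
    if wr == 0.0:
        Hr = _lstsq_nonneg_H(Yr_s, W)
        unweighted = unweighted + ("rna",)
    if wi == 0.0:
        Hi = _lstsq_nonneg_H(Yi_s, W)
        unweighted = unweighted + ("img",)

    _normalize_columns(W, [Hr, Hi])

    return JointFactorModel(
        W=W,
        H_rna=Hr,
        H_img=Hi,
        alpha=config.alpha,
        k=config.k,
        objective_trace=trace,
        seed=config.seed,
        converged=converged,
        rescale_rna=scale_r,
        rescale_img=scale_i,
        unweighted_blocks=unweighted,
        barcodes=list(Y_rna.barcodes) if isinstance(Y_rna, SpotExpression) else None,
        gene_ids=list(Y_rna.gene_ids) if isinstance(Y_rna, SpotExpression) else None,
        feature_names=(
            list(Y_img.feature_names) if isinstance(Y_img, SpotImageFeatures) else None
        ),
        n_outer_iter=n_iter,
    )


def nmf_fit(Y, config: FitConfig | None = None, **kwargs) -> JointFactorModel:
    """Unimodal NMF on a single non-negative matrix, same solver path.

    Equivalent to the expression-only limit of the joint problem. The
    returned model's ``H_img`` is an empty (k, 0) matrix.
    """
    if config is None:
        config = FitConfig(**kwargs)
    elif kwargs:
        config = FitConfig(**{**config.__dict__, **kwargs})
    Yv = _values_of(Y, "Y")
    if not np.any(Yv):
        raise ValueError("input matrix is all zeros; nothing to factorize")
    m, n = Yv.shape
    if config.k > min(m, n):
        warnings.warn(
            f"rank k={config.k} exceeds min(m, n)={min(m, n)}",
            UserWarning, stacklevel=2,
        )
    scale = float(np.linalg.norm(Yv)) if config.modality_rescale else 1.0
    Ys = Yv / scale
    rng = np.random.default_rng(config.seed)
    # weight 2.0 mirrors the alpha=2.0 joint path exactly (HALS updates are
    # invariant to a common positive scaling of the gradient pieces)
    W0, H0, _ = _initial_factors(Ys, None, 2.0, 0.0, config)
    W, H, _, trace, converged, n_iter = _run_ahals(
        Ys, None, 2.0, 0.0, W0, H0, None, config, rng
    )
    Hi = np.zeros((config.k, 0))
    _normalize_columns(W, [H, Hi])
    return JointFactorModel(
        W=W, H_rna=H, H_img=Hi, alpha=2.0, k=config.k, objective_trace=trace,
        seed=config.seed, converged=converged, rescale_rna=scale, rescale_img=1.0,
        unweighted_blocks=("img",),
        barcodes=list(Y.barcodes) if isinstance(Y, SpotExpression) else None,
        gene_ids=list(Y.gene_ids) if isinstance(Y, SpotExpression) else None,
        n_outer_iter=n_iter,
    )


def transform(model: JointFactorModel, Y_rna_new, Y_img_new,
              max_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    """Project new spots onto fixed loadings: minimize the joint objective
    over W only (iterated HALS W-steps to a fixed point)."""
    Yr = np.asarray(_values_of(Y_rna_new, "Y_rna_new"), dtype=np.float64)
    Yi = np.asarray(_values_of(Y_img_new, "Y_img_new"), dtype=np.float64)
    if Yr.shape[1] != model.H_rna.shape[1]:
        raise ValueError(
            f"gene axis mismatch: new data has {Yr.shape[1]} genes, "
            f"model has {model.H_rna.shape[1]}"
        )
    if Yi.shape[1] != model.H_img.shape[1]:
        raise ValueError(
            f"feature axis mismatch: new data has {Yi.shape[1]} features, "
            f"model has {model.H_img.shape[1]}"
        )
    if Yr.shape[0] != Yi.shape[0]:
        raise ValueError("new expression and image blocks have different spot counts")
    Yr = Yr / model.rescale_rna
    Yi = Yi / model.rescale_img
    wr, wi = model.alpha, 2.0 - model.alpha
    Hr, Hi = model.H_rna, model.H_img
    m = Yr.shape[0]
    k = model.k
    A = np.zeros((m, k))
    B = np.zeros((k, k))
    if wr > 0:
        A += wr * (Yr @ Hr.T)
        B += wr * (Hr @ Hr.T)
    if wi > 0:
        A += wi * (Yi @ Hi.T)
        B += wi * (Hi @ Hi.T)
    W = np.maximum(np.linalg.lstsq(B + _EPS * np.eye(k), A.T, rcond=None)[0].T, 0.0)
    diag = np.diag(B).copy()
    for _ in range(max_iter):
        step = 0.0
        for j in range(k):
            if diag[j] < _EPS:
                W[:, j] = 0.0
                continue
            wj = W[:, j] + (A[:, j] - W @ B[:, j]) / diag[j]
            np.maximum(wj, 0.0, out=wj)
            d = wj - W[:, j]
            step += float(d @ d)
            W[:, j] = wj
        if step <= tol * max(float(np.sum(W * W)), 1.0):
            break
    return W


# ---------------------------------------------------------------------------
# serialization


def save_model(model: JointFactorModel, out_dir: str | Path) -> Path:
    """Write W/H_rna/H_img as CSV (identifier headers) plus metadata JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    k = model.k
    factors = [f"factor_{i}" for i in range(k)]
    barcodes = model.barcodes or [f"spot_{i}" for i in range(model.W.shape[0])]
    genes = model.gene_ids or [f"gene_{i}" for i in range(model.H_rna.shape[1])]
    feats = model.feature_names or [f"feat_{i}" for i in range(model.H_img.shape[1])]
    pd.DataFrame(model.W, index=barcodes, columns=factors).to_csv(out / "W.csv")
    pd.DataFrame(model.H_rna, index=factors, columns=genes).to_csv(out / "H_rna.csv")
    pd.DataFrame(model.H_img, index=factors, columns=feats).to_csv(out / "H_img.csv")
    meta = {
        "alpha": model.alpha,
        "k": model.k,
        "seed": model.seed,
        "converged": model.converged,
        "rescale_rna": model.rescale_rna,
        "rescale_img": model.rescale_img,
        "unweighted_blocks": list(model.unweighted_blocks),
        "n_outer_iter": model.n_outer_iter,
        "objective_trace": [float(x) for x in model.objective_trace],
    }
    (out / "model.json").write_text(json.dumps(meta, indent=2))
    return out


def load_model(model_dir: str | Path) -> JointFactorModel:
    d = Path(model_dir)
    W = pd.read_csv(d / "W.csv", index_col=0)
    Hr = pd.read_csv(d / "H_rna.csv", index_col=0)
    Hi = pd.read_csv(d / "H_img.csv", index_col=0)
    meta = json.loads((d / "model.json").read_text())
    return JointFactorModel(
        W=W.to_numpy(dtype=np.float64),
        H_rna=Hr.to_numpy(dtype=np.float64),
        H_img=Hi.to_numpy(dtype=np.float64),
        alpha=meta["alpha"],
        k=meta["k"],
        objective_trace=np.asarray(meta["objective_trace"], dtype=np.float64),
        seed=meta["seed"],
        converged=meta["converged"],
        rescale_rna=meta["rescale_rna"],
        rescale_img=meta["rescale_img"],
        unweighted_blocks=tuple(meta["unweighted_blocks"]),
        barcodes=list(W.index.astype(str)),
        gene_ids=list(Hr.columns.astype(str)),
        feature_names=list(Hi.columns.astype(str)),
        n_outer_iter=meta["n_outer_iter"],
    )
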