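"""Initialization strategies for the joint factorization.

Two options: half-normal random draws (seeded, scaled to the data's mean
magnitude) and plain NNDSVD built from the leading singular triplets of the
weighted concatenated matrix.
"""

from __future__ import annotations

import numpy as np

__all__ = ["init_random_halfnormal", "init_nndsvd", "init_nndsvd_joint"]


def init_random_halfnormal(
    m: int,
    n: int,
    f: int,
    k: int,
    seed: int,
    scale: float = 1.0,
    data_mean: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (W0, H_rna0, H_img0) with entries |z| * scale * c, z ~ N(0, 1).

    The magnitude c = sqrt(data_mean / k) makes the initial product W0 @ H0
    land near the data's mean entry, keeping early iterations
    well-conditioned. A pure function of (shapes, seed, scale, data_mean).
    """
    if seed is None:
        raise ValueError("seed is required for half-normal initialization")
    if min(m, n, k) < 1 or f < 0:
        raise ValueError(f"invalid dimensions m={m}, n={n}, f={f}, k={k}")
    if scale <= 0:
        raise ValueError("scale must be positive")
    c = scale * np.sqrt(max(data_mean, 0.0) / k)
    rng = np.random.default_rng(seed)
    W0 = np.abs(rng.standard_normal((m, k))) * c
    H_rna0 = np.abs(rng.standard_normal((k, n))) * c
    H_img0 = np.abs(rng.standard_normal((k, f))) * c
    return W0, H_rna0, H_img0


def init_nndsvd(Y: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Plain NNDSVD: deterministic non-negative initialization from the k
    leading singular triplets.

    For each triplet (u, s, v), the positive parts (u+, v+) and negative
    parts (u-, v-) form two candidate non-negative rank-1 terms; the one
    carrying more of the triplet's energy is kept and scaled to preserve it.
    Zeros are left as zeros (no mean or random filling).
    """
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim != 2:
        raise ValueError("Y must be 2-D")
    if (Y < 0).any():
        raise ValueError("NNDSVD requires a non-negative matrix")
    m, n = Y.shape
    if k > min(m, n):
        raise ValueError(f"k={k} exceeds min(m, n)={min(m, n)}")
    U, S, Vt = np.linalg.svd(Y, full_matrices=False)
    W = np.zeros((m, k))
    H = np.zeros((k, n))
    # leading triplet of a non-negative matrix is entrywise sign-consistent
    # (Perron-Frobenius); take absolute values directly
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, k):
        u, v = U[:, j], Vt[j, :]
        up, un = np.maximum(u, 0.0), np.maximum(-u, 0.0)
        vp, vn = np.maximum(v, 0.0), np.maximum(-v, 0.0)
        up_n, un_n = np.linalg.norm(up), np.linalg.norm(un)
        vp_n, vn_n = np.linalg.norm(vp), np.linalg.norm(vn)
        pos_energy = up_n * vp_n
        neg_energy = un_n * vn_n
        if pos_energy >= neg_energy:
            if pos_energy > 0:
                sigma = np.sqrt(S[j] * pos_energy)
                W[:, j] = sigma * up / up_n
                H[j, :] = sigma * vp / vp_n
        else:
            sigma = np.sqrt(S[j] * neg_energy)
            W[:, j] = sigma * un / un_n
            H[j, :] = sigma * vn / vn_n
    return W, H


def init_nndsvd_joint(
    Yr: np.ndarray,
    Yi: np.ndarray | None,
    wr: float,
    wi: float,
    k: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """NNDSVD for the two-block problem via the weighted concatenation
    [sqrt(wr)*Yr | sqrt(wi)*Yi]; the H block columns are un-weighted after the
    split so W0 @ H0 approximates each original block.

    A zero-weight block gets zero loadings (it does not enter the objective
    and is refit post hoc by the solver).
    """
    n = Yr.shape[1]
    blocks = []
    if wr > 0:
        blocks.append(np.sqrt(wr) * Yr)
    if wi > 0 and Yi is not None:
        blocks.append(np.sqrt(wi) * Yi)
    if not blocks:
        raise ValueError("at least one block must have positive weight")
    Yc = np.concatenate(blocks, axis=1) if len(blocks) > 1 else blocks[0]
    W0, Hc = init_nndsvd(Yc, k)
    pos = 0
    if wr > 0:
        Hr0 = Hc[:, pos:pos + n] / np.sqrt(wr)
        pos += n
    else:
        Hr0 = np.zeros((k, n))
    if Yi is None:
        return W0, Hr0, None
    f = Yi.shape[1]
    if wi > 0:
        Hi0 = Hc[:, pos:pos + f] / np.sqrt(wi)
    else:
        Hi0 = np.zeros((k, f))
    return W0, Hr0, Hi0
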