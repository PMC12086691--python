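"""Factor post-processing: clustering, agreement metrics, contingency
tables, top-gene ranking, factor-target correlation, and gene-set scoring."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import (
    adjusted_mutual_info_score,
    adjusted_rand_score,
    fowlkes_mallows_score,
)
from sklearn.neighbors import kneighbors_graph

from .core import SpotExpression

__all__ = [
    "cluster_factors",
    "clustering_scores",
    "contingency_table",
    "top_genes",
    "factor_correlation",
    "signature_score",
]


def cluster_factors(
    W: np.ndarray,
    method: str = "kmeans",
    n_clusters: int | None = None,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Cluster spots by their factor scores.

    ``kmeans`` honors ``n_clusters`` exactly; ``graph`` builds a k-nearest-
    neighbour graph on the rows of W and runs modularity-style community
    detection (Leiden) at the given resolution.
    """
    W = np.asarray(W, dtype=np.float64)
    m = W.shape[0]
    if method == "kmeans":
        if n_clusters is None:
            raise ValueError("kmeans requires n_clusters")
        if n_clusters > m:
            raise ValueError(f"n_clusters={n_clusters} exceeds spot count {m}")
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
        return km.fit_predict(W)
    if method == "graph":
        import igraph as ig
        import leidenalg

        nn = min(n_neighbors, m - 1)
        adj = kneighbors_graph(W, n_neighbors=nn, mode="connectivity",
                               include_self=False)
        adj = adj.maximum(adj.T).tocoo()  # symmetrize
        edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
        g = ig.Graph(n=m, edges=edges)
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=-1,
        )
        return np.asarray(part.membership, dtype=int)
    raise ValueError(f"unknown clustering method {method!r}")


def _paired(labels, reference) -> tuple[np.ndarray, np.ndarray, int]:
    labels = np.asarray(labels)
    reference = np.asarray(reference)
    if labels.shape != reference.shape:
        raise ValueError(
            f"label length {labels.shape} != reference length {reference.shape}"
        )
    if reference.dtype == object or reference.dtype.kind in "UOf":
        mask = pd.notna(reference)
    else:
        mask = np.ones(len(reference), dtype=bool)
    return labels[mask], reference[mask], int((~mask).sum())


def clustering_scores(labels, reference) -> dict[str, float]:
    """ARI, AMI and Fowlkes-Mallows between computed labels and a reference
    partition. Spots with a missing reference label are dropped and counted
    in the returned report."""
    lab, ref, n_dropped = _paired(labels, reference)
    if len(lab) == 0:
        raise ValueError("no spots with both a label and a reference annotation")
    return {
        "ari": float(adjusted_rand_score(ref, lab)),
        "ami": float(adjusted_mutual_info_score(ref, lab)),
        "fowlkes_mallows": float(fowlkes_mallows_score(ref, lab)),
        "n_spots": int(len(lab)),
        "n_dropped": n_dropped,
    }


def contingency_table(labels, reference) -> pd.DataFrame:
    """Cluster x reference co-assignment counts (grand total = number of
    spots carrying both labels)."""
    lab, ref, _ = _paired(labels, reference)
    return pd.crosstab(pd.Series(lab, name="cluster"),
                       pd.Series(ref, name="reference"))


def top_genes(H_rna: np.ndarray, gene_ids, factor_index: int,
              n_top: int = 150) -> pd.DataFrame:
    """Genes ranked by descending loading in one factor's H_rna row; ties
    broken by gene identifier for determinism."""
    H_rna = np.asarray(H_rna, dtype=np.float64)
    k, n = H_rna.shape
    if not 0 <= factor_index < k:
        raise ValueError(f"factor_index {factor_index} out of range [0, {k})")
    gene_ids = np.asarray([str(g) for g in gene_ids])
    if len(gene_ids) != n:
        raise ValueError(f"{len(gene_ids)} gene ids for {n} loading columns")
    if n_top > n:
        warnings.warn(f"n_top={n_top} exceeds gene count {n}; truncating",
                      UserWarning, stacklevel=2)
        n_top = n
    row = H_rna[factor_index]
    order = np.lexsort((gene_ids, -row))[:n_top]
    return pd.DataFrame({"gene": gene_ids[order], "loading": row[order]})


def factor_correlation(W: np.ndarray, target) -> np.ndarray:
    """Pearson correlation of every factor (W column) with a per-spot target
    vector. Constant columns (or a constant target) give r = 0 with a
    warning instead of NaN."""
    W = np.asarray(W, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64).ravel()
    if W.shape[0] != target.shape[0]:
        raise ValueError(
            f"W has {W.shape[0]} spots but target has {target.shape[0]}"
        )
    tc = target - target.mean()
    t_ss = float(tc @ tc)
    Wc = W - W.mean(axis=0, keepdims=True)
    w_ss = np.sum(Wc * Wc, axis=0)
    out = np.zeros(W.shape[1])
    if t_ss <= 0:
        warnings.warn("target vector is constant; correlations set to 0",
                      UserWarning, stacklevel=2)
        return out
    ok = w_ss > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} constant factor column(s); their correlation "
            "is set to 0", UserWarning, stacklevel=2)
    out[ok] = (Wc[:, ok].T @ tc) / np.sqrt(w_ss[ok] * t_ss)
    return out


def signature_score(
    Y_rna,
    gene_set,
    n_background_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
    gene_ids=None,
) -> np.ndarray:
    """Per-spot gene-set score: mean expression of the set minus the mean of
    an expression-matched background.

    Genes are binned by their average expression across spots into
    ``n_background_bins`` equal-count bins; for each set gene, up to
    ``ctrl_size`` control genes are sampled (seeded) from its bin, and the
    score is mean(set) - mean(controls) per spot.
    """
    if isinstance(Y_rna, SpotExpression):
        values = Y_rna.values
        ids = np.asarray(Y_rna.gene_ids)
    else:
        values = np.asarray(Y_rna, dtype=np.float64)
        if gene_ids is None:
            raise ValueError("gene_ids required when Y_rna is a bare matrix")
        ids = np.asarray([str(g) for g in gene_ids])

    wanted = [str(g) for g in gene_set]
    id_pos = {g: i for i, g in enumerate(ids)}
    kept = [g for g in wanted if g in id_pos]
    dropped = [g for g in wanted if g not in id_pos]
    if dropped:
        warnings.warn(f"{len(dropped)} gene(s) not in the matrix, dropped: "
                      f"{dropped[:10]}", UserWarning, stacklevel=2)
    if not kept:
        raise ValueError("no genes of the set are present in the matrix")
    set_idx = np.asarray([id_pos[g] for g in kept])

    mean_expr = values.mean(axis=0)
    n_bins = min(n_background_bins, len(ids))
    # equal-count bins over the average-expression ranking
    ranks = pd.Series(mean_expr).rank(method="first").to_numpy()
    bins = np.ceil(ranks / (len(ids) / n_bins)).astype(int) - 1
    rng = np.random.default_rng(seed)
    ctrl_idx: list[int] = []
    for gi in set_idx:
        pool = np.flatnonzero(bins == bins[gi])
        take = min(ctrl_size, len(pool))
        ctrl_idx.extend(rng.choice(pool, size=take, replace=False))
    ctrl_idx = np.unique(ctrl_idx)
    return values[:, set_idx].mean(axis=1) - values[:, ctrl_idx].mean(axis=1)
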