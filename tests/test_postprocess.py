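import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest

from spotfactor import (
    cluster_factors,
    clustering_scores,
    contingency_table,
    factor_correlation,
    signature_score,
    top_genes,
)

# ---------------------------------------------------------------------------
# independent metric oracles (pair counting / entropy formulas)


def pair_counts(u, v):
    ss = sd = ds = dd = 0
    n = len(u)
    for i in range(n):
        for j in range(i + 1, n):
            su, sv = u[i] == u[j], v[i] == v[j]
            if su and sv:
                ss += 1
            elif su and not sv:
                sd += 1
            elif not su and sv:
                ds += 1
            else:
                dd += 1
    return ss, sd, ds, dd


def ari_oracle(u, v):
    ss, sd, ds, dd = pair_counts(u, v)
    denom = (ss + sd) * (sd + dd) + (ss + ds) * (ds + dd)
    if denom == 0:
        return 1.0
    return 2.0 * (ss * dd - sd * ds) / denom


def fm_oracle(u, v):
    ss, sd, ds, dd = pair_counts(u, v)
    denom = math.sqrt((ss + sd) * (ss + ds))
    return ss / denom if denom > 0 else 0.0


def ami_oracle(u, v):
    """AMI with arithmetic averaging, expected MI under the hypergeometric
    model, all from first principles."""
    n = len(u)
    ulabs, vlabs = sorted(set(u)), sorted(set(v))
    a = {x: sum(1 for t in u if t == x) for x in ulabs}
    b = {y: sum(1 for t in v if t == y) for y in vlabs}
    nij = {(x, y): sum(1 for t in range(n) if u[t] == x and v[t] == y)
           for x in ulabs for y in vlabs}
    mi = 0.0
    for (x, y), c in nij.items():
        if c > 0:
            mi += (c / n) * math.log(n * c / (a[x] * b[y]))
    hu = -sum((a[x] / n) * math.log(a[x] / n) for x in ulabs)
    hv = -sum((b[y] / n) * math.log(b[y] / n) for y in vlabs)
    emi = 0.0
    for x in ulabs:
        for y in vlabs:
            ai, bj = a[x], b[y]
            lo, hi = max(1, ai + bj - n), min(ai, bj)
            for c in range(lo, hi + 1):
                p = (math.comb(bj, c) * math.comb(n - bj, ai - c)
                     / math.comb(n, ai))
                emi += p * (c / n) * math.log(n * c / (ai * bj))
    denom = 0.5 * (hu + hv) - emi
    if abs(denom) < 1e-15:
        return 1.0
    return (mi - emi) / denom


def all_partitions(n):
    """All set partitions of range(n) as label vectors (restricted growth)."""
    def rec(prefix, maxlab):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for lab in range(maxlab + 2):
            yield from rec(prefix + [lab], max(maxlab, lab))
    yield from rec([0], 0)


class TestClusterFactors:
    def test_separable_blocks_kmeans(self):
        rng = np.random.default_rng(0)
        W = np.vstack([
            rng.normal([5, 0], 0.1, size=(20, 2)),
            rng.normal([0, 5], 0.1, size=(20, 2)),
        ])
        W = np.abs(W)
        truth = np.repeat([0, 1], 20)
        labels = cluster_factors(W, "kmeans", n_clusters=2, seed=0)
        assert clustering_scores(labels, truth)["ari"] == pytest.approx(1.0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        W = np.abs(rng.standard_normal((50, 4)))
        for method, kw in [("kmeans", {"n_clusters": 3}),
                           ("graph", {"resolution": 1.0})]:
            l1 = cluster_factors(W, method, seed=7, **kw)
            l2 = cluster_factors(W, method, seed=7, **kw)
            np.testing.assert_array_equal(l1, l2)

    def test_graph_mode_finds_separable_blocks(self):
        rng = np.random.default_rng(2)
        W = np.abs(np.vstack([
            rng.normal([6, 0, 0], 0.1, size=(25, 3)),
            rng.normal([0, 6, 0], 0.1, size=(25, 3)),
            rng.normal([0, 0, 6], 0.1, size=(25, 3)),
        ]))
        truth = np.repeat([0, 1, 2], 25)
        labels = cluster_factors(W, "graph", n_neighbors=10, resolution=0.5,
                                 seed=0)
        assert clustering_scores(labels, truth)["ari"] == pytest.approx(1.0)

    def test_resolution_sweep_nondecreasing_cluster_count(self):
        rng = np.random.default_rng(3)
        W = np.abs(rng.standard_normal((80, 5)))
        counts = [
            len(np.unique(cluster_factors(W, "graph", n_neighbors=10,
                                          resolution=r, seed=0)))
            for r in (0.1, 0.5, 1.0, 2.0, 4.0)
        ]
        assert all(c2 >= c1 for c1, c2 in zip(counts, counts[1:]))

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            cluster_factors(np.ones((5, 2)), "kmeans", n_clusters=6)


class TestClusteringScores:
    def test_identical_partitions_are_perfect(self):
        labels = [0, 0, 1, 1, 2, 2]
        s = clustering_scores(labels, labels)
        assert s["ari"] == s["ami"] == s["fowlkes_mallows"] == pytest.approx(1.0)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 3, size=30)
        ref = rng.integers(0, 4, size=30)
        renamed = np.array([9, 4, 7])[labels]
        s1 = clustering_scores(labels, ref)
        s2 = clustering_scores(renamed, ref)
        for key in ("ari", "ami", "fowlkes_mallows"):
            assert s1[key] == pytest.approx(s2[key])

    def test_contingency_worked_example_matches_pair_counting(self):
        # contingency [[10, 0], [0, 5], [2, 3]]
        labels = [0] * 10 + [1] * 5 + [2] * 5
        ref = [0] * 10 + [1] * 5 + [0] * 2 + [1] * 3
        s = clustering_scores(labels, ref)
        assert s["ari"] == pytest.approx(ari_oracle(labels, ref))
        assert s["fowlkes_mallows"] == pytest.approx(fm_oracle(labels, ref))
        assert s["ami"] == pytest.approx(ami_oracle(labels, ref))

    def test_exhaustive_small_partitions_match_oracles(self):
        ref = (0, 0, 1, 1, 2)
        for labels in all_partitions(5):
            s = clustering_scores(list(labels), list(ref))
            assert s["ari"] == pytest.approx(ari_oracle(labels, ref), abs=1e-10)
            assert s["fowlkes_mallows"] == pytest.approx(
                fm_oracle(labels, ref), abs=1e-10)
            assert s["ami"] == pytest.approx(ami_oracle(labels, ref), abs=1e-8)

    def test_missing_reference_dropped_and_reported(self):
        labels = [0, 0, 1, 1]
        ref = np.array(["a", "a", None, "b"], dtype=object)
        s = clustering_scores(labels, ref)
        assert s["n_dropped"] == 1
        assert s["n_spots"] == 3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            clustering_scores([0, 1], [0, 1, 2])


class TestContingencyTable:
    def test_identical_partitions_diagonal(self):
        labels = [0, 0, 1, 2, 2, 2]
        tab = contingency_table(labels, labels)
        assert (np.diag(tab.values) == [2, 1, 3]).all()
        assert tab.values.sum() == 6
        assert np.count_nonzero(tab.values) == 3

    def test_row_col_sums_match_counts(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 3, size=40)
        ref = rng.integers(0, 2, size=40)
        tab = contingency_table(labels, ref)
        for c in np.unique(labels):
            assert tab.loc[c].sum() == (labels == c).sum()
        for r in np.unique(ref):
            assert tab[r].sum() == (ref == r).sum()


class TestTopGenes:
    def test_one_hot_row(self):
        H = np.zeros((2, 5))
        H[0, 3] = 1.0
        out = top_genes(H, [f"g{i}" for i in range(5)], 0, n_top=1)
        assert out["gene"].tolist() == ["g3"]

    def test_full_ranking_is_permutation(self):
        rng = np.random.default_rng(6)
        H = np.abs(rng.standard_normal((3, 8)))
        genes = [f"g{i}" for i in range(8)]
        out = top_genes(H, genes, 1, n_top=8)
        assert sorted(out["gene"]) == sorted(genes)

    def test_matches_sort_oracle_with_tie_break(self):
        H = np.array([[3.0, 1.0, 3.0, 2.0]])
        out = top_genes(H, ["gb", "gc", "ga", "gd"], 0, n_top=4)
        # descending loading; ties (3.0) broken alphabetically: ga before gb
        assert out["gene"].tolist() == ["ga", "gb", "gd", "gc"]

    def test_truncation_warns(self):
        with pytest.warns(UserWarning, match="truncat"):
            out = top_genes(np.ones((1, 3)), ["a", "b", "c"], 0, n_top=10)
        assert len(out) == 3

    def test_bad_factor_index(self):
        with pytest.raises(ValueError, match="factor_index"):
            top_genes(np.ones((2, 3)), ["a", "b", "c"], 5)


class TestFactorCorrelation:
    def test_self_column_is_one(self):
        rng = np.random.default_rng(7)
        W = np.abs(rng.standard_normal((20, 3)))
        r = factor_correlation(W, W[:, 1])
        assert r[1] == pytest.approx(1.0)

    def test_negated_column_is_minus_one(self):
        rng = np.random.default_rng(8)
        W = np.abs(rng.standard_normal((20, 2)))
        r = factor_correlation(W, -W[:, 0])
        assert r[0] == pytest.approx(-1.0)

    def test_small_worked_vectors_match_formula(self):
        W = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        t = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        # direct covariance formula
        wc, tc = W[:, 0] - W[:, 0].mean(), t - t.mean()
        expected = (wc @ tc) / np.sqrt((wc @ wc) * (tc @ tc))
        assert factor_correlation(W, t)[0] == pytest.approx(expected)

    def test_constant_column_gives_zero_with_warning(self):
        W = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.warns(UserWarning, match="constant factor"):
            r = factor_correlation(W, np.arange(10.0))
        assert r[0] == 0.0
        assert r[1] == pytest.approx(1.0)

    def test_constant_target_gives_zeros(self):
        with pytest.warns(UserWarning, match="constant"):
            r = factor_correlation(np.random.default_rng(0).random((5, 2)),
                                   np.ones(5))
        np.testing.assert_array_equal(r, 0.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="spots"):
            factor_correlation(np.ones((4, 2)), np.ones(5))


class TestSignatureScore:
    @pytest.fixture()
    def matrix(self):
        rng = np.random.default_rng(9)
        values = np.abs(rng.standard_normal((30, 40)))
        genes = [f"g{i:02d}" for i in range(40)]
        return values, genes

    def test_all_genes_scores_near_zero(self, matrix):
        values, genes = matrix
        score = signature_score(values, genes, gene_ids=genes,
                                n_background_bins=1, ctrl_size=40, seed=0)
        np.testing.assert_allclose(score, 0.0, atol=1e-12)

    def test_zero_gene_set_scores_nonpositive(self, matrix):
        values, genes = matrix
        values = values.copy()
        values[:, :3] = 0.0
        score = signature_score(values, genes[:3], gene_ids=genes,
                                n_background_bins=1, ctrl_size=40, seed=0)
        assert (score <= 1e-12).all()

    def test_matches_mean_minus_background_oracle(self, matrix):
        """With one bin and ctrl_size >= n_genes the background is every
        gene, making the score a deterministic closed form."""
        values, genes = matrix
        gene_set = ["g05", "g17", "g33"]
        score = signature_score(values, gene_set, gene_ids=genes,
                                n_background_bins=1, ctrl_size=100, seed=0)
        idx = [5, 17, 33]
        expected = values[:, idx].mean(axis=1) - values.mean(axis=1)
        np.testing.assert_allclose(score, expected, atol=1e-12)

    def test_reproducible_given_seed(self, matrix):
        values, genes = matrix
        s1 = signature_score(values, genes[:5], gene_ids=genes, seed=3,
                             n_background_bins=5, ctrl_size=3)
        s2 = signature_score(values, genes[:5], gene_ids=genes, seed=3,
                             n_background_bins=5, ctrl_size=3)
        np.testing.assert_array_equal(s1, s2)

    def test_missing_genes_warn_empty_set_errors(self, matrix):
        values, genes = matrix
        with pytest.warns(UserWarning, match="dropped"):
            signature_score(values, ["g00", "nope"], gene_ids=genes, seed=0)
        with pytest.raises(ValueError, match="no genes"):
            signature_score(values, ["nope"], gene_ids=genes, seed=0)
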