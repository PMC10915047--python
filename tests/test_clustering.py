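import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import spiderpref as sp
from spiderpref.clustering import (
    bic_for_partition,
    centroid_linkage,
    cut_tree,
    criterion_columns,
    select_clusters,
    standardize,
)


def naive_centroid_merges(points):
    """O(n^3) agglomeration oracle: merge the closest centroid pair each step."""
    clusters = {i: [i] for i in range(len(points))}
    centroids = {i: np.asarray(points[i], dtype=float) for i in range(len(points))}
    next_id = len(points)
    heights = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                d = float(np.linalg.norm(centroids[a] - centroids[b]))
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        members = clusters.pop(a) + clusters.pop(b)
        clusters[next_id] = members
        centroids[next_id] = np.mean([points[i] for i in members], axis=0)
        del centroids[a], centroids[b]
        heights.append(d)
        next_id += 1
    return heights


class TestStandardize:
    def test_closed_form_column(self):
        z = standardize(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(z.ravel(), [-1, 0, 1])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 4))
        z = standardize(x)
        assert np.allclose(standardize(z), z, atol=1e-12)

    def test_moments_on_random_input(self):
        rng = np.random.default_rng(1)
        z = standardize(rng.normal(3, 7, size=(50, 3)))
        assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_zero_variance_column_named(self):
        df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            standardize(df)


class TestCentroidLinkage:
    def test_two_points_merge_at_their_distance(self):
        link = centroid_linkage(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert link.shape == (1, 4)
        assert link[0, 2] == pytest.approx(5.0)

    def test_three_collinear_points_centroid_geometry(self):
        link = centroid_linkage(np.array([[0.0], [1.0], [10.0]]))
        assert set(link[0, :2].astype(int)) == {0, 1}
        assert link[0, 2] == pytest.approx(1.0)
        assert link[1, 2] == pytest.approx(9.5)  # |10 - 0.5|

    def test_merge_heights_match_naive_oracle(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(50, 2))
        link = centroid_linkage(pts)
        assert np.allclose(sorted(link[:, 2]),
                           sorted(naive_centroid_merges(pts)), atol=1e-8)

    def test_row_order_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(23)
        pts = rng.normal(size=(30, 2))
        perm = rng.permutation(30)
        la = cut_tree(centroid_linkage(pts), 3)
        lb = cut_tree(centroid_linkage(pts[perm]), 3)[np.argsort(perm)]
        # same partition up to label names
        pairs_a = la[:, None] == la[None, :]
        pairs_b = lb[:, None] == lb[None, :]
        assert np.array_equal(pairs_a, pairs_b)


class TestCutTree:
    def test_extreme_cuts(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(12, 2))
        link = centroid_linkage(pts)
        assert len(np.unique(cut_tree(link, 12))) == 12
        assert len(np.unique(cut_tree(link, 1))) == 1

    def test_two_separated_blobs_split_exactly(self):
        rng = np.random.default_rng(4)
        a = rng.normal([-5, 0], 0.3, size=(15, 2))
        b = rng.normal([5, 0], 0.3, size=(15, 2))
        labels = cut_tree(centroid_linkage(np.vstack([a, b])), 2)
        assert len(set(labels[:15])) == 1
        assert len(set(labels[15:])) == 1
        assert labels[0] != labels[15]


class TestBic:
    def test_single_cluster_matches_density_oracle(self):
        rng = np.random.default_rng(9)
        z = rng.standard_normal((100, 1))
        labels = np.zeros(100, dtype=int)
        mu, var = z.mean(), z.var()
        oracle = -2 * norm.logpdf(z, mu, np.sqrt(var)).sum() + 2 * np.log(100)
        assert bic_for_partition(z, labels) == pytest.approx(oracle, abs=1e-8)

    def test_loglik_doubles_when_rows_duplicated(self):
        rng = np.random.default_rng(10)
        z = rng.standard_normal((40, 2))
        labels = (z[:, 0] > 0).astype(int)
        n, d = 40, 2

        def loglik_from_bic(bic, n, k):
            m = (k - 1) + k * d + d
            return -(bic - m * np.log(n)) / 2

        b1 = bic_for_partition(z, labels)
        z2 = np.vstack([z, z])
        b2 = bic_for_partition(z2, np.r_[labels, labels])
        assert loglik_from_bic(b2, 2 * n, 2) == pytest.approx(
            2 * loglik_from_bic(b1, n, 2), rel=1e-9)

    def test_singleton_cluster_finite_with_floor_warning(self):
        z = np.array([[0.0], [0.1], [0.2], [5.0]])
        labels = np.array([0, 0, 0, 1])
        with pytest.warns(UserWarning, match="floor"):
            bic = bic_for_partition(z, labels, covariance="diagonal")
        assert np.isfinite(bic)

    def test_empty_cluster_rejected(self):
        z = np.zeros((4, 1))
        with pytest.raises(ValueError, match="align"):
            bic_for_partition(z, np.array([0, 0, 1]))

    def test_unknown_covariance_rejected(self):
        with pytest.raises(ValueError, match="covariance"):
            bic_for_partition(np.zeros((4, 1)), np.zeros(4, dtype=int),
                              covariance="full")


class TestSelectClusters:
    def test_two_blob_structure_selected(self):
        rng = np.random.default_rng(6)
        pts = np.concatenate([rng.normal(-3, 0.5, 20),
                              rng.normal(3, 0.5, 20)])[:, None]
        res = select_clusters(pts)
        assert res.selected_k == 2
        assert res.bic[2] <= min(res.bic.values())
        assert len(np.unique(res.labels)) == 2

    def test_labels_invariant_under_row_permutation(self):
        rng = np.random.default_rng(7)
        pts = np.concatenate([rng.normal(-3, 0.5, 20),
                              rng.normal(3, 0.5, 20)])[:, None]
        perm = rng.permutation(40)
        a = select_clusters(pts).labels
        b = select_clusters(pts[perm]).labels[np.argsort(perm)]
        assert np.array_equal(a[:, None] == a[None, :], b[:, None] == b[None, :])

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            select_clusters(np.random.default_rng(0).normal(size=(5, 2)))

    def test_polarized_cohort_partition_recovered(self):
        """Two groups at opposite body/leg extremes are recovered (Rand >= 0.9)."""
        from spiderpref.synthetic import (
            REFERENCE_CONDITION_MEANS,
            ClusterGroup,
            GeneratorConfig,
        )

        off = {("bodyleg", "dangerous"): -0.25}
        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            cfg = GeneratorConfig(
                condition_means=dict(REFERENCE_CONDITION_MEANS),
                cluster_spec=(ClusterGroup(0.5, off),
                              ClusterGroup(0.5, {k: -v for k, v in off.items()})),
                seed=seed).validated()
            cohort = sp.generate_cohort(cfg)
            m = sp.summary_matrix(cohort, "mean")
            res = select_clusters(m[["bodyleg_dangerous"]])
            truth = (m["bodyleg_dangerous"]
                     > m["bodyleg_dangerous"].mean()).to_numpy().astype(int)
            same_truth = truth[:, None] == truth[None, :]
            same_got = res.labels[:, None] == res.labels[None, :]
            iu = np.triu_indices(len(truth), k=1)
            rand = (same_truth == same_got)[iu].mean()
            hits += rand >= 0.9
        assert hits >= 0.9 * n_rep


def test_criterion_presets_resolve():
    assert criterion_columns("single:hairiness:dangerous") == ["hairiness_dangerous"]
    assert len(criterion_columns("all-features")) == 6
    assert criterion_columns("dangerous") == [
        "hairiness_dangerous", "bodyleg_dangerous", "locomotion_dangerous"]
    assert criterion_columns("all-plus-spq")[0] == "spq"
    with pytest.raises(ValueError):
        criterion_columns("single:hairiness")
    with pytest.raises(ValueError):
        criterion_columns("everything")
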