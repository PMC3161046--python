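import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import pdist

from somatlas.downstream import (
    cluster_size_fraction,
    f_score,
    hierarchical_cluster,
    ic_variance_fraction,
    ica_project,
    pcm,
    to_newick,
)
from somatlas.errors import ValidationError
from somatlas.io_formats import SampleAnnotation
from somatlas.som_core import metagene_matrix


def naive_upgma_cophenetic(points):
    """Independent average-linkage oracle returning cophenetic distances."""
    n = len(points)
    clusters = {i: [i] for i in range(n)}
    dist = {(i, j): float(np.linalg.norm(points[i] - points[j]))
            for i in range(n) for j in range(i + 1, n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        (a, b), d = min(dist.items(), key=lambda kv: kv[1])
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        merged = clusters.pop(a) + clusters.pop(b)
        new_dists = {}
        for c, members in clusters.items():
            pairs = [float(np.linalg.norm(points[i] - points[j]))
                     for i in merged for j in members]
            new_dists[tuple(sorted((next_id, c)))] = float(np.mean(pairs))
        dist = {k: v for k, v in dist.items()
                if a not in k and b not in k}
        dist.update(new_dists)
        clusters[next_id] = merged
        next_id += 1
    return coph


class TestHierarchicalCluster:
    def test_identical_samples_merge_at_zero(self):
        values = np.array([[1.0, 1.0, 5.0], [2.0, 2.0, 7.0]])
        result = hierarchical_cluster(values, axis="samples")
        assert result.sample_linkage[0, 2] == 0.0
        assert set(result.sample_linkage[0, :2].astype(int)) == {0, 1}

    def test_close_pair_merges_first(self):
        # three samples at mutual distances 1, 1, 10 -> (0,1) merge first
        values = np.array([[0.0, 1.0, 10.0]])
        values = np.vstack([values, np.zeros((1, 3))])
        result = hierarchical_cluster(values, axis="samples")
        assert set(result.sample_linkage[0, :2].astype(int)) == {0, 1}

    def test_cophenetic_oracle(self):
        rng = np.random.default_rng(3)
        points = rng.normal(size=(10, 4))
        result = hierarchical_cluster(points.T, axis="samples", linkage="average")
        got = cophenet(result.sample_linkage)
        expected = naive_upgma_cophenetic(points)
        np.testing.assert_allclose(
            got, expected[np.triu_indices(10, k=1)], rtol=1e-9
        )

    def test_two_way_returns_both_orders(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(8, 5))
        result = hierarchical_cluster(values, axis="both")
        assert sorted(result.sample_order) == list(range(5))
        assert sorted(result.gene_order) == list(range(8))

    def test_single_item_axis_rejected(self):
        with pytest.raises(ValidationError):
            hierarchical_cluster(np.zeros((1, 5)), axis="genes")

    def test_newick_round_trip_leaf_set(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(6, 4))
        result = hierarchical_cluster(values, axis="samples")
        labels = [f"s{j}" for j in range(4)]
        newick = to_newick(result.sample_linkage, labels)
        assert newick.endswith(";")
        for label in labels:
            assert label in newick


class TestPCM:
    def test_unit_diagonal_and_symmetry(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(50, 6))
        result = pcm(values, [f"s{j}" for j in range(6)])
        np.testing.assert_allclose(np.diag(result.corr), 1.0)
        np.testing.assert_allclose(result.corr, result.corr.T)
        assert np.nanmax(np.abs(result.corr)) <= 1.0 + 1e-12

    def test_anticorrelated_profiles(self):
        p = np.random.default_rng(1).normal(size=50)
        values = np.column_stack([p, -p])
        result = pcm(values, ["a", "b"])
        assert result.corr[0, 1] == pytest.approx(-1.0)

    def test_zero_variance_sample_is_na(self):
        values = np.column_stack([np.ones(10), np.arange(10.0), np.arange(10.0) ** 2])
        with pytest.warns(UserWarning, match="zero-variance"):
            result = pcm(values, ["flat", "b", "c"])
        assert np.isnan(result.corr[0, 1]) and np.isnan(result.corr[0, 0])
        assert np.isfinite(result.corr[1, 2])

    def test_metagene_intra_category_beats_single_gene(
        self, trained_som, centered_fixture
    ):
        centered, _, annotation = centered_fixture
        meta = metagene_matrix(trained_som)
        gene_pcm = pcm(centered.values, centered.sample_ids, annotation)
        meta_pcm = pcm(meta, centered.sample_ids, annotation)
        assert np.median(meta_pcm.intra) > np.median(gene_pcm.intra)


class TestICA:
    def test_separated_clusters_recovered(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.1, size=(10, 30)) + np.array([[5.0]] * 10)
        b = rng.normal(0, 0.1, size=(10, 30))
        values = np.hstack([a, b])  # 10 features x 60 samples
        coords = ica_project(values, 2, seed=0)
        from sklearn.metrics import silhouette_score
        labels = [0] * 30 + [1] * 30
        # the two clusters separate along one component
        per_component = [
            silhouette_score(coords[:, [j]], labels) for j in range(2)
        ]
        assert max(per_component) > 0.8

    def test_unmixing_oracle(self):
        rng = np.random.default_rng(6)
        sources = rng.uniform(-1, 1, size=(2, 500))
        mixing = rng.normal(size=(2, 2))
        mixed = mixing @ sources  # 2 features x 500 'samples'
        coords = ica_project(mixed, 2, seed=1)
        corr = np.corrcoef(np.vstack([coords.T, sources]))[:2, 2:]
        best = np.abs(corr).max(axis=1)
        assert (best > 0.95).all()

    def test_seed_determinism(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(20, 15))
        a = ica_project(values, 2, seed=3)
        b = ica_project(values, 2, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_rank_deficient_rejected(self):
        values = np.outer(np.arange(10.0), np.ones(8))
        with pytest.raises(ValidationError):
            ica_project(values, 2, seed=0)


class TestFScore:
    def test_tight_separated_clusters_large(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 0.05, size=(5, 10))
        b = rng.normal(0, 0.05, size=(5, 10)) + 10.0
        values = np.hstack([a, b])
        labels = ["a"] * 10 + ["b"] * 10
        assert f_score(values, labels) > 1.0

    def test_permutation_null_near_one(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(50, 20))
        labels = ["a"] * 10 + ["b"] * 10
        scores = [
            f_score(values, list(rng.permutation(labels)))
            for _ in range(100)
        ]
        assert np.mean(scores) == pytest.approx(1.0, abs=0.1)

    def test_scale_invariance(self):
        rng = np.random.default_rng(10)
        values = rng.normal(size=(30, 12))
        labels = (["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        assert f_score(values * 7.3, labels) == pytest.approx(
            f_score(values, labels), rel=1e-9
        )

    def test_small_category_rejected(self):
        with pytest.raises(ValidationError):
            f_score(np.zeros((5, 3)), ["a", "a", "b"])


class TestICVarianceFraction:
    def test_union_is_hundred_percent(self):
        rng = np.random.default_rng(11)
        coords = rng.normal(size=(12, 2))
        labels = ["a"] * 12
        assert ic_variance_fraction(coords, labels, "a", ["a"]) == pytest.approx(100.0)

    def test_collapsed_category_zero(self):
        coords = np.vstack([np.zeros((4, 2)), np.random.default_rng(0).normal(size=(8, 2))])
        labels = ["point"] * 4 + ["cloud"] * 8
        assert ic_variance_fraction(coords, labels, "point", ["point", "cloud"]) \
            == pytest.approx(0.0)

    def test_three_equal_variance_categories(self):
        rng = np.random.default_rng(12)
        coords = rng.normal(size=(300, 2))
        labels = ["a"] * 100 + ["b"] * 100 + ["c"] * 100
        fractions = [
            ic_variance_fraction(coords, labels, cat, ["a", "b", "c"])
            for cat in "abc"
        ]
        for fraction in fractions:
            assert fraction == pytest.approx(100 / 3, abs=12.0)


class TestClusterSizeFraction:
    def test_pure_case_hundred_percent(self):
        values = np.zeros((10, 6))
        values[:, :3] = 5.0  # all features overexpressed in category 'a'
        clusters = np.zeros(10, dtype=int)
        labels = ["a"] * 3 + ["b"] * 3
        assert cluster_size_fraction(values, clusters, labels, "a") == 100.0

    def test_fractions_bounded_by_partition(self):
        rng = np.random.default_rng(13)
        values = rng.normal(size=(40, 9))
        clusters = rng.integers(0, 4, size=40)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        total = sum(
            cluster_size_fraction(values, clusters, labels, cat) for cat in "abc"
        )
        assert total <= 100.0 + 1e-9

    def test_planted_three_modules_within_ten_percent(self):
        rng = np.random.default_rng(14)
        shares = [0.5, 0.3, 0.2]
        n = 200
        values = rng.normal(0, 0.2, size=(n, 9))
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        clusters = np.zeros(n, dtype=int)
        bounds = np.cumsum([0] + [int(s * n) for s in shares])
        for ci, cat_cols in enumerate([(0, 3), (3, 6), (6, 9)]):
            rows = slice(bounds[ci], bounds[ci + 1])
            values[rows, cat_cols[0]:cat_cols[1]] += 2.0
            clusters[rows] = ci
        for ci, cat in enumerate("abc"):
            fraction = cluster_size_fraction(values, clusters, labels, cat)
            assert fraction == pytest.approx(shares[ci] * 100, abs=10.0)
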