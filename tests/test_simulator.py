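import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from heartclones.geometry import make_half_heart_slab
from heartclones.simulator import (
    SimulationConfig,
    merge_into_clusters,
    place_clone_centroids,
    regions_to_frame,
    sample_clone_count,
    simulate_region,
    simulate_regions,
)


def brute_force_partition(points, threshold):
    """Independent single-linkage oracle: full pairwise adjacency plus
    transitive closure via networkx connected components."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(points)))
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            if np.linalg.norm(points[i] - points[j]) < threshold:
                g.add_edge(i, j)
    return {frozenset(c) for c in nx.connected_components(g)}


def labels_to_partition(labels):
    return {
        frozenset(np.flatnonzero(labels == c))
        for c in np.unique(labels)
    }


class TestSampleCloneCount:
    def test_rate_zero_is_degenerate_at_zero(self):
        rng = np.random.default_rng(0)
        assert all(sample_clone_count(0.0, rng) == 0 for _ in range(50))

    def test_poisson_moments(self):
        rng = np.random.default_rng(1)
        draws = np.array([sample_clone_count(3.0, rng) for _ in range(100_000)])
        se_mean = np.sqrt(3.0 / len(draws))
        assert abs(draws.mean() - 3.0) < 3 * se_mean
        assert abs(draws.var() - 3.0) < 0.1  # Poisson: variance = mean

    def test_rejects_negative_rate(self):
        with pytest.raises(ValueError):
            sample_clone_count(-1.0, np.random.default_rng(0))


class TestPlacement:
    def test_zero_clones_gives_empty_array(self, default_geometry):
        pts = place_clone_centroids(0, default_geometry, np.random.default_rng(0))
        assert pts.shape == (0, 3)

    def test_all_points_inside_slab(self, default_geometry):
        pts = place_clone_centroids(
            10_000, default_geometry, np.random.default_rng(2)
        )
        hi = [default_geometry.slab_side] * 2 + [default_geometry.slab_depth]
        assert np.all(pts >= 0) and np.all(pts <= hi)

    def test_uniform_coordinate_means(self, default_geometry):
        n = 100_000
        pts = place_clone_centroids(n, default_geometry, np.random.default_rng(3))
        extents = np.array(
            [default_geometry.slab_side] * 2 + [default_geometry.slab_depth]
        )
        se = extents / np.sqrt(12 * n)  # SE of a uniform's sample mean
        assert np.all(np.abs(pts.mean(axis=0) - extents / 2) < 3 * se)


class TestMergeIntoClusters:
    def test_pair_within_surface_threshold_merges(self):
        # gap between 54 µm spheres at centroid distance 100 is negative,
        # i.e. they overlap, so well under the 50 µm cutoff
        pts = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        labels = merge_into_clusters(pts, 54.0, 50.0, "surface")
        assert labels.tolist() == [0, 0]

    def test_boundary_tie_is_not_merged(self):
        pts = np.array([[0.0, 0, 0], [158.0, 0, 0]])  # exactly 2*54 + 50
        labels = merge_into_clusters(pts, 54.0, 50.0, "surface")
        assert len(set(labels)) == 2

    def test_transitive_chain_forms_one_cluster(self):
        # A-B and B-C below threshold, A-C above: single-linkage chains
        pts = np.array([[0.0, 0, 0], [150.0, 0, 0], [300.0, 0, 0]])
        labels = merge_into_clusters(pts, 54.0, 50.0, "surface")
        assert len(set(labels)) == 1

    def test_centroid_metric_uses_raw_distance(self):
        pts = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        labels = merge_into_clusters(pts, 54.0, 50.0, "centroid")
        assert len(set(labels)) == 2  # 100 >= 50: distinct under centroid rule

    def test_empty_input(self):
        assert len(merge_into_clusters(np.zeros((0, 3)), 54, 50)) == 0

    def test_matches_brute_force_oracle(self, default_geometry):
        rng = np.random.default_rng(42)
        for _ in range(50):
            k = int(rng.integers(1, 13))
            pts = place_clone_centroids(k, default_geometry, rng)
            labels = merge_into_clusters(pts, 54.0, 50.0, "surface")
            assert labels_to_partition(labels) == brute_force_partition(
                pts, 2 * 54.0 + 50.0
            )

    @given(st.integers(0, 2**32 - 1), st.integers(1, 15))
    @settings(max_examples=30, deadline=None)
    def test_labels_form_valid_partition(self, seed, k):
        geometry = make_half_heart_slab()
        pts = place_clone_centroids(k, geometry, np.random.default_rng(seed))
        labels = merge_into_clusters(pts, 54.0, 50.0)
        sizes = np.bincount(labels)
        assert len(labels) == k
        assert sizes.sum() == k and np.all(sizes >= 1)
        # labels are consecutive integers in order of first appearance
        first_seen = [labels[np.flatnonzero(labels == c)[0]]
                      for c in range(labels.max() + 1)]
        assert first_seen == sorted(first_seen)


class TestSimulateRegion:
    def test_conditioning_guarantees_at_least_one_clone(self, small_config):
        rng = np.random.default_rng(7)
        low = small_config.with_rate(0.3)
        assert all(
            simulate_region(low, rng).n_clones >= 1 for _ in range(500)
        )

    def test_zero_disc_centroid_metric_keeps_singletons(self, default_geometry):
        config = SimulationConfig(
            geometry=default_geometry, rate_m=5.0, disc_dist=0.0,
            merge_metric="centroid", seed=3,
        )
        rng = np.random.default_rng(3)
        for _ in range(200):
            r = simulate_region(config, rng)
            assert r.n_clusters == r.n_clones

    def test_conditioning_unsatisfiable_at_rate_zero(self, default_geometry):
        config = SimulationConfig(geometry=default_geometry, rate_m=0.0)
        with pytest.raises(RuntimeError):
            simulate_region(config, np.random.default_rng(0))

    def test_tiny_rate_gives_mostly_single_clones(self, default_geometry):
        # zero-truncated Poisson: P(X=1 | X>=1) ~ 0.995 at m=0.01
        config = SimulationConfig(geometry=default_geometry, rate_m=0.01)
        rng = np.random.default_rng(9)
        ones = sum(
            simulate_region(config, rng).n_clones == 1 for _ in range(10_000)
        )
        assert ones / 10_000 >= 0.99

    def test_conditioned_counts_fit_zero_truncated_poisson(self, default_geometry):
        m = 2.0
        config = SimulationConfig(geometry=default_geometry, rate_m=m, seed=13)
        rng = np.random.default_rng(13)
        counts = np.array(
            [simulate_region(config, rng).n_clones for _ in range(50_000)]
        )
        kmax = 12
        observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)[1:]
        pmf = stats.poisson.pmf(np.arange(1, kmax), m) / (1 - np.exp(-m))
        expected = np.append(pmf, 1.0 - pmf.sum()) * len(counts)
        result = stats.chisquare(observed, expected)
        assert result.pvalue > 1e-3

    def test_mean_clusters_non_increasing_in_disc_dist(self, default_geometry):
        # common seed => identical clone configurations, so a larger
        # cutoff can only merge more: exact pointwise monotonicity
        means = []
        for disc in [0.0, 25.0, 50.0, 100.0]:
            config = SimulationConfig(
                geometry=default_geometry, rate_m=4.0, disc_dist=disc, seed=17
            )
            counts = [r.n_clusters for r in simulate_regions(config, n=2000)]
            means.append(np.mean(counts))
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_fixed_seed_reproduces_regions_byte_for_byte(self, small_config):
        frame_a = regions_to_frame(list(simulate_regions(small_config, n=200)))
        frame_b = regions_to_frame(list(simulate_regions(small_config, n=200)))
        assert frame_a.to_csv(index=False) == frame_b.to_csv(index=False)


def test_config_validation(default_geometry):
    with pytest.raises(ValueError):
        SimulationConfig(geometry=default_geometry, rate_m=-1.0)
    with pytest.raises(ValueError):
        SimulationConfig(geometry=default_geometry, clone_radius=-1.0)
    with pytest.raises(ValueError):
        SimulationConfig(geometry=default_geometry, n_sims=0)
    with pytest.raises(ValueError):
        SimulationConfig(geometry=default_geometry, merge_metric="midpoint")


def test_merge_threshold_by_metric(default_geometry):
    surface = SimulationConfig(geometry=default_geometry)
    centroid = SimulationConfig(geometry=default_geometry,
                                merge_metric="centroid")
    assert surface.merge_threshold == 2 * 54.0 + 50.0
    assert centroid.merge_threshold == 50.0
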