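import numpy as np
import pytest

from stratatrend.spatial import (DisconnectedGraphError,
                                 build_proximity_matrix, car_logdet,
                                 car_precision, greedy_coloring,
                                 min_connecting_threshold, read_centroids,
                                 sample_car, write_centroids)

from conftest import random_connected_graph


def brute_force_W(centroids, threshold):
    """Independent O(m^2) double-loop oracle for the proximity matrix."""
    cent = np.asarray(centroids, float)
    m = len(cent)
    W = np.zeros((m, m))
    for j in range(m):
        for k in range(m):
            dx, dy = cent[j] - cent[k]
            if j != k and np.sqrt(dx**2 + dy**2) <= threshold:
                W[j, k] = 1.0
    return W


class TestProximityMatrix:
    def test_two_distant_strata_are_isolated(self):
        with pytest.warns(UserWarning, match="no neighbours"):
            g = build_proximity_matrix([(0, 0), (10, 0)], threshold=7.75)
        assert g.W.tolist() == [[0, 0], [0, 0]]
        assert g.isolated == ("s1", "s2")
        assert not g.is_connected_enough
        with pytest.raises(DisconnectedGraphError):
            g.require_connected()

    def test_collinear_band_structure(self, path3_graph):
        assert path3_graph.W.tolist() == [[0, 1, 0], [1, 0, 1], [0, 1, 0]]
        assert np.diag(path3_graph.D).tolist() == [1, 2, 1]
        assert path3_graph.D[np.triu_indices(3, 1)].sum() == 0

    def test_threshold_tie_counts_as_neighbour(self):
        g = build_proximity_matrix([(0, 0), (2, 0)], threshold=2.0)
        assert g.W[0, 1] == 1

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_proximity_matrix([(0, 0), (1, 0)], 2.0,
                                   stratum_ids=["a", "a"])

    def test_coincident_centroids_warn_but_connect(self):
        with pytest.warns(UserWarning, match="coincident"):
            g = build_proximity_matrix([(0, 0), (0, 0), (1, 0)], 1.5)
        assert g.W[0, 1] == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_layouts(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(5, 30))
        cent = rng.uniform(0, 15, size=(m, 2))
        thr = min_connecting_threshold(cent)
        g = build_proximity_matrix(cent, thr)
        np.testing.assert_array_equal(g.W, brute_force_W(cent, thr))
        assert g.W.sum(axis=1).min() >= 1
        np.testing.assert_array_equal(np.diag(g.D), g.W.sum(axis=1))
        assert (g.W == g.W.T).all()


class TestMinConnectingThreshold:
    def test_line_example(self):
        cent = [(0, 0), (1, 0), (5, 0)]
        assert min_connecting_threshold(cent) == 4.0

    def test_coincident_pair_plus_distant(self):
        cent = [(0, 0), (0, 0), (3, 4)]
        assert min_connecting_threshold(cent) == 5.0

    def test_needs_two_strata(self):
        with pytest.raises(ValueError):
            min_connecting_threshold([(0, 0)])

    @pytest.mark.parametrize("seed", range(5))
    def test_is_the_connectivity_boundary(self, seed):
        rng = np.random.default_rng(100 + seed)
        cent = rng.uniform(0, 10, size=(12, 2))
        d_star = min_connecting_threshold(cent)
        at = build_proximity_matrix(cent, d_star)
        assert at.W.sum(axis=1).min() >= 1
        with pytest.warns(UserWarning):
            below = build_proximity_matrix(cent, d_star * (1 - 1e-9))
        assert below.W.sum(axis=1).min() == 0

    def test_monotone_under_stratum_addition(self, rng):
        cent = rng.uniform(0, 10, size=(10, 2))
        d_before = min_connecting_threshold(cent)
        # nearest-neighbour distances of retained strata can only shrink
        far = np.vstack([cent, [[50.0, 50.0]]])
        assert min_connecting_threshold(far) >= d_before
        near = np.vstack([cent, cent[:1] + 0.01])
        assert min_connecting_threshold(near) <= d_before


class TestCarPrecision:
    def test_lam_zero_is_scaled_row_sums(self, path3_graph):
        Q = car_precision(path3_graph, tau=2.0, lam=0.0)
        np.testing.assert_array_equal(Q, 2.0 * path3_graph.D)

    def test_path_graph_example(self, path3_graph):
        Q = car_precision(path3_graph, tau=1.0, lam=0.5)
        expected = [[1, -0.5, 0], [-0.5, 2, -0.5], [0, -0.5, 1]]
        np.testing.assert_array_equal(Q, expected)

    def test_exact_symmetry_and_cholesky(self, rng):
        for m in (5, 20, 60):
            g = random_connected_graph(m, rng)
            for lam in (0.0, 0.25, 0.5, 0.9):
                Q = car_precision(g, tau=1.7, lam=lam)
                assert (Q == Q.T).all()
                np.linalg.cholesky(Q)  # PD on connected graphs

    def test_logdet_matches_dense(self, rng):
        g = random_connected_graph(10, rng)
        for tau, lam in [(1.0, 0.0), (2.5, 0.6), (0.3, 0.95)]:
            dense = np.linalg.slogdet(car_precision(g, tau, lam))[1]
            assert car_logdet(g, tau, lam) == pytest.approx(dense, abs=1e-9)

    def test_invalid_parameters_rejected(self, path3_graph):
        with pytest.raises(ValueError):
            car_precision(path3_graph, tau=-1.0, lam=0.0)
        with pytest.raises(ValueError):
            car_precision(path3_graph, tau=1.0, lam=1.0)

    def test_isolated_stratum_error_names_it(self):
        with pytest.warns(UserWarning):
            g = build_proximity_matrix([(0, 0), (1, 0), (9, 0)], 1.5)
        with pytest.raises(DisconnectedGraphError, match="s3"):
            car_precision(g, tau=1.0, lam=0.5)

    def test_sampled_field_covariance_matches_dense_inverse(self, rng):
        g = random_connected_graph(6, rng)
        tau, lam = 1.5, 0.6
        draws = sample_car(g, tau, lam, size=50_000, rng=rng)
        emp = np.cov(draws.T)
        dense = np.linalg.inv(car_precision(g, tau, lam))
        scale = np.sqrt(np.outer(np.diag(dense), np.diag(dense)))
        assert np.max(np.abs(emp - dense) / scale) < 0.05


def test_greedy_coloring_is_proper(rng):
    g = random_connected_graph(25, rng)
    colors = greedy_coloring(g.W)
    j, k = np.nonzero(g.W)
    assert (colors[j] != colors[k]).all()


def test_centroid_csv_roundtrip(tmp_path, rng):
    cent = rng.uniform(0, 5, size=(4, 2))
    path = tmp_path / "centroids.csv"
    write_centroids(path, ["a", "b", "c", "d"], cent)
    ids, back = read_centroids(path)
    assert ids == ("a", "b", "c", "d")
    np.testing.assert_allclose(back, cent)


def test_matrix_export_labels(tmp_path, path3_graph):
    import pandas as pd

    path3_graph.write(tmp_path / "W.csv", tmp_path / "D.csv")
    W = pd.read_csv(tmp_path / "W.csv", index_col=0)
    assert list(W.columns) == ["s1", "s2", "s3"]
    assert W.to_numpy().tolist() == path3_graph.W.astype(int).tolist()
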