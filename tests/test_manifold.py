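"""Graph construction, geodesics and classical MDS are verified against
brute-force and closed-form oracles; the embedding must reproduce known
geometry exactly in the Euclidean case."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

from specal import manifold
from specal.exceptions import DisconnectedGraphError
from specal.manifold import (
    build_knn_graph,
    classical_mds,
    geodesic_distances,
    isomap_fit,
    isomap_transform,
    reconstruction_rmse,
    select_components,
)


def floyd_warshall(weights: np.ndarray) -> np.ndarray:
    """Reference all-pairs shortest paths (dense, cubic)."""
    D = weights.copy()
    n = D.shape[0]
    for k in range(n):
        for i in range(n):
            D[i] = np.minimum(D[i], D[i, k] + D[k])
    return D


def random_knn_case(rng, n, d, k):
    X = rng.normal(size=(n, d))
    graph = build_knn_graph(X, k)
    dense = graph.adjacency.toarray()
    dense[dense == 0] = np.inf
    np.fill_diagonal(dense, 0.0)
    return X, graph, dense


class TestKNNGraph:
    def test_three_collinear_points(self):
        X = np.array([[0.0], [1.0], [3.0]])
        graph = build_knn_graph(X, k=1)
        adj = graph.adjacency.toarray()
        assert adj[0, 1] == 1.0 and adj[1, 0] == 1.0
        assert adj[1, 2] == 2.0 and adj[2, 1] == 2.0  # union symmetrization
        assert adj[0, 2] == 0.0

    def test_complete_graph_exact_weights(self, rng):
        X = rng.normal(size=(12, 3))
        graph = build_knn_graph(X, k=11)
        assert np.allclose(graph.adjacency.toarray(), cdist(X, X))

    def test_neighbor_sets_match_brute_force(self, rng):
        X = rng.normal(size=(50, 4))
        k = 6
        graph = build_knn_graph(X, k)
        dist = cdist(X, X)
        directed = set()
        for i in range(50):
            order = sorted(range(50), key=lambda j: (dist[i, j], j))
            for j in [j for j in order if j != i][:k]:
                directed.add((i, j))
        expected = {(i, j) for i, j in directed} | {(j, i) for i, j in directed}
        got = set(zip(*graph.adjacency.nonzero()))
        assert got == expected

    def test_duplicate_points_get_floor_weight(self):
        X = np.array([[0.0], [0.0], [5.0]])
        graph = build_knn_graph(X, k=1)
        assert graph.adjacency[0, 1] == manifold.EDGE_WEIGHT_FLOOR

    def test_k_bounds(self, rng):
        X = rng.normal(size=(5, 2))
        for bad in (0, 5, 7):
            with pytest.raises(ValueError):
                build_knn_graph(X, bad)


class TestGeodesics:
    def test_path_graph_hand_computed(self):
        X = np.array([[0.0], [1.0], [2.0]])
        D = geodesic_distances(build_knn_graph(X, k=1))
        assert D[0, 2] == pytest.approx(2.0)
        assert np.allclose(np.diag(D), 0.0)

    def test_complete_metric_graph_uses_direct_edges(self, rng):
        X = rng.normal(size=(10, 3))
        D = geodesic_distances(build_knn_graph(X, k=9))
        assert np.allclose(D, cdist(X, X))

    def test_matches_floyd_warshall_on_random_graphs(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 31))
            X, graph, dense = random_knn_case(
                rng, n, 3, int(rng.integers(2, min(5, n - 1))))
            try:
                D = geodesic_distances(graph)
            except DisconnectedGraphError:
                continue
            assert np.allclose(D, floyd_warshall(dense), atol=1e-12)

    def test_disconnected_raises_and_bridge_connects(self):
        X = np.vstack([np.zeros((3, 2)), 10.0 + np.zeros((3, 2))])
        X += np.arange(6)[:, None] * 0.01
        graph = build_knn_graph(X, k=1)
        with pytest.raises(DisconnectedGraphError):
            geodesic_distances(graph)
        D = geodesic_distances(graph, on_disconnected="bridge", points=X)
        assert np.all(np.isfinite(D))
        assert np.allclose(D, D.T)

    def test_shortest_paths_never_exceed_direct_edges(self, rng):
        X = rng.normal(size=(20, 2))
        graph = build_knn_graph(X, k=4)
        D = geodesic_distances(graph, on_disconnected="bridge", points=X)
        adj = graph.adjacency.tocoo()
        for i, j, w in zip(adj.row, adj.col, adj.data):
            assert D[i, j] <= w + 1e-12


class TestClassicalMDS:
    def test_line_recovered_exactly(self):
        coords = np.array([0.0, 1.0, 2.0, 3.0])
        D = np.abs(coords[:, None] - coords[None, :])
        _, F, Y = classical_mds(D, 1)
        centered = coords - coords.mean()
        assert np.allclose(np.abs(Y[:, 0]), np.abs(centered), atol=1e-10)
        assert np.allclose(cdist(Y, Y), D, atol=1e-10)

    def test_planar_distances_reproduced(self, rng):
        P = rng.normal(size=(15, 2))
        D = cdist(P, P)
        _, _, Y = classical_mds(D, 2)
        assert np.abs(cdist(Y, Y) - D).max() <= 1e-8

    def test_eigenvalues_match_dense_oracle(self, rng):
        P = rng.normal(size=(10, 3))
        D = cdist(P, P)
        V, F, _ = classical_mds(D, 10)
        n = 10
        H = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * H @ (D ** 2) @ H
        expected = np.sort(np.linalg.eigvalsh(B))[::-1]
        assert np.allclose(F, expected, atol=1e-8)

    def test_embedding_column_norm_equals_eigenvalue(self, rng):
        P = rng.normal(size=(12, 3))
        _, F, Y = classical_mds(cdist(P, P), 3)
        assert np.allclose((Y ** 2).sum(axis=0), np.clip(F, 0, None),
                           atol=1e-8)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            classical_mds(np.array([[0.0, 1.0], [2.0, 0.0]]), 1)
        with pytest.raises(ValueError):
            classical_mds(np.array([[1.0, 1.0], [1.0, 1.0]]), 1)


class TestIsomap:
    def test_complete_graph_degenerates_to_mds(self, rng):
        X = rng.normal(size=(20, 3)) @ rng.normal(size=(3, 8))
        model = isomap_fit(X, k=19, n_components=3)
        assert np.abs(cdist(model.embedding, model.embedding)
                      - cdist(X, X)).max() <= 1e-8

    def test_curve_arc_length_recovered(self, rng):
        """A noiseless constant-speed 3-D spiral isometrically embedded in
        125-D: the 1-D Isomap coordinate must be rank-equivalent to the
        curve parameter."""
        t = np.linspace(0, 2 * np.pi, 200)
        curve = np.column_stack([np.cos(3 * t), np.sin(3 * t), 2 * t])
        Q, _ = np.linalg.qr(rng.normal(size=(125, 3)))
        X = curve @ Q.T[:3]
        model = isomap_fit(X, k=5, n_components=1)
        rho = abs(spearmanr(model.embedding[:, 0], t).statistic)
        assert rho >= 0.99

    def test_five_point_hand_trace(self):
        """Path of 5 points at 0,1,2,4,8 with k=1: geodesics are the summed
        gaps; the 1-D embedding reproduces them."""
        coords = np.array([0.0, 1.0, 2.0, 4.0, 8.0])
        model = isomap_fit(coords[:, None], k=1, n_components=1)
        expected_D = np.abs(coords[:, None] - coords[None, :])
        assert np.allclose(model.geodesics, expected_D)
        Y = model.embedding[:, 0]
        assert np.allclose(np.abs(np.diff(Y)), np.diff(coords), atol=1e-8)

    def test_transform_reproduces_training_embedding(self, rng):
        X = rng.normal(size=(40, 6))
        model = isomap_fit(X, k=6, n_components=3, on_disconnected="bridge")
        Y_new = isomap_transform(model, X)
        assert np.abs(Y_new - model.embedding).max() <= 1e-6

    def test_duplicate_of_training_point_maps_to_its_row(self, rng):
        X = rng.normal(size=(30, 4))
        model = isomap_fit(X, k=5, n_components=2, on_disconnected="bridge")
        Y_new = isomap_transform(model, X[7][None, :])
        assert np.allclose(Y_new[0], model.embedding[7], atol=1e-6)

    def test_midpoint_embeds_between_neighbors(self):
        t = np.linspace(0, 1, 50)
        X = np.column_stack([t, t ** 2])
        model = isomap_fit(X, k=3, n_components=1)
        mid = 0.5 * (X[20] + X[21])
        y = isomap_transform(model, mid[None, :])[0, 0]
        lo, hi = sorted([model.embedding[20, 0], model.embedding[21, 0]])
        assert lo <= y <= hi

    def test_model_archive_round_trip(self, rng, tmp_path):
        X = rng.normal(size=(25, 4))
        model = isomap_fit(X, k=5, n_components=2, on_disconnected="bridge")
        model.save(tmp_path / "model.npz")
        back = manifold.IsomapModel.load(tmp_path / "model.npz")
        assert np.array_equal(back.embedding, model.embedding)
        assert np.array_equal(back.geodesics, model.geodesics)
        assert np.allclose(isomap_transform(back, X[:3]),
                           isomap_transform(model, X[:3]))

    def test_transform_z_bound_checked(self, rng):
        X = rng.normal(size=(10, 3))
        model = isomap_fit(X, k=9, n_components=2)
        with pytest.raises(ValueError):
            isomap_transform(model, X, n_components=11)

    def test_permutation_invariance_up_to_sign(self, rng):
        X = rng.normal(size=(25, 5))
        perm = rng.permutation(25)
        m1 = isomap_fit(X, k=24, n_components=2)
        m2 = isomap_fit(X[perm], k=24, n_components=2)
        for c in range(2):
            a, b = m1.embedding[perm, c], m2.embedding[:, c]
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)


class TestComponentSelection:
    def test_exact_dimension_recovered(self, rng):
        X = rng.normal(size=(30, 3)) @ rng.normal(size=(3, 20))
        best, curve = select_components(X, k=29, z_range=range(1, 11))
        assert best == 3
        assert curve[2] <= 1e-8

    def test_rmse_zero_at_intrinsic_dimension(self, rng):
        X = rng.normal(size=(25, 4)) @ rng.normal(size=(4, 15))
        model = isomap_fit(X, k=24, n_components=25)
        assert reconstruction_rmse(model, 4) <= 1e-8

    def test_rmse_curve_non_increasing(self, rng):
        X = rng.normal(size=(40, 10))
        _, curve = select_components(X, k=39, z_range=range(1, 21))
        assert np.all(np.diff(curve) <= 1e-9)

    def test_curve_matches_individual_recomputation(self, rng):
        X = rng.normal(size=(20, 5))
        _, curve = select_components(X, k=19, z_range=range(1, 6))
        model = isomap_fit(X, k=19, n_components=5)
        for i, z in enumerate(range(1, 6)):
            assert curve[i] == pytest.approx(reconstruction_rmse(model, z))

    def test_toy_rmse_matches_hand_summation(self):
        coords = np.array([0.0, 1.0, 2.0, 4.0, 8.0])
        model = isomap_fit(coords[:, None], k=1, n_components=1)
        Y = model.embedding[:, 0]
        total, count = 0.0, 0
        for i in range(5):
            for j in range(i + 1, 5):
                total += (model.geodesics[i, j] - abs(Y[i] - Y[j])) ** 2
                count += 1
        assert reconstruction_rmse(model, 1) == pytest.approx(
            np.sqrt(total / count))

    def test_z_range_validated(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            select_components(X, k=9, z_range=range(1, 11))
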