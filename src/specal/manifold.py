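"""Isomap spectral reconstruction.

The embedding pipeline is the classical one: a symmetrized k-nearest-
neighbor graph with Euclidean edge weights in preprocessed spectral space,
all-pairs shortest-path ("geodesic") distances on that graph, and classical
multidimensional scaling of the squared geodesic distance matrix.  The
embedding coordinates are the top eigenvectors of the double-centered
matrix ``B = -1/2 H D^2 H`` scaled by the square roots of their
eigenvalues (``Y = V_Z F_Z^{1/2}``).

The number of retained components Z is chosen by scanning a range
(default 1–20) and minimizing the root-mean-square discrepancy between
geodesic and embedded pairwise distances.  Held-out spectra are embedded by
a Nystrom projection: geodesic distances to all training points through the
new point's nearest training neighbors, then projection on the stored
eigenbasis — the fit is inductive, training spectra only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import cdist

from .exceptions import DisconnectedGraphError

__all__ = [
    "NeighborGraph",
    "IsomapModel",
    "build_knn_graph",
    "geodesic_distances",
    "classical_mds",
    "isomap_fit",
    "isomap_transform",
    "reconstruction_rmse",
    "select_components",
]

#: Floor for edge weights so duplicate points do not create zero-weight edges.
EDGE_WEIGHT_FLOOR = 1e-12

DEFAULT_K = 10
DEFAULT_Z_RANGE = range(1, 21)


@dataclass
class NeighborGraph:
    """Symmetrized k-NN graph with Euclidean edge weights."""

    n_nodes: int
    adjacency: csr_matrix   # symmetric, zero diagonal, weights > 0
    k: int


@dataclass
class IsomapModel:
    """Everything needed to reproduce and extend the embedding."""

    training_points: np.ndarray
    graph: NeighborGraph
    geodesics: np.ndarray          # D_G, n x n
    eigenvalues: np.ndarray        # descending, full spectrum of B
    eigenvectors: np.ndarray       # unit-norm columns, same order
    n_components: int
    n_clipped: int                 # negative eigenvalues clipped within Z

    @property
    def embedding(self) -> np.ndarray:
        """Training coordinates ``Y = V_Z F_Z^{1/2}`` (clipped at zero)."""
        F = np.clip(self.eigenvalues[: self.n_components], 0.0, None)
        return self.eigenvectors[:, : self.n_components] * np.sqrt(F)

    def save(self, path) -> None:
        """Persist as a single ``.npz`` archive: arrays plus a JSON manifest
        (``meta``) holding k, Z and the clipped-eigenvalue count."""
        import json

        adj = self.graph.adjacency.tocoo()
        np.savez(
            path,
            training_points=self.training_points,
            geodesics=self.geodesics,
            eigenvalues=self.eigenvalues,
            eigenvectors=self.eigenvectors,
            graph_row=adj.row, graph_col=adj.col, graph_weight=adj.data,
            meta=np.frombuffer(json.dumps({
                "k": self.graph.k,
                "n_nodes": self.graph.n_nodes,
                "n_components": self.n_components,
                "n_clipped": self.n_clipped,
            }).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path) -> "IsomapModel":
        import json

        with np.load(path) as payload:
            meta = json.loads(payload["meta"].tobytes().decode())
            n = meta["n_nodes"]
            adj = csr_matrix(
                (payload["graph_weight"],
                 (payload["graph_row"], payload["graph_col"])),
                shape=(n, n))
            return cls(
                training_points=payload["training_points"],
                graph=NeighborGraph(n_nodes=n, adjacency=adj, k=meta["k"]),
                geodesics=payload["geodesics"],
                eigenvalues=payload["eigenvalues"],
                eigenvectors=payload["eigenvectors"],
                n_components=meta["n_components"],
                n_clipped=meta["n_clipped"],
            )


def build_knn_graph(X: np.ndarray, k: int) -> NeighborGraph:
    """Symmetrized (union) k-nearest-neighbor graph.

    Ties in distance are broken toward the smaller index; zero distances
    (duplicate points) are floored at ``EDGE_WEIGHT_FLOOR``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_samples (= {n})")
    dist = cdist(X, X)
    # stable argsort on (distance, index): smaller index wins among ties
    order = np.argsort(dist, axis=1, kind="stable")
    rows, cols, weights = [], [], []
    for i in range(n):
        neighbors = [j for j in order[i] if j != i][:k]
        for j in neighbors:
            rows.append(i)
            cols.append(j)
            weights.append(max(dist[i, j], EDGE_WEIGHT_FLOOR))
    adj = csr_matrix((weights, (rows, cols)), shape=(n, n))
    adj = adj.maximum(adj.T)   # union symmetrization; weights are symmetric
    return NeighborGraph(n_nodes=n, adjacency=adj, k=k)


def geodesic_distances(graph: NeighborGraph, on_disconnected: str = "raise",
                       points: np.ndarray | None = None) -> np.ndarray:
    """All-pairs shortest-path distance matrix D_G (Dijkstra per source).

    ``on_disconnected``: ``"raise"`` (default) or ``"bridge"`` — connect
    components by their single shortest inter-component Euclidean edge
    (requires ``points``); silent infinite distances are never produced.
    """
    adj = graph.adjacency
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        if on_disconnected == "raise" or points is None:
            raise DisconnectedGraphError(
                f"neighborhood graph has {n_comp} components; increase k "
                "or pass on_disconnected='bridge'")
        adj = _bridge_components(adj, labels, np.asarray(points, dtype=float))
    D = shortest_path(adj, method="D", directed=False)
    return D


def _bridge_components(adj: csr_matrix, labels: np.ndarray,
                       X: np.ndarray) -> csr_matrix:
    """Greedily join components by their shortest Euclidean bridge."""
    adj = adj.tolil(copy=True)
    labels = labels.copy()
    while len(np.unique(labels)) > 1:
        comp0 = np.where(labels == labels[0])[0]
        rest = np.where(labels != labels[0])[0]
        d = cdist(X[comp0], X[rest])
        a, b = np.unravel_index(np.argmin(d), d.shape)
        i, j = comp0[a], rest[b]
        w = max(d[a, b], EDGE_WEIGHT_FLOOR)
        adj[i, j] = w
        adj[j, i] = w
        labels[labels == labels[j]] = labels[0]
    return adj.tocsr()


def classical_mds(D: np.ndarray, n_components: int):
    """Classical (Torgerson) MDS of a distance matrix.

    Returns ``(V_Z, F_Z, Y)``: the top ``n_components`` unit eigenvectors
    and eigenvalues of ``B = -1/2 H D^2 H`` (descending; each eigenvector's
    largest-magnitude entry made positive) and the coordinate matrix
    ``Y = V_Z diag(max(F, 0))^{1/2}``.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("D must be symmetric")
    if np.abs(np.diag(D)).max() > 1e-10 or D.min() < -1e-10:
        raise ValueError("D must have zero diagonal and no negative entries")
    if not 1 <= n_components <= n:
        raise ValueError("n_components must be in [1, n]")
    D2 = D ** 2
    # B = -1/2 H D^2 H, computed without materializing H
    row_mean = D2.mean(axis=1, keepdims=True)
    B = -0.5 * (D2 - row_mean - row_mean.T + D2.mean())
    B = 0.5 * (B + B.T)
    eigenvalues, eigenvectors = np.linalg.eigh(B)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    eigenvectors = eigenvectors[:, order]
    # deterministic sign: largest-|.| entry of each eigenvector positive
    for c in range(eigenvectors.shape[1]):
        pivot = np.argmax(np.abs(eigenvectors[:, c]))
        if eigenvectors[pivot, c] < 0:
            eigenvectors[:, c] *= -1
    V = eigenvectors[:, :n_components]
    F = eigenvalues[:n_components]
    Y = V * np.sqrt(np.clip(F, 0.0, None))
    return V, F, Y


def isomap_fit(X: np.ndarray, k: int = DEFAULT_K, n_components: int = 2,
               on_disconnected: str = "raise") -> IsomapModel:
    """Fit the full Isomap pipeline on training points."""
    X = np.asarray(X, dtype=float)
    graph = build_knn_graph(X, k)
    D = geodesic_distances(graph, on_disconnected=on_disconnected, points=X)
    V, F, _ = classical_mds(D, D.shape[0])
    n_clipped = int(np.sum(F[:n_components] < 0))
    return IsomapModel(
        training_points=X,
        graph=graph,
        geodesics=D,
        eigenvalues=F,
        eigenvectors=V,
        n_components=n_components,
        n_clipped=n_clipped,
    )


def isomap_transform(model: IsomapModel, X_new: np.ndarray,
                     n_components: int | None = None) -> np.ndarray:
    """Nystrom out-of-sample embedding of new points.

    Geodesic distance from a new point to every training point is taken as
    the minimum over its k nearest training neighbors ``i`` of
    ``||x - x_i|| + D_G[i, j]``; the squared distances are then projected on
    the stored eigenbasis.  Transforming a training point reproduces its
    training coordinates.
    """
    Z = model.n_components if n_components is None else n_components
    if Z > model.eigenvalues.size:
        raise ValueError(
            f"requested {Z} components but only {model.eigenvalues.size} stored")
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    dist = cdist(X_new, model.training_points)
    k = model.graph.k
    D = model.geodesics
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    geo = np.empty((X_new.shape[0], D.shape[0]))
    for r in range(X_new.shape[0]):
        anchors = order[r]
        # min over anchors of (euclid to anchor + geodesic from anchor)
        geo[r] = np.min(dist[r, anchors][:, None] + D[anchors, :], axis=0)
    col_mean_sq = (D ** 2).mean(axis=0)
    F = model.eigenvalues[:Z]
    V = model.eigenvectors[:, :Z]
    scale = np.zeros(Z)
    positive = F > 0
    scale[positive] = 1.0 / (2.0 * np.sqrt(F[positive]))
    return ((col_mean_sq[None, :] - geo ** 2) @ V) * scale


def reconstruction_rmse(model: IsomapModel, n_components: int) -> float:
    """RMS discrepancy between geodesic and embedded pairwise distances.

    Uses the first ``n_components`` embedding columns; the sum runs over
    all unordered pairs.
    """
    if not 1 <= n_components <= model.eigenvalues.size:
        raise ValueError("n_components out of range")
    F = np.clip(model.eigenvalues[:n_components], 0.0, None)
    Y = model.eigenvectors[:, :n_components] * np.sqrt(F)
    embedded = cdist(Y, Y)
    iu = np.triu_indices(Y.shape[0], k=1)
    diff = model.geodesics[iu] - embedded[iu]
    return float(np.sqrt(np.mean(diff ** 2)))


def argmin_with_ties(curve: np.ndarray) -> int:
    """Index of the curve minimum, taking the first value within numerical
    tolerance of it — so exact-dimension plateaus resolve to the smallest Z."""
    curve = np.asarray(curve, dtype=float)
    tol = 1e-8 * (curve.max() - curve.min()) + 1e-12
    return int(np.argmax(curve <= curve.min() + tol))


def select_components(X: np.ndarray, k: int = DEFAULT_K,
                      z_range=DEFAULT_Z_RANGE,
                      on_disconnected: str = "raise"):
    """Choose Z minimizing the reconstruction RMSE over a candidate range.

    Returns ``(best_z, rmse_curve)`` with the curve indexed like
    ``z_range``; the smallest Z wins ties (within numerical tolerance).
    """
    z_range = list(z_range)
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not z_range or min(z_range) < 1 or max(z_range) > n - 1:
        raise ValueError("z_range must lie within [1, n_samples - 1]")
    model = isomap_fit(X, k=k, n_components=max(z_range),
                       on_disconnected=on_disconnected)
    curve = np.array([reconstruction_rmse(model, z) for z in z_range])
    best_z = z_range[argmin_with_ties(curve)]
    return best_z, curve
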