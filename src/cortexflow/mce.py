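"""Minimum Curvilinear Embedding (MCE) of per-condition feature vectors.

Each screened condition is summarized by five features (foci density
rho, mean AP velocity, oscillation period T_osc, hydrodynamic length
lambda, chirality index c).  After column-wise z-scoring, the pairwise
correlation distance (1 - Pearson r between the two 5-vectors) defines
a complete graph; its minimum spanning tree (Kruskal) yields nonlinear
"curvilinear" sample distances: the minimum curvilinear kernel D, where
D_ij is the sum of edge weights along the unique MST path from i to j.
D is a tree metric by construction.  A spectral decomposition of the
(double-centred, classical-MDS-style) kernel gives two coordinates per
condition along the principal nonlinear directions; a non-centred SVD
variant is available.  Cluster assignment itself is left to the user
(in the original screen it was done by manual inspection); an optional
k-medoids helper is provided purely as a convenience.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "MCKernel",
    "Embedding2D",
    "FEATURE_COLUMNS",
    "zscore_features",
    "mc_kernel",
    "embed",
    "kmedoids_labels",
]

FEATURE_COLUMNS = ("rho", "vx_mean", "Tosc", "lambda", "c")


@dataclass
class FeatureTable:
    """Per-condition feature matrix (rows: conditions) with a z-scored copy."""

    data: pd.DataFrame
    zscored: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("condition names must be unique")


@dataclass
class MCKernel:
    """Curvilinear (MST path) distance matrix with its spanning tree."""

    D: np.ndarray
    mst_edges: list[tuple[int, int, float]]
    labels: list[str] = field(default_factory=list)


@dataclass
class Embedding2D:
    """Two leading embedding coordinates per condition."""

    coords: np.ndarray          # shape (n, 2)
    singular_values: np.ndarray
    labels: list[str] = field(default_factory=list)


def zscore_features(
    table: FeatureTable | pd.DataFrame,
    impute_c_zero_for: Sequence[str] = (),
) -> FeatureTable:
    """Column-wise z-scoring (sample standard deviation).

    Conditions listed in ``impute_c_zero_for`` get a chirality index of
    zero before standardization (used for conditions whose chiral fit is
    undefined but whose counter-rotation is essentially zero).  Rows
    with any other missing value are dropped with a warning, never
    silently imputed.
    """
    df = table.data.copy() if isinstance(table, FeatureTable) else table.copy()
    if len(df) < 3:
        raise ValueError("need at least 3 conditions")
    for cond in impute_c_zero_for:
        if cond not in df.index:
            raise KeyError(f"unknown condition {cond!r}")
        df.loc[cond, "c"] = 0.0
    incomplete = df.isna().any(axis=1)
    if incomplete.any():
        import warnings

        warnings.warn(
            f"dropping conditions with missing features: {list(df.index[incomplete])}",
            stacklevel=2,
        )
        df = df[~incomplete]
    sd = df.std(ddof=1)
    if (sd == 0).any() or sd.isna().any():
        bad = list(sd.index[(sd == 0) | sd.isna()])
        raise ValueError(f"zero spread in column(s) {bad}: cannot z-score")
    z = (df - df.mean()) / sd
    return FeatureTable(data=df, zscored=z)


def _correlation_distance_matrix(rows: np.ndarray) -> np.ndarray:
    n = rows.shape[0]
    sd = rows.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("constant feature row: correlation distance undefined")
    centered = rows - rows.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    corr = (centered @ centered.T) / np.outer(norms, norms)
    corr = np.clip(corr, -1.0, 1.0)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return d


def mc_kernel(z: FeatureTable | pd.DataFrame | np.ndarray) -> MCKernel:
    """Minimum curvilinear kernel of a (z-scored) feature table.

    Direct distances are correlation distances between row vectors;
    the Kruskal MST of the complete graph gives the tree over which
    pairwise path distances accumulate.  Equal-weight edge ties are
    broken by lexicographic node order for determinism.
    """
    if isinstance(z, FeatureTable):
        df = z.zscored if z.zscored is not None else z.data
        rows = df.to_numpy(dtype=float)
        labels = [str(i) for i in df.index]
    elif isinstance(z, pd.DataFrame):
        rows = z.to_numpy(dtype=float)
        labels = [str(i) for i in z.index]
    else:
        rows = np.asarray(z, dtype=float)
        labels = [str(i) for i in range(rows.shape[0])]
    n = rows.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows")
    d = _correlation_distance_matrix(rows)

    g = nx.Graph()
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=float(d[i, j]))
    # Kruskal with deterministic tie-break: sort edges by (weight, i, j).
    mst = nx.minimum_spanning_tree(g, algorithm="kruskal", weight="weight")
    edges = sorted((min(u, v), max(u, v), data["weight"]) for u, v, data in mst.edges(data=True))

    tree = nx.Graph()
    tree.add_nodes_from(range(n))
    for u, v, w in edges:
        tree.add_edge(u, v, weight=w)
    D = np.zeros((n, n))
    for src, dists in nx.all_pairs_dijkstra_path_length(tree, weight="weight"):
        for dst, dist in dists.items():
            D[src, dst] = dist
    D = 0.5 * (D + D.T)
    return MCKernel(D=D, mst_edges=edges, labels=labels)


def _orient_axis(coord: np.ndarray) -> np.ndarray:
    """Flip sign so the largest-magnitude loading is positive."""
    i = int(np.argmax(np.abs(coord)))
    return coord if coord[i] >= 0 else -coord


def embed(kernel: MCKernel, mode: str = "centered") -> Embedding2D:
    """Embed the curvilinear kernel into two dimensions.

    ``centered`` (default): classical-MDS-style double centring of the
    squared distances, B = -1/2 J (D*D) J, followed by the top-2
    spectral coordinates.  ``noncentered``: SVD of D itself, coordinates
    from the two leading singular triplets.  If the kernel has rank < 2
    the second coordinate is zeroed with a warning.
    """
    D = kernel.D
    n = D.shape[0]
    if mode == "centered":
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D * D) @ J
        eigval, eigvec = np.linalg.eigh(B)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        sv = np.sqrt(np.clip(eigval[:2], 0.0, None))
        coords = eigvec[:, :2] * sv
    elif mode == "noncentered":
        u, s, _ = np.linalg.svd(D)
        sv = s[:2]
        coords = u[:, :2] * sv
    else:
        raise ValueError("mode must be 'centered' or 'noncentered'")
    if sv.size < 2 or sv[1] <= 1e-12 * max(sv[0], 1.0):
        import warnings

        warnings.warn("kernel rank < 2: second coordinate zeroed", stacklevel=2)
        coords[:, 1] = 0.0
    coords = np.column_stack([_orient_axis(coords[:, 0]), _orient_axis(coords[:, 1])])
    return Embedding2D(coords=coords, singular_values=sv, labels=kernel.labels)


def kmedoids_labels(D: np.ndarray, k: int, seed: int = 0, n_restarts: int = 10) -> np.ndarray:
    """Optional convenience k-medoids (PAM-style) on a distance matrix.

    This is NOT part of the screen procedure (cluster assignment there
    is manual); it is offered purely as a helper for exploration.
    """
    n = D.shape[0]
    rng = np.random.default_rng(seed)
    best_cost, best_labels = np.inf, None
    for _ in range(n_restarts):
        medoids = rng.choice(n, size=k, replace=False)
        for _ in range(100):
            labels = np.argmin(D[:, medoids], axis=1)
            new_medoids = medoids.copy()
            for ci in range(k):
                members = np.where(labels == ci)[0]
                if members.size == 0:
                    continue
                costs = D[np.ix_(members, members)].sum(axis=0)
                new_medoids[ci] = members[int(np.argmin(costs))]
            if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
                break
            medoids = new_medoids
        cost = float(D[np.arange(n), medoids[labels]].sum())
        if cost < best_cost:
            best_cost, best_labels = cost, labels.copy()
    return best_labels
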