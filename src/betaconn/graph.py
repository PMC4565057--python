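"""Graph metrics on thresholded ROI networks.

The weighted Fisher-z matrix is binarized at a threshold (z > tau), and the
binary graph yields degree, betweenness, eigenvector centrality, clustering
coefficient and characteristic path length; strength keeps the surviving
weights.  Hubs are nodes whose degree exceeds the mean by more than one
(sample) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityMatrix


@dataclass
class NodeMetrics:
    """Per-node centralities plus graph-level summaries."""

    table: pd.DataFrame
    characteristic_path_length: float
    reachable_fraction: float

    def __getitem__(self, col):
        return self.table[col].to_numpy()


def _as_array(W) -> np.ndarray:
    vals = W.values if isinstance(W, ConnectivityMatrix) else np.asarray(W, dtype=float)
    if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(np.nan_to_num(vals), np.nan_to_num(vals.T)):
        raise ValueError("matrix must be symmetric")
    return np.asarray(vals, dtype=float)


def binarize(W, tau: float) -> np.ndarray:
    """b_ij = 1 iff w_ij > tau (i != j); NaN edges never survive."""
    vals = _as_array(W)
    with np.errstate(invalid="ignore"):
        B = (vals > tau).astype(np.int8)
    np.fill_diagonal(B, 0)
    return B


def _eigenvector_centrality(B: np.ndarray) -> np.ndarray:
    """Power iteration on the largest connected component, scaled so the
    maximum entry is 1; nodes outside the component get 0."""
    n = B.shape[0]
    n_comp, comp = _components(B)
    sizes = np.bincount(comp)
    big = np.argmax(sizes)
    idx = np.nonzero(comp == big)[0]
    sub = B[np.ix_(idx, idx)].astype(float)
    out = np.zeros(n)
    if sub.sum() == 0:  # no edges anywhere
        return out
    v = np.ones(len(idx))
    for _ in range(10_000):
        # shifted iteration (A + I): same eigenvectors, but converges on
        # bipartite graphs where plain power iteration oscillates
        w = sub @ v + v
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        w /= norm
        if np.linalg.norm(w - v) < 1e-10:
            v = w
            break
        v = w
    v = np.abs(v)
    out[idx] = v / v.max()
    return out


def _components(B: np.ndarray):
    from scipy.sparse.csgraph import connected_components

    return connected_components(B, directed=False)


def clustering_coefficient(B) -> np.ndarray:
    """C_i = 2 * triangles_i / (k_i (k_i - 1)); 0 when k_i < 2."""
    B = np.asarray(B, dtype=np.int64).copy()
    np.fill_diagonal(B, 0)
    k = B.sum(axis=1)
    tri = np.diag(B @ B @ B) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        C = 2.0 * tri / (k * (k - 1))
    C[k < 2] = 0.0
    return C


def characteristic_path_length(B) -> tuple:
    """Mean shortest-path length over reachable unordered node pairs, plus
    the fraction of pairs that are reachable.  Raises on an edgeless graph."""
    B = np.asarray(B)
    np.fill_diagonal(B := B.copy(), 0)
    if B.sum() == 0:
        raise ValueError("graph has no edges; path length undefined")
    D = shortest_path(B, method="D", directed=False, unweighted=True)
    iu = np.triu_indices(B.shape[0], k=1)
    d = D[iu]
    finite = np.isfinite(d)
    return float(d[finite].mean()), float(finite.mean())


def centrality_metrics(B, W=None) -> NodeMetrics:
    """All node metrics for a binary graph ``B`` (optionally with the
    thresholded weighted matrix ``W`` for strength).

    Degree: row sums of B.  Strength: row sums of W (or of B if W is None).
    Betweenness: shortest-path counting over unordered pairs, endpoints
    excluded, equal split across tied geodesics.  Eigenvector centrality:
    largest component, max scaled to 1.  Clustering: triangle density around
    each node.
    """
    B = np.asarray(B, dtype=np.int64)
    if B.shape[0] != B.shape[1] or not np.array_equal(B, B.T):
        raise ValueError("binary matrix must be square and symmetric")
    np.fill_diagonal(B, 0)
    n = B.shape[0]
    degree = B.sum(axis=1)
    if W is not None:
        Wv = _as_array(W).copy()
        np.fill_diagonal(Wv, 0.0)
        strength = np.nansum(np.where(B > 0, Wv, 0.0), axis=1)
    else:
        strength = degree.astype(float)

    G = nx.from_numpy_array(B)
    betweenness = np.array(
        [nx.betweenness_centrality(G, normalized=False)[i] for i in range(n)]
    )
    clustering = clustering_coefficient(B)
    eigvec = _eigenvector_centrality(B)

    if B.sum() > 0:
        cpl, frac = characteristic_path_length(B)
    else:
        cpl, frac = np.nan, 0.0

    table = pd.DataFrame(
        {
            "degree": degree,
            "strength": strength,
            "betweenness": betweenness,
            "eigenvector": eigvec,
            "clustering": clustering,
        }
    )
    table["is_hub"] = hub_selection(degree)
    return NodeMetrics(
        table=table, characteristic_path_length=cpl, reachable_fraction=frac
    )


def hub_selection(degrees) -> np.ndarray:
    """Hubs: degree more than one sample standard deviation above the mean.

    Zero spread (all degrees equal) yields no hubs."""
    d = np.asarray(degrees, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 nodes")
    sd = d.std(ddof=1)
    if sd == 0:
        return np.zeros(d.size, dtype=bool)
    return d > d.mean() + sd
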