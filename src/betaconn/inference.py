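"""Group-level statistics on connectivity edges.

Edgewise paired and two-sample t-tests operate on Fisher-z values (the
transform makes correlations approximately normal, so ordinary t machinery
applies), with permutation alternatives (sign-flip for paired designs,
label-shuffle for two groups) and Storey's q-value FDR correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import ConnectivityMatrix


@dataclass
class EdgeStats:
    """Per-edge test results (upper-triangle order i < j)."""

    t: np.ndarray
    p: np.ndarray
    df: int
    kind: str
    q: np.ndarray | None = None
    flagged: np.ndarray | None = None  # edges with undefined statistics
    labels: list | None = None
    edges: list | None = None  # (i, j) node-label pairs

    @property
    def n_edges(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        d = {"t": self.t, "p": self.p}
        if self.q is not None:
            d["q"] = self.q
        df = pd.DataFrame(d)
        if self.edges is not None:
            df.insert(0, "node_i", [e[0] for e in self.edges])
            df.insert(1, "node_j", [e[1] for e in self.edges])
        return df


def _upper_triangle_stack(mats):
    """Stack a list of ConnectivityMatrix (or square arrays) into
    (subjects, edges) using the upper triangle, plus edge labels."""
    arrays, labels = [], None
    for m in mats:
        if isinstance(m, ConnectivityMatrix):
            arrays.append(m.values)
            labels = labels or list(m.labels)
        else:
            arrays.append(np.asarray(m, dtype=np.float64))
    n = arrays[0].shape[0]
    iu = np.triu_indices(n, k=1)
    stacked = np.stack([a[iu] for a in arrays])
    if labels is None:
        labels = list(range(n))
    edges = [(labels[i], labels[j]) for i, j in zip(*iu)]
    return stacked, labels, edges


def paired_t_stat(diffs: np.ndarray):
    """Vectorized one-sample t on difference scores (subjects on axis 0).

    Zero-variance differences: t = 0 when the mean is also 0, else NaN
    (flagged by callers)."""
    d = np.atleast_2d(np.asarray(diffs, dtype=np.float64))
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[(sd == 0) & (mean == 0)] = 0.0
    t[(sd == 0) & (mean != 0)] = np.nan  # undefined, not infinite
    return t, n - 1


def edgewise_paired_t(a: list, b: list) -> EdgeStats:
    """Paired t-test per edge on z-differences a - b (same subjects, matched
    order); df = n - 1, two-sided p."""
    A, labels, edges = _upper_triangle_stack(a)
    B, _, _ = _upper_triangle_stack(b)
    if A.shape != B.shape:
        raise ValueError("matched lists differ in shape")
    if A.shape[0] < 3:
        raise ValueError("need n >= 3 subjects for a paired t-test")
    t, df = paired_t_stat(A - B)
    flagged = np.isnan(t)
    p = np.where(flagged, np.nan, 2.0 * stats.t.sf(np.abs(t), df))
    p = np.where(t == 0, 1.0, p)
    return EdgeStats(t=t, p=p, df=df, kind="paired", flagged=flagged,
                     labels=labels, edges=edges)


def edgewise_two_sample_t(g1: list, g2: list) -> EdgeStats:
    """Pooled-variance two-sample t per edge (g1 - g2); df = n1 + n2 - 2."""
    A, labels, edges = _upper_triangle_stack(g1)
    B, _, _ = _upper_triangle_stack(g2)
    n1, n2 = A.shape[0], B.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    sp2 = ((n1 - 1) * A.var(axis=0, ddof=1) + (n2 - 1) * B.var(axis=0, ddof=1)) / (
        n1 + n2 - 2
    )
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = A.mean(axis=0) - B.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / se
    t[(se == 0) & (diff == 0)] = 0.0
    t[(se == 0) & (diff != 0)] = np.nan
    flagged = np.isnan(t)
    df = n1 + n2 - 2
    p = np.where(flagged, np.nan, 2.0 * stats.t.sf(np.abs(t), df))
    p = np.where(t == 0, 1.0, p)
    return EdgeStats(t=t, p=p, df=df, kind="two-sample", flagged=flagged,
                     labels=labels, edges=edges)


def permutation_test(
    data,
    scheme: str = "sign-flip",
    n_perm: int = 5000,
    seed: int = 0,
    statistic=None,
) -> np.ndarray:
    """Two-sided permutation p-values per edge.

    ``scheme='sign-flip'``: ``data`` is (subjects, edges) paired differences;
    the statistic (default: sum) is recomputed under random sign flips.
    ``scheme='label-shuffle'``: ``data`` is a tuple (g1, g2) of
    (subjects, edges) arrays; group labels are reshuffled.

    When the full rearrangement set is no larger than ``n_perm`` it is
    enumerated exhaustively and p is the exact count/total (the identity
    rearrangement is part of the set); otherwise ``n_perm`` random draws are
    used with the add-one estimate (1 + hits) / (1 + n_perm), which can never
    be zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    if scheme == "sign-flip":
        d = np.atleast_2d(np.asarray(data, dtype=np.float64))
        if d.shape[1] == 1 and np.ndim(data) == 1:
            d = d.T
        n = d.shape[0]
        if n < 1:
            raise ValueError("no subjects")
        stat = statistic or (lambda x: x.sum(axis=0))
        t_obs = np.abs(stat(d))
        if 2**n <= n_perm:
            hits = np.zeros(d.shape[1])
            total = 2**n
            for signs in product((1.0, -1.0), repeat=n):
                t_perm = np.abs(stat(d * np.asarray(signs)[:, None]))
                hits += t_perm >= t_obs - 1e-12
            return hits / total
        hits = np.zeros(d.shape[1])
        for _ in range(n_perm):
            signs = rng.choice((1.0, -1.0), size=n)
            hits += np.abs(stat(d * signs[:, None])) >= t_obs - 1e-12
        return (1.0 + hits) / (1.0 + n_perm)

    if scheme == "label-shuffle":
        g1 = np.atleast_2d(np.asarray(data[0], dtype=np.float64))
        g2 = np.atleast_2d(np.asarray(data[1], dtype=np.float64))
        pooled = np.concatenate([g1, g2], axis=0)
        n1, n = g1.shape[0], pooled.shape[0]
        if n1 < 1 or n - n1 < 1:
            raise ValueError("each group needs at least one member")
        stat = statistic or (
            lambda a, b: a.mean(axis=0) - b.mean(axis=0)
        )
        t_obs = np.abs(stat(g1, g2))
        n_arrangements = comb(n, n1)
        if n_arrangements <= n_perm:
            hits = np.zeros(pooled.shape[1])
            for idx in combinations(range(n), n1):
                sel = np.zeros(n, dtype=bool)
                sel[list(idx)] = True
                t_perm = np.abs(stat(pooled[sel], pooled[~sel]))
                hits += t_perm >= t_obs - 1e-12
            return hits / n_arrangements
        hits = np.zeros(pooled.shape[1])
        for _ in range(n_perm):
            perm = rng.permutation(n)
            t_perm = np.abs(stat(pooled[perm[:n1]], pooled[perm[n1:]]))
            hits += t_perm >= t_obs - 1e-12
        return (1.0 + hits) / (1.0 + n_perm)

    raise ValueError(f"unknown scheme {scheme!r}")


def storey_fdr(p, lam: float = 0.5, pi0: float | None = None) -> np.ndarray:
    """Storey q-values.

    pi0 (the null proportion) is estimated as #{p > lam} / ((1 - lam) m),
    floored at 1/m and capped at 1; pass ``pi0=1`` to reproduce
    Benjamini-Hochberg adjusted p-values exactly.  q_(i) is the running
    minimum of pi0 * m * p_(j) / j over j >= i, mapped back to input order.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1D vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = np.sum(p > lam) / ((1.0 - lam) * m)
        pi0 = min(1.0, max(1.0 / m, pi0))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q
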