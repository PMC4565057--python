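"""Memory-bounded voxel-wise degree centrality and strength.

With N in-mask voxels the full correlation matrix has N(N-1)/2 unique
entries (~2.45e9 at N = 70,000) and cannot be held in memory.  Instead the
beta matrix A (M trials x N voxels) is column-standardized once, after which
every correlation is an inner product of two columns; each voxel's
correlation row is then streamed in column chunks, Fisher z-transformed,
thresholded and reduced to a degree count and a strength sum — peak extra
storage is O(M*chunk + N), never the N x N matrix.

The default threshold is z > 0.25 (positive tail); re-running at 0.2 and
0.3 is the recommended sensitivity check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .connectivity import R_CLIP

logger = logging.getLogger("betaconn")

DEFAULT_THRESHOLD = 0.25
SENSITIVITY_THRESHOLDS = (0.2, 0.25, 0.3)
DEFAULT_CHUNK = 2048


@dataclass
class StandardizedSeries:
    """Column-standardized beta matrix Z (mean 0, unit norm per column), so
    Z.T @ Z is the Pearson correlation matrix."""

    Z: np.ndarray
    kept: np.ndarray        # original column indices that survived
    n_excluded: int = 0

    @property
    def n_trials(self) -> int:
        return self.Z.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.Z.shape[1]


@dataclass
class DegreeMap:
    """Per-voxel degree D_i (count of supra-threshold connections) and
    strength S_i (sum of surviving Fisher-z weights)."""

    degree: np.ndarray
    strength: np.ndarray
    threshold: float
    mode: str
    kept: np.ndarray
    peak_buffer_values: int = 0  # instrumentation: max temp floats allocated


def standardize_columns(A: np.ndarray) -> StandardizedSeries:
    """Remove each column's mean and scale to unit norm.

    Zero-variance columns cannot be standardized; they are excluded and
    recorded (``kept`` maps surviving columns back to the input).
    """
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] < 2:
        raise ValueError("need a 2D matrix with M >= 2 trials")
    centered = A - A.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    keep = norms > 0
    if not keep.all():
        logger.warning("excluding %d zero-variance columns", int((~keep).sum()))
    Z = centered[:, keep] / norms[keep]
    return StandardizedSeries(
        Z=Z, kept=np.nonzero(keep)[0], n_excluded=int((~keep).sum())
    )


def _stream(Z: np.ndarray, tau: float, mode: str, chunk: int):
    """One pass over all voxels: per voxel j, build its correlation row in
    column chunks, Fisher-z, threshold, accumulate degree and strength.
    Self-correlation is excluded before counting."""
    M, N = Z.shape
    degree = np.zeros(N, dtype=np.int64)
    strength = np.zeros(N, dtype=np.float64)
    peak = 0
    for j in range(N):
        zj = Z[:, j]
        for start in range(0, N, chunk):
            stop = min(start + chunk, N)
            r = zj @ Z[:, start:stop]
            peak = max(peak, M * (stop - start) + (stop - start))
            np.clip(r, -R_CLIP, R_CLIP, out=r)
            zvals = np.arctanh(r)
            if start <= j < stop:
                zvals[j - start] = 0.0  # exclude the self term
            surv = zvals > tau if mode == "positive" else np.abs(zvals) > tau
            degree[j] += int(surv.sum())
            strength[j] += float(zvals[surv].sum())
    return degree, strength, peak + N * 3  # + accumulators


def streaming_degree(
    series: StandardizedSeries,
    tau: float = DEFAULT_THRESHOLD,
    mode: str = "positive",
    chunk: int = DEFAULT_CHUNK,
) -> DegreeMap:
    """Voxel-wise degree map D_j = #{i != j : z_ij > tau} (positive mode) or
    |z_ij| > tau (absolute mode), computed without materializing the N x N
    matrix.  ``chunk`` only bounds memory; the result is chunk-invariant."""
    if tau <= 0:
        raise ValueError("threshold must be positive")
    if mode not in ("positive", "absolute"):
        raise ValueError(f"unknown mode {mode!r}")
    if chunk < 1:
        raise ValueError("chunk must be >= 1")
    degree, strength, peak = _stream(series.Z, tau, mode, chunk)
    return DegreeMap(
        degree=degree, strength=strength, threshold=tau, mode=mode,
        kept=series.kept, peak_buffer_values=peak,
    )


def streaming_strength(
    series: StandardizedSeries,
    tau: float = DEFAULT_THRESHOLD,
    mode: str = "positive",
    chunk: int = DEFAULT_CHUNK,
) -> DegreeMap:
    """Voxel-wise strength map S_j = sum of surviving Fisher-z weights
    (same streaming pass as :func:`streaming_degree`)."""
    return streaming_degree(series, tau, mode, chunk)


def fast_correlation_sum(series: StandardizedSeries) -> np.ndarray:
    """Associative shortcut S = Z.T @ (Z @ 1): per-voxel sum of ALL
    correlation coefficients, self term (=1) included.

    Extremely fast, but no thresholding or Fisher transform is possible and
    positive and negative correlations cancel — use with care.
    """
    Z = series.Z
    return Z.T @ (Z @ np.ones(Z.shape[1]))
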