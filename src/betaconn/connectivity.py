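"""Beta-series connectivity: Fisher-z math, ROI networks, seed maps.

Functional connectivity between two locations is the correlation of their
trial-wise amplitude series.  All stored connectivity values are Fisher
z-transformed (z = atanh(r), r clipped to |r| <= 1 - 1e-7 so maps stay
finite); with N trials the z values are approximately normal with standard
error 1/sqrt(N-3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import Atlas, BetaSeriesImage, VolumeMap

logger = logging.getLogger("betaconn")

R_CLIP = 1.0 - 1e-7
Z_CLIP = float(np.arctanh(R_CLIP))  # ~8.4, the largest representable z


@dataclass
class RoiBetaSeries:
    """trials x ROI matrix of mean beta values for one condition."""

    values: np.ndarray
    labels: list
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.shape[1] != len(self.labels):
            raise ValueError("label count != ROI count")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric node x node Fisher-z matrix, zero diagonal."""

    values: np.ndarray
    labels: list
    method: str = "pearson"
    condition: str = ""
    n_trials: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# Fisher transform
# ---------------------------------------------------------------------------

def fisher_z(r):
    """z = atanh(r) = 0.5*ln((1+r)/(1-r)), r clipped to +-(1 - 1e-7) first."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlation outside [-1, 1]")
    out = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    return out if out.ndim else float(out)


def fisher_z_inverse(z):
    """r = tanh(z); inverse of :func:`fisher_z` away from the clip boundary."""
    out = np.tanh(np.asarray(z, dtype=np.float64))
    return out if out.ndim else float(out)


def beta_series_sem(n_trials: int) -> float:
    """Standard error of a Fisher-z correlation from N trials: 1/sqrt(N-3)."""
    if n_trials <= 3:
        raise ValueError(f"need N > 3 trials, got {n_trials}")
    return 1.0 / np.sqrt(n_trials - 3)


# ---------------------------------------------------------------------------
# Matrices and maps
# ---------------------------------------------------------------------------

def correlation_matrix(series: RoiBetaSeries, method: str = "pearson") -> ConnectivityMatrix:
    """Pairwise Fisher-z connectivity between ROI beta-series.

    Spearman is Pearson on average-ranked data.  Zero-variance columns get
    missing (NaN) off-diagonal entries with a logged warning.  The diagonal
    is forced to 0 and the matrix is exactly symmetric.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    X = series.values
    if X.shape[0] < 4:
        raise ValueError("need N >= 4 trials for a usable correlation")
    if method == "spearman":
        X = np.apply_along_axis(rankdata, 0, X)
    sd = X.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "%d zero-variance ROI series -> entries set missing", int(degenerate.sum())
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.atleast_2d(r)
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    ok = ~np.isnan(r)
    z = np.full_like(r, np.nan)
    z[ok] = fisher_z(r[ok])
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(
        values=z,
        labels=list(series.labels),
        method=method,
        condition=series.condition,
        n_trials=series.n_trials,
    )


def roi_mean_series(betas: BetaSeriesImage, atlas: Atlas) -> RoiBetaSeries:
    """Mean beta-series per atlas region (over in-mask valid voxels).

    Regions with no valid voxel inside the analysis mask are dropped with a
    warning.
    """
    if atlas.labels.shape != tuple(betas.shape):
        raise ValueError("atlas geometry does not match beta-series grid")
    flat_labels = atlas.labels.reshape(-1)[betas.voxel_indices]
    flat_labels = np.where(betas.valid, flat_labels, 0)
    means, labels = [], []
    for rid in atlas.region_ids:
        cols = flat_labels == rid
        if not cols.any():
            logger.warning("ROI %s has no valid voxels; dropped", atlas.names[int(rid)])
            continue
        means.append(betas.values[:, cols].mean(axis=1))
        labels.append(atlas.names[int(rid)])
    if not means:
        raise ValueError("no ROI overlaps the analysis mask")
    return RoiBetaSeries(
        values=np.column_stack(means), labels=labels, condition=betas.condition
    )


def sphere_roi(center_mm, radius_mm: float, shape, affine) -> VolumeMap:
    """Binary sphere mask: voxels whose center lies within ``radius_mm`` (mm,
    inclusive) of ``center_mm``."""
    shape = tuple(shape)
    affine = np.asarray(affine, dtype=np.float64)
    center = np.asarray(center_mm, dtype=np.float64)
    # voxel index of the center; must land inside the volume
    ijk = np.linalg.inv(affine) @ np.append(center, 1.0)
    if np.any(ijk[:3] < -0.5) or np.any(ijk[:3] > np.asarray(shape) - 0.5):
        raise ValueError(f"sphere center {center_mm} outside volume bounds")
    grid = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    mm = grid @ affine[:3, :3].T + affine[:3, 3]
    inside = np.sum((mm - center) ** 2, axis=1) <= radius_mm**2 + 1e-9
    if not inside.any():
        raise ValueError("sphere contains no voxel centers; increase radius")
    return VolumeMap(
        data=inside.reshape(shape).astype(np.uint8), affine=affine, kind="mask"
    )


def seed_connectivity_map(
    betas: BetaSeriesImage, seed: VolumeMap, target: VolumeMap | None = None
) -> VolumeMap:
    """Fisher-z map of the mean seed beta-series against every target voxel.

    Voxels outside the target mask (default: all valid analysis voxels) are
    NaN.
    """
    if betas.n_trials < 4:
        raise ValueError("need N >= 4 trials")
    flat_seed = seed.data.reshape(-1)[betas.voxel_indices] > 0
    flat_seed &= betas.valid
    if not flat_seed.any():
        raise ValueError("empty seed after masking")
    seed_series = betas.values[:, flat_seed].mean(axis=1)

    if target is None:
        in_target = betas.valid.copy()
    else:
        in_target = (target.data.reshape(-1)[betas.voxel_indices] > 0) & betas.valid

    Y = betas.values[:, in_target]
    s = seed_series - seed_series.mean()
    s_norm = np.linalg.norm(s)
    Yc = Y - Y.mean(axis=0)
    denom = s_norm * np.linalg.norm(Yc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (s @ Yc) / denom
    r[denom == 0] = np.nan
    z = np.full(r.shape, np.nan)
    ok = ~np.isnan(r)
    z[ok] = fisher_z(r[ok])

    out = np.full(int(np.prod(betas.shape)), np.nan)
    out[betas.voxel_indices[in_target]] = z
    return VolumeMap(data=out.reshape(betas.shape), affine=betas.affine, kind="z")


def edge_count(n_nodes: int) -> int:
    """Unique edges in a symmetric matrix of n nodes: n*(n-1)/2."""
    if n_nodes < 1:
        raise ValueError("need at least one node")
    return n_nodes * (n_nodes - 1) // 2
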