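"""Trial-wise GLM estimation and beta-series extraction.

The model is Y = X b + e per voxel, estimated by ordinary least squares,
optionally after AR(1) prewhitening with a single pooled autocorrelation
coefficient (estimated from OLS residuals over all in-mask voxels and runs).
With HRF derivatives in the model, the three per-trial betas are combined
into a signed "amplitude of effect":  sign(b1) * sqrt(b1^2 + b2^2 + b3^2),
with sign(0) = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignMatrix
from .io_formats import BetaSeriesImage, TimeSeriesImage, VolumeMap

logger = logging.getLogger("betaconn")


@dataclass
class GlmEstimates:
    """Per-voxel least-squares estimates over the analysis mask."""

    betas: np.ndarray          # columns x voxels
    residuals: np.ndarray      # scans x voxels
    design: DesignMatrix
    voxel_indices: np.ndarray  # flat index into the 3D grid
    shape: tuple
    affine: np.ndarray
    valid: np.ndarray          # False where the series was degenerate
    ar_coefficient: float | None = None


def _stack_runs(bold) -> tuple:
    """Concatenate one or more runs along time; returns (Y 2D stacked over
    scans x all grid voxels flattened, shape, affine)."""
    runs = [bold] if isinstance(bold, TimeSeriesImage) else list(bold)
    shape = runs[0].shape
    affine = runs[0].affine
    for r in runs:
        if r.shape != shape:
            raise ValueError("runs differ in grid shape")
    data = np.concatenate([r.data.reshape(-1, r.n_scans).T for r in runs], axis=0)
    return data, shape, affine


def fit_ols(bold, design: DesignMatrix, mask: VolumeMap) -> GlmEstimates:
    """Ordinary least squares fit of ``design`` to every in-mask voxel.

    ``bold`` is a :class:`TimeSeriesImage` or a list of runs ordered like the
    design's runs.  Voxels with zero temporal variance are flagged invalid
    and get NaN betas.  Uses the pseudo-inverse, so rank-deficient designs
    produce the minimum-norm solution (warning logged).
    """
    Y_all, shape, affine = _stack_runs(bold)
    if Y_all.shape[0] != design.n_scans:
        raise ValueError(
            f"scan count mismatch: data {Y_all.shape[0]}, design {design.n_scans}"
        )
    if mask.shape != shape:
        raise ValueError("mask geometry does not match BOLD")
    voxel_indices = np.nonzero(mask.data.reshape(-1) > 0)[0]
    Y = Y_all[:, voxel_indices]

    X = design.matrix
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning(
            "design rank-deficient (%d < %d); using pseudo-inverse", rank, X.shape[1]
        )
    pinv = np.linalg.pinv(X)
    betas = pinv @ Y
    residuals = Y - X @ betas

    valid = Y.std(axis=0) > 0
    if not valid.all():
        logger.warning("%d zero-variance voxels flagged inside mask",
                       int((~valid).sum()))
        betas[:, ~valid] = np.nan
        residuals[:, ~valid] = np.nan
    return GlmEstimates(
        betas=betas, residuals=residuals, design=design,
        voxel_indices=voxel_indices, shape=shape, affine=affine, valid=valid,
    )


def estimate_ar1(residuals: np.ndarray, run_lengths=None, design=None) -> float:
    """Pooled lag-1 autocorrelation of residuals.

    rho = sum_t r_t r_{t-1} / sum_t r_t^2, summed over all voxels and within
    run boundaries (the lag never crosses a run junction), clipped to
    (-0.99, 0.99).

    OLS residuals are a projection of the true errors, which biases their
    raw lag-1 ratio toward zero (the more design columns per scan, the
    stronger the shrinkage).  Pass ``design`` (a :class:`DesignMatrix` or
    plain matrix) to invert that bias: the returned rho is then the AR(1)
    coefficient whose projected covariance reproduces the observed ratio
    (moment matching on tr(L P V P) / tr(P V P)).
    """
    r = np.atleast_2d(np.asarray(residuals, dtype=np.float64))
    if r.shape[0] == 1 and r.shape[1] > 1 and residuals.ndim == 1:
        r = r.T
    r = r[:, ~np.any(np.isnan(r), axis=0)] if np.isnan(r).any() else r
    if r.shape[0] < 3:
        raise ValueError("need at least 3 scans to estimate AR(1)")
    if run_lengths is None:
        run_lengths = [r.shape[0]]
    num = 0.0
    den = float(np.sum(r * r))
    if den == 0:
        raise ValueError("zero-variance residuals")
    start = 0
    for n in run_lengths:
        block = r[start : start + n]
        num += float(np.sum(block[1:] * block[:-1]))
        start += n
    raw = float(np.clip(num / den, -0.99, 0.99))
    if design is None:
        return raw
    X = design.matrix if isinstance(design, DesignMatrix) else np.asarray(design)
    return _debias_ar1(raw, X, run_lengths)


def _debias_ar1(observed: float, X: np.ndarray, run_lengths) -> float:
    """Solve for the AR(1) rho whose OLS-projected covariance yields the
    observed residual lag-1 ratio: observed = tr(L P V(rho) P) / tr(P V(rho) P)
    with P the residual projector and L the within-run lag-1 operator."""
    from scipy.optimize import brentq

    n = X.shape[0]
    P = np.eye(n) - X @ np.linalg.pinv(X)
    L = np.zeros((n, n))
    start = 0
    for m in run_lengths:
        idx = np.arange(start + 1, start + m)
        L[idx, idx - 1] = 1.0
        start += m

    def expected(rho: float) -> float:
        V = np.zeros((n, n))
        s = 0
        for m in run_lengths:
            t = np.arange(m)
            V[s : s + m, s : s + m] = rho ** np.abs(t[:, None] - t[None, :])
            s += m
        C = P @ V @ P
        return float(np.trace(L @ C) / np.trace(C))

    lo, hi = -0.95, 0.95
    try:
        if (expected(lo) - observed) * (expected(hi) - observed) > 0:
            return float(np.clip(observed, -0.99, 0.99))  # outside invertible range
        return float(brentq(lambda r: expected(r) - observed, lo, hi, xtol=1e-4))
    except Exception:  # pragma: no cover - numerical fallback
        return float(np.clip(observed, -0.99, 0.99))


def _whiten_rows(M: np.ndarray, rho: float, run_lengths) -> np.ndarray:
    """AR(1) whitening per run block: first row scaled by sqrt(1-rho^2),
    remaining rows y_t - rho*y_{t-1}."""
    out = np.empty_like(M, dtype=np.float64)
    start = 0
    for n in run_lengths:
        block = M[start : start + n]
        out[start] = np.sqrt(1.0 - rho**2) * block[0]
        out[start + 1 : start + n] = block[1:] - rho * block[:-1]
        start += n
    return out


def prewhiten_fit(bold, design: DesignMatrix, rho: float) -> GlmEstimates:
    """OLS on the AR(1)-whitened system (rows of Y and X transformed per run).

    With rho = 0 this reduces exactly to :func:`fit_ols`.  The transform is
    one-way: whitening with rho then -rho does not return the original data.
    Residuals are returned on the whitened scale (that is what the AR(1)
    re-estimate should see).
    """
    if not -1 < rho < 1:
        raise ValueError(f"AR(1) coefficient must lie in (-1, 1), got {rho}")
    Y_all, shape, affine = _stack_runs(bold)
    run_lengths = list(design.run_scans.values())
    if Y_all.shape[0] != design.n_scans:
        raise ValueError("scan count mismatch")
    Yw = _whiten_rows(Y_all, rho, run_lengths)
    Xw = _whiten_rows(design.matrix, rho, run_lengths)

    voxel_indices = np.arange(Y_all.shape[1])
    pinv = np.linalg.pinv(Xw)
    betas = pinv @ Yw
    residuals = Yw - Xw @ betas
    valid = Y_all.std(axis=0) > 0
    betas[:, ~valid] = np.nan
    residuals[:, ~valid] = np.nan
    return GlmEstimates(
        betas=betas, residuals=residuals, design=design,
        voxel_indices=voxel_indices, shape=shape, affine=affine, valid=valid,
        ar_coefficient=rho,
    )


def fit_glm(bold, design: DesignMatrix, mask: VolumeMap, ar1: bool = True) -> GlmEstimates:
    """Two-pass fit: OLS, then (optionally) AR(1) estimation from the OLS
    residuals and a prewhitened refit restricted to the mask."""
    est = fit_ols(bold, design, mask)
    if not ar1:
        return est
    resid = est.residuals[:, est.valid]
    rho = estimate_ar1(resid, run_lengths=list(design.run_scans.values()),
                       design=design)
    Y_all, shape, affine = _stack_runs(bold)
    run_lengths = list(design.run_scans.values())
    Yw = _whiten_rows(Y_all[:, est.voxel_indices], rho, run_lengths)
    Xw = _whiten_rows(design.matrix, rho, run_lengths)
    betas = np.linalg.pinv(Xw) @ Yw
    residuals = Yw - Xw @ betas
    betas[:, ~est.valid] = np.nan
    residuals[:, ~est.valid] = np.nan
    return GlmEstimates(
        betas=betas, residuals=residuals, design=design,
        voxel_indices=est.voxel_indices, shape=shape, affine=affine,
        valid=est.valid, ar_coefficient=rho,
    )


def amplitude_of_effect(b1, b2, b3):
    """Signed amplitude combining canonical and derivative betas:
    sign(b1) * sqrt(b1^2 + b2^2 + b3^2), with sign(0) = 0."""
    b1 = np.asarray(b1, dtype=np.float64)
    b2 = np.asarray(b2, dtype=np.float64)
    b3 = np.asarray(b3, dtype=np.float64)
    out = np.sign(b1) * np.sqrt(b1**2 + b2**2 + b3**2)
    return out if out.ndim else float(out)


def extract_beta_series(
    est: GlmEstimates, design: DesignMatrix, condition: str
) -> BetaSeriesImage:
    """Pull the per-trial betas for one condition, ordered by (run, onset).

    If the design includes HRF derivatives, each trial's value is the
    amplitude-of-effect combination of its three betas; otherwise it is the
    canonical beta alone.
    """
    if condition not in design.conditions:
        raise ValueError(f"condition {condition!r} not in design")
    hrf_idx = design.trial_columns(condition, basis="hrf")
    has_deriv = any(c.basis == "tderiv" for c in design.columns)
    if has_deriv:
        td_idx = design.trial_columns(condition, basis="tderiv")
        dd_idx = design.trial_columns(condition, basis="dderiv")
        values = amplitude_of_effect(
            est.betas[hrf_idx], est.betas[td_idx], est.betas[dd_idx]
        )
    else:
        values = est.betas[hrf_idx]
    info = pd.DataFrame(
        {
            "run": [design.columns[i].run for i in hrf_idx],
            "onset": [design.columns[i].onset for i in hrf_idx],
            "trial_index": [design.columns[i].trial_index for i in hrf_idx],
        }
    )
    return BetaSeriesImage(
        values=np.asarray(values),
        condition=condition,
        voxel_indices=est.voxel_indices,
        shape=est.shape,
        affine=est.affine,
        valid=est.valid,
        trial_info=info,
    )


def flag_outlier_trials(series, threshold: float = 3.5) -> np.ndarray:
    """Robust-z outlier flags per trial.

    A trial is flagged when |b_i - median| > threshold * 1.4826 * MAD.
    For 2D input (trials x units) flags are computed per column.  A constant
    series (MAD = 0) yields no flags.
    """
    x = np.asarray(getattr(series, "values", series), dtype=np.float64)
    if x.shape[0] < 5:
        raise ValueError("need at least 5 trials to flag outliers")
    med = np.median(x, axis=0, keepdims=True)
    mad = np.median(np.abs(x - med), axis=0, keepdims=True)
    scale = 1.4826 * mad
    dev = np.abs(x - med)
    with np.errstate(divide="ignore", invalid="ignore"):
        robust_z = dev / scale
    # MAD = 0: the majority of trials are identical; any deviation from the
    # median has infinite robust z, an all-equal series flags nothing
    flags = np.where(scale > 0, robust_z > threshold, dev > 0)
    return flags
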