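"""Trial-wise GLM design construction.

Each trial gets its own regressor: a boxcar of the event duration at
microtime resolution (default 16 bins per TR), convolved with the canonical
double-gamma hemodynamic response function (optionally with its temporal and
dispersion derivatives), then sampled at the middle microtime bin of every
scan.  Runs are concatenated into one model with block-diagonal per-run
motion and discrete-cosine high-pass columns (the DCT block includes the
per-run constant).  The default high-pass cutoff is 128 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .io_formats import ConfoundSet

HRF_LENGTH_S = 32.0
#: double-gamma shape parameters: response peak ~5 s, undershoot ~15 s
_PEAK_DELAY = 6.0
_UNDERSHOOT_DELAY = 16.0
_PEAK_DISP = 1.0
_UNDERSHOOT_DISP = 1.0
_UNDERSHOOT_RATIO = 1.0 / 6.0


# ---------------------------------------------------------------------------
# HRF kernels
# ---------------------------------------------------------------------------

@dataclass
class HrfKernel:
    """An impulse-response kernel sampled every ``dt`` seconds over 32 s."""

    values: np.ndarray
    dt: float
    kind: str = "canonical"

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt


def _double_gamma(t: np.ndarray, peak_disp: float) -> np.ndarray:
    h = gamma_dist.pdf(t, _PEAK_DELAY / peak_disp, scale=peak_disp)
    h -= _UNDERSHOOT_RATIO * gamma_dist.pdf(
        t, _UNDERSHOOT_DELAY / _UNDERSHOOT_DISP, scale=_UNDERSHOOT_DISP
    )
    return h


def canonical_hrf(dt: float) -> HrfKernel:
    """Canonical double-gamma HRF at resolution ``dt``, normalized to unit sum.

    Peak ~5 s after onset, undershoot ~15 s, total support 32 s
    (32/dt + 1 samples).
    """
    if not 0 < dt <= 1:
        raise ValueError(f"dt must be in (0, 1], got {dt}")
    t = np.arange(0, HRF_LENGTH_S + dt / 2, dt)
    h = _double_gamma(t, _PEAK_DISP)
    return HrfKernel(values=h / h.sum(), dt=dt, kind="canonical")


def hrf_derivatives(dt: float) -> tuple:
    """Temporal and dispersion derivatives of the canonical HRF.

    Temporal: backward difference of the (unit-sum) canonical against itself
    shifted by 1 s.  Dispersion: finite difference against a kernel whose
    peak dispersion is widened to 1.01, divided by 0.01; both kernels share
    the canonical's normalization constant so the perturbation is pure.
    """
    can = canonical_hrf(dt)
    shift = int(round(1.0 / dt))
    shifted = np.zeros_like(can.values)
    shifted[shift:] = can.values[: can.values.size - shift]
    tderiv = (can.values - shifted) / 1.0

    t = can.times
    norm = _double_gamma(t, _PEAK_DISP).sum()
    widened = _double_gamma(t, 1.01) / norm
    dderiv = (can.values - widened) / 0.01
    return (
        HrfKernel(values=tderiv, dt=dt, kind="temporal-derivative"),
        HrfKernel(values=dderiv, dt=dt, kind="dispersion-derivative"),
    )


# ---------------------------------------------------------------------------
# High-pass filter basis
# ---------------------------------------------------------------------------

def dct_basis(n_scans: int, tr: float, cutoff: float) -> np.ndarray:
    """Orthonormal discrete-cosine high-pass basis (constant included).

    K = floor(2 * n_scans * tr / cutoff + 1) columns; column k is
    cos(pi k (2t+1) / (2 n)) scaled to unit norm.  Frequencies above the
    basis span are what the high-pass filter removes when these columns
    are included in the design.
    """
    if cutoff <= 2 * tr:
        raise ValueError(
            f"cutoff {cutoff}s too small for TR {tr}s (must exceed 2*TR)"
        )
    n = int(n_scans)
    K = int(np.floor(2.0 * n * tr / cutoff + 1))
    K = min(K, n)
    t = np.arange(n)
    basis = np.empty((n, K))
    basis[:, 0] = 1.0 / np.sqrt(n)
    for k in range(1, K):
        basis[:, k] = np.sqrt(2.0 / n) * np.cos(np.pi * k * (2 * t + 1) / (2 * n))
    return basis


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

@dataclass
class ColumnInfo:
    """Metadata for one design column."""

    name: str
    kind: str  # trial | motion | confound | dct
    run: int
    condition: str | None = None
    trial_index: int | None = None
    basis: str | None = None  # hrf | tderiv | dderiv
    onset: float | None = None


@dataclass
class DesignMatrix:
    """scans x regressors matrix with labeled columns, runs concatenated."""

    matrix: np.ndarray
    columns: list
    tr: float
    run_scans: dict = field(default_factory=dict)

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def conditions(self) -> list:
        seen = []
        for c in self.columns:
            if c.kind == "trial" and c.condition not in seen:
                seen.append(c.condition)
        return seen

    def trial_columns(self, condition: str | None = None, basis: str = "hrf"):
        """Indices of trial columns (one basis), ordered by (run, onset)."""
        idx = [
            (c.run, c.onset, i)
            for i, c in enumerate(self.columns)
            if c.kind == "trial"
            and c.basis == basis
            and (condition is None or c.condition == condition)
        ]
        idx.sort()
        return [i for _, _, i in idx]

    def n_trials(self, condition: str | None = None) -> int:
        return len(self.trial_columns(condition))

    def run_slice(self, run: int) -> slice:
        start = 0
        for r, n in self.run_scans.items():
            if r == run:
                return slice(start, start + n)
            start += n
        raise KeyError(f"run {run} not in design")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=[c.name for c in self.columns])


def trial_regressor(
    onset: float,
    duration: float,
    n_scans: int,
    tr: float,
    kernel: HrfKernel,
    microtime_bins: int = 16,
) -> np.ndarray:
    """One trial's regressor: microtime boxcar (impulse if duration 0)
    convolved with ``kernel``, sampled at the middle microtime bin of
    each scan."""
    dt = tr / microtime_bins
    n_bins = n_scans * microtime_bins
    onset_bin = int(round(onset / dt))
    stim = np.zeros(n_bins)
    if duration <= 0:
        stim[onset_bin] = 1.0
    else:
        stop = min(onset_bin + int(round(duration / dt)), n_bins)
        stim[onset_bin:stop] = 1.0
    conv = np.convolve(stim, kernel.values)[:n_bins]
    sample_at = np.arange(n_scans) * microtime_bins + microtime_bins // 2
    return conv[sample_at]


def build_design(
    events: pd.DataFrame,
    confounds: list | None,
    n_scans: list | dict,
    tr: float,
    derivatives: bool = False,
    cutoff: float = 128.0,
    microtime_bins: int = 16,
) -> DesignMatrix:
    """Build the concatenated trial-wise design matrix.

    Parameters
    ----------
    events : canonical event table (see :func:`betaconn.io_formats.read_events`).
    confounds : per-run :class:`ConfoundSet` (list ordered like runs, or None).
    n_scans : per-run scan counts, dict {run: n} or list ordered by run id.
    derivatives : add temporal + dispersion derivative columns per trial.
    cutoff : DCT high-pass cutoff in seconds (constant column included).
    """
    if len(events) == 0:
        raise ValueError("no trials in events table")
    runs = sorted(events["run"].unique())
    if isinstance(n_scans, dict):
        run_scans = {int(r): int(n_scans[r]) for r in runs}
    else:
        if len(n_scans) != len(runs):
            raise ValueError("n_scans length != number of runs")
        run_scans = {int(r): int(n) for r, n in zip(runs, n_scans)}
    if confounds is not None:
        if len(confounds) != len(runs):
            raise ValueError("confounds length != number of runs")
        for r, c in zip(runs, confounds):
            if c.n_scans != run_scans[int(r)]:
                raise ValueError(
                    f"run {r}: {c.n_scans} confound rows != {run_scans[int(r)]} scans"
                )

    dt = tr / microtime_bins
    hrf = canonical_hrf(dt)
    kernels = [("hrf", hrf)]
    if derivatives:
        td, dd = hrf_derivatives(dt)
        kernels += [("tderiv", td), ("dderiv", dd)]

    total = sum(run_scans.values())
    trial_blocks, trial_cols = [], []
    offset = 0
    for r in runs:
        n = run_scans[int(r)]
        run_events = events[events["run"] == r]
        run_len_s = n * tr
        for _, ev in run_events.iterrows():
            if ev["onset"] + ev["duration"] > run_len_s:
                raise ValueError(
                    f"trial at onset {ev['onset']}s (run {r}) extends past run end"
                )
            for basis, kern in kernels:
                col = np.zeros(total)
                col[offset : offset + n] = trial_regressor(
                    ev["onset"], ev["duration"], n, tr, kern, microtime_bins
                )
                trial_blocks.append(col)
                trial_cols.append(
                    ColumnInfo(
                        name=f"trial_r{r}_t{int(ev['trial_index'])}_{basis}",
                        kind="trial",
                        run=int(r),
                        condition=str(ev["condition"]),
                        trial_index=int(ev["trial_index"]),
                        basis=basis,
                        onset=float(ev["onset"]),
                    )
                )
        offset += n

    nuisance_blocks, nuisance_cols = [], []
    offset = 0
    for ri, r in enumerate(runs):
        n = run_scans[int(r)]
        if confounds is not None:
            vals = confounds[ri].values
            for j, label in enumerate(confounds[ri].columns):
                col = np.zeros(total)
                col[offset : offset + n] = vals[:, j]
                kind = "motion" if label in ("x", "y", "z", "pitch", "roll", "yaw") else "confound"
                nuisance_blocks.append(col)
                nuisance_cols.append(
                    ColumnInfo(name=f"{label}_r{r}", kind=kind, run=int(r))
                )
        dct = dct_basis(n, tr, cutoff)
        for k in range(dct.shape[1]):
            col = np.zeros(total)
            col[offset : offset + n] = dct[:, k]
            nuisance_blocks.append(col)
            nuisance_cols.append(
                ColumnInfo(name=f"dct{k}_r{r}", kind="dct", run=int(r))
            )
        offset += n

    matrix = np.column_stack(trial_blocks + nuisance_blocks)
    return DesignMatrix(
        matrix=matrix,
        columns=trial_cols + nuisance_cols,
        tr=tr,
        run_scans=run_scans,
    )
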