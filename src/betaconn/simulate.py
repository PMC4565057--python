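"""Synthetic event-related BOLD generator with known ground truth.

The forward model mirrors the analysis GLM: each region's signal is the sum
of per-trial regressors (boxcar convolved with the canonical HRF) weighted
by that trial's ground-truth amplitude, drawn from a multivariate normal
whose covariance sets the *true* inter-regional amplitude correlation.  On
top of the signal sit AR(1) noise (independent across voxels), a slow
sinusoidal drift (period well above the 128 s high-pass cutoff scale, so
the DCT filter removes it), and optional motion-coupled artifacts.

Defaults mirror a slow event-related paradigm: TR 2 s, 6 s stimulus, 10 s
fixation, 3 runs, 4 conditions, 8 trials/condition/run — i.e. 24 beta
values per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import canonical_hrf, trial_regressor
from .io_formats import (
    Atlas,
    ConfoundSet,
    TimeSeriesImage,
    VolumeMap,
    make_event_table,
)

DEFAULT_CONDITIONS = (
    "emotional_single",
    "emotional_social",
    "neutral_single",
    "neutral_social",
)


@dataclass
class SimulationSpec:
    """All knobs of the generator; ``seed`` fixes every random draw."""

    runs: int = 3
    trials_per_condition_per_run: int = 8
    conditions: tuple = DEFAULT_CONDITIONS
    stimulus_s: float = 6.0
    iti_s: float = 10.0
    tr: float = 2.0
    grid_shape: tuple = (12, 12, 6)
    n_regions: int = 4
    amplitude_means: float | np.ndarray = 1.0
    amplitude_cov: np.ndarray | None = None  # regions x regions; default 0.25*I
    noise_sd: float = 0.5
    ar_rho: float = 0.3
    drift_amplitude: float = 1.0
    drift_period_s: float = 256.0
    motion_coupling: float = 0.0
    pad_scans: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iti_s < self.tr:
            raise ValueError("inter-trial interval must be >= TR")
        if self.amplitude_cov is not None:
            cov = np.asarray(self.amplitude_cov, dtype=float)
            if cov.shape != (self.n_regions, self.n_regions):
                raise ValueError("amplitude_cov must be regions x regions")
            eigs = np.linalg.eigvalsh((cov + cov.T) / 2)
            if eigs.min() < -1e-10:
                raise ValueError("amplitude covariance is not PSD")
            self.amplitude_cov = cov

    @property
    def trial_slot_s(self) -> float:
        return self.stimulus_s + self.iti_s

    @property
    def trials_per_run(self) -> int:
        return self.trials_per_condition_per_run * len(self.conditions)

    @property
    def n_trials_per_condition(self) -> int:
        return self.trials_per_condition_per_run * self.runs

    @property
    def scans_per_run(self) -> int:
        return int(np.ceil(self.trials_per_run * self.trial_slot_s / self.tr)) + self.pad_scans

    def cov(self) -> np.ndarray:
        if self.amplitude_cov is not None:
            return self.amplitude_cov
        return 0.25 * np.eye(self.n_regions)

    def means(self) -> np.ndarray:
        m = np.asarray(self.amplitude_means, dtype=float)
        if m.ndim == 0:
            return np.full((len(self.conditions), self.n_regions), float(m))
        if m.shape == (len(self.conditions), self.n_regions):
            return m
        raise ValueError("amplitude_means must be scalar or conditions x regions")


@dataclass
class TrialAmplitudes:
    """Ground-truth per-trial amplitudes: {condition: (trials, regions)}."""

    per_condition: dict

    def __getitem__(self, condition: str) -> np.ndarray:
        return self.per_condition[condition]


@dataclass
class SimulatedDataset:
    runs: list                      # TimeSeriesImage per run
    events: pd.DataFrame
    confounds: list                 # ConfoundSet per run
    atlas: Atlas
    mask: VolumeMap
    amplitudes: TrialAmplitudes
    spec: SimulationSpec


def phantom_atlas(grid_shape, n_regions: int) -> Atlas:
    """Deterministic phantom parcellation: disjoint equal-size cuboids.

    The grid is split into blocks along the axes (factorizing ``n_regions``
    greedily), so regions tile part of the volume without overlap and have
    identical voxel counts.
    """
    shape = tuple(int(s) for s in grid_shape)
    # factor n_regions into (fx, fy, fz) that fit the grid
    best = None
    for fx in range(1, n_regions + 1):
        if n_regions % fx:
            continue
        rem = n_regions // fx
        for fy in range(1, rem + 1):
            if rem % fy:
                continue
            fz = rem // fy
            if fx <= shape[0] and fy <= shape[1] and fz <= shape[2]:
                score = max(fx, fy, fz)
                if best is None or score < best[0]:
                    best = (score, fx, fy, fz)
    if best is None:
        raise ValueError(f"cannot tile {n_regions} regions into grid {shape}")
    _, fx, fy, fz = best
    bx, by, bz = shape[0] // fx, shape[1] // fy, shape[2] // fz
    labels = np.zeros(shape, dtype=np.int32)
    rid = 1
    for i in range(fx):
        for j in range(fy):
            for k in range(fz):
                labels[i * bx : (i + 1) * bx, j * by : (j + 1) * by,
                       k * bz : (k + 1) * bz] = rid
                rid += 1
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    affine[:3, 3] = -1.5 * (np.asarray(shape) - 1)
    names = {i: f"Region_{i}" for i in range(1, n_regions + 1)}
    return Atlas(labels=labels, affine=affine, names=names)


def simulate_amplitudes(spec: SimulationSpec) -> TrialAmplitudes:
    """Draw ground-truth trial amplitudes per condition: multivariate normal
    across regions with the spec's mean and covariance; fully seeded."""
    rng = np.random.default_rng([spec.seed % (2**31), 11])
    cov = spec.cov()
    means = spec.means()
    n = spec.n_trials_per_condition
    per_condition = {
        cond: rng.multivariate_normal(means[ci], cov, size=n, method="cholesky"
                                      if _is_pd(cov) else "svd")
        for ci, cond in enumerate(spec.conditions)
    }
    return TrialAmplitudes(per_condition=per_condition)


def _is_pd(cov: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(cov)
        return True
    except np.linalg.LinAlgError:
        return False


def _schedule(spec: SimulationSpec, rng) -> pd.DataFrame:
    """Random interleaving of conditions within each run, fixed slot timing."""
    rows = []
    for run in range(1, spec.runs + 1):
        order = np.repeat(np.arange(len(spec.conditions)),
                          spec.trials_per_condition_per_run)
        rng.shuffle(order)
        for slot, ci in enumerate(order):
            rows.append(
                {
                    "onset": slot * spec.trial_slot_s,
                    "duration": spec.stimulus_s,
                    "condition": spec.conditions[ci],
                    "run": run,
                }
            )
    return make_event_table(pd.DataFrame(rows))


def simulate_dataset(
    spec: SimulationSpec, amplitudes: TrialAmplitudes | None = None
) -> SimulatedDataset:
    """Generate the full dataset: BOLD runs, events, motion, atlas, mask.

    Signal: per region r and trial k, amplitude[k, r] times the trial's
    HRF regressor, added to every voxel of the region.  Noise: stationary
    AR(1) per voxel (sd ``noise_sd``, coefficient ``ar_rho``).  Drift:
    sinusoid of period ``drift_period_s`` with a random phase per run.
    Motion: smooth random walks; ``motion_coupling`` scales how strongly the
    summed motion trace leaks into every voxel.
    """
    if amplitudes is None:
        amplitudes = simulate_amplitudes(spec)
    rng = np.random.default_rng([spec.seed % (2**31), 23])
    atlas = phantom_atlas(spec.grid_shape, spec.n_regions)
    events = _schedule(spec, rng)

    n_scans = spec.scans_per_run
    n_vox = int(np.prod(spec.grid_shape))
    flat_labels = atlas.labels.reshape(-1)
    kernel = canonical_hrf(spec.tr / 16)

    # per-condition trial counters (amplitude rows are consumed in
    # (run, onset) order, matching extract_beta_series ordering)
    counters = {c: 0 for c in spec.conditions}
    runs_out, confounds_out = [], []
    for run in range(1, spec.runs + 1):
        run_events = events[events["run"] == run]
        region_signal = np.zeros((n_scans, spec.n_regions))
        for _, ev in run_events.iterrows():
            reg = trial_regressor(ev["onset"], ev["duration"], n_scans,
                                  spec.tr, kernel)
            cond = ev["condition"]
            amp = amplitudes[cond][counters[cond]]
            counters[cond] += 1
            region_signal += np.outer(reg, amp)

        data = np.zeros((n_scans, n_vox))
        for r in range(spec.n_regions):
            data[:, flat_labels == r + 1] += region_signal[:, [r]]

        if spec.noise_sd > 0:
            innov_sd = spec.noise_sd * np.sqrt(1.0 - spec.ar_rho**2)
            e = rng.standard_normal((n_scans, n_vox)) * innov_sd
            noise = np.empty_like(e)
            noise[0] = e[0] / np.sqrt(1.0 - spec.ar_rho**2)
            for t in range(1, n_scans):
                noise[t] = spec.ar_rho * noise[t - 1] + e[t]
            data += noise

        t_s = np.arange(n_scans) * spec.tr
        if spec.drift_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi)
            data += spec.drift_amplitude * np.sin(
                2 * np.pi * t_s / spec.drift_period_s + phase
            )[:, None]

        motion = np.cumsum(rng.normal(0, 0.02, size=(n_scans, 6)), axis=0)
        if spec.motion_coupling:
            data += spec.motion_coupling * motion.sum(axis=1)[:, None]

        runs_out.append(
            TimeSeriesImage(
                data=data.T.reshape(spec.grid_shape + (n_scans,)),
                affine=atlas.affine,
                tr=spec.tr,
                run_id=run,
            )
        )
        confounds_out.append(ConfoundSet(values=motion, run_id=run))

    mask = VolumeMap(
        data=np.ones(spec.grid_shape, dtype=np.uint8),
        affine=atlas.affine,
        kind="mask",
    )
    return SimulatedDataset(
        runs=runs_out,
        events=events,
        confounds=confounds_out,
        atlas=atlas,
        mask=mask,
        amplitudes=amplitudes,
        spec=spec,
    )


def two_region_spec(rho: float, seed: int = 0, **overrides) -> SimulationSpec:
    """Convenience spec for correlation-recovery studies: the default
    event-related schedule (3 runs, 4 conditions, 8 trials/condition/run,
    so N = 24 per condition) with two regions whose trial amplitudes
    correlate at ``rho`` (unit variance) in every condition."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    defaults = dict(
        runs=3,
        trials_per_condition_per_run=8,
        grid_shape=(10, 10, 4),
        n_regions=2,
        amplitude_means=1.0,
        amplitude_cov=cov,
        noise_sd=0.5,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationSpec(**defaults)
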