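"""Reading and writing the file formats the pipeline touches.

Images are NIfTI-1 (via nibabel), event tables are BIDS-dialect TSV
(onset/duration in seconds from run start), motion parameters are
SPM ``rp_*.txt``-style whitespace-delimited text with six columns
(x, y, z translations in mm; pitch, roll, yaw rotations in rad),
and atlases are an integer NIfTI label volume plus an (id, name) TSV.

Voxel indices are 0-based; mm coordinates come from the affine
(RAS+ / MNI convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("betaconn")

MOTION_COLUMNS = ("x", "y", "z", "pitch", "roll", "yaw")

MAP_KINDS = ("mask", "z", "degree", "strength", "t", "q", "beta")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class TimeSeriesImage:
    """A 4D BOLD run: (x, y, z, scan) grid, voxel->mm affine, TR in seconds."""

    data: np.ndarray
    affine: np.ndarray
    tr: float
    run_id: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got {self.data.ndim}D")
        if self.data.shape[3] < 1:
            raise ValueError("need at least one scan")
        if not self.tr > 0:
            raise ValueError(f"TR must be positive, got {self.tr}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def n_scans(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple:
        return self.data.shape[:3]


@dataclass
class ConfoundSet:
    """Per-run nuisance regressors: six labeled motion columns plus extras."""

    values: np.ndarray
    columns: tuple = MOTION_COLUMNS
    run_id: int = 1

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        n_extra = self.values.shape[1] - len(MOTION_COLUMNS)
        if n_extra < 0:
            raise ValueError(
                f"expected >=6 motion columns, got {self.values.shape[1]}"
            )
        if len(self.columns) != self.values.shape[1]:
            self.columns = MOTION_COLUMNS + tuple(
                f"confound_{k}" for k in range(n_extra)
            )

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]


@dataclass
class Atlas:
    """Integer label volume (0 = background) with an id -> name table."""

    labels: np.ndarray
    affine: np.ndarray
    names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded):
                raise ValueError("atlas volume has non-integer labels")
            self.labels = rounded.astype(np.int32)
        present = self.region_ids
        missing = [int(i) for i in present if int(i) not in self.names]
        if missing:
            raise ValueError(f"labels missing from table: {missing}")

    @property
    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def region_count(self) -> int:
        return int(self.region_ids.size)

    def drop_regions(self, prefixes: tuple) -> "Atlas":
        """Return a copy with every region whose name starts with one of
        ``prefixes`` relabeled to background and dropped from the table."""
        drop = {i for i, n in self.names.items() if n.startswith(tuple(prefixes))}
        labels = self.labels.copy()
        labels[np.isin(labels, list(drop))] = 0
        names = {i: n for i, n in self.names.items() if i not in drop}
        return Atlas(labels=labels, affine=self.affine, names=names)


@dataclass
class VolumeMap:
    """A 3D scalar map sharing the geometry of its source image."""

    data: np.ndarray
    affine: np.ndarray
    kind: str = "mask"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D map, got {self.data.ndim}D")
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}")

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class BetaSeriesImage:
    """Per-condition trial-wise amplitude estimates over the analysis mask.

    ``values`` is (trials, voxels); ``voxel_indices`` maps each column to a
    flat index into the 3D grid of ``shape``; ``valid`` marks voxels whose
    GLM fit succeeded (non-degenerate time series).
    """

    values: np.ndarray
    condition: str
    voxel_indices: np.ndarray
    shape: tuple
    affine: np.ndarray
    valid: np.ndarray
    trial_info: pd.DataFrame | None = None

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def to_volumes(self) -> np.ndarray:
        """Scatter the series back onto the grid as a 4D (x,y,z,trial) array,
        NaN outside the mask."""
        out = np.full(self.shape + (self.n_trials,), np.nan)
        flat = out.reshape(-1, self.n_trials)
        flat[self.voxel_indices, :] = self.values.T
        return out


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_bold(path, tr: float | None = None, run_id: int = 1) -> TimeSeriesImage:
    """Load a 4D BOLD NIfTI. TR comes from the header unless overridden."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected 4D BOLD image, got {data.ndim}D: {path}")
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        if tr <= 0:
            raise ValueError(f"header TR missing/invalid in {path}; pass tr=")
    return TimeSeriesImage(data=data, affine=img.affine, tr=float(tr), run_id=run_id)


def read_events(path) -> pd.DataFrame:
    """Load a BIDS-dialect events TSV.

    Requires columns ``onset``, ``duration``, ``condition``; ``run`` defaults
    to 1. Rows are sorted by (run, onset) with the file order breaking ties,
    and ``trial_index`` is assigned 0.. in that order within each run.
    """
    df = pd.read_csv(path, sep="\t")
    return make_event_table(df)


def make_event_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize an events frame (see :func:`read_events`)."""
    df = df.copy()
    for col in ("onset", "duration", "condition"):
        if col not in df.columns:
            raise ValueError(f"events table missing mandatory column {col!r}")
    if "run" not in df.columns:
        df["run"] = 1
    if len(df) == 0:
        df["trial_index"] = pd.Series(dtype=int)
        return df.reset_index(drop=True)
    if (df["onset"] < 0).any():
        raise ValueError("negative onset in events table")
    if (df["duration"] < 0).any():
        raise ValueError("negative duration in events table")
    df = df.sort_values(["run", "onset"], kind="stable").reset_index(drop=True)
    df["trial_index"] = df.groupby("run").cumcount()
    df["run"] = df["run"].astype(int)
    return df


def read_motion(path, run_id: int = 1) -> ConfoundSet:
    """Load SPM-style motion parameters (>=6 whitespace-delimited columns)."""
    values = np.loadtxt(path, ndmin=2)
    if values.shape[1] < 6:
        raise ValueError(
            f"expected >=6 motion columns, got {values.shape[1]}: {path}"
        )
    return ConfoundSet(values=values, run_id=run_id)


def load_atlas(label_image, label_table) -> Atlas:
    """Load an atlas from a NIfTI label volume and an (id, name) TSV."""
    img = nib.load(str(label_image))
    table = pd.read_csv(label_table, sep="\t")
    if not {"id", "name"} <= set(table.columns):
        raise ValueError("atlas table needs 'id' and 'name' columns")
    names = {int(i): str(n) for i, n in zip(table["id"], table["name"])}
    atlas = Atlas(labels=np.asanyarray(img.dataobj), affine=img.affine, names=names)
    logger.info("loaded atlas with %d regions", atlas.region_count)
    return atlas


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_map(vmap: VolumeMap, path) -> Path:
    """Write a 3D map as NIfTI-1; values (incl. NaN) round-trip exactly."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vmap.data, dtype=np.float64), vmap.affine)
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))
    return path


def read_map(path, kind: str = "z") -> VolumeMap:
    img = nib.load(str(path))
    return VolumeMap(data=np.asanyarray(img.dataobj), affine=img.affine, kind=kind)


def write_bold(image: TimeSeriesImage, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(image.data, image.affine)
    img.header.set_data_dtype(np.float64)
    zooms = list(img.header.get_zooms())
    zooms[3] = image.tr
    img.header.set_zooms(zooms)
    img.header["pixdim"][4] = image.tr
    nib.save(img, str(path))
    return path


def write_events(events: pd.DataFrame, path) -> Path:
    path = Path(path)
    events.to_csv(path, sep="\t", index=False)
    return path


def write_motion(confounds: ConfoundSet, path) -> Path:
    path = Path(path)
    np.savetxt(path, confounds.values, fmt="%.8e")
    return path


def write_atlas(atlas: Atlas, image_path, table_path) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine)
    nib.save(img, str(image_path))
    pd.DataFrame(
        {"id": list(atlas.names), "name": list(atlas.names.values())}
    ).to_csv(table_path, sep="\t", index=False)


def write_beta_series(betas: BetaSeriesImage, image_path, manifest_path) -> None:
    """Persist a beta-series as a 4D NIfTI (trial on the 4th axis) + TSV manifest."""
    img = nib.Nifti1Image(betas.to_volumes(), betas.affine)
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(image_path))
    info = betas.trial_info
    if info is None:
        info = pd.DataFrame({"trial": np.arange(betas.n_trials)})
    info = info.copy()
    info["condition"] = betas.condition
    info.to_csv(manifest_path, sep="\t", index=False)


def read_beta_series(image_path, manifest_path) -> BetaSeriesImage:
    img = nib.load(str(image_path))
    vols = np.asanyarray(img.dataobj)
    if vols.ndim != 4:
        raise ValueError("beta-series image must be 4D")
    flat = vols.reshape(-1, vols.shape[3])
    inside = ~np.all(np.isnan(flat), axis=1)
    voxel_indices = np.nonzero(inside)[0]
    values = flat[voxel_indices, :].T
    info = pd.read_csv(manifest_path, sep="\t")
    condition = str(info["condition"].iloc[0]) if len(info) else ""
    return BetaSeriesImage(
        values=values,
        condition=condition,
        voxel_indices=voxel_indices,
        shape=vols.shape[:3],
        affine=img.affine,
        valid=np.ones(voxel_indices.size, dtype=bool),
        trial_info=info,
    )
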