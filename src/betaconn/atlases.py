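"""Bundled parcellation fixtures.

The AAL label table uses the standard 116 region names (90 cerebrum labels
plus 18 cerebellar hemisphere labels prefixed ``Cerebelum`` — the atlas'
historical single-l spelling — and 8 ``Vermis`` labels).  The label VOLUMES
here are synthetic low-resolution stand-ins: deterministic nearest-centroid
parcellations of an ellipsoidal "brain", built at import-free cost so no
binary atlas files ship with the package.  Region counts and the
cerebellum-exclusion bookkeeping behave exactly like the real atlases;
anatomical locations do not.
"""

from __future__ import annotations

import numpy as np

from .io_formats import Atlas

_AAL_CEREBRUM_PAIRS = [
    "Precentral", "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid",
    "Frontal_Mid_Orb", "Frontal_Inf_Oper", "Frontal_Inf_Tri",
    "Frontal_Inf_Orb", "Rolandic_Oper", "Supp_Motor_Area", "Olfactory",
    "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus", "Insula",
    "Cingulum_Ant", "Cingulum_Mid", "Cingulum_Post", "Hippocampus",
    "ParaHippocampal", "Amygdala", "Calcarine", "Cuneus", "Lingual",
    "Occipital_Sup", "Occipital_Mid", "Occipital_Inf", "Fusiform",
    "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
    "Angular", "Precuneus", "Paracentral_Lobule", "Caudate", "Putamen",
    "Pallidum", "Thalamus", "Heschl", "Temporal_Sup", "Temporal_Pole_Sup",
    "Temporal_Mid", "Temporal_Pole_Mid", "Temporal_Inf",
]

_AAL_CEREBELLUM_PAIRS = [
    "Cerebelum_Crus1", "Cerebelum_Crus2", "Cerebelum_3", "Cerebelum_4_5",
    "Cerebelum_6", "Cerebelum_7b", "Cerebelum_8", "Cerebelum_9",
    "Cerebelum_10",
]

_AAL_VERMIS = [
    "Vermis_1_2", "Vermis_3", "Vermis_4_5", "Vermis_6", "Vermis_7",
    "Vermis_8", "Vermis_9", "Vermis_10",
]

#: The 116 AAL region names in the standard L/R interleaved order.
AAL_NAMES: tuple = tuple(
    f"{base}_{side}" for base in _AAL_CEREBRUM_PAIRS for side in ("L", "R")
) + tuple(
    f"{base}_{side}" for base in _AAL_CEREBELLUM_PAIRS for side in ("L", "R")
) + tuple(_AAL_VERMIS)

CEREBELLUM_PREFIXES = ("Cerebelum", "Vermis")


def _voronoi_atlas(names, shape, voxel_mm, seed) -> Atlas:
    """Deterministic synthetic parcellation: seed one centroid per region
    inside an ellipsoid inscribed in the grid, label every in-ellipsoid voxel
    by its nearest centroid.  Every region is nonempty (each centroid is its
    own nearest voxel's closest seed)."""
    rng = np.random.default_rng(seed)
    shape = tuple(shape)
    n = len(names)
    half = (np.asarray(shape) - 1) / 2.0
    # rejection-sample centroids inside the ellipsoid
    centroids = []
    while len(centroids) < n:
        p = rng.uniform(0, np.asarray(shape) - 1, size=3)
        if np.sum(((p - half) / half) ** 2) <= 0.9:
            centroids.append(p)
    centroids = np.array(centroids)

    grid = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    inside = np.sum(((grid - half) / half) ** 2, axis=1) <= 1.0
    labels = np.zeros(grid.shape[0], dtype=np.int32)
    pts = grid[inside].astype(float)
    d2 = (
        np.sum(pts**2, axis=1)[:, None]
        - 2 * pts @ centroids.T
        + np.sum(centroids**2, axis=1)[None, :]
    )
    labels[inside] = np.argmin(d2, axis=1) + 1

    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -half * voxel_mm  # center the grid on the origin (MNI-ish)
    table = {i + 1: name for i, name in enumerate(names)}
    return Atlas(labels=labels.reshape(shape), affine=affine, names=table)


def aal_atlas(shape=(20, 24, 20), voxel_mm: float = 9.0) -> Atlas:
    """The AAL 116-region fixture (real names, synthetic low-res volume)."""
    return _voronoi_atlas(AAL_NAMES, shape, voxel_mm, seed=20160116)


def aal_atlas_no_cerebellum(shape=(20, 24, 20), voxel_mm: float = 9.0) -> Atlas:
    """AAL fixture with Cerebelum/Vermis labels dropped: 90 regions."""
    return aal_atlas(shape, voxel_mm).drop_regions(CEREBELLUM_PREFIXES)


def synthetic_dosenbach_atlas(shape=(24, 28, 24), voxel_mm: float = 7.0) -> Atlas:
    """A 160-node sphere-ROI fixture in the style of the Dosenbach functional
    parcellation.  Coordinates are synthetic (deterministic draws), not the
    published centers; use it for shape/bookkeeping tests only."""
    names = tuple(f"node_{k:03d}" for k in range(1, 161))
    return _voronoi_atlas(names, shape, voxel_mm, seed=20100160)
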