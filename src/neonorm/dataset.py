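"""In-memory containers and on-disk formats for masked scalar-map cohorts.

A cohort is represented by two aligned objects:

* :class:`CohortTable` — a thin wrapper over a :class:`pandas.DataFrame`
  holding one row per subject (covariates, group label, outcome scores).
* :class:`VoxelDataset` — the masked image data as a dense array of shape
  ``(n_subjects, n_voxels, n_metrics)`` plus grid geometry (shape, affine,
  in-mask voxel indices).

The subject axis of the dataset is aligned with the rows of the cohort
table; this alignment is the single source of truth for which volume
belongs to which subject and is validated on every join.

On disk the package uses NIfTI-1 for volumes (one 4D image per metric,
4th axis = subjects in table order), a binary NIfTI mask, and a TSV
covariate table with a fixed, documented header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from neonorm.errors import InputError

METRICS = ("fa", "md")

#: Required covariate columns, in canonical order.
COHORT_COLUMNS = (
    "subject_id",
    "group",
    "pma_scan",
    "ga_birth",
    "sex",
    "motion",
    "imd",
    "outcome_cognitive",
    "outcome_language",
    "outcome_motor",
)

GROUPS = ("normative", "atypical")


@dataclass
class CohortTable:
    """Per-subject covariates aligned to the image volumes.

    ``sex`` is coded female=0 / male=1 throughout the package.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise InputError(f"cohort table is missing columns: {missing}")
        ids = self.frame["subject_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise InputError(f"duplicate subject_id values: {dupes}")
        bad = set(self.frame["group"]) - set(GROUPS)
        if bad:
            raise InputError(f"unknown group labels: {sorted(bad)}")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def subject_ids(self) -> list[str]:
        return self.frame["subject_id"].tolist()

    def rows(self, group: str | None = None) -> pd.DataFrame:
        if group is None:
            return self.frame
        return self.frame[self.frame["group"] == group]

    def indices(self, group: str) -> np.ndarray:
        """Positional indices (into the subject axis) of one group."""
        return np.flatnonzero((self.frame["group"] == group).to_numpy())

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CohortTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class VoxelDataset:
    """Masked 4D scalar maps as ``(subjects, in-mask voxels, metrics)``.

    ``values[s, v, m]`` is metric ``m`` of subject ``s`` at the ``v``-th
    in-mask voxel; ``voxel_indices`` maps ``v`` to a flat (C-order) index
    into the 3D grid.
    """

    values: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    metric_names: tuple[str, ...] = METRICS
    clip_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise InputError("values must be (subjects, voxels, metrics)")
        if self.values.shape[1] != int(self.mask.sum()):
            raise InputError(
                f"voxel axis ({self.values.shape[1]}) does not match mask "
                f"size ({int(self.mask.sum())})"
            )
        if self.values.shape[2] != len(self.metric_names):
            raise InputError("metric axis does not match metric_names")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.mask.shape

    @property
    def voxel_indices(self) -> np.ndarray:
        """Flat C-order grid indices of the in-mask voxels."""
        return np.flatnonzero(self.mask.ravel())

    def metric(self, name: str) -> np.ndarray:
        """(subjects, voxels) slice for one metric."""
        return self.values[:, :, self.metric_names.index(name)]

    def embed(self, voxel_values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a per-voxel vector back into the 3D grid."""
        voxel_values = np.asarray(voxel_values)
        out = np.full(self.mask.size, fill, dtype=np.float64)
        out[self.voxel_indices] = voxel_values
        return out.reshape(self.mask.shape)

    def subset_subjects(self, idx: Sequence[int] | np.ndarray) -> "VoxelDataset":
        return VoxelDataset(
            self.values[np.asarray(idx)], self.mask, self.affine,
            self.metric_names,
        )


def _nifti(data: np.ndarray, affine: np.ndarray) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(data), np.asarray(affine))


def write_volumes(
    dataset: VoxelDataset, directory: str | Path, fill: float = 0.0
) -> dict[str, Path]:
    """Write one 4D NIfTI per metric plus the mask; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for m, name in enumerate(dataset.metric_names):
        grid = np.full(
            (*dataset.grid_shape, dataset.n_subjects), fill, dtype=np.float64
        )
        flat = grid.reshape(-1, dataset.n_subjects)
        flat[dataset.voxel_indices] = dataset.values[:, :, m].T
        path = directory / f"{name}.nii.gz"
        _nifti(grid, dataset.affine).to_filename(path)
        paths[name] = path
    mask_path = directory / "mask.nii.gz"
    _nifti(dataset.mask.astype(np.uint8), dataset.affine).to_filename(mask_path)
    paths["mask"] = mask_path
    return paths


def read_dataset(
    metric_paths: dict[str, str | Path], mask_path: str | Path
) -> VoxelDataset:
    """Load 4D metric images + mask into a :class:`VoxelDataset`.

    All images must share grid shape; affines must agree to 1e-6.
    """
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    affine = mask_img.affine
    flat_idx = np.flatnonzero(mask.ravel())
    names = tuple(metric_paths)
    stacked = []
    for name in names:
        img = nib.load(str(metric_paths[name]))
        if img.shape[:3] != mask.shape:
            raise InputError(
                f"grid of '{name}' {img.shape[:3]} does not match mask "
                f"{mask.shape}"
            )
        if not np.allclose(img.affine, affine, atol=1e-6):
            raise InputError(f"affine of '{name}' does not match the mask")
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim == 3:
            data = data[..., None]
        stacked.append(data.reshape(-1, data.shape[3])[flat_idx].T)
    values = np.stack(stacked, axis=2)
    return VoxelDataset(values, mask, affine, metric_names=names)
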