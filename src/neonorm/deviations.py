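"""Z-score deviation maps, extreme-deviation masks, and group overlap maps.

A subject's deviation at a voxel is

    Z = (observed − predictive mean) / predictive SD

with the predictive SD taken from the normative GP (noise variance
included by default, so Z is standard normal for subjects drawn from the
normative population). Extreme deviations are defined by the strict
threshold |Z| > 3.1, split by direction and metric into FA+, FA−, MD+
and MD− masks. Group-level spatial consistency is summarised by overlap
maps (percentage of subjects extreme at each voxel) and by thresholding
those at a consistency percentage (default 4%).

Voxels whose normative model is degenerate carry NaN Z-scores and are
excluded from both numerator and denominator of any percentage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from neonorm.dataset import CohortTable, VoxelDataset
from neonorm.errors import ConfigurationError, InputError
from neonorm.gpr import VoxelModelStore

logger = logging.getLogger(__name__)

#: Directions, as (metric index, sign) pairs.
DIRECTIONS = {
    "fa_plus": (0, +1),
    "fa_minus": (0, -1),
    "md_plus": (1, +1),
    "md_minus": (1, -1),
}

DEFAULT_THRESHOLD = 3.1
DEFAULT_CONSISTENCY_PERCENT = 4.0


@dataclass
class DeviationMaps:
    """Per-subject Z volumes over the mask plus directional extreme masks.

    ``z`` has shape (subjects, voxels, metrics); NaN marks voxels with a
    degenerate normative model. ``masks[direction]`` are boolean
    (subjects, voxels) arrays, empty until :func:`threshold_extremes`.
    """

    z: np.ndarray
    subject_ids: list[str]
    valid: np.ndarray                      # (V,) True where model usable
    threshold: float | None = None
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    metric_names: tuple[str, ...] = ("fa", "md")

    @property
    def n_subjects(self) -> int:
        return self.z.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.z.shape[1]


def zscore_from_predictions(
    values: np.ndarray,
    pred_mean: np.ndarray,
    pred_sd: np.ndarray,
    subject_ids: list[str],
) -> DeviationMaps:
    """Z-scores from observed values and precomputed predictive moments.

    Used both for holdout subjects (moments from the full normative model)
    and for normative subjects (moments from their held-out CV fold).
    """
    values = np.asarray(values, dtype=np.float64)
    if values.shape != pred_mean.shape or values.shape != pred_sd.shape:
        raise InputError("values and predictions have mismatched shapes")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - pred_mean) / pred_sd
    valid = np.all(np.isfinite(pred_sd), axis=(0, 2))
    z[:, ~valid, :] = np.nan
    n_bad = int((~valid).sum())
    if n_bad:
        logger.info("%d voxels excluded as degenerate/unscorable", n_bad)
    return DeviationMaps(z=z, subject_ids=list(subject_ids), valid=valid)


def zscore_map(
    dataset: VoxelDataset,
    cohort: CohortTable,
    store: VoxelModelStore,
    include_noise: bool = True,
) -> DeviationMaps:
    """Score every subject in ``dataset`` against a fitted normative model.

    Intended for holdout (atypical) subjects: the store must have been
    fitted on a cohort excluding them. Normative subjects should instead
    be scored with their cross-validation fold's predictions (see
    :func:`neonorm.gpr.crossvalidate`), so no subject is scored by a model
    that saw its own data.
    """
    if dataset.n_subjects != len(cohort):
        raise InputError("dataset subjects do not match cohort rows")
    if dataset.n_voxels != store.n_voxels:
        raise InputError("dataset voxel count does not match model store")
    pma = cohort.frame["pma_scan"].to_numpy()
    sex = cohort.frame["sex"].to_numpy()
    mean, sd = store.predict_all(pma, sex, include_noise=include_noise)
    return zscore_from_predictions(dataset.values, mean, sd, cohort.subject_ids)


def threshold_extremes(
    dev: DeviationMaps, threshold: float = DEFAULT_THRESHOLD
) -> DeviationMaps:
    """Mark extreme deviations per direction with strict inequalities.

    positive mask = {Z > +t}, negative mask = {Z < −t}; NaN (missing)
    voxels fall in neither mask. Modifies and returns ``dev``.
    """
    if threshold <= 0:
        raise ConfigurationError("threshold must be > 0")
    dev.threshold = threshold
    for name, (m, sign) in DIRECTIONS.items():
        zm = dev.z[:, :, m]
        with np.errstate(invalid="ignore"):
            dev.masks[name] = (
                (zm > threshold) if sign > 0 else (zm < -threshold)
            )
    return dev


def extreme_fraction(dev: DeviationMaps) -> float:
    """Grand fraction of finite |Z| exceeding the threshold (all metrics)."""
    if dev.threshold is None:
        raise InputError("call threshold_extremes first")
    finite = np.isfinite(dev.z)
    with np.errstate(invalid="ignore"):
        extreme = np.abs(dev.z) > dev.threshold
    return float(extreme[finite].sum() / finite.sum())


@dataclass
class OverlapMap:
    """Per-voxel percentage of subjects with an extreme deviation."""

    percent: np.ndarray       # (V,)
    n_subjects: int
    group: str
    direction: str


def overlap_map(
    masks: np.ndarray, group: str = "", direction: str = ""
) -> OverlapMap:
    """Voxel-wise percentage overlap: 100 × mean of binary masks."""
    masks = np.asarray(masks, dtype=bool)
    if masks.ndim != 2 or masks.shape[0] == 0:
        raise InputError("need a non-empty (subjects, voxels) mask stack")
    percent = 100.0 * masks.mean(axis=0)
    return OverlapMap(
        percent=percent, n_subjects=masks.shape[0], group=group,
        direction=direction,
    )


def overlap_maps(dev: DeviationMaps, group: str = "") -> dict[str, OverlapMap]:
    """All four directional overlap maps for one scored group."""
    if not dev.masks:
        raise InputError("call threshold_extremes first")
    return {
        name: overlap_map(dev.masks[name], group=group, direction=name)
        for name in DIRECTIONS
    }


def consistency_mask(
    overlap: OverlapMap, percent: float = DEFAULT_CONSISTENCY_PERCENT
) -> np.ndarray:
    """Voxels where strictly more than ``percent`` % of subjects are extreme."""
    if not 0 < percent < 100:
        raise ConfigurationError("consistency percent must be in (0, 100)")
    return overlap.percent > percent


# ---------------------------------------------------------------------------
# NIfTI export


def write_deviation_maps(
    dev: DeviationMaps, dataset: VoxelDataset, directory: str | Path
) -> list[Path]:
    """Write Z volumes (float32) and directional masks (uint8) as NIfTI."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for s, sid in enumerate(dev.subject_ids):
        for m, metric in enumerate(dev.metric_names):
            grid = dataset.embed(dev.z[s, :, m]).astype(np.float32)
            p = directory / f"{sid}_{metric}_z.nii.gz"
            nib.Nifti1Image(grid, dataset.affine).to_filename(p)
            paths.append(p)
        for name, mask in dev.masks.items():
            grid = dataset.embed(mask[s].astype(np.float64), fill=0.0)
            p = directory / f"{sid}_{name}_mask.nii.gz"
            nib.Nifti1Image(grid.astype(np.uint8), dataset.affine).to_filename(p)
            paths.append(p)
    return paths


def write_overlap_maps(
    overlaps: dict[str, OverlapMap],
    dataset: VoxelDataset,
    directory: str | Path,
    consistency_percent: float = DEFAULT_CONSISTENCY_PERCENT,
) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, om in overlaps.items():
        grid = dataset.embed(om.percent, fill=0.0).astype(np.float32)
        p = directory / f"overlap_{om.group}_{name}.nii.gz"
        nib.Nifti1Image(grid, dataset.affine).to_filename(p)
        paths.append(p)
        cmask = consistency_mask(om, consistency_percent)
        grid = dataset.embed(cmask.astype(np.float64), fill=0.0).astype(np.uint8)
        p = directory / f"consistency_{om.group}_{name}.nii.gz"
        nib.Nifti1Image(grid, dataset.affine).to_filename(p)
        paths.append(p)
    return paths
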