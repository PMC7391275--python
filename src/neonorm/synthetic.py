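"""Synthetic neonatal FA/MD cohort generator with known ground truth.

The generator emulates the statistical structure the normative-modelling
pipeline assumes, in "template space" directly (no diffusion simulation):

* two groups — a normative term-born cohort (GA at birth >= 37 weeks) and
  an atypical preterm cohort (GA < 37 weeks), both scanned at 37-45 weeks
  postmenstrual age (PMA);
* per-voxel smooth age trends — FA increases and MD decreases with PMA,
  with spatially smooth intercept/slope fields so neighbouring voxels are
  correlated, as in real parameter maps;
* small smooth sex-offset fields per metric;
* i.i.d. Gaussian subject-level noise per voxel;
* focal lesions in the atypical group only: a few spherical clusters per
  subject at random locations (little spatial overlap between subjects),
  raising MD and lowering FA by a multiple of the subject-level noise SD;
* outcome scores on the Bayley composite scale (mean 100, SD 15) that
  decrease linearly with a subject's injected lesion-volume fraction plus
  independent noise, so index-outcome correlation tests have a known sign.
  Lesion load also grows with the degree of prematurity, giving the GA
  correlations a known sign.

Everything is a pure function of ``(spec, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from neonorm.dataset import CohortTable, VoxelDataset, write_volumes
from neonorm.errors import ConfigurationError, InputError

import pandas as pd

#: PMA (weeks) at which intercept fields are anchored.
REFERENCE_PMA = 40.0

#: Floor applied to generated MD values (μm²/ms).
MD_FLOOR = 0.05


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the target study design: 270 term-born / 82 preterm
    subjects scanned between 37 and 45 weeks PMA. Noise SDs are set so a
    well-specified normative model reaches whole-brain mean absolute
    errors of roughly 0.031 (FA) and 0.17 μm²/ms (MD); for Gaussian
    residuals MAE = SD * sqrt(2/pi), giving SDs of about 0.04 and 0.2.
    """

    n_normative: int = 270
    n_atypical: int = 82
    pma_range: tuple[float, float] = (37.0, 45.0)
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    seed: int = 0
    noise_sd_fa: float = 0.04
    noise_sd_md: float = 0.20
    lesion_count_range: tuple[int, int] = (1, 4)
    lesion_effect_sd_multiplier: float = 5.0
    #: Gaussian sigma (voxels) used to smooth the random parameter fields.
    smoothness: float = 2.0
    #: Intracerebral mask = ellipsoid with semi-axes this fraction of grid.
    mask_radius_frac: float = 0.45
    lesion_radius_range: tuple[float, float] = (1.5, 3.0)
    #: Target correlation between lesion-volume fraction and outcomes
    #: (negative: more lesion load, lower score).
    outcome_lesion_rho: float = 0.55

    def validate(self) -> None:
        if self.n_normative < 20:
            raise ConfigurationError("n_normative must be >= 20")
        if self.n_atypical < 0:
            raise ConfigurationError("n_atypical must be >= 0")
        lo, hi = self.pma_range
        if not lo < hi:
            raise ConfigurationError("pma_range low must be < high")
        if any(g < 4 for g in self.grid_shape):
            raise ConfigurationError("grid_shape axes must all be >= 4")
        if self.noise_sd_fa <= 0:
            raise ConfigurationError("noise_sd_fa must be > 0")
        if self.noise_sd_md <= 0:
            raise ConfigurationError("noise_sd_md must be > 0")
        if self.lesion_count_range[0] > self.lesion_count_range[1]:
            raise ConfigurationError("lesion_count_range must be (min <= max)")
        if self.lesion_count_range[0] < 0:
            raise ConfigurationError("lesion_count_range must be non-negative")
        if self.smoothness <= 0:
            raise ConfigurationError("smoothness must be > 0")
        if not 0 < self.mask_radius_frac <= 0.5:
            raise ConfigurationError("mask_radius_frac must be in (0, 0.5]")


@dataclass
class GroundTruth:
    """Per-voxel generative parameters and per-subject lesion assignments.

    Field arrays are full-grid 3D; lesion masks are boolean full-grid
    volumes, always subsets of the intracerebral mask. ``lesion_offsets``
    maps subject_id -> {"fa": signed offset, "md": signed offset} applied
    uniformly inside that subject's lesion voxels.
    """

    mask: np.ndarray
    affine: np.ndarray
    fa_intercept: np.ndarray
    fa_slope: np.ndarray
    md_intercept: np.ndarray
    md_slope: np.ndarray
    sex_offset_fa: np.ndarray
    sex_offset_md: np.ndarray
    lesion_masks: dict[str, np.ndarray] = field(default_factory=dict)
    lesion_offsets: dict[str, dict[str, float]] = field(default_factory=dict)

    def lesion_fraction(self, subject_id: str) -> float:
        """Lesioned percentage of intracerebral voxels for one subject."""
        mask = self.lesion_masks.get(subject_id)
        if mask is None:
            return 0.0
        return 100.0 * mask.sum() / self.mask.sum()

    def check_invariants(self, spec: CohortSpec) -> None:
        lo, hi = spec.pma_range
        m = self.mask
        for pma in (lo, hi):
            fa = self.fa_intercept[m] + self.fa_slope[m] * (pma - REFERENCE_PMA)
            if fa.min() < 0 or (fa + np.abs(self.sex_offset_fa[m])).max() > 1:
                raise ConfigurationError("FA plane leaves [0, 1] inside PMA range")
            md = self.md_intercept[m] + self.md_slope[m] * (pma - REFERENCE_PMA)
            if (md - np.abs(self.sex_offset_md[m])).min() <= 0:
                raise ConfigurationError("MD plane is not positive inside PMA range")
        for sid, lmask in self.lesion_masks.items():
            if np.any(lmask & ~self.mask):
                raise ConfigurationError(f"lesion mask of {sid} leaves the brain mask")


def _smooth_field(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    mean: float,
    sd: float,
    sigma: float,
    clip: tuple[float, float],
) -> np.ndarray:
    """Smoothed Gaussian random field rescaled to the requested mean/SD."""
    raw = gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    raw = (raw - raw.mean()) / max(raw.std(), 1e-12)
    return np.clip(mean + sd * raw, *clip)


def _ellipsoid_mask(shape: tuple[int, int, int], radius_frac: float) -> np.ndarray:
    center = (np.asarray(shape) - 1) / 2.0
    radii = np.maximum(np.asarray(shape) * radius_frac, 1.5)
    grids = np.ogrid[[slice(0, s) for s in shape]]
    d2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d2 <= 1.0


def _sphere(
    shape: tuple[int, int, int], center: np.ndarray, radius: float
) -> np.ndarray:
    grids = np.ogrid[[slice(0, s) for s in shape]]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def generate_cohort(spec: CohortSpec) -> tuple[CohortTable, GroundTruth]:
    """Draw covariates, ground-truth fields and lesion assignments.

    Deterministic given ``spec`` (the seed is part of the spec). Outcome
    scores of atypical subjects carry a negative linear dependence on the
    subject's lesion-volume fraction; normative outcomes are pure noise
    around 100.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2024]))
    shape = tuple(spec.grid_shape)
    mask = _ellipsoid_mask(shape, spec.mask_radius_frac)
    affine = np.diag([1.5, 1.5, 1.5, 1.0])  # template-like 1.5 mm grid

    sig = spec.smoothness
    truth = GroundTruth(
        mask=mask,
        affine=affine,
        # FA rises with PMA; intercepts anchored at 40 w. Clip bounds keep
        # the noise-free plane inside [0, 1] across 37-45 w and more than
        # 3 noise SDs away from the FA floor, so clipping stays rare.
        fa_intercept=_smooth_field(rng, shape, 0.30, 0.06, sig, (0.18, 0.55)),
        fa_slope=_smooth_field(rng, shape, 0.010, 0.003, sig, (0.001, 0.015)),
        # MD falls with PMA (μm²/ms).
        md_intercept=_smooth_field(rng, shape, 1.20, 0.15, sig, (0.70, 1.80)),
        md_slope=_smooth_field(rng, shape, -0.025, 0.008, sig, (-0.050, -0.005)),
        sex_offset_fa=_smooth_field(rng, shape, 0.0, 0.005, sig, (-0.02, 0.02)),
        sex_offset_md=_smooth_field(rng, shape, 0.0, 0.010, sig, (-0.04, 0.04)),
    )

    n = spec.n_normative + spec.n_atypical
    ids = [f"sub-{i:04d}" for i in range(1, n + 1)]
    group = ["normative"] * spec.n_normative + ["atypical"] * spec.n_atypical
    lo, hi = spec.pma_range

    ga = np.empty(n)
    pma = np.empty(n)
    norm = slice(0, spec.n_normative)
    atyp = slice(spec.n_normative, n)
    ga[norm] = rng.uniform(37.0, 42.0, spec.n_normative)
    # scan can only happen after birth
    pma[norm] = rng.uniform(np.maximum(ga[norm], lo), hi)
    ga[atyp] = rng.uniform(24.0, 36.9, spec.n_atypical)
    pma[atyp] = rng.uniform(lo, hi, spec.n_atypical)

    sex = rng.integers(0, 2, n)  # female=0, male=1
    motion = rng.gamma(4.0, 0.25, n)
    motion[atyp] += 0.15  # preterm infants move a little more
    imd = rng.uniform(1.0, 60.0, n)

    # Lesions: count and size grow with prematurity so lesion load (and
    # hence the atypicality indices) correlates negatively with GA.
    lo_c, hi_c = spec.lesion_count_range
    mask_coords = np.argwhere(mask)
    frac = np.zeros(n)
    for i in range(spec.n_normative, n):
        sid = ids[i]
        severity = float(np.clip((37.0 - ga[i]) / 13.0, 0.0, 1.0))
        count = lo_c + rng.binomial(hi_c - lo_c, 0.25 + 0.5 * severity)
        lmask = np.zeros(shape, dtype=bool)
        for _ in range(count):
            center = mask_coords[rng.integers(len(mask_coords))]
            radius = rng.uniform(*spec.lesion_radius_range) * (
                0.8 + 0.6 * severity
            )
            lmask |= _sphere(shape, center, radius)
        lmask &= mask
        if lmask.any():
            truth.lesion_masks[sid] = lmask
            mult = spec.lesion_effect_sd_multiplier * rng.uniform(1.0, 1.3)
            truth.lesion_offsets[sid] = {
                "fa": -mult * spec.noise_sd_fa,
                "md": +mult * spec.noise_sd_md,
            }
            frac[i] = truth.lesion_fraction(sid)

    # Outcomes: Bayley-like composites (mean 100, SD 15). Atypical scores
    # decrease with standardised lesion-volume fraction at correlation
    # outcome_lesion_rho; normative scores are independent noise.
    rho = spec.outcome_lesion_rho
    f_at = frac[atyp]
    if spec.n_atypical > 1 and f_at.std() > 0:
        z_f = (f_at - f_at.mean()) / f_at.std(ddof=1)
    else:
        z_f = np.zeros(spec.n_atypical)
    outcomes = {}
    for name in ("cognitive", "language", "motor"):
        eps = rng.standard_normal(n)
        score = 100.0 + 15.0 * eps
        score[atyp] = 100.0 + 15.0 * (
            -rho * z_f + np.sqrt(1.0 - rho**2) * eps[atyp]
        )
        outcomes[f"outcome_{name}"] = score

    table = CohortTable(
        pd.DataFrame(
            {
                "subject_id": ids,
                "group": group,
                "pma_scan": pma,
                "ga_birth": ga,
                "sex": sex,
                "motion": motion,
                "imd": imd,
                **outcomes,
            }
        )
    )
    truth.check_invariants(spec)
    return table, truth


def generate_scalar_maps(
    table: CohortTable, truth: GroundTruth, spec: CohortSpec
) -> VoxelDataset:
    """Render per-subject FA/MD maps from the ground truth.

    voxel value = intercept + slope * (PMA - 40) + sex_offset * sex
    + N(0, noise_sd²), plus the subject's lesion offset inside lesion
    voxels. FA is clipped to [0, 1] and MD floored at a small positive
    value; clip events are counted in ``dataset.clip_counts``.
    """
    spec.validate()
    known = set(table.subject_ids)
    unknown = set(truth.lesion_masks) - known
    if unknown:
        raise InputError(f"ground truth references unknown subjects: {sorted(unknown)}")

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7071]))
    flat_idx = np.flatnonzero(truth.mask.ravel())
    fields = {
        "fa": (truth.fa_intercept, truth.fa_slope, truth.sex_offset_fa,
               spec.noise_sd_fa),
        "md": (truth.md_intercept, truth.md_slope, truth.sex_offset_md,
               spec.noise_sd_md),
    }
    n = len(table)
    values = np.empty((n, flat_idx.size, 2))
    pma = table.frame["pma_scan"].to_numpy()
    sex = table.frame["sex"].to_numpy()
    for m, name in enumerate(("fa", "md")):
        icpt, slope, sexo, sd = (
            f.ravel()[flat_idx] if isinstance(f, np.ndarray) else f
            for f in fields[name]
        )
        plane = (
            icpt[None, :]
            + slope[None, :] * (pma[:, None] - REFERENCE_PMA)
            + sexo[None, :] * sex[:, None]
        )
        values[:, :, m] = plane + sd * rng.standard_normal((n, flat_idx.size))

    for i, sid in enumerate(table.subject_ids):
        lmask = truth.lesion_masks.get(sid)
        if lmask is None:
            continue
        lidx = np.isin(flat_idx, np.flatnonzero(lmask.ravel()))
        off = truth.lesion_offsets[sid]
        values[i, lidx, 0] += off["fa"]
        values[i, lidx, 1] += off["md"]

    clip_counts = {
        "fa_low": int((values[:, :, 0] < 0).sum()),
        "fa_high": int((values[:, :, 0] > 1).sum()),
        "md_floor": int((values[:, :, 1] < MD_FLOOR).sum()),
    }
    values[:, :, 0] = np.clip(values[:, :, 0], 0.0, 1.0)
    values[:, :, 1] = np.maximum(values[:, :, 1], MD_FLOOR)
    return VoxelDataset(
        values, truth.mask, truth.affine, metric_names=("fa", "md"),
        clip_counts=clip_counts,
    )


def write_dataset(
    dataset: VoxelDataset,
    table: CohortTable,
    directory: str | Path,
    truth: GroundTruth | None = None,
    spec: CohortSpec | None = None,
) -> dict[str, Path]:
    """Write volumes, covariates and (optionally) the ground-truth sidecar.

    Layout: ``fa.nii.gz``, ``md.nii.gz``, ``mask.nii.gz``,
    ``cohort.tsv`` and ``ground_truth.json``. The sidecar is a flat
    key/value + array JSON document sufficient to reconstruct the truth.
    """
    if dataset.n_subjects != len(table):
        raise InputError(
            f"dataset has {dataset.n_subjects} subjects but table has "
            f"{len(table)} rows"
        )
    directory = Path(directory)
    paths = write_volumes(dataset, directory)
    tsv = directory / "cohort.tsv"
    table.to_tsv(tsv)
    paths["cohort"] = tsv
    if truth is not None:
        sidecar = directory / "ground_truth.json"
        write_ground_truth(truth, sidecar, spec)
        paths["ground_truth"] = sidecar
    return paths


def write_ground_truth(
    truth: GroundTruth, path: str | Path, spec: CohortSpec | None = None
) -> None:
    doc = {
        "schema": "neonorm-ground-truth-1",
        "grid_shape": list(truth.mask.shape),
        "affine": np.asarray(truth.affine).ravel().tolist(),
        "mask_indices": np.flatnonzero(truth.mask.ravel()).tolist(),
        "spec": asdict(spec) if spec is not None else None,
        "lesion_offsets": truth.lesion_offsets,
        "lesion_indices": {
            sid: np.flatnonzero(m.ravel()).tolist()
            for sid, m in truth.lesion_masks.items()
        },
    }
    for name in (
        "fa_intercept", "fa_slope", "md_intercept", "md_slope",
        "sex_offset_fa", "sex_offset_md",
    ):
        doc[name] = getattr(truth, name).ravel().tolist()
    Path(path).write_text(json.dumps(doc))


def read_ground_truth(path: str | Path) -> GroundTruth:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != "neonorm-ground-truth-1":
        raise InputError(f"unrecognised ground-truth schema in {path}")
    shape = tuple(doc["grid_shape"])
    mask = np.zeros(int(np.prod(shape)), dtype=bool)
    mask[doc["mask_indices"]] = True
    mask = mask.reshape(shape)

    def grid(name: str) -> np.ndarray:
        return np.asarray(doc[name], dtype=np.float64).reshape(shape)

    lesion_masks = {}
    for sid, idx in doc["lesion_indices"].items():
        m = np.zeros(int(np.prod(shape)), dtype=bool)
        m[idx] = True
        lesion_masks[sid] = m.reshape(shape)
    return GroundTruth(
        mask=mask,
        affine=np.asarray(doc["affine"]).reshape(4, 4),
        fa_intercept=grid("fa_intercept"),
        fa_slope=grid("fa_slope"),
        md_intercept=grid("md_intercept"),
        md_slope=grid("md_slope"),
        sex_offset_fa=grid("sex_offset_fa"),
        sex_offset_md=grid("sex_offset_md"),
        lesion_masks=lesion_masks,
        lesion_offsets=doc["lesion_offsets"],
    )


def pairwise_lesion_jaccard(truth: GroundTruth) -> np.ndarray:
    """Pairwise Jaccard overlap of lesion masks across lesioned subjects."""
    masks = [m.ravel() for m in truth.lesion_masks.values()]
    out = []
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            inter = np.count_nonzero(masks[i] & masks[j])
            union = np.count_nonzero(masks[i] | masks[j])
            out.append(inter / union if union else 0.0)
    return np.asarray(out)
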