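"""Canned synthetic studies and the quantities the analysis measures on them.

This module defines the desk-scale study conditions used throughout the
repository (analysis scripts, tests, acceptance script) and the
measurements taken on them:

* a *reference study* (100 term + 82 preterm on a 20³ grid) for
  calibration, slope-recovery and lesion-detection properties of the
  voxel-wise normative GP;
* a *battery study* (smaller grid) on which the full pipeline — CV-based
  term scoring, holdout preterm scoring, atypicality indices and the
  statistical battery — runs end to end in minutes on one CPU;
* *power/null studies* (small grids) for seeded meta-repeats of the
  battery's detection power and family-wise error.

All functions are deterministic given their seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from neonorm.atypicality import atypicality_index, atypicality_table
from neonorm.dataset import CohortTable, VoxelDataset
from neonorm.deviations import (
    DeviationMaps,
    extreme_fraction,
    threshold_extremes,
    zscore_from_predictions,
    zscore_map,
)
from neonorm.gpr import FitConfig, VoxelModelStore, crossvalidate, fit_all
from neonorm.stats import BatteryConfig, BatteryReport, run_full_battery
from neonorm.synthetic import (
    CohortSpec,
    GroundTruth,
    generate_cohort,
    generate_scalar_maps,
)

logger = logging.getLogger(__name__)


def reference_spec(seed: int) -> CohortSpec:
    """The 20³-grid study used for model-level properties (no holdouts)."""
    return CohortSpec(
        n_normative=100, n_atypical=0, grid_shape=(20, 20, 20), seed=seed
    )


def battery_spec(seed: int) -> CohortSpec:
    """A 14³-grid two-group study small enough for CV scoring of the term
    group plus the full battery in a few minutes."""
    return CohortSpec(
        n_normative=100, n_atypical=82, grid_shape=(14, 14, 14),
        lesion_radius_range=(1.0, 2.0), lesion_count_range=(0, 3),
        seed=seed,
    )


def power_spec(seed: int) -> CohortSpec:
    """Small-grid study for seeded power meta-repeats of the battery."""
    return CohortSpec(
        n_normative=50, n_atypical=60, grid_shape=(10, 10, 10),
        mask_radius_frac=0.35, lesion_radius_range=(1.0, 1.6),
        lesion_count_range=(0, 2), seed=seed,
    )


def null_spec(seed: int) -> CohortSpec:
    """Lesion-free cohort for family-wise-error checks.

    The normative cohort is kept large enough (n=80) that the scoring
    asymmetry — term subjects Z-scored by CV-fold models trained on 4/5
    of the cohort, preterm subjects by the full model — does not itself
    shift the index distributions between groups; at much smaller
    training cohorts that asymmetry biases the null group comparison
    (see the methods note's limitations).
    """
    return replace(power_spec(seed), lesion_count_range=(0, 0),
                   grid_shape=(8, 8, 8), n_normative=80, n_atypical=40)


@dataclass
class FittedStudy:
    spec: CohortSpec
    cohort: CohortTable
    truth: GroundTruth
    dataset: VoxelDataset
    store: VoxelModelStore
    fit_config: FitConfig


def fit_reference_study(
    seed: int, fit_config: FitConfig | None = None
) -> FittedStudy:
    """Generate the reference cohort and fit the normative model on it."""
    spec = reference_spec(seed)
    cohort, truth = generate_cohort(spec)
    dataset = generate_scalar_maps(cohort, truth, spec)
    if fit_config is None:
        fit_config = FitConfig(restarts=1, maxiter=60, seed=seed)
    store = fit_all(dataset, cohort, fit_config)
    return FittedStudy(spec, cohort, truth, dataset, store, fit_config)


def null_extreme_fraction(
    study: FittedStudy, n_subjects: int = 200, seed: int = 999,
    threshold: float = 3.1,
) -> float:
    """Grand |Z| > t fraction for fresh normative draws scored on the model.

    The null subjects come from the *generator's* ground truth (not the
    fitted model), so this checks the whole chain: hyperparameter
    estimation, noise-inclusive predictive SD, and the Z arithmetic. For
    a calibrated model the fraction is ≈ 2(1 − Φ(t)) ≈ 0.194% at t=3.1.
    """
    null = replace(
        study.spec, n_normative=n_subjects, n_atypical=0,
        seed=int(np.random.SeedSequence([study.spec.seed, seed, 1]).generate_state(1)[0] % (2**31)),
    )
    cohort, _ = generate_cohort(null)
    dataset = generate_scalar_maps(cohort, study.truth, null)
    dev = zscore_map(dataset, cohort, study.store, include_noise=True)
    threshold_extremes(dev, threshold)
    return extreme_fraction(dev)


def slope_recovery(study: FittedStudy) -> dict[str, float]:
    """Median |error| of the GP-implied PMA slope, relative to the slope
    field's across-voxel SD.

    The per-voxel slope is extracted as the least-squares slope of the
    noise-free predictive mean over an interior PMA grid (sex = 0), which
    suppresses RBF wiggle relative to a two-point difference.
    """
    grid = np.linspace(38.0, 44.9, 8)
    mean, _ = study.store.predict_all(
        grid, np.zeros_like(grid), include_noise=False
    )
    A = np.column_stack([np.ones_like(grid), grid])
    coef = np.linalg.lstsq(A, mean.reshape(len(grid), -1), rcond=None)[0][1]
    slope_hat = coef.reshape(study.dataset.n_voxels, 2)
    vidx = study.dataset.voxel_indices
    out = {}
    for m, (name, field) in enumerate(
        (("fa", study.truth.fa_slope), ("md", study.truth.md_slope))
    ):
        true = field.ravel()[vidx]
        err = np.median(np.abs(slope_hat[:, m] - true))
        out[f"{name}_median_abs_err"] = float(err)
        out[f"{name}_generative_sd"] = float(true.std())
        out[f"{name}_err_ratio"] = float(err / true.std())
    return out


def lesion_detection(
    study: FittedStudy, n_atypical: int = 40, seed: int = 777,
    threshold: float = 3.1,
) -> dict[str, float]:
    """Voxel-level sensitivity and false-positive rate for injected lesions.

    Atypical subjects are drawn on the reference ground truth (lesions
    lower FA and raise MD by ≥5 noise SDs) and scored against the fitted
    model. A lesion voxel counts as detected when the subject's FA− or
    MD+ mask covers it; any extreme outside the lesions is a false
    positive.
    """
    atyp = replace(
        study.spec, n_normative=20, n_atypical=n_atypical,
        seed=int(np.random.SeedSequence([study.spec.seed, seed, 2]).generate_state(1)[0] % (2**31)),
    )
    cohort, truth_a = generate_cohort(atyp)
    # lesions must live on the reference truth's parameter fields
    truth = replace_fields(study.truth, truth_a)
    dataset = generate_scalar_maps(cohort, truth, atyp)
    idx = cohort.indices("atypical")
    sub_cohort = CohortTable(cohort.frame.iloc[idx].reset_index(drop=True))
    dev = zscore_map(
        dataset.subset_subjects(idx), sub_cohort, study.store,
        include_noise=True,
    )
    threshold_extremes(dev, threshold)
    vidx = dataset.voxel_indices
    hit_n = les_n = fp_n = clean_n = 0
    for i, sid in enumerate(sub_cohort.subject_ids):
        lmask = truth.lesion_masks.get(sid)
        les = (
            np.isin(vidx, np.flatnonzero(lmask.ravel()))
            if lmask is not None else np.zeros(len(vidx), dtype=bool)
        )
        correct = dev.masks["md_plus"][i] | dev.masks["fa_minus"][i]
        any_extreme = correct | dev.masks["md_minus"][i] | dev.masks["fa_plus"][i]
        hit_n += int((correct & les).sum())
        les_n += int(les.sum())
        fp_n += int((any_extreme & ~les).sum())
        clean_n += int((~les).sum())
    return {
        "sensitivity": hit_n / les_n if les_n else float("nan"),
        "false_positive_rate_pct": 100.0 * fp_n / clean_n,
        "n_lesion_voxels": les_n,
    }


def replace_fields(reference: GroundTruth, other: GroundTruth) -> GroundTruth:
    """Ground truth with reference parameter fields + other's lesions."""
    from dataclasses import replace as dc_replace

    return dc_replace(
        reference,
        lesion_masks=other.lesion_masks,
        lesion_offsets=other.lesion_offsets,
    )


@dataclass
class StudyOutputs:
    cohort: CohortTable
    truth: GroundTruth
    table: pd.DataFrame          # atypicality indices joined to covariates
    report: BatteryReport
    mean_mae: dict[str, float]
    term_dev: DeviationMaps
    preterm_dev: DeviationMaps | None


def run_study(
    spec: CohortSpec,
    fit_config: FitConfig | None = None,
    battery_config: BatteryConfig | None = None,
    cv_folds: int = 5,
    threshold: float = 3.1,
) -> StudyOutputs:
    """The full analysis in memory: fit, CV-score term, score preterm,
    atypicality indices, statistical battery."""
    if fit_config is None:
        fit_config = FitConfig(restarts=1, maxiter=60, seed=spec.seed)
    if battery_config is None:
        battery_config = BatteryConfig(seed=spec.seed)
    cohort, truth = generate_cohort(spec)
    dataset = generate_scalar_maps(cohort, truth, spec)
    nidx = cohort.indices("normative")
    norm_cohort = CohortTable(cohort.frame.iloc[nidx].reset_index(drop=True))
    norm_ds = dataset.subset_subjects(nidx)
    store = fit_all(norm_ds, norm_cohort, fit_config)
    mae = crossvalidate(norm_ds, norm_cohort, k=cv_folds,
                        seed=spec.seed, config=fit_config)
    term_dev = zscore_from_predictions(
        norm_ds.values, mae.held_out_mean, mae.held_out_sd,
        norm_cohort.subject_ids,
    )
    threshold_extremes(term_dev, threshold)
    records = [atypicality_index(term_dev)]
    preterm_dev = None
    aidx = cohort.indices("atypical")
    if aidx.size:
        atyp_cohort = CohortTable(
            cohort.frame.iloc[aidx].reset_index(drop=True)
        )
        preterm_dev = zscore_map(
            dataset.subset_subjects(aidx), atyp_cohort, store,
            include_noise=True,
        )
        threshold_extremes(preterm_dev, threshold)
        records.append(atypicality_index(preterm_dev))
    table = atypicality_table(pd.concat(records, ignore_index=True), cohort)
    report = run_full_battery(table, battery_config)
    return StudyOutputs(
        cohort=cohort, truth=truth, table=table, report=report,
        mean_mae=mae.mean_mae, term_dev=term_dev, preterm_dev=preterm_dev,
    )


def power_meta_repeats(
    n_runs: int = 20,
    base_seed: int = 0,
    spec_fn=power_spec,
) -> pd.DataFrame:
    """Run the battery on ``n_runs`` seeded cohorts; per-run detection flags.

    Returns one row per run with, per family, whether the key tests
    rejected — used both for power (lesion-linked specs) and family-wise
    error (null specs) summaries.
    """
    rows = []
    for r in range(n_runs):
        seed = int(np.random.SeedSequence([base_seed, r]).generate_state(1)[0] % (2**31))
        out = run_study(
            spec_fn(seed),
            fit_config=FitConfig(restarts=1, maxiter=50, seed=seed),
            battery_config=BatteryConfig(
                bootstrap_reps=100, prediction_resamples=30, seed=seed
            ),
        )
        t = out.report.tests
        md_group = t[(t.family == "group_difference")
                     & t.test.str.startswith("md_plus")]
        atyp_out = t[(t.family == "outcome_correlation")
                     & (t.group == "atypical")]
        md_out = atyp_out[atyp_out.test.str.startswith("md_plus")]
        rows.append(
            {
                "seed": seed,
                "md_plus_group_reject": bool(md_group.reject.any()),
                "md_plus_group_A": float(md_group.effect.iloc[0]),
                "md_plus_outcome_reject": bool(md_out.reject.any()),
                "any_group_reject": bool(
                    t[t.family == "group_difference"].reject.any()
                ),
                "any_ga_reject": bool(
                    t[t.family == "ga_correlation"].reject.any()
                ),
                "any_outcome_reject": bool(atyp_out.reject.any()),
            }
        )
        logger.info("meta-run %d/%d done", r + 1, n_runs)
    return pd.DataFrame(rows)
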