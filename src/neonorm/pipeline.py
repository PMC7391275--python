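"""End-to-end orchestration: simulate → fit → score → atypicality → stats.

A run is driven by a single :class:`RunConfig` (YAML on disk) and a seed.
Stage outputs land under one run directory with a ``manifest.json``
recording the config hash, package versions, the subject-id-to-volume-
index map, per-stage runtimes and completion flags; reruns with
``resume=True`` skip stages whose outputs already exist under the same
config hash. All randomness derives from the config seed, so two runs of
the same config produce byte-identical report TSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from neonorm.atypicality import atypicality_index, atypicality_table, write_atypicality_tsv
from neonorm.dataset import CohortTable, VoxelDataset, read_dataset
from neonorm.deviations import (
    overlap_maps,
    threshold_extremes,
    write_overlap_maps,
    zscore_from_predictions,
    zscore_map,
)
from neonorm.errors import ConfigurationError, InputError, NeonormError
from neonorm.gpr import FitConfig, VoxelModelStore, crossvalidate, fit_all
from neonorm.stats import BatteryConfig, run_full_battery
from neonorm.synthetic import CohortSpec, generate_cohort, generate_scalar_maps, write_dataset

logger = logging.getLogger(__name__)

STAGES = ("simulate", "validate", "fit", "score", "overlap", "atypicality", "stats")


def _version() -> str:
    import neonorm

    return neonorm.__version__


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run.

    Either ``simulate`` holds a :class:`CohortSpec`-shaped mapping (the
    demo path) or the three input paths point at existing volumes and a
    covariate TSV. Defaults follow the analysis definition: |Z| > 3.1,
    4% consistency, 5 CV folds, 1000/100 bootstrap replications,
    α = 0.05, noise variance included in the Z denominator.
    """

    output_dir: str = "neonorm_run"
    seed: int = 0
    # input paths (ignored when simulate is set)
    fa_path: str | None = None
    md_path: str | None = None
    mask_path: str | None = None
    cohort_path: str | None = None
    simulate: dict | None = None
    # analysis parameters
    threshold: float = 3.1
    consistency_percent: float = 4.0
    cv_folds: int = 5
    bootstrap_reps: int = 1000
    prediction_resamples: int = 100
    alpha: float = 0.05
    include_noise: bool = True
    restarts: int = 3
    maxiter: int = 100
    jitter: float = 1e-8
    resume: bool = False

    def validate(self) -> None:
        if self.threshold <= 0:
            raise ConfigurationError("threshold must be > 0")
        if not 0 < self.consistency_percent < 100:
            raise ConfigurationError("consistency_percent must be in (0, 100)")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.simulate is None:
            for f in ("fa_path", "md_path", "mask_path", "cohort_path"):
                if getattr(self, f) is None:
                    raise ConfigurationError(
                        f"{f} is required when simulate is not set"
                    )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)

    def content_hash(self) -> str:
        doc = asdict(self)
        doc.pop("resume", None)  # resuming does not change the result
        blob = json.dumps(doc, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def cohort_spec(self) -> CohortSpec:
        doc = dict(self.simulate or {})
        doc.setdefault("seed", self.seed)
        for key in ("pma_range", "grid_shape", "lesion_count_range",
                    "lesion_radius_range"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return CohortSpec(**doc)

    def fit_config(self) -> FitConfig:
        return FitConfig(
            restarts=self.restarts, maxiter=self.maxiter,
            jitter=self.jitter, seed=self.seed,
        )


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(
    dataset: VoxelDataset, cohort: CohortTable
) -> ValidationReport:
    """Fail-fast sanity checks on grids, covariates and value ranges."""
    rep = ValidationReport()
    if dataset.n_subjects != len(cohort):
        rep.errors.append(
            f"image 4th axis has {dataset.n_subjects} volumes but the "
            f"covariate table has {len(cohort)} rows"
        )
    for col in ("pma_scan", "ga_birth", "sex", "motion", "imd"):
        if cohort.frame[col].isna().any():
            bad = cohort.frame.loc[
                cohort.frame[col].isna(), "subject_id"
            ].tolist()
            rep.errors.append(f"missing {col} for subjects {bad}")
    pma = cohort.frame["pma_scan"]
    if (pma < 30).any() or (pma > 50).any():
        rep.warnings.append(
            "PMA at scan outside 30-50 weeks for some subjects"
        )
    if "fa" in dataset.metric_names:
        fa = dataset.metric("fa")
        if fa.min() < 0 or fa.max() > 1:
            rep.errors.append("FA values outside [0, 1]")
    if "md" in dataset.metric_names:
        md = dataset.metric("md")
        if np.nanmedian(md) < 0.01:
            rep.warnings.append(
                "MD values look like mm²/s (~1e-3); expected μm²/ms (~1) — "
                "rescale by 1000"
            )
        if md.min() <= 0:
            rep.errors.append("non-positive MD values inside the mask")
    return rep


class _Manifest:
    def __init__(self, path: Path, config: RunConfig) -> None:
        self.path = path
        self.doc = {
            "config_hash": config.content_hash(),
            "neonorm_version": _version(),
            "stages": {},
            "id_to_index": {},
        }
        if path.exists():
            old = json.loads(path.read_text())
            if old.get("config_hash") == self.doc["config_hash"]:
                self.doc = old

    def done(self, stage: str) -> bool:
        return self.doc["stages"].get(stage, {}).get("complete", False)

    def mark(self, stage: str, runtime: float, **extra) -> None:
        self.doc["stages"][stage] = {
            "complete": True, "runtime_s": round(runtime, 3), **extra,
        }
        self.save()

    def save(self) -> None:
        self.path.write_text(json.dumps(self.doc, indent=2, sort_keys=True))


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Any stage failure raises with the stage name prepended so the
    offending context is visible to the caller.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest = _Manifest(out / "manifest.json", config)

    stage = "simulate/load"
    try:
        t0 = time.perf_counter()
        if config.simulate is not None:
            spec = config.cohort_spec()
            cohort, truth = generate_cohort(spec)
            dataset = generate_scalar_maps(cohort, truth, spec)
            if not (config.resume and manifest.done("simulate")):
                write_dataset(dataset, cohort, out / "data", truth, spec)
                manifest.mark("simulate", time.perf_counter() - t0,
                              clip_counts=dataset.clip_counts)
        else:
            dataset = read_dataset(
                {"fa": config.fa_path, "md": config.md_path},
                config.mask_path,
            )
            cohort = CohortTable.from_tsv(config.cohort_path)
        manifest.doc["id_to_index"] = {
            sid: i for i, sid in enumerate(cohort.subject_ids)
        }
        manifest.save()

        stage = "validate"
        t0 = time.perf_counter()
        report = validate_inputs(dataset, cohort)
        for w in report.warnings:
            logger.warning("validate: %s", w)
        if not report.ok:
            raise InputError("; ".join(report.errors))
        manifest.mark("validate", time.perf_counter() - t0,
                      warnings=report.warnings)

        norm_idx = cohort.indices("normative")
        atyp_idx = cohort.indices("atypical")
        norm_cohort = CohortTable(
            cohort.frame.iloc[norm_idx].reset_index(drop=True)
        )
        norm_ds = dataset.subset_subjects(norm_idx)

        stage = "fit"
        store_path = out / "model_store.npz"
        cv_path = out / "cv_predictions.npz"
        if config.resume and manifest.done("fit") and store_path.exists():
            store = VoxelModelStore.load(store_path)
            cv = np.load(cv_path)
            cv_mean, cv_sd = cv["mean"], cv["sd"]
            fold_assignment = cv["folds"]
        else:
            t0 = time.perf_counter()
            fit_cfg = config.fit_config()
            store = fit_all(norm_ds, norm_cohort, fit_cfg)
            store.save(store_path)
            maemap = crossvalidate(
                norm_ds, norm_cohort, k=config.cv_folds,
                seed=config.seed, config=fit_cfg,
            )
            cv_mean, cv_sd = maemap.held_out_mean, maemap.held_out_sd
            fold_assignment = maemap.fold_assignment
            np.savez_compressed(
                cv_path, mean=cv_mean, sd=cv_sd, folds=fold_assignment
            )
            pd.DataFrame(
                {
                    "metric": list(maemap.mean_mae),
                    "mean_mae": list(maemap.mean_mae.values()),
                }
            ).to_csv(out / "cv_mae.tsv", sep="\t", index=False,
                     float_format="%.10g")
            manifest.mark("fit", time.perf_counter() - t0,
                          mean_mae=maemap.mean_mae)

        stage = "score"
        t0 = time.perf_counter()
        # normative subjects: scored against their held-out CV fold
        dev_norm = zscore_from_predictions(
            norm_ds.values, cv_mean, cv_sd, norm_cohort.subject_ids
        )
        threshold_extremes(dev_norm, config.threshold)
        devs = {"normative": dev_norm}
        if atyp_idx.size:
            atyp_cohort = CohortTable(
                cohort.frame.iloc[atyp_idx].reset_index(drop=True)
            )
            atyp_ds = dataset.subset_subjects(atyp_idx)
            dev_atyp = zscore_map(
                atyp_ds, atyp_cohort, store,
                include_noise=config.include_noise,
            )
            threshold_extremes(dev_atyp, config.threshold)
            devs["atypical"] = dev_atyp
        manifest.mark("score", time.perf_counter() - t0)

        stage = "overlap"
        t0 = time.perf_counter()
        for gname, dev in devs.items():
            write_overlap_maps(
                overlap_maps(dev, group=gname), dataset, out / "overlap",
                config.consistency_percent,
            )
        manifest.mark("overlap", time.perf_counter() - t0)

        stage = "atypicality"
        t0 = time.perf_counter()
        records = pd.concat(
            [atypicality_index(dev) for dev in devs.values()],
            ignore_index=True,
        )
        atyp_table = atypicality_table(records, cohort)
        write_atypicality_tsv(atyp_table, out / "atypicality.tsv")
        manifest.mark("atypicality", time.perf_counter() - t0)

        stage = "stats"
        t0 = time.perf_counter()
        battery = run_full_battery(
            atyp_table,
            BatteryConfig(
                alpha=config.alpha,
                bootstrap_reps=config.bootstrap_reps,
                prediction_resamples=config.prediction_resamples,
                seed=config.seed,
            ),
        )
        battery.to_tsv(out / "stats_report.tsv")
        with open(out / "stats_models.txt", "w") as fh:
            for label, model in battery.models.items():
                fh.write(f"== {label}\n")
                fh.write(
                    f"adj R2 = {model.adj_r2:.4f} "
                    f"[{model.adj_r2_ci[0]:.4f}, {model.adj_r2_ci[1]:.4f}] "
                    f"(95% CI, {len(model.adj_r2_draws)} reps)\n"
                    f"F({model.f_dof[0]}, {model.f_dof[1]}) = "
                    f"{model.f_statistic:.3f}, p = {model.f_p_value:.4g}\n"
                    f"bootstrap prediction adj R2 = "
                    f"{model.prediction_adj_r2:.4f}\n"
                )
                for name, (coef, p) in zip(
                    model.params.index,
                    zip(model.params, model.p_values),
                ):
                    fh.write(f"  {name}: {coef:.6g} (p = {p:.4g})\n")
        manifest.mark("stats", time.perf_counter() - t0)
    except NeonormError as err:
        raise type(err)(f"[stage {stage}] {err}") from err
    return out
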