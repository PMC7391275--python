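"""Fit the voxel-wise normative GP on the term cohort and cross-validate.

Per voxel, a two-output GP of (FA, MD) on (PMA at scan, sex) is fitted on
the term sample by marginal-likelihood maximization; accuracy is measured
by PMA-stratified 5-fold cross-validation as the per-voxel mean absolute
error (MAE) between held-out predictions and observations. The held-out
predictive moments are kept so term subjects can later be Z-scored by
models that never saw them.
"""

import argparse

import numpy as np
import pandas as pd

from neonorm.dataset import CohortTable, read_dataset
from neonorm.gpr import crossvalidate, fit_all

from common import DATA_DIR, DEFAULT_SEED, MODEL_DIR, fit_config


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=DEFAULT_SEED)
    parser.add_argument("--folds", type=int, default=5)
    args = parser.parse_args()

    dataset = read_dataset(
        {"fa": DATA_DIR / "fa.nii.gz", "md": DATA_DIR / "md.nii.gz"},
        DATA_DIR / "mask.nii.gz",
    )
    cohort = CohortTable.from_tsv(DATA_DIR / "cohort.tsv")
    idx = cohort.indices("normative")
    norm_cohort = CohortTable(cohort.frame.iloc[idx].reset_index(drop=True))
    norm_ds = dataset.subset_subjects(idx)

    cfg = fit_config(args.seed)
    store = fit_all(norm_ds, norm_cohort, cfg)
    MODEL_DIR.mkdir(parents=True, exist_ok=True)
    store.save(MODEL_DIR / "model_store.npz")
    print(f"fitted {store.n_voxels} voxels on {store.n_train} term subjects "
          f"({int(store.converged.sum())} converged, "
          f"{int(store.degenerate.sum())} degenerate)")

    mae = crossvalidate(norm_ds, norm_cohort, k=args.folds, seed=args.seed,
                        config=cfg)
    np.savez_compressed(
        MODEL_DIR / "cv_predictions.npz", mean=mae.held_out_mean,
        sd=mae.held_out_sd, folds=mae.fold_assignment,
    )
    pd.DataFrame(
        {"metric": list(mae.mean_mae), "mean_mae": list(mae.mean_mae.values())}
    ).to_csv(MODEL_DIR / "cv_mae.tsv", sep="\t", index=False,
             float_format="%.10g")
    print(f"{args.folds}-fold CV whole-mask MAE: "
          f"FA {mae.mean_mae['fa']:.4f}, MD {mae.mean_mae['md']:.4f} μm²/ms")


if __name__ == "__main__":
    main()
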