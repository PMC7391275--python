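"""Z-score every subject against the normative model; map group overlap.

Preterm (holdout) subjects are scored with the model trained on the full
term sample; term subjects are scored with the predictions of the
cross-validation fold that held them out. Extreme deviations (|Z| > 3.1)
are split into FA+/FA−/MD+/MD− masks, summarised as voxel-wise
percentage-overlap maps per group, and thresholded at the 4% consistency
rule.
"""

import argparse

import numpy as np

from neonorm.dataset import CohortTable, read_dataset
from neonorm.deviations import (
    consistency_mask,
    overlap_maps,
    threshold_extremes,
    write_overlap_maps,
    zscore_from_predictions,
    zscore_map,
)
from neonorm.gpr import VoxelModelStore

from common import DATA_DIR, DEFAULT_SEED, MAPS_DIR, MODEL_DIR


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=DEFAULT_SEED)
    parser.add_argument("--threshold", type=float, default=3.1)
    parser.add_argument("--consistency", type=float, default=4.0)
    args = parser.parse_args()

    dataset = read_dataset(
        {"fa": DATA_DIR / "fa.nii.gz", "md": DATA_DIR / "md.nii.gz"},
        DATA_DIR / "mask.nii.gz",
    )
    cohort = CohortTable.from_tsv(DATA_DIR / "cohort.tsv")
    store = VoxelModelStore.load(MODEL_DIR / "model_store.npz")
    cv = np.load(MODEL_DIR / "cv_predictions.npz")

    nidx = cohort.indices("normative")
    norm_cohort = CohortTable(cohort.frame.iloc[nidx].reset_index(drop=True))
    dev_term = zscore_from_predictions(
        dataset.subset_subjects(nidx).values, cv["mean"], cv["sd"],
        norm_cohort.subject_ids,
    )
    threshold_extremes(dev_term, args.threshold)

    aidx = cohort.indices("atypical")
    atyp_cohort = CohortTable(cohort.frame.iloc[aidx].reset_index(drop=True))
    dev_pre = zscore_map(
        dataset.subset_subjects(aidx), atyp_cohort, store, include_noise=True
    )
    threshold_extremes(dev_pre, args.threshold)

    MAPS_DIR.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        MAPS_DIR / "deviations.npz",
        term_z=dev_term.z, preterm_z=dev_pre.z,
        term_valid=dev_term.valid, preterm_valid=dev_pre.valid,
    )

    for group, dev in (("term", dev_term), ("preterm", dev_pre)):
        oms = overlap_maps(dev, group=group)
        write_overlap_maps(oms, dataset, MAPS_DIR, args.consistency)
        consistent = {
            name: int(consistency_mask(om, args.consistency).sum())
            for name, om in oms.items()
        }
        peak = {name: float(om.percent.max()) for name, om in oms.items()}
        print(f"{group}: voxels with >{args.consistency:g}% of subjects "
              f"extreme: {consistent}; peak overlap %: "
              f"{ {k: round(v, 1) for k, v in peak.items()} }")


if __name__ == "__main__":
    main()
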