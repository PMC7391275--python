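"""Generate the synthetic neonatal cohort and write it to results/data.

Creates FA/MD 4D volumes, the intracerebral mask, the covariate table and
the ground-truth sidecar for a two-group study: term-born (normative)
infants with GA ≥ 37 weeks and preterm infants (GA < 37 weeks) carrying
focal lesions whose load is linked to prematurity and to the outcome
scores.
"""

import argparse

import numpy as np

from neonorm.synthetic import generate_cohort, generate_scalar_maps, write_dataset

from common import DATA_DIR, DEFAULT_SEED, study_spec


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=DEFAULT_SEED)
    args = parser.parse_args()

    spec = study_spec(args.seed)
    cohort, truth = generate_cohort(spec)
    dataset = generate_scalar_maps(cohort, truth, spec)
    paths = write_dataset(dataset, cohort, DATA_DIR, truth, spec)

    n_term = len(cohort.rows("normative"))
    n_preterm = len(cohort.rows("atypical"))
    lesioned = [s for s in cohort.subject_ids if s in truth.lesion_masks]
    frac = [truth.lesion_fraction(s) for s in lesioned]
    print(f"cohort: {n_term} term + {n_preterm} preterm subjects")
    print(f"grid {spec.grid_shape}, {dataset.n_voxels} intracerebral voxels")
    print(f"{len(lesioned)} preterm subjects carry lesions; median lesion "
          f"load {np.median(frac):.2f}% of intracerebral voxels")
    print(f"value clipping events: {dataset.clip_counts}")
    print(f"written to {paths['cohort'].parent}")


if __name__ == "__main__":
    main()
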