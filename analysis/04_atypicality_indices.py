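"""Reduce each subject's extreme-deviation masks to whole-brain indices.

The four atypicality indices (FA+, FA−, MD+, MD−) are the percentage of
valid intracerebral voxels carrying an extreme deviation in that
direction; they are joined to the covariates as the input of the
statistical battery.
"""

import argparse

import numpy as np
import pandas as pd

from neonorm.atypicality import (
    INDEX_COLUMNS,
    atypicality_index,
    atypicality_table,
    write_atypicality_tsv,
)
from neonorm.dataset import CohortTable
from neonorm.deviations import DeviationMaps, threshold_extremes

from common import DATA_DIR, MAPS_DIR, RESULTS


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    cohort = CohortTable.from_tsv(DATA_DIR / "cohort.tsv")
    maps = np.load(MAPS_DIR / "deviations.npz")
    records = []
    for group, prefix in (("normative", "term"), ("atypical", "preterm")):
        ids = cohort.rows(group)["subject_id"].tolist()
        dev = DeviationMaps(
            z=maps[f"{prefix}_z"], subject_ids=ids,
            valid=maps[f"{prefix}_valid"],
        )
        threshold_extremes(dev, 3.1)
        records.append(atypicality_index(dev))
    table = atypicality_table(pd.concat(records, ignore_index=True), cohort)
    write_atypicality_tsv(table, RESULTS / "atypicality.tsv")

    med = table.groupby("group")[list(INDEX_COLUMNS)].median().round(3)
    print("median atypicality index (% of intracerebral voxels):")
    print(med.to_string())
    print(f"table written to {RESULTS / 'atypicality.tsv'}")


if __name__ == "__main__":
    main()
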