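"""Whole-brain atypicality indices.

Each subject's four directional extreme-deviation masks (FA+, FA−, MD+,
MD−) are reduced to whole-brain indices: the percentage of valid
intracerebral voxels carrying an extreme deviation in that direction.
Voxels with a degenerate normative model are excluded from numerator and
denominator alike, and their count is recorded per subject.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from neonorm.dataset import CohortTable
from neonorm.deviations import DeviationMaps
from neonorm.errors import InputError

INDEX_COLUMNS = ("fa_plus", "fa_minus", "md_plus", "md_minus")


def atypicality_index(dev: DeviationMaps) -> pd.DataFrame:
    """Per-subject indices: 100 × extreme-voxel count / valid voxel count.

    Returns one row per subject with the four indices (percent), the
    total mask size and the number of excluded (degenerate) voxels.
    """
    if not dev.masks:
        raise InputError("call threshold_extremes before atypicality_index")
    n_valid = int(dev.valid.sum())
    if n_valid == 0:
        raise InputError("empty intracerebral mask: no valid voxels")
    rows = {"subject_id": dev.subject_ids}
    for name in INDEX_COLUMNS:
        counts = dev.masks[name][:, dev.valid].sum(axis=1)
        rows[name] = 100.0 * counts / n_valid
    rows["n_mask_voxels"] = np.full(dev.n_subjects, dev.n_voxels)
    rows["n_excluded_voxels"] = np.full(dev.n_subjects, dev.n_voxels - n_valid)
    return pd.DataFrame(rows)


def atypicality_table(
    records: pd.DataFrame, cohort: CohortTable
) -> pd.DataFrame:
    """Join index records onto the cohort covariates by subject_id.

    Preserves the cohort table's row order; every record must match a
    cohort row and subject_ids must be unique.
    """
    if len(records) == 0:
        raise InputError("need at least one atypicality record")
    if records["subject_id"].duplicated().any():
        dupes = records["subject_id"][records["subject_id"].duplicated()]
        raise InputError(f"duplicate subject_id in records: {sorted(set(dupes))}")
    unknown = set(records["subject_id"]) - set(cohort.subject_ids)
    if unknown:
        raise InputError(f"records for unknown subjects: {sorted(unknown)}")
    merged = cohort.frame.merge(records, on="subject_id", how="inner")
    return merged.reset_index(drop=True)


def write_atypicality_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_atypicality_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
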