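"""Shared paths and study configuration for the numbered analysis scripts.

The scripts run the desk-scale synthetic study end to end: a 100-subject
term cohort and an 82-subject preterm cohort on a 14³ grid (about a
thousand intracerebral voxels), small enough to fit per-voxel GPs on one
CPU in minutes while preserving every stage of the analysis.
"""

from pathlib import Path

from neonorm.experiments import battery_spec
from neonorm.gpr import FitConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA_DIR = RESULTS / "data"
MODEL_DIR = RESULTS / "model"
MAPS_DIR = RESULTS / "maps"

DEFAULT_SEED = 7


def study_spec(seed: int = DEFAULT_SEED):
    return battery_spec(seed)


def fit_config(seed: int = DEFAULT_SEED) -> FitConfig:
    return FitConfig(restarts=1, maxiter=60, seed=seed)
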