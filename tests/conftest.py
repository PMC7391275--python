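import numpy as np
import pytest

from neonorm.dataset import CohortTable
from neonorm.gpr import FitConfig, fit_all
from neonorm.synthetic import CohortSpec, generate_cohort, generate_scalar_maps


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """A small but fully featured cohort: 30 term + 12 preterm, 10³ grid."""
    return CohortSpec(
        n_normative=30,
        n_atypical=12,
        grid_shape=(10, 10, 10),
        mask_radius_frac=0.4,
        lesion_radius_range=(1.0, 1.8),
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    table, truth = generate_cohort(tiny_spec)
    dataset = generate_scalar_maps(table, truth, tiny_spec)
    return table, truth, dataset


@pytest.fixture(scope="session")
def fast_config() -> FitConfig:
    return FitConfig(restarts=1, maxiter=60, seed=0)


@pytest.fixture(scope="session")
def tiny_fit(tiny_cohort, fast_config):
    """Normative-model fit of the tiny cohort's term subjects."""
    table, truth, dataset = tiny_cohort
    idx = table.indices("normative")
    norm_table = CohortTable(table.frame.iloc[idx].reset_index(drop=True))
    norm_ds = dataset.subset_subjects(idx)
    store = fit_all(norm_ds, norm_table, fast_config)
    return norm_table, norm_ds, store
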