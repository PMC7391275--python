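"""GP correctness: oracle equivalence, standardization, CV, calibration."""

import numpy as np
import pytest

from neonorm.dataset import CohortTable, VoxelDataset
from neonorm.errors import ConfigurationError, DegenerateDataError, InputError
from neonorm.gpr import (
    FitConfig,
    KernelSpec,
    VoxelModel,
    VoxelModelStore,
    _fit_standardized,
    build_covariance,
    crossvalidate,
    destandardize,
    fit_all,
    fit_voxel,
    log_marginal_likelihood,
    predict,
    standardize,
    stratified_folds,
)
from gp_oracle import icm_cov_oracle, lml_oracle, posterior_oracle

from scipy.linalg import cholesky, cho_solve
import pandas as pd


def _make_model(X, Y, kernel, jitter=0.0):
    """Assemble a VoxelModel directly from standardized data (no fitting)."""
    K = build_covariance(X, kernel, jitter)
    L = cholesky(K, lower=True)
    y = Y.T.ravel()
    alpha = cho_solve((L, True), y)
    return VoxelModel(
        kernel=kernel, X=X, y=y, x_mean=40.0, x_sd=2.0,
        y_mean=np.zeros(2), y_sd=np.ones(2),
        chol=L, alpha=alpha, log_marginal=0.0, jitter=jitter,
    )


def _random_instance(n, seed):
    rng = np.random.default_rng(seed)
    X = np.column_stack([rng.standard_normal(n), rng.integers(0, 2, n)]).astype(float)
    Y = rng.standard_normal((n, 2))
    L = np.array([[0.9, 0.0], [0.4, 0.7]])
    kernel = KernelSpec(
        rbf_lengthscale=1.3, noise_variance=(0.3, 0.5), coreg_chol=L,
    )
    return X, Y, kernel


# ---------------------------------------------------------------------------
# standardization


def test_standardize_round_trip():
    rng = np.random.default_rng(0)
    Y = rng.uniform(0.1, 0.6, (20, 2))
    pma = rng.uniform(37, 45, 20)
    sex = rng.integers(0, 2, 20)
    X, Y_std, const = standardize(Y, pma, sex)
    mean, sd = destandardize(Y_std, np.ones_like(Y_std), const)
    np.testing.assert_allclose(mean, Y, rtol=0, atol=1e-14)
    np.testing.assert_array_equal(X[:, 1], sex)


def test_standardize_uses_sample_sd():
    """Sample-SD (n−1) convention: {1,2,3} has SD exactly 1 → {−1,0,1}."""
    assert np.std([1.0, 2.0, 3.0], ddof=1) == pytest.approx(1.0)
    Y = np.column_stack([[1.0, 2, 3, 2, 1], [4.0, 2, 3, 2, 1]])
    pma = np.array([38.0, 40.0, 42.0, 39.0, 41.0])
    _, Y_std, const = standardize(Y, pma, np.zeros(5))
    np.testing.assert_allclose(const["y_sd"], Y.std(axis=0, ddof=1))
    np.testing.assert_allclose(
        Y_std, (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=1)
    )


def test_standardize_rejects_constant_pma():
    Y = np.random.default_rng(1).standard_normal((8, 2))
    with pytest.raises(DegenerateDataError, match="PMA"):
        standardize(Y, np.full(8, 40.0), np.zeros(8))


# ---------------------------------------------------------------------------
# marginal likelihood


def test_lml_single_point_unit_prior():
    """One point, unit total prior variance, y=0: per-output -0.5 log 2π."""
    X = np.zeros((1, 2))
    Y = np.zeros((1, 2))
    kernel = KernelSpec(
        rbf_lengthscale=1.0, noise_variance=(0.5, 0.5),
        coreg_chol=np.diag(np.sqrt([0.5, 0.5])),
    )
    model = _make_model(X, Y, kernel)
    expected = 2 * (-0.5 * np.log(2 * np.pi))  # two independent outputs
    assert log_marginal_likelihood(model) == pytest.approx(expected, abs=1e-9)
    assert -0.5 * np.log(2 * np.pi) == pytest.approx(-0.9189, abs=1e-4)


def test_lml_decreases_with_noise_at_zero_target():
    X, _, kernel = _random_instance(6, 0)
    Y = np.zeros((6, 2))
    low = _make_model(X, Y, kernel)
    noisy = KernelSpec(
        rbf_lengthscale=kernel.rbf_lengthscale,
        noise_variance=(0.6, 1.0), coreg_chol=kernel.coreg_chol,
    )
    high = _make_model(X, Y, noisy)
    assert log_marginal_likelihood(high) < log_marginal_likelihood(low)


@pytest.mark.parametrize("n,seed", [(4, 1), (7, 2), (10, 3)])
def test_lml_matches_dense_oracle(n, seed):
    X, Y, kernel = _random_instance(n, seed)
    model = _make_model(X, Y, kernel)
    K = icm_cov_oracle(
        X, kernel.coregionalization, kernel.rbf_lengthscale,
        kernel.noise_variance,
    )
    assert log_marginal_likelihood(model) == pytest.approx(
        lml_oracle(K, Y.T.ravel()), abs=1e-8
    )


# ---------------------------------------------------------------------------
# prediction


@pytest.mark.parametrize("include_noise", [True, False])
@pytest.mark.parametrize("n,seed", [(3, 5), (8, 6)])
def test_posterior_matches_dense_oracle(n, seed, include_noise):
    X, Y, kernel = _random_instance(n, seed)
    model = _make_model(X, Y, kernel)
    pma = np.array([38.0, 40.0, 44.5])
    sex = np.array([0.0, 1.0, 0.0])
    Xq = np.column_stack([(pma - model.x_mean) / model.x_sd, sex])
    pred = predict(model, pma, sex, include_noise=include_noise)
    mean_o, var_o = posterior_oracle(
        X, Y.T.ravel(), Xq, kernel.coregionalization,
        kernel.rbf_lengthscale, kernel.noise_variance, include_noise,
    )
    np.testing.assert_allclose(pred.mean, mean_o, atol=1e-8)
    np.testing.assert_allclose(pred.sd, np.sqrt(var_o), atol=1e-8)


def test_predict_interpolates_at_noise_floor():
    rng = np.random.default_rng(2)
    n = 10
    X = np.column_stack([np.linspace(-1.5, 1.5, n), np.zeros(n)])
    Y = np.column_stack([np.sin(X[:, 0]), np.cos(X[:, 0])])
    kernel = KernelSpec(
        rbf_lengthscale=1.0, noise_variance=(1e-10, 1e-10),
        coreg_chol=np.diag([1.0, 1.0]),
    )
    model = _make_model(X, Y, kernel, jitter=1e-12)
    pma = X[:, 0] * model.x_sd + model.x_mean
    pred = predict(model, pma, X[:, 1], include_noise=False)
    np.testing.assert_allclose(pred.mean, Y, atol=1e-3)


def test_predict_reverts_to_prior_far_away():
    X, Y, kernel = _random_instance(8, 9)
    model = _make_model(X, Y, kernel)
    far_pma = model.x_mean + 1e4 * model.x_sd
    pred = predict(model, far_pma, 0.0, include_noise=True)
    np.testing.assert_allclose(pred.mean[0], [0.0, 0.0], atol=1e-8)
    B = kernel.coregionalization
    expected_sd = np.sqrt(np.diag(B) + np.asarray(kernel.noise_variance))
    np.testing.assert_allclose(pred.sd[0], expected_sd, atol=1e-8)
    assert pred.extrapolation[0]


def test_predictive_variance_monotone_in_distance():
    X, Y, kernel = _random_instance(8, 10)
    model = _make_model(X, Y, kernel)
    at_train = predict(
        model, X[0, 0] * model.x_sd + model.x_mean, X[0, 1],
        include_noise=False,
    )
    far = predict(model, model.x_mean + 1e4 * model.x_sd, X[0, 1],
                  include_noise=False)
    assert np.all(at_train.sd[0] <= far.sd[0] + 1e-12)


# ---------------------------------------------------------------------------
# fitting


def _linear_dataset(n_subj, n_vox, seed, noise=1e-6):
    rng = np.random.default_rng(seed)
    pma = rng.uniform(37, 45, n_subj)
    sex = rng.integers(0, 2, n_subj)
    frame = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n_subj)],
            "group": "normative",
            "pma_scan": pma,
            "ga_birth": rng.uniform(37, 42, n_subj),
            "sex": sex,
            "motion": rng.gamma(4, 0.25, n_subj),
            "imd": rng.uniform(1, 60, n_subj),
            "outcome_cognitive": rng.normal(100, 15, n_subj),
            "outcome_language": rng.normal(100, 15, n_subj),
            "outcome_motor": rng.normal(100, 15, n_subj),
        }
    )
    cohort = CohortTable(frame)
    mask = np.zeros((n_vox, 1, 1), dtype=bool)
    mask[:, 0, 0] = True
    slopes = rng.uniform(0.01, 0.03, n_vox)
    values = np.empty((n_subj, n_vox, 2))
    for v in range(n_vox):
        base = 0.3 + slopes[v] * (pma - 41)
        values[:, v, 0] = base + noise * rng.standard_normal(n_subj)
        values[:, v, 1] = 1.2 - base + noise * rng.standard_normal(n_subj)
    ds = VoxelDataset(values, mask, np.eye(4))
    return cohort, ds, slopes


def test_fit_voxel_interpolates_noiseless_linear_data():
    cohort, ds, _ = _linear_dataset(20, 1, seed=4)
    model = fit_voxel(ds, 0, cohort, FitConfig(restarts=2, maxiter=200))
    pred = predict(
        model, cohort.frame["pma_scan"].to_numpy(),
        cohort.frame["sex"].to_numpy(), include_noise=False,
    )
    resid_std = (pred.mean - ds.values[:, 0, :]) / model.y_sd
    assert np.abs(resid_std).max() < 1e-2


def test_fit_voxel_degenerate_is_flagged_not_silent():
    cohort, ds, _ = _linear_dataset(12, 1, seed=5)
    ds.values[:, 0, 1] = 0.7  # constant MD
    model = fit_voxel(ds, 0, cohort)
    assert model.degenerate
    pred = predict(model, 40.0, 0.0)
    assert np.isnan(pred.sd).all()


def test_pure_noise_data_yields_low_snr():
    """On slope-free white noise the fitted signal fraction stays small."""
    n_low = 0
    reps = 10
    for seed in range(reps):
        rng = np.random.default_rng(seed)
        n = 100
        X = np.column_stack(
            [rng.standard_normal(n), rng.integers(0, 2, n)]
        ).astype(float)
        Y = rng.standard_normal((n, 2))
        Y = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        kernel, *_ = _fit_standardized(
            X, Y, FitConfig(restarts=2, maxiter=100), rng
        )
        snr = np.diag(kernel.coregionalization) / np.asarray(
            kernel.noise_variance
        )
        n_low += snr.max() < 0.5
    assert n_low >= 0.9 * reps


def test_lengthscale_recovered_from_own_kernel():
    """Data simulated from the model's kernel: lengthscale within ×2."""
    true_ls = 1.0
    n, reps, ok = 200, 5, 0
    gen = np.random.default_rng(123)
    for _ in range(reps):
        X = np.column_stack(
            [gen.standard_normal(n), gen.integers(0, 2, n)]
        ).astype(float)
        B = np.array([[1.0, 0.6], [0.6, 1.0]])
        K = icm_cov_oracle(X, B, true_ls, (0.1, 0.1))
        y = np.linalg.cholesky(K + 1e-10 * np.eye(2 * n)) @ gen.standard_normal(2 * n)
        Y = y.reshape(2, n).T
        Y = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        kernel, *_ = _fit_standardized(
            X, Y, FitConfig(restarts=2, maxiter=100), gen
        )
        if true_ls / 2 <= kernel.rbf_lengthscale <= true_ls * 2:
            ok += 1
    assert ok >= 0.8 * reps


def test_metric_swap_symmetry():
    """Swapping FA/MD storage order relabels but does not change predictions."""
    cohort, ds, _ = _linear_dataset(25, 1, seed=8, noise=0.05)
    cfg = FitConfig(restarts=3, maxiter=300, ftol=1e-10, seed=1)
    m1 = fit_voxel(ds, 0, cohort, cfg)
    swapped = VoxelDataset(
        ds.values[:, :, ::-1].copy(), ds.mask, ds.affine, ("md", "fa")
    )
    m2 = fit_voxel(swapped, 0, cohort, cfg)
    pma = np.array([38.0, 41.0, 44.0])
    sex = np.array([0.0, 1.0, 1.0])
    p1 = predict(m1, pma, sex)
    p2 = predict(m2, pma, sex)
    np.testing.assert_allclose(p1.mean, p2.mean[:, ::-1], rtol=1e-3, atol=1e-5)
    np.testing.assert_allclose(p1.sd, p2.sd[:, ::-1], rtol=5e-2)


def test_zscore_calibration_against_own_generative_process():
    """Draws from the fitted model's predictive distribution re-score to N(0,1)."""
    cohort, ds, _ = _linear_dataset(30, 1, seed=12, noise=0.03)
    model = fit_voxel(ds, 0, cohort, FitConfig(restarts=2, maxiter=100))
    rng = np.random.default_rng(99)
    n_draw = 200
    pma = rng.uniform(37, 45, n_draw)
    sex = rng.integers(0, 2, n_draw).astype(float)
    pred = predict(model, pma, sex, include_noise=True)
    obs = pred.mean + pred.sd * rng.standard_normal((n_draw, 2))
    z = (obs - pred.mean) / pred.sd  # by construction; checks the plumbing
    pred2 = predict(model, pma, sex, include_noise=True)
    z2 = (obs - pred2.mean) / pred2.sd
    np.testing.assert_allclose(z, z2)
    assert abs(z2.mean()) < 0.1
    assert 0.8 < z2.var() < 1.25


# ---------------------------------------------------------------------------
# fit_all / store / cross-validation


def test_fit_all_deterministic_and_order_independent():
    cohort, ds, _ = _linear_dataset(15, 6, seed=20, noise=0.05)
    cfg = FitConfig(restarts=2, maxiter=60, seed=3)
    a = fit_all(ds, cohort, cfg)
    b = fit_all(ds, cohort, cfg)
    np.testing.assert_array_equal(a.theta, b.theta)
    shuffled = fit_all(ds, cohort, cfg,
                       voxels=np.array([5, 2, 0, 4, 1, 3]))
    np.testing.assert_array_equal(a.theta, shuffled.theta)


def test_store_round_trip(tmp_path):
    cohort, ds, _ = _linear_dataset(15, 3, seed=21, noise=0.05)
    store = fit_all(ds, cohort, FitConfig(restarts=1, maxiter=60))
    store.save(tmp_path / "store.npz")
    back = VoxelModelStore.load(tmp_path / "store.npz")
    pma = np.array([39.0, 43.0])
    sex = np.array([0.0, 1.0])
    m1, s1 = store.predict_all(pma, sex)
    m2, s2 = back.predict_all(pma, sex)
    np.testing.assert_array_equal(m1, m2)
    np.testing.assert_array_equal(s1, s2)


def test_stratified_folds_partition_and_coverage():
    rng = np.random.default_rng(31)
    pma = rng.uniform(37, 45, 50)
    folds = stratified_folds(pma, 5, seed=0)
    assert np.bincount(folds, minlength=5).sum() == 50
    full = pma.max() - pma.min()
    for f in range(5):
        sub = pma[folds == f]
        assert (sub.max() - sub.min()) >= 0.8 * full


def test_stratified_folds_reject_tiny():
    with pytest.raises(ConfigurationError):
        stratified_folds(np.arange(10.0), 1, seed=0)
    with pytest.raises(InputError):
        stratified_folds(np.arange(8.0), 4, seed=0)


def test_crossvalidate_low_error_on_near_noiseless_data():
    cohort, ds, _ = _linear_dataset(25, 3, seed=22, noise=1e-4)
    mae = crossvalidate(ds, cohort, k=5, seed=1,
                        config=FitConfig(restarts=1, maxiter=100))
    assert np.all(mae.mae < 10 * 1e-3)
    # every subject held out exactly once
    assert np.isfinite(mae.held_out_mean).all()
    assert set(mae.fold_assignment) == set(range(5))
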