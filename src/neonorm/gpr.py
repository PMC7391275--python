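"""Per-voxel two-output Gaussian process regression of (FA, MD) on (PMA, sex).

Model
-----
At each voxel the two standardized outputs are modelled jointly with an
intrinsic coregionalization (ICM) covariance

    K = B ⊗ k_RBF(X, X')  +  diag(σ²_FA I_n, σ²_MD I_n)

where ``X`` holds the standardized PMA at scan and the 0/1 sex code with
one shared RBF lengthscale over both coordinates, and ``B = L Lᵀ`` is a
2×2 positive-semidefinite coregionalization matrix parameterized by its
Cholesky factor (3 free parameters). The RBF variance is fixed at 1: the
output scales live entirely in ``B`` (the two are unidentifiable in a
product). Hyperparameters — lengthscale, the three entries of ``L`` and
the two white-noise variances — are optimized by maximizing the exact log
marginal likelihood

    log p(y) = −½ yᵀK⁻¹y − ½ log|K| − (N/2) log 2π

with analytic gradients, quasi-Newton steps on log-transformed positive
parameters, and a configurable number of seeded restarts. Inference is
exact (Cholesky); a small diagonal jitter is escalated ×10 up to three
times if factorization fails.

Outputs are standardized per voxel (sample SD, n−1 denominator) so that
FA (~0.2, unitless) and MD (~1 μm²/ms) can share one kernel; predictions
are returned in original units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import optimize
from scipy.linalg import cho_solve, cholesky, solve_triangular

from neonorm.dataset import CohortTable, VoxelDataset
from neonorm.errors import (
    ConfigurationError,
    DegenerateDataError,
    InputError,
    NumericalError,
)

logger = logging.getLogger(__name__)

LOG_2PI = float(np.log(2.0 * np.pi))

#: Variance below which an output is treated as degenerate (constant).
DEGENERATE_VAR = 1e-24


# ---------------------------------------------------------------------------
# configuration & kernel


@dataclass(frozen=True)
class FitConfig:
    """Optimizer configuration for per-voxel hyperparameter estimation."""

    restarts: int = 3
    maxiter: int = 100
    jitter: float = 1e-8
    seed: int = 0
    #: SD of the log-parameter jitter applied to restarts after the first.
    restart_jitter_sd: float = 0.3
    #: L-BFGS relative objective tolerance; hyperparameters only need a
    #: few significant digits for stable predictive moments.
    ftol: float = 1e-6

    def validate(self) -> None:
        if self.restarts < 1:
            raise ConfigurationError("restarts must be >= 1")
        if self.jitter <= 0:
            raise ConfigurationError("jitter must be > 0")


@dataclass
class KernelSpec:
    """ICM kernel hyperparameters (standardized-output scale).

    ``rbf_variance`` is fixed at 1.0 by construction; the per-output
    signal scales are carried by the coregionalization matrix
    ``B = coreg_chol @ coreg_chol.T``.
    """

    rbf_lengthscale: float
    noise_variance: tuple[float, float]
    coreg_chol: np.ndarray
    rbf_variance: float = 1.0

    @property
    def coregionalization(self) -> np.ndarray:
        L = np.asarray(self.coreg_chol)
        return L @ L.T

    def validate(self) -> None:
        if self.rbf_lengthscale <= 0:
            raise ConfigurationError("rbf_lengthscale must be > 0")
        if any(v <= 0 for v in self.noise_variance):
            raise ConfigurationError("noise variances must be > 0")
        L = np.asarray(self.coreg_chol)
        if L.shape != (2, 2) or L[0, 1] != 0:
            raise ConfigurationError("coreg_chol must be 2x2 lower-triangular")

    def theta(self) -> np.ndarray:
        """Pack into the optimizer vector (log transform on positives)."""
        L = np.asarray(self.coreg_chol)
        return np.array(
            [
                np.log(self.rbf_lengthscale),
                np.log(L[0, 0]),
                L[1, 0],
                np.log(L[1, 1]),
                np.log(self.noise_variance[0]),
                np.log(self.noise_variance[1]),
            ]
        )

    @classmethod
    def from_theta(cls, theta: np.ndarray) -> "KernelSpec":
        L = np.array(
            [[np.exp(theta[1]), 0.0], [theta[2], np.exp(theta[3])]]
        )
        return cls(
            rbf_lengthscale=float(np.exp(theta[0])),
            noise_variance=(float(np.exp(theta[4])), float(np.exp(theta[5]))),
            coreg_chol=L,
        )


def rbf(x1: np.ndarray, x2: np.ndarray, lengthscale: float) -> np.ndarray:
    """Unit-variance RBF kernel matrix between row-wise input sets."""
    d2 = (
        np.sum(x1**2, axis=1)[:, None]
        + np.sum(x2**2, axis=1)[None, :]
        - 2.0 * x1 @ x2.T
    )
    return np.exp(-0.5 * np.maximum(d2, 0.0) / lengthscale**2)


def build_covariance(
    X: np.ndarray, kernel: KernelSpec, jitter: float = 0.0
) -> np.ndarray:
    """Dense (2n × 2n) training covariance, outputs stacked FA-then-MD."""
    n = X.shape[0]
    K = np.kron(kernel.coregionalization, rbf(X, X, kernel.rbf_lengthscale))
    noise = np.repeat(np.asarray(kernel.noise_variance), n)
    K[np.diag_indices_from(K)] += noise + jitter
    return K


def _chol_with_jitter(
    K: np.ndarray, jitter: float
) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor with ×10 jitter escalation (3 retries)."""
    current = jitter
    for _ in range(4):
        try:
            L = cholesky(
                K + current * np.eye(K.shape[0]), lower=True,
                check_finite=False,
            )
            return L, current
        except np.linalg.LinAlgError:
            current *= 10.0
    raise NumericalError(
        f"covariance not positive definite after jitter escalation to "
        f"{current / 10:.1e}"
    )


# ---------------------------------------------------------------------------
# marginal likelihood and gradient


def _nll_grad(
    theta: np.ndarray, X: np.ndarray, y2: np.ndarray, D2: np.ndarray,
    jitter: float,
) -> tuple[float, np.ndarray]:
    """Negative log marginal likelihood and gradient wrt theta.

    ``y2`` is (n, 2) standardized targets; ``D2`` the precomputed squared
    distance matrix of X (shared across voxels). Gradients use
    d lml/dθ = ½ tr((ααᵀ − K⁻¹) ∂K/∂θ) evaluated blockwise on the 2×2
    output structure, so the cost per parameter is O(n²).
    """
    n = X.shape[0]
    ls = np.exp(theta[0])
    a, b, c = np.exp(theta[1]), theta[2], np.exp(theta[3])
    s2 = np.exp(theta[4:6])
    Lc = np.array([[a, 0.0], [b, c]])
    B = Lc @ Lc.T
    Kr = np.exp(-0.5 * D2 / ls**2)
    K = np.kron(B, Kr)
    K[np.diag_indices_from(K)] += np.repeat(s2, n) + jitter
    try:
        Lchol = cholesky(K, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        return 1e25, np.zeros_like(theta)
    y = y2.T.ravel()  # stacked (FA block then MD block)
    alpha = cho_solve((Lchol, True), y, check_finite=False)
    nll = (
        0.5 * float(y @ alpha)
        + float(np.log(np.diag(Lchol)).sum())
        + 0.5 * 2 * n * LOG_2PI
    )
    Kinv = cho_solve((Lchol, True), np.eye(2 * n), check_finite=False)
    W = np.outer(alpha, alpha) - Kinv
    W4 = W.reshape(2, n, 2, n)

    # blockwise inner products with Kr and its lengthscale derivative
    dKr = Kr * (D2 / ls**2)  # dKr/d(log ls)
    M = np.einsum("anbm,nm->ab", W4, Kr)
    N = np.einsum("anbm,nm->ab", W4, dKr)

    dB_da = np.array([[2 * a, b], [b, 0.0]]) * a  # chain rule for log a
    dB_db = np.array([[0.0, a], [a, 2 * b]])
    dB_dc = np.array([[0.0, 0.0], [0.0, 2 * c]]) * c

    grad = np.empty(6)
    grad[0] = 0.5 * float(np.sum(B * N))
    grad[1] = 0.5 * float(np.sum(dB_da * M))
    grad[2] = 0.5 * float(np.sum(dB_db * M))
    grad[3] = 0.5 * float(np.sum(dB_dc * M))
    trW = np.einsum("anan->a", W4)
    grad[4] = 0.5 * s2[0] * trW[0]
    grad[5] = 0.5 * s2[1] * trW[1]
    return nll, -grad


# ---------------------------------------------------------------------------
# model container


@dataclass
class VoxelModel:
    """A fitted per-voxel GP: hyperparameters + cached decomposition."""

    kernel: KernelSpec
    X: np.ndarray               # (n, 2) standardized training inputs
    y: np.ndarray               # (2n,) stacked standardized targets
    x_mean: float
    x_sd: float
    y_mean: np.ndarray          # (2,)
    y_sd: np.ndarray            # (2,)
    chol: np.ndarray | None
    alpha: np.ndarray | None
    log_marginal: float
    jitter: float
    converged: bool = True
    degenerate: bool = False
    restarts_used: int = 1
    metric_names: tuple[str, ...] = ("fa", "md")

    @property
    def n_train(self) -> int:
        return self.X.shape[0]

    @property
    def pma_range(self) -> tuple[float, float]:
        pma = self.X[:, 0] * self.x_sd + self.x_mean
        return float(pma.min()), float(pma.max())


@dataclass
class PredictiveDistribution:
    """Posterior mean/SD per metric in original units at query points."""

    mean: np.ndarray            # (m, 2)
    sd: np.ndarray              # (m, 2)
    includes_noise: bool
    extrapolation: np.ndarray   # (m,) bool, True when PMA outside training


def log_marginal_likelihood(model: VoxelModel) -> float:
    """Exact log marginal likelihood recomputed from the cached factors."""
    if model.chol is None or model.alpha is None:
        raise InputError("model has no cached factorization")
    n_tot = model.y.size
    return (
        -0.5 * float(model.y @ model.alpha)
        - float(np.log(np.diag(model.chol)).sum())
        - 0.5 * n_tot * LOG_2PI
    )


def standardize(
    Y: np.ndarray, pma: np.ndarray, sex: np.ndarray
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray | float]]:
    """Center/scale outputs and PMA (sample SD, n−1); sex passes as 0/1.

    Returns (X, Y_std, constants). Raises on degenerate predictors; a
    zero-variance *output* raises :class:`DegenerateDataError` and is
    handled by :func:`fit_voxel` as a flagged noise-only voxel.
    """
    Y = np.asarray(Y, dtype=np.float64)
    pma = np.asarray(pma, dtype=np.float64)
    if Y.shape[0] < 5:
        raise InputError("need at least 5 training subjects")
    x_sd = pma.std(ddof=1)
    if x_sd**2 < DEGENERATE_VAR:
        raise DegenerateDataError("zero predictor variance: PMA is constant")
    y_mean = Y.mean(axis=0)
    y_sd = Y.std(axis=0, ddof=1)
    if np.any(y_sd**2 < DEGENERATE_VAR):
        raise DegenerateDataError("zero output variance at this voxel")
    x_mean = pma.mean()
    X = np.column_stack([(pma - x_mean) / x_sd, np.asarray(sex, float)])
    Y_std = (Y - y_mean) / y_sd
    constants = {
        "x_mean": float(x_mean), "x_sd": float(x_sd),
        "y_mean": y_mean, "y_sd": y_sd,
    }
    return X, Y_std, constants


def destandardize(
    mean_std: np.ndarray, sd_std: np.ndarray, constants: dict
) -> tuple[np.ndarray, np.ndarray]:
    """Exact inverse of :func:`standardize` for predictive moments."""
    return (
        mean_std * constants["y_sd"] + constants["y_mean"],
        sd_std * constants["y_sd"],
    )


def _initial_theta(Y_std: np.ndarray) -> np.ndarray:
    """Data-driven starting point: split unit variance ~70/30 signal/noise."""
    C = np.cov(Y_std.T) * 0.7 + 1e-3 * np.eye(2)
    L = cholesky(C, lower=True)
    return np.array(
        [0.0, np.log(L[0, 0]), L[1, 0], np.log(L[1, 1]),
         np.log(0.3), np.log(0.3)]
    )


def _fit_standardized(
    X: np.ndarray,
    Y_std: np.ndarray,
    config: FitConfig,
    rng: np.random.Generator,
    D2: np.ndarray | None = None,
) -> tuple[KernelSpec, float, bool, int]:
    """Maximize the marginal likelihood; returns best kernel and diagnostics."""
    if D2 is None:
        diff = X[:, None, :] - X[None, :, :]
        D2 = np.sum(diff**2, axis=2)
    theta0 = _initial_theta(Y_std)
    best = None
    converged = False
    used = 0
    for r in range(config.restarts):
        start = theta0.copy()
        if r > 0:
            start += config.restart_jitter_sd * rng.standard_normal(6)
        res = optimize.minimize(
            _nll_grad,
            start,
            args=(X, Y_std, D2, config.jitter),
            jac=True,
            method="L-BFGS-B",
            # generous box bounds on the log/free parameters; they only
            # stop line-search excursions into overflow territory
            bounds=[(-5, 8), (-10, 3), (-20, 20), (-10, 3), (-20, 3), (-20, 3)],
            options={"maxiter": config.maxiter, "ftol": config.ftol},
        )
        used = r + 1
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            converged = True
    kernel = KernelSpec.from_theta(best.x)
    return kernel, -float(best.fun), converged, used


def _restart_rng(seed: int, voxel_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, voxel_index]))


def fit_voxel(
    dataset: VoxelDataset,
    voxel: int,
    cohort: CohortTable,
    config: FitConfig = FitConfig(),
) -> VoxelModel:
    """Fit one voxel's two-output GP on the given cohort rows.

    Degenerate voxels (an output with zero variance across subjects) are
    returned flagged ``degenerate=True`` with no kernel optimization; they
    are excluded from downstream Z-score denominators rather than scored.
    """
    config.validate()
    if not 0 <= voxel < dataset.n_voxels:
        raise InputError(f"voxel index {voxel} outside mask (0..{dataset.n_voxels - 1})")
    pma = cohort.frame["pma_scan"].to_numpy()
    sex = cohort.frame["sex"].to_numpy()
    Y = dataset.values[:, voxel, :]
    if Y.shape[0] != len(cohort):
        raise InputError("dataset subjects do not match cohort rows")
    try:
        X, Y_std, const = standardize(Y, pma, sex)
    except DegenerateDataError:
        x_mean, x_sd = float(pma.mean()), float(pma.std(ddof=1))
        return VoxelModel(
            kernel=KernelSpec(1.0, (1.0, 1.0), np.zeros((2, 2))),
            X=np.column_stack([(pma - x_mean) / max(x_sd, 1e-12), sex]),
            y=np.zeros(2 * len(pma)),
            x_mean=x_mean, x_sd=x_sd,
            y_mean=Y.mean(axis=0), y_sd=np.ones(2),
            chol=None, alpha=None, log_marginal=-np.inf,
            jitter=config.jitter, converged=False, degenerate=True,
        )
    rng = _restart_rng(config.seed, voxel)
    kernel, lml, converged, used = _fit_standardized(X, Y_std, config, rng)
    if not converged:
        logger.warning("voxel %d: optimizer did not converge on any restart", voxel)
    K = build_covariance(X, kernel)
    L, jit = _chol_with_jitter(K, config.jitter)
    y = Y_std.T.ravel()
    alpha = cho_solve((L, True), y, check_finite=False)
    return VoxelModel(
        kernel=kernel, X=X, y=y,
        x_mean=const["x_mean"], x_sd=const["x_sd"],
        y_mean=const["y_mean"], y_sd=const["y_sd"],
        chol=L, alpha=alpha, log_marginal=lml, jitter=jit,
        converged=converged, degenerate=False, restarts_used=used,
    )


def predict(
    model: VoxelModel,
    pma: np.ndarray | float,
    sex: np.ndarray | float,
    include_noise: bool = True,
) -> PredictiveDistribution:
    """GP posterior mean and SD at query covariates, in original units.

    With ``include_noise`` the per-output white-noise variance is added to
    the posterior variance before de-standardization, i.e. the SD reflects
    the total predictive uncertainty for a *new observation* — the
    denominator used by the deviation Z-scores. Queries with PMA outside
    the training range are flagged ``extrapolation``.
    """
    pma = np.atleast_1d(np.asarray(pma, dtype=np.float64))
    sex = np.broadcast_to(np.atleast_1d(np.asarray(sex, float)), pma.shape)
    lo, hi = model.pma_range
    extrap = (pma < lo) | (pma > hi)
    if extrap.any():
        logger.debug(
            "%d/%d queries extrapolate beyond the training PMA range "
            "[%.1f, %.1f]", int(extrap.sum()), pma.size, lo, hi,
        )
    m = pma.size
    if model.degenerate:
        mean = np.broadcast_to(model.y_mean, (m, 2)).copy()
        sd = np.full((m, 2), np.nan)
        return PredictiveDistribution(mean, sd, include_noise, extrap)
    Xq = np.column_stack([(pma - model.x_mean) / model.x_sd, sex])
    B = model.kernel.coregionalization
    Krq = rbf(Xq, model.X, model.kernel.rbf_lengthscale)   # (m, n)
    Kstar = np.kron(B, Krq)                                # (2m, 2n)
    mean_std = (Kstar @ model.alpha).reshape(2, m).T
    V = solve_triangular(model.chol, Kstar.T, lower=True, check_finite=False)
    var_std = np.repeat(np.diag(B), m).reshape(2, m).T - (V**2).sum(axis=0).reshape(2, m).T
    var_std = np.maximum(var_std, 1e-12)
    if include_noise:
        var_std = var_std + np.asarray(model.kernel.noise_variance)[None, :]
    mean, sd = destandardize(
        mean_std, np.sqrt(var_std),
        {"y_mean": model.y_mean, "y_sd": model.y_sd},
    )
    return PredictiveDistribution(mean, sd, include_noise, extrap)


# ---------------------------------------------------------------------------
# whole-mask fitting


@dataclass
class VoxelModelStore:
    """All per-voxel fitted models of one run, in flat-array form.

    Self-contained for prediction: holds the shared standardized inputs,
    per-voxel standardization constants and standardized targets, so the
    covariance factorizations can be rebuilt exactly on load.
    """

    schema: str
    X: np.ndarray                # (n, 2) standardized training inputs
    x_mean: float
    x_sd: float
    theta: np.ndarray            # (V, 6) packed kernel parameters
    y_mean: np.ndarray           # (V, 2)
    y_sd: np.ndarray             # (V, 2)
    Y_std: np.ndarray            # (V, n, 2)
    log_marginal: np.ndarray     # (V,)
    converged: np.ndarray        # (V,) bool
    degenerate: np.ndarray       # (V,) bool
    jitter: np.ndarray           # (V,)
    metric_names: tuple[str, ...] = ("fa", "md")

    SCHEMA = "neonorm-model-store-1"

    @property
    def n_voxels(self) -> int:
        return self.theta.shape[0]

    @property
    def n_train(self) -> int:
        return self.X.shape[0]

    def model(self, voxel: int) -> VoxelModel:
        """Rebuild a single :class:`VoxelModel` (recomputing its factors)."""
        if self.degenerate[voxel]:
            return VoxelModel(
                kernel=KernelSpec(1.0, (1.0, 1.0), np.zeros((2, 2))),
                X=self.X, y=np.zeros(2 * self.n_train),
                x_mean=self.x_mean, x_sd=self.x_sd,
                y_mean=self.y_mean[voxel], y_sd=np.ones(2),
                chol=None, alpha=None, log_marginal=-np.inf,
                jitter=float(self.jitter[voxel]),
                converged=False, degenerate=True,
            )
        kernel = KernelSpec.from_theta(self.theta[voxel])
        K = build_covariance(self.X, kernel)
        L, jit = _chol_with_jitter(K, float(self.jitter[voxel]))
        y = self.Y_std[voxel].T.ravel()
        alpha = cho_solve((L, True), y, check_finite=False)
        return VoxelModel(
            kernel=kernel, X=self.X, y=y,
            x_mean=self.x_mean, x_sd=self.x_sd,
            y_mean=self.y_mean[voxel], y_sd=self.y_sd[voxel],
            chol=L, alpha=alpha,
            log_marginal=float(self.log_marginal[voxel]),
            jitter=jit, converged=bool(self.converged[voxel]),
        )

    def predict_all(
        self,
        pma: np.ndarray,
        sex: np.ndarray,
        include_noise: bool = True,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Predictive mean/SD for every (subject, voxel, metric).

        Returns arrays of shape (m, V, 2) in original units; degenerate
        voxels yield NaN SD (and the training mean as mean).
        """
        pma = np.asarray(pma, dtype=np.float64)
        sex = np.asarray(sex, dtype=np.float64)
        m, V, n = pma.size, self.n_voxels, self.n_train
        mean = np.empty((m, V, 2))
        sd = np.full((m, V, 2), np.nan)
        train_pma = self.X[:, 0] * self.x_sd + self.x_mean
        extrap = (pma < train_pma.min()) | (pma > train_pma.max())
        if extrap.any():
            logger.warning(
                "%d/%d subjects extrapolate beyond the training PMA range "
                "[%.1f, %.1f]",
                int(extrap.sum()), m, train_pma.min(), train_pma.max(),
            )
        for v in range(V):
            if self.degenerate[v]:
                mean[:, v, :] = self.y_mean[v][None, :]
                continue
            model = self.model(v)
            pred = predict(model, pma, sex, include_noise=include_noise)
            mean[:, v, :] = pred.mean
            sd[:, v, :] = pred.sd
        return mean, sd

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            schema=self.SCHEMA,
            X=self.X, x_mean=self.x_mean, x_sd=self.x_sd,
            theta=self.theta, y_mean=self.y_mean, y_sd=self.y_sd,
            Y_std=self.Y_std, log_marginal=self.log_marginal,
            converged=self.converged, degenerate=self.degenerate,
            jitter=self.jitter,
            metric_names=np.asarray(self.metric_names),
        )

    @classmethod
    def load(cls, path: str | Path) -> "VoxelModelStore":
        with np.load(path, allow_pickle=False) as z:
            if str(z["schema"]) != cls.SCHEMA:
                raise InputError(f"unrecognised model-store schema in {path}")
            return cls(
                schema=str(z["schema"]),
                X=z["X"], x_mean=float(z["x_mean"]), x_sd=float(z["x_sd"]),
                theta=z["theta"], y_mean=z["y_mean"], y_sd=z["y_sd"],
                Y_std=z["Y_std"], log_marginal=z["log_marginal"],
                converged=z["converged"], degenerate=z["degenerate"],
                jitter=z["jitter"],
                metric_names=tuple(str(s) for s in z["metric_names"]),
            )


def fit_all(
    dataset: VoxelDataset,
    cohort: CohortTable,
    config: FitConfig = FitConfig(),
    voxels: np.ndarray | None = None,
) -> VoxelModelStore:
    """Fit every in-mask voxel independently; order-independent by design.

    Restart seeds derive from ``(config.seed, voxel index)`` so results are
    identical regardless of processing order or parallel scheduling.
    """
    config.validate()
    if dataset.n_subjects != len(cohort):
        raise InputError("dataset subjects do not match cohort rows")
    pma = cohort.frame["pma_scan"].to_numpy(dtype=np.float64)
    sex = cohort.frame["sex"].to_numpy(dtype=np.float64)
    x_sd = pma.std(ddof=1)
    if x_sd**2 < DEGENERATE_VAR:
        raise DegenerateDataError("zero predictor variance: PMA is constant")
    x_mean = pma.mean()
    X = np.column_stack([(pma - x_mean) / x_sd, sex])
    diff = X[:, None, :] - X[None, :, :]
    D2 = np.sum(diff**2, axis=2)

    V = dataset.n_voxels
    if voxels is None:
        voxels = np.arange(V)
    n = dataset.n_subjects
    theta = np.zeros((V, 6))
    y_mean = np.zeros((V, 2))
    y_sd = np.ones((V, 2))
    Y_std_all = np.zeros((V, n, 2))
    lml = np.full(V, -np.inf)
    converged = np.zeros(V, dtype=bool)
    degenerate = np.zeros(V, dtype=bool)
    jitter = np.full(V, config.jitter)

    n_done = 0
    for v in voxels:
        Y = dataset.values[:, v, :]
        mu = Y.mean(axis=0)
        sdv = Y.std(axis=0, ddof=1)
        if np.any(sdv**2 < DEGENERATE_VAR):
            degenerate[v] = True
            y_mean[v] = mu
            continue
        Y_std = (Y - mu) / sdv
        rng = _restart_rng(config.seed, int(v))
        kernel, ll, conv, _ = _fit_standardized(X, Y_std, config, rng, D2)
        theta[v] = kernel.theta()
        y_mean[v], y_sd[v] = mu, sdv
        Y_std_all[v] = Y_std
        lml[v] = ll
        converged[v] = conv
        n_done += 1
        if n_done % 1000 == 0:
            logger.info("fitted %d/%d voxels", n_done, len(voxels))
    n_fail = int((~converged & ~degenerate).sum())
    if n_fail:
        logger.warning("%d voxels did not converge on any restart", n_fail)
    if degenerate.any():
        logger.info("%d degenerate voxels flagged", int(degenerate.sum()))
    return VoxelModelStore(
        schema=VoxelModelStore.SCHEMA,
        X=X, x_mean=float(x_mean), x_sd=float(x_sd),
        theta=theta, y_mean=y_mean, y_sd=y_sd, Y_std=Y_std_all,
        log_marginal=lml, converged=converged, degenerate=degenerate,
        jitter=jitter, metric_names=dataset.metric_names,
    )


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class MAEMap:
    """Per-voxel, per-metric held-out mean absolute error (original units)."""

    mae: np.ndarray              # (V, 2)
    fold_assignment: np.ndarray  # (n,) fold id per subject
    mean_mae: dict[str, float]   # whole-mask mean per metric
    held_out_mean: np.ndarray    # (n, V, 2) CV-predicted mean per subject
    held_out_sd: np.ndarray      # (n, V, 2)


def stratified_folds(
    pma: np.ndarray, k: int, seed: int
) -> np.ndarray:
    """PMA-stratified fold assignment: sort by PMA, deal round-robin.

    Subjects are sorted by PMA (ties broken by a seeded shuffle) and dealt
    into ``k`` folds in turn, so every fold spans the full PMA range.
    """
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    n = pma.size
    rng = np.random.default_rng(np.random.SeedSequence([seed, 555]))
    tiebreak = rng.random(n)
    order = np.lexsort((tiebreak, pma))
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % k
    counts = np.bincount(folds, minlength=k)
    if counts.min() < 3:
        raise InputError(
            f"fold sizes {counts.tolist()} too small (need >= 3 per fold)"
        )
    return folds


def crossvalidate(
    dataset: VoxelDataset,
    cohort: CohortTable,
    k: int = 5,
    seed: int = 0,
    config: FitConfig = FitConfig(),
) -> MAEMap:
    """Stratified k-fold CV of the per-voxel models on the normative cohort.

    Each fold is predicted by models trained on the remaining folds; the
    per-voxel, per-metric MAE pools all held-out predictions. The held-out
    predictive moments are retained so normative subjects can be Z-scored
    against models that never saw them.
    """
    pma = cohort.frame["pma_scan"].to_numpy()
    folds = stratified_folds(pma, k, seed)
    n, V = dataset.n_subjects, dataset.n_voxels
    ho_mean = np.full((n, V, 2), np.nan)
    ho_sd = np.full((n, V, 2), np.nan)
    for f in range(k):
        test = np.flatnonzero(folds == f)
        train = np.flatnonzero(folds != f)
        sub_ds = dataset.subset_subjects(train)
        sub_cohort = CohortTable(cohort.frame.iloc[train].reset_index(drop=True))
        store = fit_all(sub_ds, sub_cohort, config)
        sexq = cohort.frame["sex"].to_numpy()[test]
        mean, sd = store.predict_all(pma[test], sexq, include_noise=True)
        ho_mean[test] = mean
        ho_sd[test] = sd
    abs_err = np.abs(dataset.values - ho_mean)
    mae = np.nanmean(abs_err, axis=0)
    mean_mae = {
        name: float(np.nanmean(mae[:, m]))
        for m, name in enumerate(dataset.metric_names)
    }
    return MAEMap(
        mae=mae, fold_assignment=folds, mean_mae=mean_mae,
        held_out_mean=ho_mean, held_out_sd=ho_sd,
    )
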