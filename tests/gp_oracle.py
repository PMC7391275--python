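"""Independent dense-inverse GP oracle used only by the tests.

Implements the textbook marginal-likelihood and posterior formulas with
explicit matrix inverses and no shared code with the package's Cholesky
path, so agreement between the two is a real cross-check.
"""

import numpy as np


def rbf_oracle(x1: np.ndarray, x2: np.ndarray, lengthscale: float) -> np.ndarray:
    out = np.empty((x1.shape[0], x2.shape[0]))
    for i in range(x1.shape[0]):
        for j in range(x2.shape[0]):
            d2 = float(np.sum((x1[i] - x2[j]) ** 2))
            out[i, j] = np.exp(-0.5 * d2 / lengthscale**2)
    return out


def icm_cov_oracle(
    X: np.ndarray,
    B: np.ndarray,
    lengthscale: float,
    noise: tuple[float, float],
    jitter: float = 0.0,
) -> np.ndarray:
    n = X.shape[0]
    Kr = rbf_oracle(X, X, lengthscale)
    K = np.zeros((2 * n, 2 * n))
    for a in range(2):
        for b in range(2):
            K[a * n:(a + 1) * n, b * n:(b + 1) * n] = B[a, b] * Kr
    for a in range(2):
        for i in range(n):
            K[a * n + i, a * n + i] += noise[a] + jitter
    return K


def lml_oracle(K: np.ndarray, y: np.ndarray) -> float:
    """log N(y; 0, K) via explicit inverse and slogdet."""
    sign, logdet = np.linalg.slogdet(K)
    assert sign > 0
    Kinv = np.linalg.inv(K)
    n = y.size
    return float(-0.5 * y @ Kinv @ y - 0.5 * logdet - 0.5 * n * np.log(2 * np.pi))


def posterior_oracle(
    X: np.ndarray,
    y: np.ndarray,
    Xq: np.ndarray,
    B: np.ndarray,
    lengthscale: float,
    noise: tuple[float, float],
    include_noise: bool,
    jitter: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and variance per (query, output), dense inverses."""
    n, m = X.shape[0], Xq.shape[0]
    K = icm_cov_oracle(X, B, lengthscale, noise, jitter)
    Kinv = np.linalg.inv(K)
    Krq = rbf_oracle(Xq, X, lengthscale)
    mean = np.empty((m, 2))
    var = np.empty((m, 2))
    for a in range(2):
        Kstar = np.hstack([B[a, b] * Krq for b in range(2)])  # (m, 2n)
        mean[:, a] = Kstar @ Kinv @ y
        for q in range(m):
            kss = B[a, a]
            var[q, a] = kss - Kstar[q] @ Kinv @ Kstar[q]
            if include_noise:
                var[q, a] += noise[a]
    return mean, var
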