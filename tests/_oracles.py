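"""Independent oracles shared by the GLM and acceptance tests."""

import numpy as np
from scipy import optimize


def poisson_mle_oracle(X, y):
    """Generic maximization of the Poisson log-likelihood (BFGS + Newton polish).

    Deliberately independent of the package's IRLS path.
    """

    def negloglik(beta):
        eta = X @ beta
        return float(np.sum(np.exp(eta)) - y @ eta)

    res = optimize.minimize(
        negloglik, np.zeros(X.shape[1]), method="BFGS",
        options={"gtol": 1e-10, "maxiter": 2000},
    )
    beta = res.x
    for _ in range(50):
        mu = np.exp(X @ beta)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * mu[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return beta


def random_small_design(rng):
    """A random full-rank Poisson design with <= 40 points, or None if degenerate."""
    n = int(rng.integers(12, 41))
    n_blocks = int(rng.integers(1, 4))
    X = np.column_stack(
        [np.ones(n), np.arange(n, dtype=float)]
        + [rng.integers(0, 2, n).astype(float) for _ in range(n_blocks)]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return None
    beta_true = np.concatenate(
        [[rng.uniform(2.0, 5.0), rng.uniform(-0.01, 0.01)],
         rng.uniform(-0.3, 0.3, n_blocks)]
    )
    y = rng.poisson(np.exp(X @ beta_true)).astype(float)
    if np.all(y == 0):
        return None
    return X, y
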