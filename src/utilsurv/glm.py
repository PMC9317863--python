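"""Quasi-Poisson log-linear baseline fit.

The baseline model is

    log E[Y_t] = alpha + beta * t + gamma_f(t),      var(Y_t) = Phi * E[Y_t]

with t the monthly trend index and gamma_f the seasonal-block effects
(block 0 is the baseline level).  Point estimates coincide with the
Poisson MLE under the log link and are computed by iteratively reweighted
least squares; the overdispersion Phi is the Pearson chi-square divided by
the residual degrees of freedom, floored at 1 so the downstream interval
construction never assumes less-than-Poisson variation.

No historical-outlier down-weighting and no trend-significance drop test
are applied: the fit is the plain quasi-Poisson baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FitError, NotConvergedError
from .windows import ReferenceDesign, design_matrix

IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100


@dataclass(frozen=True)
class BaselineFit:
    """Estimated baseline for one reference design."""

    design: ReferenceDesign
    alpha: float
    beta: float
    gamma: dict[int, float]
    phi: float
    phi_raw: float
    fitted_means: np.ndarray
    n_points: int
    converged: bool
    iterations: int
    dropped_blocks: list[int] = field(default_factory=list)

    @property
    def coefficients(self) -> dict[str, float]:
        out = {"intercept": self.alpha, "trend": self.beta}
        out.update({f"block_{b}": g for b, g in self.gamma.items()})
        return out

    def diagnostics(self) -> dict:
        """Key-value fit report, JSON-serializable."""
        return {
            "coefficients": self.coefficients,
            "phi_raw": self.phi_raw,
            "phi": self.phi,
            "n_points": self.n_points,
            "iterations": self.iterations,
            "converged": self.converged,
            "dropped_blocks": list(self.dropped_blocks),
        }


def _irls(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool, int]:
    """Poisson log-link IRLS.  Returns (coefficients, converged, iterations)."""
    mu = y + 0.5  # strictly positive start even at zero counts
    eta = np.log(mu)
    coef = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, IRLS_MAX_ITER + 1):
        z = eta + (y - mu) / mu
        sw = np.sqrt(mu)
        new_coef, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        eta = X @ new_coef
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        # global relative change: stable when some coefficients are ~0
        denom = max(float(np.max(np.abs(coef))), 1e-10)
        if float(np.max(np.abs(new_coef - coef))) / denom < IRLS_TOL:
            coef = new_coef
            converged = True
            break
        coef = new_coef
    return coef, converged, it


def fit_quasipoisson(design: ReferenceDesign) -> BaselineFit:
    """Fit the quasi-Poisson baseline to a reference design.

    Raises
    ------
    FitError
        On an all-zero response or a rank-deficient design after dropping
        empty-block columns.
    """
    X, y, names, dropped = design_matrix(design)
    if np.all(y == 0):
        raise FitError(
            "all-zero response: the log-linear baseline is undefined; "
            "check the series or widen the window"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError(
            f"rank-deficient design ({X.shape[1]} columns, "
            f"rank {np.linalg.matrix_rank(X)}) after dropping blocks {dropped}"
        )
    if X.shape[0] < X.shape[1] + 1:
        raise FitError(
            f"too few points ({X.shape[0]}) for {X.shape[1]} coefficients"
        )

    coef, converged, iterations = _irls(X, y)
    mu = np.exp(np.clip(X @ coef, -30.0, 30.0))

    n, k = X.shape
    if n - k <= 0:
        raise FitError("no residual degrees of freedom for dispersion")
    pearson = float(np.sum((y - mu) ** 2 / mu))
    phi_raw = pearson / (n - k)

    gamma = {
        int(name.split("_", 1)[1]): float(c)
        for name, c in zip(names, coef)
        if name.startswith("block_")
    }
    return BaselineFit(
        design=design,
        alpha=float(coef[0]),
        beta=float(coef[1]),
        gamma=gamma,
        phi=max(1.0, phi_raw),
        phi_raw=phi_raw,
        fitted_means=mu,
        n_points=n,
        converged=converged,
        iterations=iterations,
        dropped_blocks=dropped,
    )


def dispersion(fit: BaselineFit, raw: bool = False) -> float:
    """The Pearson overdispersion estimate, raw or floored at 1."""
    if not fit.converged:
        raise NotConvergedError("dispersion requested from an unconverged fit")
    return fit.phi_raw if raw else max(1.0, fit.phi_raw)
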