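"""Shared numerical machinery: fit-result container, quasi-Newton driver and
observed-information standard errors."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Optional

import numpy as np
import pandas as pd
from scipy import optimize

#: Wald multiplier for 95% confidence intervals / significance flags.
Z_95 = 1.959963984540054


@dataclass
class FitResult:
    """Maximum-likelihood fit: structured parameters, flat estimates aligned
    with ``names``, observed-information SEs (NaN where fixed or undefined),
    log-likelihood and convergence metadata."""

    params: Any
    names: tuple[str, ...]
    estimates: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_used: int
    fixed_beta2: Optional[float] = None
    message: str = ""
    cov: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def se_defined(self) -> bool:
        free = [i for i, n in enumerate(self.names) if not self._is_fixed(n)]
        return bool(np.all(np.isfinite(self.se[free])))

    def _is_fixed(self, name: str) -> bool:
        return self.fixed_beta2 is not None and name == "beta2"

    def estimate(self, name: str) -> float:
        return float(self.estimates[self.names.index(name)])

    def se_of(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def wald_ci(self, name: str, z: float = Z_95) -> tuple[float, float]:
        est, se = self.estimate(name), self.se_of(name)
        return est - z * se, est + z * se

    def to_frame(self) -> pd.DataFrame:
        z = self.estimates / np.where(self.se > 0, self.se, np.nan)
        return pd.DataFrame(
            {
                "parameter": list(self.names),
                "estimate": self.estimates,
                "se": self.se,
                "significant": np.abs(z) > Z_95,
            }
        )


def maximize_loglik(
    fun_and_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    theta0: np.ndarray,
    maxiter: int = 1000,
) -> optimize.OptimizeResult:
    """Maximise a log-likelihood with L-BFGS-B on the negative objective.

    ``fun_and_grad`` returns (loglik, gradient). Convergence is declared when
    the optimiser reports success, or the final projected gradient norm is
    below 1e-5 per observation-scale unit.
    """

    def neg(theta: np.ndarray) -> tuple[float, np.ndarray]:
        ll, g = fun_and_grad(theta)
        if not np.isfinite(ll):
            return 1e300, np.zeros_like(theta)
        return -ll, -g

    res = optimize.minimize(
        neg,
        np.asarray(theta0, dtype=float),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-8},
    )
    # L-BFGS-B can stop on ftol with a healthy gradient; treat a small
    # gradient at the returned point as converged regardless of status.
    gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    res.converged = bool(res.success or gnorm < 1e-4)
    return res


def observed_information(
    grad: Callable[[np.ndarray], np.ndarray], theta: np.ndarray, rel_step: float = 1e-5
) -> np.ndarray:
    """Observed information (negative Hessian of the log-likelihood) by
    central differencing of the analytic gradient, symmetrised.

    Step per coordinate: ``max(rel_step, rel_step * |theta_j|)``.
    """
    theta = np.asarray(theta, dtype=float)
    p = theta.size
    H = np.empty((p, p))
    for j in range(p):
        h = max(rel_step, rel_step * abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        H[:, j] = (grad(tp) - grad(tm)) / (2 * h)
    H = 0.5 * (H + H.T)
    return -H


def se_from_information(info: np.ndarray) -> tuple[np.ndarray, Optional[np.ndarray], str]:
    """Standard errors from an observed-information matrix.

    Returns ``(se, cov, message)``; if the matrix is not positive definite
    (or near-singular) the SEs are NaN and the message carries a diagnostic
    rather than raising.
    """
    p = info.shape[0]
    eigvals = np.linalg.eigvalsh(info)
    if eigvals[0] <= 0:
        return np.full(p, np.nan), None, "observed information not positive definite"
    msg = ""
    if eigvals[0] < 1e-12 * eigvals[-1]:
        msg = "observed information near-singular; SEs may be unstable"
    cov = np.linalg.inv(info)
    return np.sqrt(np.diag(cov)), cov, msg


@dataclass(frozen=True)
class Standardizer:
    """Column-wise affine map used to condition the optimisation; fitted
    coefficients are reported on the raw covariate scale."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(mean=mean, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale

    def coef_to_std(self, intercept: float, coef: np.ndarray) -> tuple[float, np.ndarray]:
        return intercept + float(coef @ self.mean), coef * self.scale

    def coef_to_raw(self, intercept: float, coef: np.ndarray) -> tuple[float, np.ndarray]:
        raw = coef / self.scale
        return intercept - float(raw @ self.mean), raw
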