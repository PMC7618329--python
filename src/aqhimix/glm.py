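"""Quasi-Poisson GLM fitting.

Point estimates are the Poisson maximum-likelihood estimates (log link,
IRLS); the covariance is the Poisson covariance inflated by the Pearson
dispersion chi^2/(n-p), which absorbs the overdispersion typical of daily
death counts without changing the point estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .errors import ConvergenceError, SingularDesignError

__all__ = ["GLMFit", "fit_quasipoisson", "check_full_rank"]

_RANK_TOL = 1e-8


@dataclass
class GLMFit:
    coefficients: np.ndarray
    covariance: np.ndarray
    dispersion: float
    deviance: float
    converged: bool
    n_obs: int
    fitted_values: np.ndarray | None = None

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


def check_full_rank(design: np.ndarray, tol: float = _RANK_TOL) -> None:
    """Raise SingularDesignError if columns are (numerically) dependent.

    QR with a relative tolerance on the diagonal of R.
    """
    r = np.linalg.qr(design, mode="r")
    diag = np.abs(np.diag(r))
    if diag.size == 0 or diag.max() == 0 or diag.min() < tol * diag.max():
        raise SingularDesignError(
            f"design is rank deficient ({design.shape[1]} columns)"
        )


def fit_quasipoisson(
    y: np.ndarray,
    design: np.ndarray,
    offset: np.ndarray | None = None,
    maxiter: int = 100,
) -> GLMFit:
    """Fit a log-link quasi-Poisson regression.

    Parameters
    ----------
    y : nonnegative counts.
    design : full-column-rank matrix including any intercept column.
    offset : optional log-scale offset.
    """
    y = np.asarray(y, dtype=float)
    design = np.asarray(design, dtype=float)
    if np.any(y < 0):
        raise ValueError("y must be nonnegative")
    if y.shape[0] != design.shape[0]:
        raise ValueError("y and design have different lengths")
    check_full_rank(design)
    model = sm.GLM(y, design, family=sm.families.Poisson(), offset=offset)
    res = model.fit(maxiter=maxiter, scale="X2")
    if not res.converged:
        raise ConvergenceError(
            f"IRLS failed to converge in {maxiter} iterations",
            trace={"deviance": float(res.deviance)},
        )
    n, p = design.shape
    dispersion = float(res.scale)  # Pearson chi2 / (n - p)
    return GLMFit(
        coefficients=np.asarray(res.params),
        covariance=np.asarray(res.cov_params()),
        dispersion=dispersion,
        deviance=float(res.deviance),
        converged=bool(res.converged),
        n_obs=n,
        fitted_values=np.asarray(res.fittedvalues),
    )
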