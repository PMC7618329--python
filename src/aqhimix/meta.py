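"""Second-stage random-effects pooling of city estimates.

Univariate pooling uses the DerSimonian-Laird method-of-moments estimator
of the between-city variance tau^2 (floored at zero), with REML available
as an option; the pooled estimate is the inverse-variance weighted mean
with weights 1/(v_i + tau^2). Vector-valued quantities (spline coefficient
blocks, weight vectors) are pooled with a diagonal between-study
covariance, estimated component-wise by the same moment method, and full
within-study covariances in the GLS combination. Compositional pollutant
weights are pooled component-wise and projected back onto the simplex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import InsufficientStudiesError, InvalidParameterError

__all__ = ["MetaResult", "re_meta_univariate", "re_meta_multivariate", "pool_weights"]


@dataclass
class MetaResult:
    pooled: np.ndarray
    pooled_cov: np.ndarray
    tau2: np.ndarray          # scalar (0-d) or per-component vector
    n_studies: int
    Q: float
    method: str

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.pooled_cov))

    def scalar(self) -> tuple[float, float]:
        """(estimate, variance) for 1-dimensional results."""
        return float(np.ravel(self.pooled)[0]), float(np.ravel(self.pooled_cov)[0])


def _dl_tau2(theta: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    w = 1.0 / v
    theta_fe = np.sum(w * theta) / np.sum(w)
    q = float(np.sum(w * (theta - theta_fe) ** 2))
    df = theta.size - 1
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    return tau2, q


def _reml_tau2(theta: np.ndarray, v: np.ndarray) -> float:
    def negloglik(tau2):
        wi = 1.0 / (v + tau2)
        mu = np.sum(wi * theta) / np.sum(wi)
        return 0.5 * (
            np.sum(np.log(v + tau2))
            + np.log(np.sum(wi))
            + np.sum(wi * (theta - mu) ** 2)
        )

    hi = max(1e-8, 10.0 * (np.var(theta) + np.max(v)))
    res = minimize_scalar(negloglik, bounds=(0.0, hi), method="bounded",
                          options={"xatol": 1e-12})
    return max(0.0, float(res.x))


def re_meta_univariate(
    estimates: np.ndarray, variances: np.ndarray, method: str = "dl"
) -> MetaResult:
    """Random-effects pooling of scalar estimates.

    method 'dl' (DerSimonian-Laird moments, default) or 'reml'.
    """
    theta = np.asarray(estimates, dtype=float).ravel()
    v = np.asarray(variances, dtype=float).ravel()
    if theta.size < 2:
        raise InsufficientStudiesError("need at least 2 studies")
    if theta.size != v.size or np.any(v <= 0):
        raise InvalidParameterError("variances must be positive and match estimates")
    tau2_dl, q = _dl_tau2(theta, v)
    if method == "dl":
        tau2 = tau2_dl
    elif method == "reml":
        tau2 = _reml_tau2(theta, v)
    else:
        raise InvalidParameterError(f"unknown method {method!r}")
    w = 1.0 / (v + tau2)
    pooled = np.sum(w * theta) / np.sum(w)
    return MetaResult(
        pooled=np.array(pooled),
        pooled_cov=np.array(1.0 / np.sum(w)),
        tau2=np.array(tau2),
        n_studies=theta.size,
        Q=q,
        method=method,
    )


def re_meta_multivariate(
    coef_vectors, cov_matrices, method: str = "dl"
) -> MetaResult:
    """Pool vector estimates with diagonal between-study covariance.

    tau^2 is estimated per component by the univariate moment method on
    the marginal (estimate, variance) pairs; the pooled vector is the GLS
    combination with weights (V_i + diag(tau^2))^{-1}.
    """
    thetas = np.asarray(coef_vectors, dtype=float)
    if thetas.ndim == 1:
        thetas = thetas[:, None]
    covs = [np.atleast_2d(np.asarray(c, dtype=float)) for c in cov_matrices]
    n, d = thetas.shape
    if n < 2:
        raise InsufficientStudiesError("need at least 2 studies")
    if any(c.shape != (d, d) for c in covs) or len(covs) != n:
        raise InvalidParameterError("covariance dimensions do not match estimates")

    tau2 = np.empty(d)
    qs = np.empty(d)
    for j in range(d):
        vj = np.array([c[j, j] for c in covs])
        if method == "reml":
            tau2[j] = _reml_tau2(thetas[:, j], vj)
            _, qs[j] = _dl_tau2(thetas[:, j], vj)
        else:
            tau2[j], qs[j] = _dl_tau2(thetas[:, j], vj)
    t_mat = np.diag(tau2)
    wsum = np.zeros((d, d))
    wtheta = np.zeros(d)
    for theta_i, cov_i in zip(thetas, covs):
        wi = np.linalg.inv(cov_i + t_mat)
        wsum += wi
        wtheta += wi @ theta_i
    pooled_cov = np.linalg.inv(wsum)
    pooled = pooled_cov @ wtheta
    return MetaResult(
        pooled=pooled,
        pooled_cov=pooled_cov,
        tau2=tau2,
        n_studies=n,
        Q=float(qs.sum()),
        method=method,
    )


def pool_weights(
    city_weights, weight_covs, method: str = "dl"
) -> tuple[np.ndarray, np.ndarray]:
    """Country-level pollutant weights: component-wise pooling + simplex projection.

    Each city's weight vector must lie on the simplex. With a single city
    the weights pass through unchanged (logged upstream). Pooled
    components are clipped at zero and renormalised to sum to one; the
    returned covariance is the component-wise pooled covariance rescaled
    by the renormalisation factor.
    """
    ws = np.asarray(city_weights, dtype=float)
    if ws.ndim == 1:
        ws = ws[None, :]
    if ws.size == 0:
        raise InvalidParameterError("empty weight input")
    if np.any(ws < -1e-10) or np.any(np.abs(ws.sum(axis=1) - 1) > 1e-6):
        raise InvalidParameterError("city weights must lie on the simplex")
    covs = [np.atleast_2d(np.asarray(c, dtype=float)) for c in weight_covs]
    n, d = ws.shape
    if n == 1:
        return ws[0].copy(), covs[0].copy()
    pooled = np.empty(d)
    var = np.empty(d)
    floor = 1e-12
    for j in range(d):
        vj = np.array([max(c[j, j], floor) for c in covs])
        res = re_meta_univariate(ws[:, j], vj, method=method)
        pooled[j], var[j] = res.scalar()
    clipped = np.clip(pooled, 0.0, None)
    total = clipped.sum()
    if total <= 0:
        raise InvalidParameterError("pooled weights degenerate (all zero)")
    out = clipped / total
    cov = np.diag(var) / total**2
    return out, cov
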