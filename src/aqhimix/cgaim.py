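"""Constrained groupwise additive index model (CGAIM) for pollutant mixtures.

The model for daily deaths Y_t is

    Y_t ~ quasiPoisson(mu_t),   log mu_t = confounders_t + g(z_t),
    z_t = sum_k w_k x_kt,       w_k >= 0, sum_k w_k = 1,  g nondecreasing,

where x_kt are the lag 0-2 moving averages of the four pollutants. The
simplex constraint makes the index scale identifiable and the weights
interpretable as relative contributions; the monotone constraint encodes
the prior that more pollution cannot lower risk.

Fitting alternates two steps until the weights stabilise:

(a) *ridge function*: with w fixed, g is expanded in an I-spline basis
    (degree 3, interior knots at quantiles of z) with nonnegative
    coefficients — any such combination is nondecreasing — and fitted
    jointly with the unconstrained confounder block by IRLS, solving a
    partially nonnegative weighted least-squares at each iteration
    (confounders projected out by QR, then NNLS on the residualised
    working response).

(b) *weights*: with g fixed, the index enters the linearised working
    model through g'(z) x_k; the simplex-constrained weighted
    least-squares update is solved as a small quadratic program (SLSQP),
    followed by backtracking on the profile quasi-deviance so the
    objective never increases across alternations.

Because the death risk function applies weights to raw concentrations,
the simplex weights are estimated directly on the raw ug/m3 scale; for
numerical conditioning all four exposures are divided by one *common*
factor (the mean of their in-city standard deviations), which leaves the
simplex weights exactly invariant. Estimating on per-pollutant
standardised scales and remapping (w_k proportional to w~_k / sd_k) is
avoided deliberately: with the weak per-city signal typical of daily
mortality data the remap inflates the estimation noise of low-variance
pollutants and, combined with the nonnegativity clipping, biases their
pooled weights upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, nnls

from .basis import ispline_basis, moving_average
from .data import POLLUTANT_COLUMNS, CityDailySeries
from .dlnm import ModelConfig, confounder_design
from .errors import (
    ConvergenceError,
    DataTooSparseError,
    DegenerateBasisError,
    InvalidParameterError,
    UnstableBootstrapError,
)
from .glm import fit_quasipoisson

__all__ = [
    "CGAIMFit",
    "MonotoneCurve",
    "fit_cgaim",
    "estimate_index_slope",
    "bootstrap_weight_uncertainty",
]

_N_INTERIOR_KNOTS = 5
_SPLINE_DEGREE = 3
_WEIGHT_TOL = 1e-5
_MAX_ALTERNATIONS = 50
_ZERO_WEIGHT = 1e-6


@dataclass
class MonotoneCurve:
    """Nondecreasing ridge function g on the (standardised) index scale."""

    grid: np.ndarray
    values: np.ndarray
    knots: np.ndarray
    boundary: tuple[float, float]
    gamma: np.ndarray

    def __call__(self, z: np.ndarray) -> np.ndarray:
        m = ispline_basis(np.asarray(z, float), self.knots, self.boundary, _SPLINE_DEGREE)
        return m @ self.gamma

    def derivative(self, z: np.ndarray, h: float | None = None) -> np.ndarray:
        span = self.boundary[1] - self.boundary[0]
        h = h or 1e-4 * span
        return (self(np.asarray(z) + h) - self(np.asarray(z) - h)) / (2 * h)


@dataclass
class CGAIMFit:
    city_id: str
    weights: np.ndarray                 # raw ug/m3 scale, simplex
    weights_std: np.ndarray             # standardised scale, simplex
    exposure_sd: np.ndarray
    monotone_curve: MonotoneCurve
    beta_index: float
    beta_index_var: float
    n_iter: int
    converged: bool
    deviance_trace: list = field(default_factory=list)
    weight_cov: np.ndarray | None = None
    pollutants: tuple[str, ...] = POLLUTANT_COLUMNS


def _simplex_project(w: np.ndarray) -> np.ndarray:
    w = np.clip(np.asarray(w, float), 0.0, None)
    s = w.sum()
    if s <= 0:
        return np.full(w.size, 1.0 / w.size)
    return w / s


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


class _RidgeFitState:
    """Result of the inner IRLS fit for fixed weights."""

    __slots__ = ("deviance", "alpha", "curve", "eta", "mu", "gz")

    def __init__(self, deviance, alpha, curve, eta, mu, gz):
        self.deviance = deviance
        self.alpha = alpha
        self.curve = curve
        self.eta = eta
        self.mu = mu
        self.gz = gz


def _fit_ridge(y, conf, z, eta0=None, max_irls=25, tol=1e-8) -> _RidgeFitState:
    """IRLS fit of confounders + monotone I-spline term at fixed index z."""
    lo, hi = float(z.min()), float(z.max())
    if hi - lo <= 0:
        raise DegenerateBasisError("index is constant")
    probs = np.linspace(0, 1, _N_INTERIOR_KNOTS + 2)[1:-1]
    knots = np.unique(np.quantile(z, probs))
    m = ispline_basis(z, knots, (lo, hi), _SPLINE_DEGREE)

    eta = np.log(y + 0.5) if eta0 is None else eta0.copy()
    mu = np.exp(eta)
    dev = _poisson_deviance(y, mu)
    alpha = gamma = None
    for _ in range(max_irls):
        sw = np.sqrt(mu)
        u = eta + (y - mu) / mu
        cw = conf * sw[:, None]
        mw = m * sw[:, None]
        uw = u * sw
        q, _r = np.linalg.qr(cw)
        m_perp = mw - q @ (q.T @ mw)
        u_perp = uw - q @ (q.T @ uw)
        gamma, _ = nnls(m_perp, u_perp)
        alpha, *_ = np.linalg.lstsq(cw, uw - mw @ gamma, rcond=None)
        eta = np.clip(conf @ alpha + m @ gamma, -30, 30)
        mu = np.exp(eta)
        new_dev = _poisson_deviance(y, mu)
        if abs(dev - new_dev) < tol * (abs(dev) + 0.1):
            dev = new_dev
            break
        dev = new_dev
    gz = m @ gamma
    grid = np.linspace(lo, hi, 200)
    curve = MonotoneCurve(
        grid=grid,
        values=ispline_basis(grid, knots, (lo, hi), _SPLINE_DEGREE) @ gamma,
        knots=knots,
        boundary=(lo, hi),
        gamma=gamma,
    )
    return _RidgeFitState(dev, alpha, curve, eta, mu, gz)


def _linear_init(y, conf, xs, max_irls=25, tol=1e-8) -> np.ndarray:
    """Constrained-linear starting weights.

    Fits the linear-ridge special case (log mu = conf + sum_k theta_k x_k
    with theta >= 0) by IRLS/NNLS and normalises theta to the simplex.
    This is a consistent estimator of the weights when the true ridge
    function is increasing, so the alternation starts near the answer
    instead of at the uninformative uniform point — which matters when
    the profile deviance is flat in w. Falls back to uniform weights if
    no positive linear signal is found.
    """
    eta = np.log(y + 0.5)
    mu = np.exp(eta)
    dev = _poisson_deviance(y, mu)
    theta = np.zeros(xs.shape[1])
    for _ in range(max_irls):
        sw = np.sqrt(mu)
        u = eta + (y - mu) / mu
        cw = conf * sw[:, None]
        xw = xs * sw[:, None]
        uw = u * sw
        q, _r = np.linalg.qr(cw)
        theta, _ = nnls(xw - q @ (q.T @ xw), uw - q @ (q.T @ uw))
        alpha, *_ = np.linalg.lstsq(cw, uw - xw @ theta, rcond=None)
        eta = np.clip(conf @ alpha + xs @ theta, -30, 30)
        mu = np.exp(eta)
        new_dev = _poisson_deviance(y, mu)
        if abs(dev - new_dev) < tol * (abs(dev) + 0.1):
            break
        dev = new_dev
    if theta.sum() <= 0:
        return np.full(xs.shape[1], 1.0 / xs.shape[1])
    return theta / theta.sum()


def _update_weights(y, conf, xs, w0, state) -> np.ndarray:
    """Simplex-constrained WLS update on the first-order expansion."""
    z = xs @ w0
    gp = state.curve.derivative(z)
    a = gp[:, None] * xs
    u = state.eta + (y - state.mu) / state.mu
    r = u - conf @ state.alpha - state.gz + gp * z
    sw = state.mu
    ata = (a * sw[:, None]).T @ a
    atr = (a * sw[:, None]).T @ r

    def obj(w):
        return 0.5 * w @ ata @ w - atr @ w

    def grad(w):
        return ata @ w - atr

    p = w0.size
    res = minimize(
        obj,
        w0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * p,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                      "jac": lambda w: np.ones(p)}],
        options={"maxiter": 100, "ftol": 1e-12},
    )
    return _simplex_project(res.x)


def _prepare(series: CityDailySeries, config: ModelConfig,
             pollutants: tuple[str, ...]):
    mas = [moving_average(series.pollutant(k), config.exposure_ma_window)
           for k in pollutants]
    x = np.column_stack(mas)
    conf, mask = confounder_design(series, config)
    mask = mask & np.all(np.isfinite(x), axis=1) & np.isfinite(series.deaths)
    p_design = conf.shape[1] + _N_INTERIOR_KNOTS + _SPLINE_DEGREE + len(pollutants)
    if mask.sum() < p_design * config.min_rows_per_column:
        raise DataTooSparseError(
            f"{mask.sum()} complete days for ~{p_design} effective columns"
        )
    y = series.deaths[mask]
    conf = conf[mask]
    x = x[mask]
    sd = x.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        bad = [k for k, s in zip(pollutants, sd) if s <= 0]
        raise DegenerateBasisError(f"constant pollutant(s) {bad}")
    # one common scale factor: conditioning without disturbing the simplex
    return y, conf, x, x / sd.mean(), sd, mask


def _alternate(y, conf, xs, w_init=None, max_alt=_MAX_ALTERNATIONS,
               tol=_WEIGHT_TOL) -> tuple[np.ndarray, _RidgeFitState, int, bool, list]:
    if w_init is None:
        w_init = _linear_init(y, conf, xs)
    w = _simplex_project(np.asarray(w_init, float))
    state = _fit_ridge(y, conf, xs @ w)
    trace = [state.deviance]
    converged = w.size == 1
    n_iter = 0
    for n_iter in range(1, max_alt + 1):
        if w.size == 1:
            break
        w_star = _update_weights(y, conf, xs, w, state)
        accepted = False
        for s in [1.0, 0.5, 0.25, 0.1, 0.03, 0.01, 0.003, 0.001]:
            w_try = _simplex_project(w + s * (w_star - w))
            z_try = xs @ w_try
            if np.ptp(z_try) <= 0:
                continue
            state_try = _fit_ridge(y, conf, z_try, eta0=state.eta)
            if state_try.deviance <= state.deviance + 1e-8:
                accepted = True
                break
        if not accepted:
            converged = True
            break
        delta = np.max(np.abs(w_try - w))
        gain = trace[-1] - state_try.deviance
        w, state = w_try, state_try
        trace.append(state.deviance)
        # stop on stable weights or a flat profile deviance
        if delta < tol or gain < 1e-7 * (abs(state.deviance) + 1.0):
            converged = True
            break
    return w, state, n_iter, converged, trace


def fit_cgaim(
    series: CityDailySeries,
    config: ModelConfig | None = None,
    pollutants: tuple[str, ...] = POLLUTANT_COLUMNS,
    w_init: np.ndarray | None = None,
    require_convergence: bool = True,
) -> CGAIMFit:
    """Fit the CGAIM to one city's series.

    Returns simplex weights on the raw ug/m3 scale, the monotone ridge
    function on the standardised index scale, and the linear index slope
    (with variance) from a quasi-Poisson refit at the fitted weights.
    """
    config = config or ModelConfig()
    y, conf, x_raw, xs, sd, _ = _prepare(series, config, pollutants)
    p = len(pollutants)
    w0 = None if w_init is None else _simplex_project(w_init)
    w_raw, state, n_iter, converged, trace = _alternate(y, conf, xs, w0)
    if not converged and require_convergence:
        raise ConvergenceError(
            f"CGAIM did not converge in {n_iter} alternations", trace=trace
        )
    w_raw = _simplex_project(np.where(w_raw < _ZERO_WEIGHT, 0.0, w_raw))
    w_std = _simplex_project(w_raw * sd)
    beta, beta_var = estimate_index_slope(series, w_raw, config, pollutants)
    return CGAIMFit(
        city_id=series.city_id,
        weights=w_raw,
        weights_std=w_std,
        exposure_sd=sd,
        monotone_curve=state.curve,
        beta_index=beta,
        beta_index_var=beta_var,
        n_iter=n_iter,
        converged=converged,
        deviance_trace=trace,
        pollutants=tuple(pollutants),
    )


def estimate_index_slope(
    series: CityDailySeries,
    weights: np.ndarray,
    config: ModelConfig | None = None,
    pollutants: tuple[str, ...] = POLLUTANT_COLUMNS,
) -> tuple[float, float]:
    """Log-RR per unit of the fixed weighted index (ug/m3-equivalent).

    Quasi-Poisson refit with a single linear term on z_t = sum_k w_k x_kt
    (lag 0-2 moving averages, raw scale) and the standard confounders.
    """
    config = config or ModelConfig()
    weights = np.asarray(weights, float)
    mas = np.column_stack(
        [moving_average(series.pollutant(k), config.exposure_ma_window)
         for k in pollutants]
    )
    z = mas @ weights
    conf, mask = confounder_design(series, config)
    mask = mask & np.isfinite(z) & np.isfinite(series.deaths)
    design = np.column_stack([z[mask], conf[mask]])
    fit = fit_quasipoisson(series.deaths[mask], design)
    return float(fit.coefficients[0]), float(fit.covariance[0, 0])


def bootstrap_weight_uncertainty(
    series: CityDailySeries,
    config: ModelConfig | None = None,
    n_boot: int = 100,
    block_length: int = 30,
    seed: int | np.random.SeedSequence = 0,
    pollutants: tuple[str, ...] = POLLUTANT_COLUMNS,
) -> np.ndarray:
    """Moving-block bootstrap covariance of the raw-scale weights.

    Complete-case rows are resampled in contiguous blocks (preserving
    short-range serial dependence); each replicate refits the weights
    from its own constrained-linear initialisation. (Warm-starting at the
    point estimate is deliberately avoided: on flat profile deviances the
    replicates would stay near the start and the covariance would badly
    understate the weight uncertainty.) Fails if more than 20% of
    replicates error out.
    """
    if n_boot < 1:
        raise InvalidParameterError("n_boot must be >= 1")
    if block_length < 1:
        raise InvalidParameterError("block_length must be >= 1")
    config = config or ModelConfig()
    rng = np.random.default_rng(seed)
    y, conf, x_raw, xs, sd, _ = _prepare(series, config, pollutants)
    n = y.size
    n_blocks = int(np.ceil(n / block_length))
    reps = []
    failures = 0
    for _ in range(n_boot):
        starts = rng.integers(0, max(1, n - block_length + 1), size=n_blocks)
        idx = (starts[:, None] + np.arange(block_length)[None, :]).ravel()[:n]
        try:
            w_b, *_ = _alternate(
                y[idx], conf[idx], xs[idx], max_alt=15, tol=1e-4
            )
            reps.append(_simplex_project(w_b))
        except Exception:
            failures += 1
    if failures > 0.2 * n_boot:
        raise UnstableBootstrapError(
            f"{failures}/{n_boot} bootstrap replicates failed"
        )
    reps = np.asarray(reps)
    return np.atleast_2d(np.cov(reps, rowvar=False))
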