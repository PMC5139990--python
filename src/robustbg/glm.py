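"""Robust Poisson GLM estimation of reflection backgrounds.

The expected background of a shoebox is modelled on the log scale as either
a constant or a plane, ``log mu_i = x_i . beta``, with photon counts assumed
Poisson.  Instead of the maximum-likelihood score, the fit solves the robust
quasi-likelihood score equations of Cantoni-Ronchetti type,

    sum_i [ psi_c(r_i) - a_i(beta) ] (1 / sqrt(mu_i)) mu_i' x_i = 0 ,

where ``r_i = (y_i - mu_i) / sqrt(mu_i)`` is the Pearson residual,
``psi_c`` the Huber clamp with tuning constant ``c``, and ``a_i(beta) =
E[psi_c(R_i)]`` the Fisher-consistency correction that makes the score
mean-zero at the true parameter.  The explanatory-variable weights are unit
and the dispersion is fixed at 1 (Poisson).  With ``c = inf`` the estimator
reduces to the classical Poisson GLM maximum-likelihood fit.

The score equations are solved by iteratively reweighted least squares
(Newton steps preconditioned by the expected score derivative), and the
asymptotic covariance of the coefficient estimate is the sandwich
``M^-1 Q M^-T`` with both ``M`` and ``Q`` evaluated using exact Poisson
moments of the clamped residual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize, special

__all__ = [
    "DEFAULT_TUNING_CONSTANT",
    "ModelSpec",
    "RobustFitConfig",
    "FitResult",
    "pearson_residual",
    "huber_psi",
    "huber_weight",
    "fisher_consistency_correction",
    "normal_efficiency",
    "default_tuning_constant",
    "design_matrix",
    "robust_glm_fit",
    "constant_background_fit",
    "estimator_covariance",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


def normal_efficiency(c: float) -> float:
    """Asymptotic relative efficiency at the standard normal of the Huber
    location estimator with tuning constant ``c``, relative to the mean.

    Computed in closed form from the standard ratio
    ``(E[psi'])^2 / E[psi^2]`` under the standard normal:
    ``E[psi'] = 2 Phi(c) - 1`` and
    ``E[psi^2] = (2 Phi(c) - 1) - 2 c phi(c) + 2 c^2 (1 - Phi(c))``.
    Strictly increasing in ``c`` and -> 1 as ``c -> inf``.
    """
    if c <= 0:
        raise ValueError(f"tuning constant must be positive, got {c}")
    if math.isinf(c):
        return 1.0
    Phi = special.ndtr(c)
    phi = math.exp(-0.5 * c * c) / _SQRT_2PI
    e_psi_prime = 2.0 * Phi - 1.0
    e_psi_sq = e_psi_prime - 2.0 * c * phi + 2.0 * c * c * (1.0 - Phi)
    return e_psi_prime * e_psi_prime / e_psi_sq


@lru_cache(maxsize=None)
def default_tuning_constant(efficiency: float = 0.95) -> float:
    """Tuning constant whose normal-distribution efficiency equals the target.

    Found by 1-D root finding of ``normal_efficiency(c) = efficiency``.
    The 95% default gives c ~= 1.345, the standard Huber choice.
    """
    if not 0.0 < efficiency < 1.0:
        raise ValueError("efficiency must be in (0, 1)")
    return optimize.brentq(
        lambda c: normal_efficiency(c) - efficiency, 1e-3, 50.0, xtol=1e-12
    )


DEFAULT_TUNING_CONSTANT = default_tuning_constant(0.95)


@dataclass(frozen=True)
class ModelSpec:
    """Background model: constant or planar on the log scale.

    The planar model's design rows are ``(1, x - x0, y - y0)`` with the
    origin ``(x0, y0)`` at the peak position; pixel centres sit at integer
    coordinates, x (column) before y (row).
    """

    kind: str = "constant"
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "planar"):
            raise ValueError(f"unknown model kind: {self.kind!r}")

    @property
    def n_coefficients(self) -> int:
        return 1 if self.kind == "constant" else 3


@dataclass(frozen=True)
class RobustFitConfig:
    """Tuning of the robust fit.

    c: Huber tuning constant; larger is more efficient, less robust.
       ``inf`` (allowed when ``allow_infinite_c``) recovers the classical
       Poisson GLM.
    tol: convergence tolerance on the max absolute coefficient change.
    max_iter: iteration cap; hitting it flags the result, never raises.
    """

    c: float = DEFAULT_TUNING_CONSTANT
    tol: float = 1e-6
    max_iter: int = 100
    allow_infinite_c: bool = True

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError(f"c must be positive, got {self.c}")
        if math.isinf(self.c) and not self.allow_infinite_c:
            raise ValueError("infinite c disallowed by configuration")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class FitResult:
    """Result of a robust background fit.

    ``beta`` is on the log scale; ``mu`` is the per-pixel expected
    background in counts/pixel.  For all-zero input the fit is degenerate:
    ``mu = 0`` everywhere, the intercept is reported as ``-inf`` and the
    covariance is undefined (None).
    """

    beta: np.ndarray
    mu: np.ndarray
    covariance: np.ndarray | None
    weights: np.ndarray
    n_iter: int
    converged: bool
    degenerate: bool = False

    @property
    def background(self) -> float:
        """Expected background at the model origin (counts/pixel)."""
        if self.degenerate:
            return 0.0
        return float(np.exp(self.beta[0]))


def pearson_residual(y, mu):
    """Pearson residual ``(y - mu)/sqrt(mu)`` for Poisson variance v(mu)=mu."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    y = np.asarray(y, dtype=float)
    return (y - mu) / np.sqrt(mu)


def huber_psi(r, c: float):
    """Huber score ``psi_c(r) = max(-c, min(c, r))``; odd in r."""
    if c <= 0:
        raise ValueError("c must be positive")
    return np.clip(r, -c, c)


def huber_weight(r, c: float):
    """Huber weight ``psi_c(r)/r`` (1 at r = 0); equals ``min(1, c/|r|)``."""
    if c <= 0:
        raise ValueError("c must be positive")
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        w = np.minimum(1.0, c / np.abs(r))
    w = np.where(r == 0.0, 1.0, w)
    if w.ndim == 0:
        return float(w)
    return w


def _support_window(mu_max: float) -> np.ndarray:
    """Integer support covering all but a < 1e-12 Poisson tail."""
    upper = int(math.ceil(mu_max + 10.0 * math.sqrt(mu_max) + 20.0))
    return np.arange(upper + 1)


def _poisson_pmf(k: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Poisson pmf on grid ``k`` for each mu (rows = mu, cols = k)."""
    mu = np.atleast_1d(np.asarray(mu, dtype=float))[:, None]
    logp = special.xlogy(k[None, :], mu) - mu - special.gammaln(k[None, :] + 1.0)
    return np.exp(logp)


def _expected_psi(mu: np.ndarray, c: float) -> np.ndarray:
    """E[psi_c(R)] for R the Pearson residual of Y ~ Poisson(mu), exact sum."""
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    if math.isinf(c):
        return np.zeros_like(mu)
    k = _support_window(float(mu.max()))
    pmf = _poisson_pmf(k, mu)
    r = (k[None, :] - mu[:, None]) / np.sqrt(mu[:, None])
    return np.sum(pmf * np.clip(r, -c, c), axis=1)


def fisher_consistency_correction(mu, c: float):
    """Fisher-consistency correction ``a(mu) = E[psi_c(R)]``.

    Computed by exact summation of the Poisson mass over a support window
    whose truncated tail is below 1e-12.  Subtracting this from psi makes
    the robust score mean-zero at the true parameter.
    """
    mu_arr = np.atleast_1d(np.asarray(mu, dtype=float))
    if np.any(mu_arr <= 0):
        raise ValueError("mu must be positive")
    if c <= 0:
        raise ValueError("c must be positive")
    out = _expected_psi(mu_arr, c)
    if np.isscalar(mu) or np.asarray(mu).ndim == 0:
        return float(out[0])
    return out


def _score_contrib(y: np.ndarray, mu: np.ndarray, c: float, a: np.ndarray) -> np.ndarray:
    """Scalar part of the per-pixel score: (psi_c(r) - a(mu)) sqrt(mu).

    For the log link, ``(1/sqrt(mu)) mu' = sqrt(mu)``.
    """
    if math.isinf(c):
        return y - mu
    r = (y - mu) / np.sqrt(mu)
    return (np.clip(r, -c, c) - a) * np.sqrt(mu)


def _expected_moments(mu: np.ndarray, c: float):
    """Exact Poisson moments of the clamped residual at mean ``mu``.

    Returns ``(a, m, v)`` per pixel, from a single exact pmf summation:

    - ``a = E[psi_c(R)]``, the Fisher-consistency correction;
    - ``m = sqrt(mu) E[psi_c(R)(Y - mu)]``, minus the expected derivative
      of the per-pixel score in ``eta = log mu`` (via the Poisson score
      identity ``d/dmu E[f(Y)] = E[f(Y)(Y/mu - 1)]``); for ``c = inf`` this
      is exactly ``mu``, the Poisson Fisher weight;
    - ``v = E[(psi_c(R) - a)^2]``, the variance of the clamped residual.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    if math.isinf(c):
        return np.zeros_like(mu), mu.copy(), np.ones_like(mu)
    k = _support_window(float(mu.max()))
    pmf = _poisson_pmf(k, mu)
    dev = k[None, :] - mu[:, None]
    sqrt_mu = np.sqrt(mu)
    psi = np.clip(dev / sqrt_mu[:, None], -c, c)
    a = np.sum(pmf * psi, axis=1)
    m = sqrt_mu * np.sum(pmf * psi * dev, axis=1)
    v = np.sum(pmf * (psi - a[:, None]) ** 2, axis=1)
    return a, m, v


def design_matrix(model: ModelSpec, coords: np.ndarray | None, n: int) -> np.ndarray:
    """Design matrix rows: (1) constant, (1, x-x0, y-y0) planar."""
    if model.kind == "constant":
        return np.ones((n, 1))
    if coords is None:
        raise ValueError("planar model requires pixel coordinates")
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (n, 2):
        raise ValueError(f"coords must have shape ({n}, 2)")
    x0, y0 = model.origin
    return np.column_stack(
        [np.ones(n), coords[:, 0] - x0, coords[:, 1] - y0]
    )


_MAX_STEP = 2.0  # damping cap on Newton steps, log-scale units
_ETA_CLIP = 500.0


def _line_search(score_at, beta, step, score0, valid=None):
    """Globalize the Newton step by monitoring the score norm.

    When every residual is clamped (gross contamination far from the
    root) the expectation-based information overestimates the curvature
    and raw Newton steps crawl; doubling the step while the score norm
    keeps falling restores fast progress.  Conversely the step is halved
    if it initially increases the score norm.  Near the root neither
    branch triggers, so quadratic convergence and the fixed point are
    untouched.

    ``valid`` guards the boundary: the score carries a sqrt(mu) factor
    and spuriously vanishes as all fitted means collapse to zero, so
    expansion never crosses into that region.
    """
    norm0 = float(np.linalg.norm(score0))
    norm1 = float(np.linalg.norm(score_at(beta + step)))
    for _ in range(10):
        if norm1 <= norm0 or np.max(np.abs(step)) < 1e-14:
            break
        step = 0.5 * step
        norm1 = float(np.linalg.norm(score_at(beta + step)))
    # expansion stops once the projected score flips sign relative to the
    # current iterate: the root has been crossed and is bracketed within
    # the last factor-2 segment
    sign0 = math.copysign(1.0, float(np.dot(step, score0))) if np.any(step) else 1.0
    for _ in range(60):
        trial = 2.0 * step
        if valid is not None and not valid(beta + trial):
            break
        s2 = score_at(beta + trial)
        if math.copysign(1.0, float(np.dot(step, s2))) != sign0:
            break
        norm2 = float(np.linalg.norm(s2))
        if norm2 < norm1:
            step, norm1 = trial, norm2
        else:
            break
    return step


_MU_FLOOR = 1e-10  # smallest admissible peak background during iteration


def _degenerate_result(n: int, p: int) -> FitResult:
    beta = np.full(p, 0.0)
    beta[0] = -np.inf
    return FitResult(
        beta=beta,
        mu=np.zeros(n),
        covariance=None,
        weights=np.ones(n),
        n_iter=0,
        converged=True,
        degenerate=True,
    )


def _validate_counts(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("y must be a non-empty 1-D count vector")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    return y


def _classical_init(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Classical (non-robust) Poisson GLM fit used to initialize IRLS.

    Started at ``log(mean(y) + eps)`` with ``eps = 1/(2n)`` so all-but-zero
    data stay finite; a handful of Fisher-scoring steps suffice.
    """
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = math.log(float(np.mean(y)) + 0.5 / n)
    for _ in range(50):
        mu = np.exp(np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP))
        score = X.T @ (y - mu)
        info = X.T @ (mu[:, None] * X)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -_MAX_STEP, _MAX_STEP)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def robust_glm_fit(
    y,
    model: ModelSpec | None = None,
    coords: np.ndarray | None = None,
    config: RobustFitConfig | None = None,
) -> FitResult:
    """Fit the robust Poisson GLM background model by IRLS.

    Parameters
    ----------
    y : 1-D array of non-negative integer counts (background pixels).
    model : ModelSpec; defaults to the constant model.
    coords : (n, 2) pixel coordinates, required for the planar model.
    config : RobustFitConfig; defaults to the 95%-efficiency tuning.

    Returns
    -------
    FitResult with coefficients on the log scale, per-pixel means,
    sandwich covariance, final Huber weights and convergence flags.
    Non-convergence is flagged, never raised, so batch processing of many
    shoeboxes does not abort.
    """
    model = model or ModelSpec()
    config = config or RobustFitConfig()
    y = _validate_counts(y)
    n = y.size
    p = model.n_coefficients
    if n < p:
        raise ValueError(f"need at least {p} pixels for the {model.kind} model")
    if not np.any(y > 0):
        return _degenerate_result(n, p)

    X = design_matrix(model, coords, n)
    beta = _classical_init(y, X)
    c = config.c

    def score_at(b: np.ndarray) -> np.ndarray:
        mu_b = np.exp(np.clip(X @ b, -_ETA_CLIP, _ETA_CLIP))
        a_b, _, _ = _expected_moments(mu_b, c)
        return X.T @ _score_contrib(y, mu_b, c, a_b)

    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        mu = np.exp(np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP))
        a, m, _ = _expected_moments(mu, c)
        score = X.T @ _score_contrib(y, mu, c, a)
        M = X.T @ (m[:, None] * X)
        try:
            step = np.linalg.solve(M, score)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular expected-information matrix: degenerate design "
                f"for the {model.kind} model"
            ) from exc
        step = np.clip(step, -_MAX_STEP, _MAX_STEP)
        step = _line_search(
            score_at, beta, step, score,
            valid=lambda b: float(np.max(X @ b)) > math.log(_MU_FLOOR),
        )
        beta = beta + step
        if np.max(np.abs(step)) < config.tol:
            converged = True
            break

    mu = np.exp(np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP))
    r = (y - mu) / np.sqrt(mu)
    weights = huber_weight(r, c) if not math.isinf(c) else np.ones(n)
    result = FitResult(
        beta=beta,
        mu=mu,
        covariance=None,
        weights=np.atleast_1d(weights),
        n_iter=n_iter,
        converged=converged,
    )
    if converged:
        try:
            result.covariance = estimator_covariance(result, X, config)
        except np.linalg.LinAlgError:
            result.covariance = None
    return result


def constant_background_fit(y, config: RobustFitConfig | None = None) -> FitResult:
    """Fast path for the constant background model.

    Exploits the identical design rows to reduce IRLS to a scalar Newton
    iteration in ``eta = log mu``; agrees with the general path on every
    input (same score equation, same tolerance).
    """
    config = config or RobustFitConfig()
    y = _validate_counts(y)
    n = y.size
    if not np.any(y > 0):
        return _degenerate_result(n, 1)

    c = config.c
    eta = math.log(float(np.mean(y)))  # exact classical MLE for the constant model
    converged = False
    n_iter = 0

    def score_at(eta_vec: np.ndarray) -> np.ndarray:
        mu_s = math.exp(min(max(float(eta_vec[0]), -_ETA_CLIP), _ETA_CLIP))
        if math.isinf(c):
            return np.array([float(np.sum(y)) - n * mu_s])
        sq = math.sqrt(mu_s)
        a_s = float(_expected_psi(np.array([mu_s]), c)[0])
        return np.array(
            [(float(np.sum(np.clip((y - mu_s) / sq, -c, c))) - n * a_s) * sq]
        )

    mu_arr = np.empty(1)
    for n_iter in range(1, config.max_iter + 1):
        mu = math.exp(min(max(eta, -_ETA_CLIP), _ETA_CLIP))
        mu_arr[0] = mu
        sqrt_mu = math.sqrt(mu)
        if math.isinf(c):
            score = float(np.sum(y)) - n * mu
            m_scalar = mu
        else:
            r = (y - mu) / sqrt_mu
            a, m, _ = _expected_moments(mu_arr, c)
            score = (float(np.sum(np.clip(r, -c, c))) - n * float(a[0])) * sqrt_mu
            m_scalar = float(m[0])
        step = score / (n * m_scalar)
        step = min(max(step, -_MAX_STEP), _MAX_STEP)
        step = float(
            _line_search(
                score_at, np.array([eta]), np.array([step]), np.array([score]),
                valid=lambda b: float(b[0]) > math.log(_MU_FLOOR),
            )[0]
        )
        eta += step
        if abs(step) < config.tol:
            converged = True
            break

    mu = math.exp(min(max(eta, -_ETA_CLIP), _ETA_CLIP))
    r = (y - mu) / math.sqrt(mu)
    weights = huber_weight(r, c) if not math.isinf(c) else np.ones(n)
    result = FitResult(
        beta=np.array([eta]),
        mu=np.full(n, mu),
        covariance=None,
        weights=np.atleast_1d(weights),
        n_iter=n_iter,
        converged=converged,
    )
    if converged:
        X = np.ones((n, 1))
        try:
            result.covariance = estimator_covariance(result, X, config)
        except np.linalg.LinAlgError:
            result.covariance = None
    return result


def estimator_covariance(
    fit: FitResult, X: np.ndarray, config: RobustFitConfig
) -> np.ndarray:
    """Sandwich asymptotic covariance ``M^-1 Q M^-T`` of the coefficients.

    ``Q = X' diag(q) X`` with ``q_i = mu_i E[(psi_c(R) - a)^2]`` the exact
    variance of the per-pixel score contribution, and ``M = X' diag(m) X``
    with ``m_i`` the exact expected score derivative.  For ``c = inf`` both
    reduce to the Poisson Fisher information, giving the classical inverse
    information (constant model: ``var(beta) = 1/(n mu)``).
    """
    if fit.degenerate:
        raise ValueError("covariance undefined for the degenerate all-zero fit")
    mu = np.asarray(fit.mu, dtype=float)
    c = config.c
    _, m, v = _expected_moments(mu, c)
    q = mu * v
    M = X.T @ (m[:, None] * X)
    Q = X.T @ (q[:, None] * X)
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "singular expected-information matrix: degenerate design"
        )
    Minv = np.linalg.inv(M)
    cov = Minv @ Q @ Minv.T
    return 0.5 * (cov + cov.T)
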