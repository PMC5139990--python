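"""Traditional outlier-handling strategies for shoebox background pixels.

Six strategies are provided, matching the vocabulary used by integration
packages: ``null`` (no handling), ``truncated`` (symmetric trimming),
``nsigma`` (mean +/- N sigma clip), ``tukey`` (IQR fences), ``plane``
(MOSFLM-style trimmed plane fit with a Poisson-scale deviation re-check)
and ``normal`` (Kabsch-style iterative removal of the largest values until
the sample looks normal).  Each returns a retained-pixel mask and a
background estimate; all constant-background strategies are invariant to
input order.

These methods assume approximately normal pixel values.  At photon-counting
background levels (lambda of order 1 or below) that assumption fails, and
several of them reject every nonzero pixel in a large fraction of
shoeboxes, driving the background estimate to exactly zero — the pathology
the robust GLM estimator in :mod:`robustbg.glm` avoids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, stats

__all__ = [
    "FilterResult",
    "filter_null",
    "filter_truncated",
    "filter_nsigma",
    "filter_tukey",
    "filter_plane",
    "filter_normal",
    "expected_normal_range",
    "FILTERS",
]


@dataclass
class FilterResult:
    """Outcome of a traditional outlier-handling strategy.

    ``background`` is a scalar (counts/pixel) for the constant methods and
    the plane coefficients ``(a, b, c)`` for the plane method, where ``a``
    is the mean background at the peak position.  ``flagged`` marks
    degenerate stops (e.g. the normal method running out of pixels).
    """

    retained: np.ndarray
    background: float | np.ndarray
    method: str
    n_rejected: int
    flagged: bool = False

    @property
    def background_level(self) -> float:
        """Scalar background level (plane: value at the origin)."""
        if isinstance(self.background, np.ndarray):
            return float(self.background[0])
        return float(self.background)


def _validate(y, min_n: int, method: str) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise ValueError(f"{method}: y must be a non-empty 1-D count vector")
    if y.size < min_n:
        raise ValueError(f"{method}: need at least {min_n} pixels, got {y.size}")
    return y


def _result(y, retained, method, background=None, flagged=False) -> FilterResult:
    retained = np.asarray(retained, dtype=bool)
    if background is None:
        background = float(np.mean(y[retained])) if retained.any() else 0.0
    return FilterResult(
        retained=retained,
        background=background,
        method=method,
        n_rejected=int((~retained).sum()),
        flagged=flagged,
    )


def filter_null(y) -> FilterResult:
    """No outlier handling: every pixel retained, background = mean."""
    y = _validate(y, 1, "null")
    return _result(y, np.ones(y.size, dtype=bool), "null")


def filter_truncated(y, fraction: float = 0.05) -> FilterResult:
    """Discard a fraction of the pixels with the highest and lowest counts.

    ``floor(fraction * n)`` pixels are dropped from each end of the sorted
    sample (stable sort, so ties are broken deterministically by input
    order); the background is the mean of the retained pixels.  Because the
    Poisson distribution is asymmetric, this symmetric trim is a biased
    estimator of the Poisson mean.
    """
    y = _validate(y, 1, "truncated")
    if not 0.0 <= fraction < 0.5:
        raise ValueError(f"truncated: fraction must be in [0, 0.5), got {fraction}")
    n = y.size
    k = int(math.floor(fraction * n))
    retained = np.ones(n, dtype=bool)
    if k > 0:
        order = np.argsort(y, kind="stable")
        retained[order[:k]] = False
        retained[order[n - k:]] = False
    return _result(y, retained, "truncated")


def filter_nsigma(y, N: float = 3.0) -> FilterResult:
    """Retain pixels within mean +/- N sigma (single pass, not iterated).

    Sigma is the population (n-divisor) standard deviation.  If sigma is 0
    exactly the pixels equal to the mean are retained.
    """
    y = _validate(y, 2, "nsigma")
    if not N > 0:
        raise ValueError("nsigma: N must be positive")
    mean = float(np.mean(y))
    sigma = float(np.std(y))
    retained = np.abs(y - mean) <= N * sigma
    return _result(y, retained, "nsigma")


def filter_tukey(y, N: float = 1.5) -> FilterResult:
    """Retain pixels inside the Tukey fences ``[Q1 - N IQR, Q3 + N IQR]``.

    Quartiles use linear interpolation between order statistics (the common
    "type 7" convention); with IQR = 0 only values equal to the median
    survive, which at very low background rejects every nonzero pixel.
    """
    y = _validate(y, 4, "tukey")
    if not N > 0:
        raise ValueError("tukey: N must be positive")
    q1, q3 = np.percentile(y, [25.0, 75.0])
    iqr = q3 - q1
    retained = (y >= q1 - N * iqr) & (y <= q3 + N * iqr)
    return _result(y, retained, "tukey")


def _fit_plane(y, coords_rel):
    X = np.column_stack([np.ones(y.size), coords_rel[:, 0], coords_rel[:, 1]])
    coeffs, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    return coeffs, X, rank


def filter_plane(y, coords, trim_fraction: float = 0.1, N: float = 4.0,
                 origin: tuple[float, float] = (0.0, 0.0)) -> FilterResult:
    """MOSFLM-style plane background with trimming and a deviation re-check.

    The top ``trim_fraction`` of pixels by value are discarded and a plane
    ``a + b x + c y`` (origin at the peak position, so ``a`` is the mean
    background) is least-squares fitted to the rest.  Every pixel is then
    re-tested and rejected when its absolute deviation from the plane
    exceeds ``N sqrt(max(a, 1))`` — the Poisson standard deviation at the
    plane's mean level, floored at one count — and the plane is refitted on
    the survivors.
    """
    y = _validate(y, 4, "plane")
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (y.size, 2):
        raise ValueError(f"plane: coords must have shape ({y.size}, 2)")
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("plane: trim_fraction must be in [0, 0.5)")
    if not N > 0:
        raise ValueError("plane: N must be positive")
    rel = coords - np.asarray(origin, dtype=float)

    n = y.size
    k = int(math.floor(trim_fraction * n))
    order = np.argsort(y, kind="stable")
    trimmed = np.ones(n, dtype=bool)
    if k > 0:
        trimmed[order[n - k:]] = False
    if trimmed.sum() < 3:
        raise ValueError("plane: fewer than 3 pixels left after trimming")
    coeffs, _, rank = _fit_plane(y[trimmed], rel[trimmed])
    if rank < 3:
        raise ValueError("plane: rank-deficient design (collinear pixel coordinates)")

    threshold = N * math.sqrt(max(float(coeffs[0]), 1.0))
    model = coeffs[0] + coeffs[1] * rel[:, 0] + coeffs[2] * rel[:, 1]
    retained = np.abs(y - model) <= threshold
    if retained.sum() < 3:
        raise ValueError("plane: fewer than 3 pixels survive the deviation check")
    coeffs, _, rank = _fit_plane(y[retained], rel[retained])
    if rank < 3:
        raise ValueError("plane: rank-deficient design after rejection "
                         "(surviving pixels are collinear)")
    return _result(y, retained, "plane", background=coeffs)


@lru_cache(maxsize=None)
def expected_normal_range(n: int) -> float:
    """Expected range of a sample of n standard normal draws.

    ``E[range] = 2 E[max] = 2 n Int z phi(z) Phi(z)^(n-1) dz`` by symmetry,
    evaluated by quadrature.  (For n = 25 this is the classical d2 constant,
    about 3.93.)
    """
    if n < 2:
        return 0.0
    val, _ = integrate.quad(
        lambda z: z * stats.norm.pdf(z) * stats.norm.cdf(z) ** (n - 1),
        -9.0, 9.0, limit=200,
    )
    return 2.0 * n * val

def filter_normal(y, slack: float = 1.0, min_survivors: int = 5) -> FilterResult:
    """Iteratively remove the largest values until the sample looks normal.

    The sample is sorted ascending; while the observed range of the
    retained values exceeds ``slack`` times the expected range of an
    equal-sized normal sample with the retained sample's standard deviation
    (ddof = 1), the current maximum is removed.  The loop stops (and the
    result is flagged) rather than dropping below ``min_survivors`` pixels.
    The background is the mean of the survivors.
    """
    y = _validate(y, min_survivors, "normal")
    if not slack > 0:
        raise ValueError("normal: slack must be positive")
    order = np.argsort(y, kind="stable")
    y_sorted = y[order]
    n = y.size
    m = n
    flagged = False
    while True:
        vals = y_sorted[:m]
        rng = float(vals[-1] - vals[0])
        if rng == 0.0:
            break
        sigma = float(np.std(vals, ddof=1))
        if rng <= slack * expected_normal_range(m) * sigma:
            break
        if m - 1 < min_survivors:
            flagged = True
            break
        m -= 1
    retained = np.zeros(n, dtype=bool)
    retained[order[:m]] = True
    return _result(y, retained, "normal", flagged=flagged)


FILTERS = {
    "null": filter_null,
    "truncated": filter_truncated,
    "nsigma": filter_nsigma,
    "tukey": filter_tukey,
    "plane": filter_plane,
    "normal": filter_normal,
}
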