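"""Diagnostics comparing background-estimation strategies on synthetic data.

This module provides the analysis battery used to characterize outlier
handling at photon-counting background levels: the exact bias of the
symmetrically trimmed Poisson-mean estimator, normalized differences of
each method against no outlier handling, index-of-dispersion selection of
contaminated shoeboxes, a median-bound robustness check based on the Choi
bounds for the Poisson median, the zero-background pathology fraction, and
a driver that runs every method on identical simulated shoeboxes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .filters import (
    filter_normal,
    filter_nsigma,
    filter_null,
    filter_plane,
    filter_truncated,
    filter_tukey,
)
from .glm import RobustFitConfig, constant_background_fit
from .simulate import BACKGROUND, Shoebox, ShoeboxSpec, simulate_dataset

__all__ = [
    "METHODS",
    "estimate_background",
    "index_of_dispersion",
    "select_outlier_shoeboxes",
    "truncated_estimator_bias",
    "normalized_difference",
    "median_bound_check",
    "zero_background_fraction",
    "run_comparison",
]

METHODS = ("null", "truncated", "nsigma", "tukey", "plane", "normal", "glm")

# Choi (1994) bounds for the Poisson median: lambda - ln 2 <= median <
# lambda + 1/3.  Inverted for the estimate of lambda against the sample
# median m: estimate - m must lie in [-1/3, ln 2].
MEDIAN_LOWER = -1.0 / 3.0
MEDIAN_UPPER = math.log(2.0)


def estimate_background(sb: Shoebox, method: str, config: RobustFitConfig | None = None,
                        **params) -> float:
    """Scalar background estimate (counts/pixel) for one shoebox.

    Dispatches on the method vocabulary: the six traditional filters plus
    ``glm`` (robust constant-model fit).  The plane method reports its
    ``a`` coefficient, the mean background at the peak position.
    """
    y = sb.background_values
    if method == "glm":
        return constant_background_fit(y, config=config).background
    if method == "null":
        return filter_null(y).background_level
    if method == "truncated":
        return filter_truncated(y, **params).background_level
    if method == "nsigma":
        return filter_nsigma(y, **params).background_level
    if method == "tukey":
        return filter_tukey(y, **params).background_level
    if method == "normal":
        return filter_normal(y, **params).background_level
    if method == "plane":
        return filter_plane(y, sb.background_coords(), origin=sb.peak,
                            **params).background_level
    raise ValueError(f"unknown method: {method!r}")


def index_of_dispersion(y) -> float:
    """Sample variance / sample mean; 1 in expectation for Poisson data.

    Values much larger than 1 flag contamination.  Undefined (NaN) when the
    sample mean is zero.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise ValueError("need at least two values")
    mean = float(np.mean(y))
    if mean == 0.0:
        return float("nan")
    return float(np.var(y, ddof=1)) / mean


def select_outlier_shoeboxes(dataset, threshold: float = 5.0) -> list:
    """Shoeboxes whose background index of dispersion exceeds the threshold."""
    if not threshold > 1:
        raise ValueError("threshold must exceed 1")
    selected = []
    for sb in dataset:
        iod = index_of_dispersion(sb.background_values)
        if np.isfinite(iod) and iod > threshold:
            selected.append(sb)
    return selected


def _poisson_cdf_grid(lam: float, t: np.ndarray) -> np.ndarray:
    # P(Y <= t) = Q(t+1, lam), the regularized upper incomplete gamma.
    return special.gammaincc(t + 1.0, lam)


def truncated_estimator_bias(lam: float, fraction: float, n: int) -> float:
    """Exact bias of the symmetrically trimmed mean of a Poisson sample.

    For a sample of size ``n`` from Poisson(lambda) with ``floor(fraction *
    n)`` order statistics removed from each end, returns ``E[trimmed mean]
    - lambda``.  The order-statistic expectations are evaluated through the
    Poisson CDF (regularized gamma function) and the regularized incomplete
    beta function:

        E[Y_(j)] = sum_t P(Y_(j) > t),
        P(Y_(j) <= t) = I_{F(t)}(j, n - j + 1).

    With ``fraction = 0`` the trimmed mean is the sample mean and the bias
    is exactly zero.
    """
    if not lam > 0:
        raise ValueError("lambda must be positive")
    if not 0.0 <= fraction < 0.5:
        raise ValueError("fraction must be in [0, 0.5)")
    if n < 3:
        raise ValueError("n must be >= 3")
    k = int(math.floor(fraction * n))
    if k == 0:
        return 0.0
    upper = int(math.ceil(lam + 10.0 * math.sqrt(lam) + 30.0))
    t = np.arange(upper + 1, dtype=float)
    F = _poisson_cdf_grid(lam, t)
    j = np.arange(k + 1, n - k + 1, dtype=float)
    # P(Y_(j) <= t) = P(Binomial(n, F(t)) >= j) = I_F(j, n-j+1)
    cdf_os = special.betainc(j[:, None], n - j[:, None] + 1.0, F[None, :])
    e_os = np.sum(1.0 - cdf_os, axis=1)
    return float(np.mean(e_os)) - lam


def normalized_difference(est_method: float, est_null: float, n_bg: int) -> float:
    """Difference of a method's estimate from the no-handling estimate,
    normalized by the null estimate's Poisson standard error.

    ``(est_method - est_null) / sqrt(max(est_null, eps) / n_bg)`` with
    ``eps = 1/(2 n_bg)`` guarding all-zero shoeboxes.  Negative values mean
    the method sits below the plain mean — the systematic direction of the
    traditional normal-theory filters at low background.
    """
    if n_bg < 1:
        raise ValueError("n_bg must be >= 1")
    if est_null < 0:
        raise ValueError("est_null must be non-negative")
    eps = 0.5 / n_bg
    se = math.sqrt(max(est_null, eps) / n_bg)
    return (est_method - est_null) / se


def median_bound_check(estimate: float, y, tol: float | None = None) -> bool:
    """Check a background estimate against the Poisson median bounds.

    For Poisson(lambda), ``lambda - ln 2 <= median < lambda + 1/3`` (Choi),
    so a sound estimate satisfies ``estimate - median(y) in [-1/3, ln 2]``.
    The interval is widened by a finite-sample tolerance (default
    ``0.5 + 3 sqrt(max(estimate, 1)/n)``) because the sample median of
    integer counts moves in unit steps.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("y must be non-empty")
    med = float(np.median(y))
    if tol is None:
        tol = 0.5 + 3.0 * math.sqrt(max(float(estimate), 1.0) / y.size)
    diff = float(estimate) - med
    return MEDIAN_LOWER - tol <= diff <= MEDIAN_UPPER + tol


def zero_background_fraction(dataset, method: str, **params) -> float:
    """Percentage of shoeboxes whose estimated background is exactly zero.

    Only shoeboxes with at least one nonzero background pixel count: a zero
    estimate then means the method rejected every nonzero pixel.  The
    ``null`` and ``glm`` methods can never do this.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    n_eligible = 0
    n_zero = 0
    for sb in dataset:
        y = sb.background_values
        if not np.any(y > 0):
            continue
        n_eligible += 1
        if estimate_background(sb, method, **params) == 0.0:
            n_zero += 1
    if n_eligible == 0:
        return 0.0
    return 100.0 * n_zero / n_eligible


def run_comparison(
    scenarios,
    methods=METHODS,
    n_replicates: int = 1000,
    seed: int = 0,
    config: RobustFitConfig | None = None,
    return_histograms: bool = False,
):
    """Run every method on identical simulated shoeboxes, per scenario.

    ``scenarios`` is a sequence of ShoeboxSpec (or scalar lambdas, promoted
    to the default geometry).  For each scenario one dataset is simulated
    and every method is applied to the same shoeboxes, so methods differ
    only in their outlier handling.  Returns a tidy DataFrame with one row
    per (scenario, method): mean normalized difference versus the null
    estimate, zero-background fraction (%), median-bound violation fraction
    (%), and mean bias against the true mean background.  With
    ``return_histograms`` the per-shoebox normalized differences are also
    returned for histogramming.
    """
    if len(scenarios) == 0 or len(methods) == 0:
        raise ValueError("need at least one scenario and one method")
    rows = []
    histograms: dict[tuple[str, str], np.ndarray] = {}
    for s_idx, scenario in enumerate(scenarios):
        if np.isscalar(scenario):
            scenario = ShoeboxSpec(background=float(scenario))
        label = _scenario_label(scenario)
        dataset = simulate_dataset(
            n_replicates, scenario, seed=_subseed(seed, s_idx)
        )
        truth_mean = float(
            np.mean([sb.truth["mean_background"] for sb in dataset])
        )
        n_bg = int(np.sum(dataset[0].mask == BACKGROUND))
        est_null = np.array(
            [estimate_background(sb, "null") for sb in dataset]
        )
        for method in methods:
            if method == "null":
                est = est_null
            else:
                est = np.array(
                    [
                        estimate_background(sb, method, config=config)
                        if method == "glm"
                        else estimate_background(sb, method)
                        for sb in dataset
                    ]
                )
            nd = np.array(
                [
                    normalized_difference(e, e0, n_bg)
                    for e, e0 in zip(est, est_null)
                ]
            )
            eligible = np.array(
                [bool(np.any(sb.background_values > 0)) for sb in dataset]
            )
            zero_frac = (
                100.0 * float(np.mean(est[eligible] == 0.0))
                if eligible.any()
                else 0.0
            )
            violations = np.array(
                [
                    not median_bound_check(e, sb.background_values)
                    for e, sb in zip(est, dataset)
                ]
            )
            rows.append(
                {
                    "scenario": label,
                    "method": method,
                    "n_shoeboxes": n_replicates,
                    "mean_normalized_difference": float(np.mean(nd)),
                    "zero_background_fraction": zero_frac,
                    "median_bound_violation_fraction": 100.0
                    * float(np.mean(violations)),
                    "mean_bias": float(np.mean(est)) - truth_mean,
                }
            )
            if return_histograms:
                histograms[(label, method)] = nd
    table = pd.DataFrame(rows)
    if return_histograms:
        return table, histograms
    return table


def _scenario_label(spec: ShoeboxSpec) -> str:
    if np.isscalar(spec.background):
        base = f"lambda={spec.background:g}"
    else:
        a, b, c = spec.background
        base = f"logplane=({a:g},{b:g},{c:g})"
    if spec.outliers is not None and (
        spec.outliers.n_hot > 0 or spec.outliers.zinger_prob > 0
    ):
        base += "+outliers"
    return base


def _subseed(seed: int, index: int) -> int:
    # splitmix64-style hash of (seed, index), folded below 2**31
    z = (seed * 0x9E3779B97F4A7C15 + index + 1) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return int((z ^ (z >> 31)) & 0x7FFFFFFF)
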