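"""Synthetic reflection shoeboxes with known ground truth.

A shoebox is a small 2-D grid of photon counts around a predicted Bragg
peak, partitioned into foreground (peak) and background pixels.  The
simulator draws background pixels from independent Poisson distributions
whose mean is either constant or planar on the log scale, optionally adds a
discretized Gaussian peak to the foreground, and can inject the two outlier
types seen on real detectors: hot pixels (a defective pixel stuck at a
large count) and zingers (random spikes, e.g. cosmic-ray events).

Everything is reproducible: a dataset seed is expanded into per-shoebox
sub-seeds with ``numpy.random.SeedSequence(seed, spawn_key=(index,))``, so
the stream a shoebox sees is independent of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = [
    "BACKGROUND",
    "FOREGROUND",
    "PeakSpec",
    "OutlierSpec",
    "ShoeboxSpec",
    "Shoebox",
    "simulate_shoebox",
    "inject_outliers",
    "summation_integrate",
    "simulate_dataset",
]

BACKGROUND = 0
FOREGROUND = 1


@dataclass(frozen=True)
class PeakSpec:
    """Discretized isotropic Gaussian peak.

    ``total`` is the expected number of peak counts over the foreground;
    the per-pixel intensity integrates the Gaussian over each pixel and is
    renormalized over the foreground pixels, so the expected summed peak
    signal equals ``total`` exactly.
    """

    total: float = 100.0
    sigma: float = 0.7
    position: tuple[float, float] | None = None  # defaults to the grid centre


@dataclass(frozen=True)
class OutlierSpec:
    """Injected contamination of background pixels."""

    n_hot: int = 0
    hot_value: int = 1000
    zinger_prob: float = 0.0
    zinger_scale: float = 50.0


@dataclass(frozen=True)
class ShoeboxSpec:
    """Ground-truth description of a synthetic shoebox.

    ``background`` is either a scalar Poisson mean (counts/pixel) or a
    triple ``(a, b, c)`` of log-plane coefficients, ``log mu = a + b dx +
    c dy`` with the origin at the peak position.  The default geometry is a
    9x9 grid with a central elliptical foreground covering a 3x3 block, a
    typical macromolecular-crystallography shoebox scale.
    """

    width: int = 9
    height: int = 9
    background: float | tuple[float, float, float] = 1.0
    peak: PeakSpec | None = None
    foreground_radius: float = 1.6
    outliers: OutlierSpec | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.width * self.height < 9:
            raise ValueError("shoebox must contain at least 9 pixels")
        if np.isscalar(self.background) and self.background < 0:
            raise ValueError("background lambda must be non-negative")

    @property
    def peak_position(self) -> tuple[float, float]:
        if self.peak is not None and self.peak.position is not None:
            return self.peak.position
        return ((self.width - 1) / 2.0, (self.height - 1) / 2.0)


@dataclass
class Shoebox:
    """A pixel grid with a foreground/background mask and optional truth.

    ``counts`` is a (height, width) grid of non-negative integers; pixel
    centres sit at integer coordinates with x the column and y the row.
    ``truth`` carries the generating parameters for synthetic data.
    """

    counts: np.ndarray
    mask: np.ndarray
    peak: tuple[float, float]
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.mask = np.asarray(self.mask)
        if self.counts.shape != self.mask.shape:
            raise ValueError("counts and mask shapes differ")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def background_values(self) -> np.ndarray:
        return self.counts[self.mask == BACKGROUND].ravel()

    @property
    def foreground_values(self) -> np.ndarray:
        return self.counts[self.mask == FOREGROUND].ravel()

    def coords(self, label: int) -> np.ndarray:
        """(n, 2) array of (x, y) pixel coordinates with the given label."""
        yy, xx = np.nonzero(self.mask == label)
        return np.column_stack([xx, yy]).astype(float)

    def background_coords(self) -> np.ndarray:
        return self.coords(BACKGROUND)


def _grid_coords(width: int, height: int):
    yy, xx = np.mgrid[0:height, 0:width]
    return xx.astype(float), yy.astype(float)


def _foreground_mask(spec: ShoeboxSpec) -> np.ndarray:
    mask = np.full((spec.height, spec.width), BACKGROUND, dtype=np.uint8)
    if spec.foreground_radius > 0:
        x0, y0 = spec.peak_position
        xx, yy = _grid_coords(spec.width, spec.height)
        r = spec.foreground_radius
        inside = ((xx - x0) / r) ** 2 + ((yy - y0) / r) ** 2 <= 1.0
        mask[inside] = FOREGROUND
    return mask


def background_mean_grid(spec: ShoeboxSpec) -> np.ndarray:
    """True expected background (counts/pixel) on the full grid."""
    xx, yy = _grid_coords(spec.width, spec.height)
    if np.isscalar(spec.background):
        return np.full((spec.height, spec.width), float(spec.background))
    a, b, c = spec.background
    x0, y0 = spec.peak_position
    return np.exp(a + b * (xx - x0) + c * (yy - y0))


def _peak_intensity(spec: ShoeboxSpec, fg: np.ndarray) -> np.ndarray:
    """Per-pixel expected peak counts (foreground only, sums to total)."""
    peak = spec.peak
    x0, y0 = spec.peak_position
    xx, yy = _grid_coords(spec.width, spec.height)
    px = stats.norm.cdf((xx + 0.5 - x0) / peak.sigma) - stats.norm.cdf(
        (xx - 0.5 - x0) / peak.sigma
    )
    py = stats.norm.cdf((yy + 0.5 - y0) / peak.sigma) - stats.norm.cdf(
        (yy - 0.5 - y0) / peak.sigma
    )
    intensity = px * py
    intensity[~fg] = 0.0
    total_in_fg = intensity.sum()
    if total_in_fg <= 0:
        raise ValueError("peak requested but foreground mask is empty")
    return intensity * (peak.total / total_in_fg)


def simulate_shoebox(spec: ShoeboxSpec, rng: np.random.Generator | None = None) -> Shoebox:
    """Generate one shoebox from its spec; outliers are injected if present.

    Background pixels are independent Poisson(mu(x, y)); foreground pixels
    additionally receive Poisson peak counts.  Fully reproducible given
    ``spec.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    mu = background_mean_grid(spec)
    mask = _foreground_mask(spec)
    counts = rng.poisson(mu).astype(np.int64)
    truth = {
        "background": spec.background,
        "mean_background": float(mu[mask == BACKGROUND].mean()),
        "peak_total": spec.peak.total if spec.peak else 0.0,
        "hot_pixels": [],
        "zinger_pixels": [],
    }
    if spec.peak is not None:
        fg = mask == FOREGROUND
        counts[fg] += rng.poisson(_peak_intensity(spec, fg)[fg])
    sb = Shoebox(counts=counts, mask=mask, peak=spec.peak_position, truth=truth)
    if spec.outliers is not None:
        sb = inject_outliers(sb, spec, rng=rng)
    return sb


def inject_outliers(
    sb: Shoebox,
    spec: ShoeboxSpec,
    rng: np.random.Generator | None = None,
    include_foreground: bool = False,
) -> Shoebox:
    """Inject hot pixels and zingers into a shoebox (in place).

    ``n_hot`` randomly chosen background pixels are replaced by
    ``hot_value``; independently, each background pixel gains
    Poisson(zinger_scale) extra counts with probability ``zinger_prob``.
    Foreground pixels are never touched unless ``include_foreground``.
    Ground-truth outlier positions are recorded in ``sb.truth``.
    """
    out = spec.outliers
    if out is None:
        raise ValueError("spec has no outlier specification")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    if include_foreground:
        eligible = np.ones(sb.mask.shape, dtype=bool)
    else:
        eligible = sb.mask == BACKGROUND
    flat_idx = np.flatnonzero(eligible)
    if out.n_hot > flat_idx.size:
        raise ValueError(
            f"n_hot={out.n_hot} exceeds the {flat_idx.size} eligible pixels"
        )
    truth = sb.truth if sb.truth is not None else {}
    if out.n_hot > 0:
        chosen = rng.choice(flat_idx, size=out.n_hot, replace=False)
        sb.counts.ravel()[chosen] = out.hot_value
        truth["hot_pixels"] = [
            (int(i % sb.counts.shape[1]), int(i // sb.counts.shape[1]))
            for i in sorted(chosen)
        ]
    if out.zinger_prob > 0:
        hit = rng.random(flat_idx.size) < out.zinger_prob
        hit_idx = flat_idx[hit]
        sb.counts.ravel()[hit_idx] += rng.poisson(out.zinger_scale, size=hit_idx.size)
        truth["zinger_pixels"] = [
            (int(i % sb.counts.shape[1]), int(i // sb.counts.shape[1]))
            for i in sorted(hit_idx)
        ]
    sb.truth = truth
    return sb


def summation_integrate(sb: Shoebox, background) -> dict:
    """Summation integration of the foreground region.

    ``intensity = sum_fg counts - sum_fg modelled background`` and
    ``variance = sum_fg counts + sum_fg modelled background``: the observed
    counts contribute their Poisson variance and the subtracted background
    model contributes a matching Poisson-level term per foreground pixel
    (the covariance of the fitted background parameters is neglected).

    ``background`` may be a scalar (counts/pixel), a plane coefficient
    triple ``(a, b, c)`` with origin at the peak, or a full per-pixel grid.
    """
    fg = sb.mask == FOREGROUND
    if not fg.any():
        raise ValueError("foreground mask is empty")
    if background is None:
        raise ValueError("background estimate is required")
    if np.isscalar(background):
        bg_grid = np.full(sb.counts.shape, float(background))
    else:
        background = np.asarray(background, dtype=float)
        if background.shape == sb.counts.shape:
            bg_grid = background
        elif background.shape == (3,):
            a, b, c = background
            x0, y0 = sb.peak
            xx, yy = _grid_coords(sb.counts.shape[1], sb.counts.shape[0])
            bg_grid = a + b * (xx - x0) + c * (yy - y0)
        else:
            raise ValueError("background must be scalar, (a, b, c) or a full grid")
    fg_counts = float(sb.counts[fg].sum())
    fg_background = float(bg_grid[fg].sum())
    return {
        "intensity": fg_counts - fg_background,
        "variance": fg_counts + fg_background,
    }


def simulate_dataset(n: int, spec, seed: int = 0) -> list[Shoebox]:
    """Simulate ``n`` independent shoeboxes.

    ``spec`` is a ShoeboxSpec used for every shoebox, or a callable
    ``spec(index) -> ShoeboxSpec`` sampling per-shoebox parameters.  Each
    shoebox draws from ``SeedSequence(seed, spawn_key=(index,))`` so the
    collection is reproducible and order independent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    shoeboxes = []
    for i in range(n):
        spec_i = spec(i) if callable(spec) else spec
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        sb = simulate_shoebox(replace(spec_i, seed=None), rng=rng)
        sb.truth["index"] = i
        shoeboxes.append(sb)
    return shoeboxes
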