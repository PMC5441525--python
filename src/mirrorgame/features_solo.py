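"""Solo-condition distribution features.

Each subject's solo recordings are summarized by three distribution-
valued features:

1. ``deltaP0_histogram`` — a 51-bin histogram of signed movement-segment
   lengths dP0 on the fixed support [-1, 1] (positions live in [0, 1]).
2. ``compute_gws`` — the global wavelet spectrum: time-averaged Morlet
   wavelet power per frequency, averaged over trials.
3. ``fit_motion_model`` + ``coefficient_histogram2d`` — window-wise
   least-squares coefficients (k, c) of a damped linear oscillator
   a(t) = -k (x - x_bar) - c v(t), pooled over trials and binned on a
   100 x 100 grid whose support is shared across the cohort ("learning
   in the model space": the subject is represented by the distribution
   of local dynamics coefficients).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _wavelet
from .preprocess import SegmentSet
from .synthetic_data import Trajectory

__all__ = ["Hist1D", "Hist2D", "GWS", "ModelCoefficients",
           "deltaP0_histogram", "compute_gws", "fit_motion_model",
           "coefficient_histogram2d", "cohort_coefficient_support"]


@dataclass
class Hist1D:
    """Unit-mass histogram on a fixed 1-D support."""

    edges: np.ndarray          # len nbins + 1
    mass: np.ndarray           # len nbins, sums to 1

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if len(self.edges) != len(self.mass) + 1:
            raise ValueError("edges must have len(mass) + 1 entries")
        if np.any(self.mass < -1e-12):
            raise ValueError("negative mass")
        if abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValueError("mass must sum to 1")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class Hist2D:
    """Unit-mass bivariate histogram on a shared grid."""

    edges_x: np.ndarray
    edges_y: np.ndarray
    mass: np.ndarray           # (nx, ny)
    axis_scales: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.edges_x = np.asarray(self.edges_x, dtype=float)
        self.edges_y = np.asarray(self.edges_y, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.shape != (len(self.edges_x) - 1, len(self.edges_y) - 1):
            raise ValueError("mass shape inconsistent with edges")
        if abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValueError("mass must sum to 1")

    @property
    def centers_x(self) -> np.ndarray:
        return 0.5 * (self.edges_x[:-1] + self.edges_x[1:])

    @property
    def centers_y(self) -> np.ndarray:
        return 0.5 * (self.edges_y[:-1] + self.edges_y[1:])


@dataclass
class GWS:
    """Global wavelet spectrum: mean-over-time wavelet power per frequency."""

    freqs: np.ndarray          # Hz, in scale order (ascending scale = descending freq)
    power: np.ndarray
    n_trials_averaged: int = 1

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must match")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass
class ModelCoefficients:
    """Window-wise damped-oscillator coefficients (k in 1/s^2, c in 1/s)."""

    pairs: np.ndarray          # (n_windows, 2) columns (k, c)
    window: float = 2.0
    overlap: float = 0.5
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=float).reshape(-1, 2)


# --------------------------------------------------------------------------- #
# operations
# --------------------------------------------------------------------------- #

def deltaP0_histogram(
    segments: SegmentSet,
    support: tuple[float, float] = (-1.0, 1.0),
    nbins: int = 51,
) -> Hist1D:
    """Histogram of signed segment lengths on a fixed support.

    Bins are equal width; a value on an interior edge goes to the right
    bin and the last bin is right-closed (numpy histogram convention).
    """
    lengths = segments.signed_lengths
    if len(lengths) == 0:
        raise ValueError("no segments to histogram")
    lo, hi = support
    if lengths.min() < lo or lengths.max() > hi:
        raise ValueError("segment length outside histogram support")
    edges = np.linspace(lo, hi, nbins + 1)
    counts, _ = np.histogram(lengths, bins=edges)
    return Hist1D(edges=edges, mass=counts / counts.sum())


def compute_gws(trials: list[Trajectory]) -> GWS:
    """Average global wavelet spectrum over trials.

    Per trial: Morlet (omega0=6) transform on the dyadic scale grid
    (s0 = 2 dt, dj = 1/12), power |W|^2 averaged over time; trial
    spectra are then averaged pointwise.  All trials must share a
    sampling rate; the scale grid of the shortest trial is used so
    spectra are comparable.
    """
    if not trials:
        raise ValueError("no trials")
    rates = {round(tr.rate, 9) for tr in trials}
    if len(rates) > 1:
        raise ValueError("trials must share a sampling rate")
    dt = 1.0 / trials[0].rate
    n_min = min(len(tr.x) for tr in trials)
    scales = _wavelet.scale_grid(n_min, dt)
    spectra = []
    for tr in trials:
        W = _wavelet.cwt_morlet(tr.x, dt, scales)
        spectra.append(np.mean(np.abs(W) ** 2, axis=1))
    power = np.mean(spectra, axis=0)
    return GWS(freqs=_wavelet.scales_to_freqs(scales), power=power,
               n_trials_averaged=len(trials))


def fit_motion_model(
    trials: list[Trajectory],
    window: float = 2.0,
    overlap: float = 0.5,
) -> ModelCoefficients:
    """Fit the local damped-oscillator model in sliding windows.

    In each window the acceleration (central differences) is regressed
    on -(x - x_bar_window) and -v plus an intercept, giving one
    stiffness/damping pair (k, c); the intercept absorbs the offset
    between the window mean and the true oscillation center, which
    otherwise biases (k, c) when a window covers a partial cycle.
    Windows slide with the stated overlap inside each trial and are
    pooled over trials.  Windows with (near-)zero positional variance
    are skipped and counted.
    """
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    pairs: list[tuple[float, float]] = []
    n_skipped = 0
    for tr in trials:
        dt = 1.0 / tr.rate
        w = int(round(window * tr.rate))
        if w < 10:
            raise ValueError("window must contain >= 10 samples")
        step = max(1, int(round(w * (1.0 - overlap))))
        x = tr.x
        v = np.gradient(x, dt)
        a = np.gradient(v, dt)
        for start in range(0, len(x) - w + 1, step):
            xs = x[start:start + w]
            if np.std(xs) < 1e-10:
                n_skipped += 1
                continue
            A = np.column_stack([-(xs - xs.mean()), -v[start:start + w],
                                 np.ones(w)])
            coef, *_ = np.linalg.lstsq(A, a[start:start + w], rcond=None)
            if np.all(np.isfinite(coef)):
                pairs.append((coef[0], coef[1]))
            else:
                n_skipped += 1
    return ModelCoefficients(pairs=np.asarray(pairs).reshape(-1, 2),
                             window=window, overlap=overlap,
                             n_skipped=n_skipped)


def cohort_coefficient_support(
    all_coeffs: list[ModelCoefficients],
    support_quantiles: tuple[float, float] = (0.01, 0.99),
    pad: float = 0.05,
) -> tuple[tuple[float, float], tuple[float, float], tuple[float, float]]:
    """Shared robust (k, c) support for a cohort.

    Returns ``(range_k, range_c, axis_scales)`` where the ranges are the
    stated quantiles of the pooled coefficients padded by ``pad`` of the
    width on each side, and axis_scales are the pooled standard
    deviations used to standardize bin centers for the ground metric.
    """
    pooled = np.vstack([c.pairs for c in all_coeffs if len(c.pairs)])
    if len(pooled) == 0:
        raise ValueError("no coefficient pairs in cohort")
    ranges = []
    for axis in range(2):
        lo, hi = np.quantile(pooled[:, axis], support_quantiles)
        if hi <= lo:
            hi = lo + 1e-6
        width = hi - lo
        ranges.append((lo - pad * width, hi + pad * width))
    scales = (float(pooled[:, 0].std()) or 1.0, float(pooled[:, 1].std()) or 1.0)
    return ranges[0], ranges[1], scales


def coefficient_histogram2d(
    coeffs: ModelCoefficients,
    range_k: tuple[float, float],
    range_c: tuple[float, float],
    grid: int = 100,
    axis_scales: tuple[float, float] = (1.0, 1.0),
) -> Hist2D:
    """Bin one subject's (k, c) pairs on the shared cohort grid.

    Out-of-range pairs are clipped to the edge bins so every pair
    contributes mass; the histogram is normalized to unit mass.
    """
    if len(coeffs.pairs) == 0:
        raise ValueError("no coefficient pairs to bin")
    edges_x = np.linspace(*range_k, grid + 1)
    edges_y = np.linspace(*range_c, grid + 1)
    k = np.clip(coeffs.pairs[:, 0], range_k[0], np.nextafter(range_k[1], -np.inf))
    c = np.clip(coeffs.pairs[:, 1], range_c[0], np.nextafter(range_c[1], -np.inf))
    counts, _, _ = np.histogram2d(k, c, bins=[edges_x, edges_y])
    return Hist2D(edges_x=edges_x, edges_y=edges_y,
                  mass=counts / counts.sum(), axis_scales=axis_scales)
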