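"""Continuous Morlet wavelet engine.

Implements the standard continuous-wavelet conventions used throughout
geophysical and movement-science time-series analysis: an analytic
Morlet mother wavelet (omega0 = 6), a dyadic scale grid
``s_j = s0 * 2**(j*dj)`` with ``s0 = 2*dt`` and ``dj = 1/12``, FFT-based
transforms, the scale->Fourier-frequency conversion
``f = (omega0 + sqrt(2 + omega0**2)) / (4*pi*s)``, and the e-folding
cone of influence ``sqrt(2)*s``.

Cross-wavelet coherence follows the usual smoothed-cross-spectrum
estimator: the cross spectrum and the two auto spectra are divided by
scale, smoothed in time with a scale-matched Gaussian and across scales
with a boxcar of 0.6 decorrelation lengths, and combined as
``|S(Wxy/s)|**2 / (S(|Wx|**2/s) * S(|Wy|**2/s))``.  Pointwise
significance is assessed against a Monte-Carlo red-noise null: pairs of
AR(1) surrogates matching the lag-1 autocorrelations of the two inputs.
"""

from __future__ import annotations

import numpy as np

OMEGA0 = 6.0
DJ_DEFAULT = 1.0 / 12.0
# Fourier factor: wavelength of a Morlet at scale 1
FOURIER_FACTOR = 4.0 * np.pi / (OMEGA0 + np.sqrt(2.0 + OMEGA0**2))


def scale_grid(n: int, dt: float, dj: float = DJ_DEFAULT,
               s0: float | None = None) -> np.ndarray:
    """Dyadic scale grid s_j = s0 * 2**(j*dj), j = 0..J."""
    if s0 is None:
        s0 = 2.0 * dt
    J = int(np.floor(np.log2(n * dt / s0) / dj))
    return s0 * 2.0 ** (dj * np.arange(J + 1))


def scales_to_freqs(scales: np.ndarray) -> np.ndarray:
    return 1.0 / (FOURIER_FACTOR * scales)


def cwt_morlet(x: np.ndarray, dt: float, scales: np.ndarray) -> np.ndarray:
    """Morlet CWT, shape (n_scales, n_times); zero-mean, FFT-based."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    npad = int(2 ** np.ceil(np.log2(n)))          # zero padding vs wrap-around
    xhat = np.fft.fft(x - x.mean(), npad)
    omega = 2.0 * np.pi * np.fft.fftfreq(npad, dt)
    W = np.empty((len(scales), n), dtype=complex)
    pos = omega > 0
    for i, s in enumerate(scales):
        psi_hat = np.zeros(npad)
        arg = s * omega[pos] - OMEGA0
        psi_hat[pos] = (np.pi ** -0.25) * np.exp(-0.5 * arg**2)
        psi_hat[pos] *= np.sqrt(2.0 * np.pi * s / dt)
        W[i] = np.fft.ifft(xhat * psi_hat)[:n]
    return W


def coi_mask(n: int, dt: float, scales: np.ndarray) -> np.ndarray:
    """Boolean (n_scales, n) mask: True inside the cone of influence."""
    edge_dist = np.minimum(np.arange(n), n - 1 - np.arange(n)) * dt
    efold = np.sqrt(2.0) * scales
    return edge_dist[None, :] > efold[:, None]


def _smooth_time(F: np.ndarray, dt: float, scales: np.ndarray) -> np.ndarray:
    """Per-scale Gaussian time smoothing, window width matched to scale."""
    n = F.shape[1]
    npad = int(2 ** np.ceil(np.log2(n)))
    omega = 2.0 * np.pi * np.fft.fftfreq(npad, dt)
    out = np.empty(F.shape, dtype=complex)
    Fhat = np.fft.fft(F, npad, axis=1)
    for i, s in enumerate(scales):
        # Fourier transform of exp(-t^2 / (2 s^2)) normalized to unit area
        g = np.exp(-0.5 * (s * omega) ** 2)
        out[i] = np.fft.ifft(Fhat[i] * g)[:n]
    if np.isrealobj(F):
        return out.real.astype(F.dtype)
    return out


def _smooth_scale(F: np.ndarray, dj: float, dj0: float = 0.6) -> np.ndarray:
    """Boxcar smoothing across scales over dj0 decorrelation lengths."""
    m = max(1, int(round(dj0 / dj)))
    if m == 1:
        return F
    kernel = np.ones(m) / m
    out = np.empty_like(F)
    for j in range(F.shape[1]):
        col = F[:, j]
        out[:, j] = np.convolve(col, kernel, mode="same")
    # renormalize edges where the kernel is truncated
    norm = np.convolve(np.ones(F.shape[0]), kernel, mode="same")
    return out / norm[:, None]


def smooth(F: np.ndarray, dt: float, scales: np.ndarray,
           dj: float = DJ_DEFAULT) -> np.ndarray:
    return _smooth_scale(_smooth_time(F, dt, scales), dj)


def coherence(
    x: np.ndarray, y: np.ndarray, dt: float,
    scales: np.ndarray, dj: float = DJ_DEFAULT,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-wavelet coherence and relative phase of x (leader) vs y.

    Returns ``(R2, phase)`` with R2 in [0, 1] and phase = arg(S(Wxy/s))
    in (-pi, pi]; positive phase means x leads y.
    """
    Wx = cwt_morlet(x, dt, scales)
    Wy = cwt_morlet(y, dt, scales)
    inv_s = (1.0 / scales)[:, None]
    Sxx = smooth(np.abs(Wx) ** 2 * inv_s, dt, scales, dj)
    Syy = smooth(np.abs(Wy) ** 2 * inv_s, dt, scales, dj)
    Wxy = Wx * np.conj(Wy) * inv_s
    Sxy = smooth(Wxy.real, dt, scales, dj) + 1j * smooth(Wxy.imag, dt, scales, dj)
    denom = Sxx * Syy
    with np.errstate(divide="ignore", invalid="ignore"):
        R2 = np.abs(Sxy) ** 2 / denom
    R2 = np.clip(np.nan_to_num(R2), 0.0, 1.0)
    phase = np.angle(Sxy)
    return R2, phase


def ar1_coefficient(x: np.ndarray) -> float:
    """Lag-1 autocorrelation (AR(1) coefficient) of a series."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    denom = np.dot(x, x)
    if denom <= 0:
        return 0.0
    r = float(np.dot(x[1:], x[:-1]) / denom)
    return float(np.clip(r, 0.0, 0.999))


def ar1_surrogate(n: int, r: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series of length n with lag-1 autocorrelation r."""
    e = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = e[0] / np.sqrt(max(1.0 - r * r, 1e-12))
    for i in range(1, n):
        x[i] = r * x[i - 1] + e[i]
    return x


_THRESHOLD_CACHE: dict[tuple, np.ndarray] = {}


def coherence_significance_threshold(
    n: int, dt: float, scales_key: tuple, scales: np.ndarray,
    r1: float, r2: float, n_surrogates: int, alpha: float, seed: int,
    dj: float = DJ_DEFAULT,
) -> np.ndarray:
    """Per-scale (1 - alpha) coherence quantile under an AR(1)xAR(1) null.

    Thresholds are cached on (n, dt, scales, rounded AR1 pair, MC
    settings) so repeated trials of a cohort reuse one Monte-Carlo run.
    """
    key = (n, round(dt, 9), scales_key, round(r1, 2), round(r2, 2),
           n_surrogates, alpha, seed)
    if key in _THRESHOLD_CACHE:
        return _THRESHOLD_CACHE[key]
    rng = np.random.default_rng(seed)
    coi = coi_mask(n, dt, scales)
    samples: list[np.ndarray] = []
    for _ in range(n_surrogates):
        a = ar1_surrogate(n, r1, rng)
        b = ar1_surrogate(n, r2, rng)
        R2, _ = coherence(a, b, dt, scales, dj)
        R2 = np.where(coi, R2, np.nan)
        samples.append(R2)
    stacked = np.stack(samples)                       # (n_surr, n_scales, n)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        thr = np.nanquantile(stacked.reshape(n_surrogates, len(scales), -1),
                             1.0 - alpha, axis=(0, 2))
    thr = np.nan_to_num(thr, nan=1.0)
    _THRESHOLD_CACHE[key] = thr
    return thr
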