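"""Leader-follower coordination features from cross-wavelet coherence.

The interaction between an artificial leader and a human follower is
summarized by the relative phase of their movements in time-frequency
space.  From each trial's cross-wavelet coherence field (with pointwise
AR(1) red-noise significance) two distribution features are derived per
subject:

* ``phase_lag_profile`` — |phi_r(f)|: per frequency, the absolute value
  of the circular mean (over significant times) of the relative phase;
  trial profiles are averaged pointwise over trials where defined.  For
  distance computations the profile is normalized to unit mass over
  frequency bins.
* ``relative_phase_series`` + ``relphase_histogram`` — phi_r(t): per
  time, the circular mean (over significant sub-2 Hz frequencies) of the
  relative phase; the concatenated series over trials is binned into a
  51-bin histogram on (-pi, pi].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _wavelet
from .features_solo import Hist1D
from .synthetic_data import Trajectory

__all__ = ["CoherenceField", "PhaseLagProfile", "RelPhaseSeries",
           "wavelet_coherence", "significance_mask", "phase_lag_profile",
           "relative_phase_series", "relphase_histogram"]


@dataclass
class CoherenceField:
    """Cross-wavelet coherence of one leader-follower trial."""

    freqs: np.ndarray          # Hz, one per scale
    times: np.ndarray          # s
    coherence: np.ndarray      # (n_scales, n_times) in [0, 1]
    phase: np.ndarray          # radians (-pi, pi]; positive = leader leads
    coi_mask: np.ndarray       # True inside the cone of influence
    sig_mask: np.ndarray | None = None
    dt: float = 0.0
    scales: np.ndarray | None = None
    ar1: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.coherence.shape != self.phase.shape or \
           self.coherence.shape != self.coi_mask.shape:
            raise ValueError("field matrices must share a shape")


@dataclass
class PhaseLagProfile:
    """|phi_r(f)|: absolute circular-mean phase lag per frequency."""

    freqs: np.ndarray
    abs_lag: np.ndarray        # radians in [0, pi]; nan where never defined
    coverage: np.ndarray       # fraction of trials with significant content

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.abs_lag)


@dataclass
class RelPhaseSeries:
    """phi_r(t): circular-mean sub-2 Hz relative phase per time sample."""

    times: np.ndarray
    phi_r: np.ndarray          # radians; nan where undefined
    defined_mask: np.ndarray


# --------------------------------------------------------------------------- #
# operations
# --------------------------------------------------------------------------- #

def wavelet_coherence(leader: Trajectory, follower: Trajectory) -> CoherenceField:
    """Cross-wavelet coherence field of a time-aligned trial pair.

    Positive phase means the leader leads the follower (the follower's
    oscillation lags), so a purely delayed follower at delay tau shows
    phase ~ 2*pi*f*tau at frequency f.
    """
    if len(leader.x) != len(follower.x) or not np.isclose(leader.rate, follower.rate):
        raise ValueError("leader and follower must share grid and rate")
    dt = 1.0 / leader.rate
    n = len(leader.x)
    scales = _wavelet.scale_grid(n, dt)
    R2, phase = _wavelet.coherence(leader.x, follower.x, dt, scales)
    return CoherenceField(
        freqs=_wavelet.scales_to_freqs(scales),
        times=leader.t.copy(),
        coherence=R2,
        phase=phase,
        coi_mask=_wavelet.coi_mask(n, dt, scales),
        dt=dt,
        scales=scales,
        ar1=(_wavelet.ar1_coefficient(leader.x),
             _wavelet.ar1_coefficient(follower.x)),
    )


def significance_mask(
    field: CoherenceField,
    n_surrogates: int = 300,
    alpha: float = 0.05,
    seed: int = 0,
) -> CoherenceField:
    """Attach the red-noise significance mask to a coherence field.

    The null is a Monte-Carlo ensemble of independent AR(1) surrogate
    pairs with the lag-1 autocorrelations of the two inputs; the
    per-scale (1 - alpha) coherence quantile inside the cone of
    influence is the significance threshold.  Deterministic under seed.
    """
    import warnings

    if n_surrogates < 50:
        warnings.warn("n_surrogates < 50 gives unstable significance thresholds",
                      stacklevel=2)
    n = field.coherence.shape[1]
    thr = _wavelet.coherence_significance_threshold(
        n, field.dt, tuple(np.round(field.scales, 12)), field.scales,
        field.ar1[0], field.ar1[1], n_surrogates, alpha, seed)
    field.sig_mask = (field.coherence > thr[:, None]) & field.coi_mask
    return field


def phase_lag_profile(fields: list[CoherenceField]) -> PhaseLagProfile:
    """Average absolute circular-mean phase lag over trials.

    Per trial and frequency the circular mean over significant times is
    ``arg(sum exp(i*phi))``; its absolute value lies in [0, pi].
    Frequencies with no significant samples are undefined for that trial
    and excluded from the across-trial average.
    """
    if not fields:
        raise ValueError("need >= 1 coherence field")
    n_freq = min(len(f.freqs) for f in fields)
    per_trial = np.full((len(fields), n_freq), np.nan)
    for i, f in enumerate(fields):
        if f.sig_mask is None:
            raise ValueError("significance mask missing; run significance_mask first")
        phasor = np.where(f.sig_mask[:n_freq], np.exp(1j * f.phase[:n_freq]), 0.0)
        counts = f.sig_mask[:n_freq].sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean_angle = np.angle(phasor.sum(axis=1))
        per_trial[i, counts > 0] = np.abs(mean_angle[counts > 0])
    defined = ~np.isnan(per_trial)
    coverage = defined.mean(axis=0)
    sums = np.where(defined, per_trial, 0.0).sum(axis=0)
    counts_tr = defined.sum(axis=0)
    abs_lag = np.full(n_freq, np.nan)
    abs_lag[counts_tr > 0] = sums[counts_tr > 0] / counts_tr[counts_tr > 0]
    if np.all(np.isnan(abs_lag)):
        raise ValueError("no significant coherence at any frequency in any trial")
    return PhaseLagProfile(freqs=fields[0].freqs[:n_freq].copy(),
                           abs_lag=abs_lag, coverage=coverage)


def relative_phase_series(field: CoherenceField, fmax: float = 2.0) -> RelPhaseSeries:
    """phi_r(t): circular mean over significant frequencies below fmax."""
    if field.sig_mask is None:
        raise ValueError("significance mask missing; run significance_mask first")
    band = field.freqs < fmax
    phasor = np.where(field.sig_mask[band], np.exp(1j * field.phase[band]), 0.0)
    counts = field.sig_mask[band].sum(axis=0)
    phi = np.full(field.coherence.shape[1], np.nan)
    defined = counts > 0
    phi[defined] = np.angle(phasor.sum(axis=0)[defined])
    return RelPhaseSeries(times=field.times.copy(), phi_r=phi, defined_mask=defined)


def relphase_histogram(series: list[RelPhaseSeries], nbins: int = 51) -> Hist1D:
    """Histogram of concatenated phi_r(t) samples on (-pi, pi]."""
    samples = np.concatenate([s.phi_r[s.defined_mask] for s in series]) \
        if series else np.empty(0)
    if len(samples) == 0:
        raise ValueError("no defined relative-phase samples to histogram")
    edges = np.linspace(-np.pi, np.pi, nbins + 1)
    counts, _ = np.histogram(samples, bins=edges)
    return Hist1D(edges=edges, mass=counts / counts.sum())
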