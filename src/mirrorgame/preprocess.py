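"""Preprocessing: uniform resampling, zero-phase low-pass filtering and
movement segmentation.

The analysis-ready form of a recording is a uniformly sampled position
series, low-pass filtered at 2 Hz with an order-2 Butterworth filter
applied forward and backward (zero phase; effective 4th-order magnitude),
from which movement segments — stretches between consecutive direction
reversals — are extracted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synthetic_data import Trajectory

__all__ = ["FilterSpec", "SegmentSet", "resample_uniform", "lowpass_filter",
           "extract_segments", "preprocess_trajectory"]


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth low-pass specification."""

    cutoff: float = 2.0
    order: int = 2
    mode: str = "forward_backward"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.mode != "forward_backward":
            raise ValueError("only forward_backward filtering is supported")


@dataclass
class SegmentSet:
    """Movement segments of one (concatenated) recording.

    signed_lengths : position change of each segment (dP0); consecutive
                     entries alternate in sign.
    durations      : matching segment durations in seconds.
    """

    signed_lengths: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        self.signed_lengths = np.asarray(self.signed_lengths, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)

    def __len__(self) -> int:
        return len(self.signed_lengths)


def resample_uniform(traj: Trajectory, target_rate: float) -> Trajectory:
    """Linearly interpolate onto a uniform grid at ``target_rate``.

    The output grid spans [t0, t_end] with step 1/target_rate, so the
    output has floor(duration * rate) + 1 samples; the first sample is
    preserved exactly.
    """
    if len(traj.t) < 2:
        raise ValueError("need >= 2 samples to resample")
    dt_in = np.diff(traj.t)
    if np.any(dt_in <= 0):
        raise ValueError("timestamps must be strictly increasing")
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    t0, t_end = traj.t[0], traj.t[-1]
    n = int(np.floor((t_end - t0) * target_rate)) + 1
    t_new = t0 + np.arange(n) / target_rate
    x_new = np.interp(t_new, traj.t, traj.x)
    return Trajectory(t=t_new, x=x_new, rate=target_rate,
                      subject_id=traj.subject_id, trial_id=traj.trial_id,
                      condition=traj.condition)


def lowpass_filter(traj: Trajectory, spec: FilterSpec = FilterSpec()) -> Trajectory:
    """Apply the zero-phase Butterworth low-pass filter.

    filtfilt with odd-reflection padding (>= 3 filter lengths) keeps the
    output the same length as the input and cancels the phase response.
    """
    nyq = traj.rate / 2.0
    if spec.cutoff >= nyq:
        raise ValueError(f"cutoff {spec.cutoff} Hz >= Nyquist {nyq} Hz")
    b, a = signal.butter(spec.order, spec.cutoff / nyq, btype="low")
    padlen = 3 * max(len(a), len(b))
    x = signal.filtfilt(b, a, traj.x, padlen=min(padlen * 4, len(traj.x) - 1))
    return Trajectory(t=traj.t.copy(), x=x, rate=traj.rate,
                      subject_id=traj.subject_id, trial_id=traj.trial_id,
                      condition=traj.condition)


def extract_segments(traj: Trajectory) -> SegmentSet:
    """Split a recording into movement segments at direction reversals.

    Boundaries sit at strict local extrema of x, detected as sign changes
    of the first difference; runs of zero difference (plateaus) collapse
    to a single boundary at the plateau center.  Leading and trailing
    partial segments are kept.  A monotone recording yields one segment.
    """
    x = traj.x
    if len(x) < 2:
        raise ValueError("need >= 2 samples to segment")
    d = np.diff(x)
    sgn = np.sign(d)
    # propagate last nonzero sign across plateaus to detect true reversals
    nz = sgn != 0
    if not np.any(nz):
        # completely flat signal: single zero-length segment
        return SegmentSet(signed_lengths=[0.0], durations=[traj.duration])
    filled = sgn.copy()
    last = 0.0
    for i in range(len(filled)):            # short loop, n ~ 10^3
        if filled[i] == 0:
            filled[i] = last
        else:
            last = filled[i]
    reversals = np.nonzero(filled[1:] * filled[:-1] < 0)[0] + 1
    boundaries = [0]
    for r in reversals:
        # r is the first difference index with the new direction; the
        # extremum sits at sample r unless a plateau precedes it, in
        # which case use the plateau center
        j = r
        while j > 0 and sgn[j - 1] == 0:
            j -= 1
        boundaries.append((j + r) // 2 if j < r else r)
    boundaries.append(len(x) - 1)
    boundaries = sorted(set(boundaries))
    b = np.asarray(boundaries)
    lengths = x[b[1:]] - x[b[:-1]]
    durations = (b[1:] - b[:-1]) / traj.rate
    return SegmentSet(signed_lengths=lengths, durations=durations)


def preprocess_trajectory(
    traj: Trajectory,
    target_rate: float | None = None,
    spec: FilterSpec = FilterSpec(),
) -> Trajectory:
    """Resample (optionally) then low-pass filter one recording."""
    out = traj
    if target_rate is not None and not np.isclose(target_rate, traj.rate):
        out = resample_uniform(out, target_rate)
    return lowpass_filter(out, spec)
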