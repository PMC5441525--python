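"""Synthetic mirror-game cohorts.

Real mirror-game recordings of schizophrenia patients are not publicly
deposited, so every downstream stage of the pipeline is exercised on
synthetic cohorts that emulate the two experimental protocols:

* **avatar** — 4 solo trials of 60 s plus 12 leader–follower trials of
  30 s per subject, sampled at 40 Hz; each subject's leader trajectories
  are derived from their own solo-style motion (individualized leaders).
* **icub** — 15 leader–follower trials of 60 s at 20 Hz; all subjects
  follow the same set of 5 slow reference trajectories (3 "slow",
  2 "fast", all slower than typical solo motion), each replayed 3 times.

Solo motion is a segment process: alternating left/right movement
segments with durations and signed lengths drawn from uniform ranges and
a minimum-jerk velocity profile inside each segment.  The follower is a
first-order delayed pursuit tracker with additive diffusion noise — a
deliberately simple stand-in for the closed-loop artificial agent used
in the original experiments, chosen because it produces the phenotypes
the features must detect (longer lag, weaker coordination) with
interpretable parameters.

Group phenotypes are encoded purely through parameters: patients get
longer segment durations (psychomotor slowing), longer perceptual-motor
lag, lower pursuit gain and higher motor noise than controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SegmentParams",
    "FollowerParams",
    "ProtocolSpec",
    "CohortConfig",
    "Trajectory",
    "Cohort",
    "generate_solo_trajectory",
    "simulate_follower",
    "generate_cohort",
    "generate_nss_table",
    "AVATAR",
    "ICUB",
    "CONTROL_SEGMENT",
    "PATIENT_SEGMENT",
    "CONTROL_FOLLOWER",
    "PATIENT_FOLLOWER",
]


# --------------------------------------------------------------------------- #
# types
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class SegmentParams:
    """Parameters of the segment-based solo motion generator.

    duration_range : (min, max) segment duration in seconds.
    length_range   : (min, max) unsigned segment length in normalized
                     position units.
    bounds         : admissible position interval, default [0, 1].
    velocity_profile : "minimum_jerk" (default) or "constant".
    """

    duration_range: tuple[float, float] = (0.6, 1.4)
    length_range: tuple[float, float] = (0.2, 0.6)
    bounds: tuple[float, float] = (0.0, 1.0)
    velocity_profile: str = "minimum_jerk"

    def __post_init__(self) -> None:
        dmin, dmax = self.duration_range
        lmin, lmax = self.length_range
        lo, hi = self.bounds
        if not (0 < dmin <= dmax):
            raise ValueError(f"invalid duration_range {self.duration_range}")
        if not (0 < lmin <= lmax):
            raise ValueError(f"invalid length_range {self.length_range}")
        if lmax > hi - lo:
            raise ValueError(
                f"length_range {self.length_range} exceeds bounds width {hi - lo}"
            )
        if self.velocity_profile not in ("minimum_jerk", "constant"):
            raise ValueError(f"unknown velocity_profile {self.velocity_profile!r}")


@dataclass(frozen=True)
class FollowerParams:
    """Delayed-pursuit follower: dx/dt = gain*(leader(t-lag) - x) + noise.

    lag      : perceptual-motor delay tau in seconds.
    gain     : pursuit stiffness g in 1/s (inverse tracking time constant).
    noise_sd : motor-noise diffusion intensity, position units per sqrt(s).
    reaction_jitter_sd : per-trial Gaussian jitter of the lag, seconds.
    """

    lag: float = 0.2
    gain: float = 8.0
    noise_sd: float = 0.02
    reaction_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.lag < 0 or self.noise_sd < 0 or self.reaction_jitter_sd < 0:
            raise ValueError("lag, noise_sd, reaction_jitter_sd must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")


@dataclass(frozen=True)
class ProtocolSpec:
    """Trial layout of one experimental protocol (overridable for scaling)."""

    name: str
    n_solo: int
    solo_duration: float
    n_dyad: int
    dyad_duration: float
    rate: float


AVATAR = ProtocolSpec("avatar", n_solo=4, solo_duration=60.0,
                      n_dyad=12, dyad_duration=30.0, rate=40.0)
ICUB = ProtocolSpec("icub", n_solo=0, solo_duration=0.0,
                    n_dyad=15, dyad_duration=60.0, rate=20.0)

# default group phenotypes (fixture parameters, not clinical claims):
# patients: slower segments, longer lag, weaker pursuit, noisier motor output
CONTROL_SEGMENT = SegmentParams(duration_range=(0.6, 1.4), length_range=(0.2, 0.6))
PATIENT_SEGMENT = SegmentParams(duration_range=(0.9, 2.1), length_range=(0.15, 0.5))
CONTROL_FOLLOWER = FollowerParams(lag=0.2, gain=8.0, noise_sd=0.02)
PATIENT_FOLLOWER = FollowerParams(lag=0.6, gain=4.0, noise_sd=0.05,
                                  reaction_jitter_sd=0.05)


@dataclass(frozen=True)
class CohortConfig:
    """Recipe for a two-group synthetic cohort."""

    n_controls: int = 15
    n_patients: int = 15
    protocol: str = "avatar"
    control_segment: SegmentParams = CONTROL_SEGMENT
    patient_segment: SegmentParams = PATIENT_SEGMENT
    control_follower: FollowerParams = CONTROL_FOLLOWER
    patient_follower: FollowerParams = PATIENT_FOLLOWER
    seed: int = 0
    # optional overrides of the protocol trial layout (None = protocol value)
    n_solo: int | None = None
    solo_duration: float | None = None
    n_dyad: int | None = None
    dyad_duration: float | None = None
    rate: float | None = None

    def __post_init__(self) -> None:
        if self.n_controls < 1 or self.n_patients < 1:
            raise ValueError("group sizes must be >= 1")
        if self.protocol not in ("avatar", "icub"):
            raise ValueError(f"unknown protocol {self.protocol!r}")

    def layout(self) -> ProtocolSpec:
        base = AVATAR if self.protocol == "avatar" else ICUB
        return ProtocolSpec(
            base.name,
            self.n_solo if self.n_solo is not None else base.n_solo,
            self.solo_duration if self.solo_duration is not None else base.solo_duration,
            self.n_dyad if self.n_dyad is not None else base.n_dyad,
            self.dyad_duration if self.dyad_duration is not None else base.dyad_duration,
            self.rate if self.rate is not None else base.rate,
        )


@dataclass
class Trajectory:
    """One uniformly sampled 1-D position recording.

    t : time in seconds, uniform strictly increasing grid.
    x : normalized position in [0, 1].
    rate : sampling rate in Hz.
    condition : "solo", "leader" or "follower".
    """

    t: np.ndarray
    x: np.ndarray
    rate: float
    subject_id: str = ""
    trial_id: str = ""
    condition: str = "solo"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.t.shape != self.x.shape:
            raise ValueError("t and x must have equal length")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    def validate(self) -> None:
        if len(self.t) < 2:
            raise ValueError("trajectory needs >= 2 samples")
        dt = np.diff(self.t)
        if np.max(np.abs(dt - 1.0 / self.rate)) >= 1e-9:
            raise ValueError("time grid is not uniform at the stated rate")
        if self.x.min() < -1e-12 or self.x.max() > 1 + 1e-12:
            raise ValueError("positions outside [0, 1]")


@dataclass
class Cohort:
    """All recordings of a synthetic two-group cohort."""

    recordings: list[Trajectory]
    labels: dict[str, str]               # subject_id -> "control" | "patient"
    covariates: dict[str, dict[str, float]] = field(default_factory=dict)
    config: CohortConfig | None = None

    def subjects(self) -> list[str]:
        return sorted(self.labels)

    def of_subject(self, subject_id: str, condition: str | None = None
                   ) -> list[Trajectory]:
        out = [r for r in self.recordings if r.subject_id == subject_id]
        if condition is not None:
            out = [r for r in out if r.condition == condition]
        return out


# --------------------------------------------------------------------------- #
# generators
# --------------------------------------------------------------------------- #

def _minimum_jerk(s: np.ndarray) -> np.ndarray:
    return 10 * s**3 - 15 * s**4 + 6 * s**5


def generate_solo_trajectory(
    params: SegmentParams,
    duration: float,
    rate: float,
    seed: int | np.random.Generator,
    start: float | None = None,
) -> Trajectory:
    """Generate one solo recording from the segment process.

    Segments alternate direction (first segment moves toward the farther
    bound); each has duration ~ Uniform(duration_range) and unsigned
    length ~ Uniform(length_range).  A segment that would exit the bounds
    is truncated at the nearer bound; the subsequent direction reversal
    (alternation) then reflects the motion back into range.  Within a
    segment, position follows the selected velocity profile (default
    minimum-jerk: x(s) = x0 + L*(10 s^3 - 15 s^4 + 6 s^5), s in [0,1]).
    """
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    if duration < params.duration_range[1]:
        raise ValueError("duration must cover at least one maximal segment")
    if rate <= 2.0 / params.duration_range[0]:
        raise ValueError("rate too low to resolve the shortest segments")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = params.bounds
    x0 = 0.5 * (lo + hi) if start is None else float(start)
    if not (lo <= x0 <= hi):
        raise ValueError("start position outside bounds")

    # draw segments until they cover the requested duration
    t_knots = [0.0]
    x_knots = [x0]
    direction = 1.0 if (hi - x0) >= (x0 - lo) else -1.0
    while t_knots[-1] < duration:
        seg_T = rng.uniform(*params.duration_range)
        seg_L = rng.uniform(*params.length_range) * direction
        target = x_knots[-1] + seg_L
        target = min(max(target, lo), hi)          # truncate at nearer bound
        t_knots.append(t_knots[-1] + seg_T)
        x_knots.append(target)
        direction = -direction

    n = int(np.floor(duration * rate)) + 1
    t = np.arange(n) / rate
    x = np.empty(n)
    t_knots_arr = np.asarray(t_knots)
    seg_idx = np.clip(np.searchsorted(t_knots_arr, t, side="right") - 1,
                      0, len(t_knots_arr) - 2)
    s = (t - t_knots_arr[seg_idx]) / (t_knots_arr[seg_idx + 1] - t_knots_arr[seg_idx])
    x_lo = np.asarray(x_knots)[seg_idx]
    x_hi = np.asarray(x_knots)[seg_idx + 1]
    if params.velocity_profile == "minimum_jerk":
        x = x_lo + (x_hi - x_lo) * _minimum_jerk(s)
    else:
        x = x_lo + (x_hi - x_lo) * s
    return Trajectory(t=t, x=np.clip(x, lo, hi), rate=rate, condition="solo")


def simulate_follower(
    leader: Trajectory,
    params: FollowerParams,
    seed: int | np.random.Generator,
) -> Trajectory:
    """Simulate a delayed pursuit follower of ``leader``.

    Euler–Maruyama at the leader's rate:
    ``x[i+1] = x[i] + dt*g*(x_L(t_i - lag) - x[i]) + noise_sd*sqrt(dt)*N(0,1)``
    with the delayed leader position linearly interpolated and the
    leader's first sample used for t < lag.  Output is clipped to [0,1].
    """
    if len(leader.t) == 0:
        raise ValueError("empty leader trajectory")
    if params.lag >= leader.duration:
        raise ValueError("lag must be shorter than the leader recording")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    lag = params.lag
    if params.reaction_jitter_sd > 0:
        lag = max(0.0, lag + rng.normal(0.0, params.reaction_jitter_sd))
    dt = 1.0 / leader.rate
    t = leader.t
    n = len(t)
    g = params.gain
    # Euler is stable only for h*g < 2; integrate on substeps when the
    # pursuit is stiff relative to the sampling rate, then decimate
    m = max(1, int(np.ceil(dt * g / 0.5)))
    h = dt / m
    t_fine = t[0] + np.arange((n - 1) * m + 1) * h
    delayed = np.interp(t_fine - lag, t, leader.x, left=leader.x[0])
    xf = np.empty(len(t_fine))
    xf[0] = leader.x[0]
    noise = params.noise_sd * np.sqrt(h) * rng.standard_normal(len(t_fine) - 1)
    for i in range(len(t_fine) - 1):
        xf[i + 1] = xf[i] + h * g * (delayed[i] - xf[i]) + noise[i]
    x = xf[::m].copy()
    np.clip(x, 0.0, 1.0, out=x)
    return Trajectory(t=t.copy(), x=x, rate=leader.rate,
                      subject_id=leader.subject_id, condition="follower")


def _icub_reference_params(control_segment: SegmentParams) -> list[SegmentParams]:
    """The 5 shared iCub leader parameter sets: 3 slow (x2 durations) and
    2 fast (x1.3 durations), both slower than typical solo motion."""
    slow = replace(control_segment,
                   duration_range=(control_segment.duration_range[0] * 2.0,
                                   control_segment.duration_range[1] * 2.0))
    fast = replace(control_segment,
                   duration_range=(control_segment.duration_range[0] * 1.3,
                                   control_segment.duration_range[1] * 1.3))
    return [slow, slow, slow, fast, fast]


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort under ``config``.

    Avatar protocol: each subject's dyad leaders are freshly generated
    with that subject's own segment parameters (individualized leaders,
    emulating replay of the subject's pre-recorded motion).  iCub
    protocol: one shared set of 5 slow reference leaders, replayed 3
    times each (cycled if the trial count is overridden).
    """
    rng = np.random.default_rng(config.seed)
    layout = config.layout()
    recordings: list[Trajectory] = []
    labels: dict[str, str] = {}
    covariates: dict[str, dict[str, float]] = {}

    shared_leaders: list[Trajectory] = []
    if config.protocol == "icub":
        ref_params = _icub_reference_params(config.control_segment)
        for k, rp in enumerate(ref_params):
            lead = generate_solo_trajectory(rp, layout.dyad_duration, layout.rate, rng)
            lead.condition = "leader"
            lead.trial_id = f"ref{k}"
            shared_leaders.append(lead)

    groups = [("control", config.n_controls, config.control_segment,
               config.control_follower),
              ("patient", config.n_patients, config.patient_segment,
               config.patient_follower)]
    for label, n_subj, seg_params, fol_params in groups:
        for i in range(n_subj):
            sid = f"{'C' if label == 'control' else 'P'}{i:03d}"
            labels[sid] = label
            # synthetic clinical covariates: patients get higher symptom
            # scores and a medication dose, controls ~0 / none
            if label == "patient":
                covariates[sid] = {
                    "panss_negative": float(np.round(rng.normal(15, 5))),
                    "dose": float(np.round(rng.gamma(4.0, 100.0))),
                }
            else:
                covariates[sid] = {"panss_negative": float(np.round(rng.normal(8, 2))),
                                   "dose": 0.0}

            for j in range(layout.n_solo):
                tr = generate_solo_trajectory(seg_params, layout.solo_duration,
                                              layout.rate, rng)
                tr.subject_id, tr.trial_id = sid, f"solo{j}"
                recordings.append(tr)

            for j in range(layout.n_dyad):
                if config.protocol == "avatar":
                    lead = generate_solo_trajectory(seg_params, layout.dyad_duration,
                                                    layout.rate, rng)
                    lead.condition = "leader"
                else:
                    src = shared_leaders[j % len(shared_leaders)]
                    lead = Trajectory(t=src.t.copy(), x=src.x.copy(), rate=src.rate,
                                      condition="leader")
                lead.subject_id, lead.trial_id = sid, f"dyad{j}"
                fol = simulate_follower(lead, fol_params, rng)
                fol.subject_id, fol.trial_id = sid, f"dyad{j}"
                recordings.append(lead)
                recordings.append(fol)
    return Cohort(recordings=recordings, labels=labels, covariates=covariates,
                  config=config)


def generate_nss_table(
    n_controls: int,
    n_patients: int,
    n_items: int = 10,
    n_informative: int = 3,
    effect: float = 1.0,
    seed: int = 0,
    max_score: int = 3,
):
    """Synthetic neurological-soft-signs questionnaire.

    Items are integer scores 0..max_score.  Informative items are drawn
    with a group-dependent ordinal shift of size ``effect`` (patients
    shifted upward); the remaining items are i.i.d. across groups.

    Returns ``(table, labels, item_names)`` with ``table`` an
    ``(n_controls+n_patients) x n_items`` integer array (controls first)
    and ``labels`` the matching list of group labels.
    """
    if n_controls < 1 or n_patients < 1:
        raise ValueError("group sizes must be >= 1")
    if not (0 <= n_informative <= n_items):
        raise ValueError("n_informative must lie in [0, n_items]")
    rng = np.random.default_rng(seed)
    n = n_controls + n_patients
    base = rng.normal(1.0, 0.8, size=(n, n_items))
    shift = np.zeros((n, n_items))
    shift[n_controls:, :n_informative] = effect
    scores = np.clip(np.round(base + shift), 0, max_score).astype(int)
    labels = ["control"] * n_controls + ["patient"] * n_patients
    item_names = [f"item{k:02d}" for k in range(n_items)]
    return scores, labels, item_names
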