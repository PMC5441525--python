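# Methods

`mirrorgame` implements a dissimilarity-based classification of subjects
from 1-D hand-movement recordings collected in a simplified mirror game:
a solo condition (free improvised motion) and a leader–follower
condition (the subject tracks an artificial agent).  This note records
the models, the numerical choices, and the limits of what the synthetic
experiments can show.

## Preprocessing

Recordings are normalized positions in [0, 1].  They are linearly
interpolated onto an exact uniform grid at the protocol rate (40 Hz for
the avatar protocol; 200 Hz down-sampled to 20 Hz for the iCub
protocol) and low-pass filtered at 2 Hz with an order-2 Butterworth
filter applied forward and backward (`scipy.signal.filtfilt`,
odd-reflection padding).  The two-pass design cancels the phase response
exactly and squares the magnitude response, so the effective attenuation
at frequency f is `1/(1 + (f/2 Hz)^4)`.

Movement segments are the stretches between consecutive direction
reversals, detected as sign changes of the first difference of the
filtered position.  Runs of zero difference (plateaus) collapse to a
single boundary at the plateau center — a deterministic, symmetric tie
break.  Leading and trailing partial segments are kept and enter the
segment-length statistics like any other; this choice is arbitrary but
fixed, and at 30–60 s per trial the two edge segments are a negligible
fraction of the pooled sample.

## Distribution features

Every subject is summarized per feature channel by a unit-mass
distribution; all comparisons below happen between distributions, never
between scalar summaries.

* **Segment-length histogram (dP0).**  Signed segment lengths pooled
  over a subject's solo trials, binned into 51 equal bins on the fixed
  support [−1, 1].  The fixed support makes all subjects' histograms
  share bin edges by construction.
* **Global wavelet spectrum (GWS).**  Morlet (ω₀ = 6) continuous wavelet
  transform on the dyadic scale grid s_j = s₀·2^(j·dj) with s₀ = 2·dt and
  dj = 1/12 (the standard toolbox defaults); the GWS is the time mean of
  |W(s, t)|² per scale, averaged over trials.  Power (not amplitude)
  averaging is used.  For distance computations the spectrum is
  normalized to unit mass over scales.
* **Motion-model coefficients.**  In sliding 2 s windows (50% overlap,
  per trial, pooled over trials) the acceleration is regressed on the
  centered position and the velocity: a(t) = −k·(x − x̄_w) − c·v(t) + b.
  Velocity and acceleration come from central differences; the intercept
  b absorbs the offset between the window mean and the true oscillation
  center, without which (k, c) are biased on windows covering partial
  cycles.  The (k, c) pairs — local stiffness (1/s²) and damping (1/s) —
  are binned on a 100×100 grid whose support is the cohort-pooled 1%–99%
  quantile range padded by 5%; out-of-range pairs are clipped to edge
  bins.  A shared cohort grid keeps subjects comparable; the clipping
  keeps unit mass.  Windows with near-zero positional variance are
  skipped and counted.
* **Phase-lag profile |φr(f)|.**  Per leader–follower trial, the
  cross-wavelet coherence field is computed (below); at each frequency
  the circular mean over significant times of the relative phase is
  taken, and its absolute value (in [0, π]) is averaged over the trials
  where it is defined.  For distance computations the profile is
  normalized to unit mass over frequency bins, with the scale index as
  the ground coordinate (scales are log-spaced, so index distance is
  log-frequency distance).
* **Relative-phase histogram φr(t).**  Per time sample, the circular
  mean of the relative phase over significant scales with frequency
  below 2 Hz; undefined samples (no significant sub-2 Hz cell) are
  dropped, not interpolated — interpolating would invent phase where the
  coherence estimate is indistinguishable from noise.  Defined samples
  are concatenated over trials and binned into 51 equal bins on (−π, π].

## Cross-wavelet coherence and significance

Coherence uses the standard smoothed estimator
`|S(W_xy/s)|² / (S(|W_x|²/s)·S(|W_y|²/s))` with Morlet transforms,
Gaussian time smoothing with scale-matched width `exp(−t²/(2s²))`, and a
boxcar across 0.6/dj scale steps.  The phase convention is
`arg(S(W_L·conj(W_F)))`: positive phase means the leader leads, so a
follower delayed by τ shows phase ≈ 2πfτ.  The cone of influence is the
Morlet e-folding time √2·s.

Pointwise significance is Monte-Carlo: pairs of AR(1) surrogates with
the lag-1 autocorrelations of the two inputs, 300 surrogates by default
(the per-scale 95th percentile of surrogate coherence inside the cone is
the threshold).  Thresholds depend only on the series length, rate and
the AR(1) pair, so they are cached with the AR(1) coefficients rounded
to 0.01; within a cohort, where all filtered movement series have nearly
identical lag-1 autocorrelation, one Monte-Carlo run serves all trials.
Calibration on independent white-noise pairs reproduces the nominal
false-positive rate (≈ 5% of the cone significant at α = 0.05).

## Classification

1. **EMD.**  Earth mover's distances between all subject pairs per
   channel.  1-D histograms and profiles use the exact closed form
   (L1 distance between CDFs weighted by bin spacing); 2-D coefficient
   histograms use the exact transportation LP over the occupied bins
   only (HiGHS via `scipy.optimize.linprog`), with bin centers
   standardized per axis by the cohort coefficient standard deviations
   before applying the Euclidean ground metric.  Both routes are checked
   in the test suite against an independently constructed dense LP.
2. **MDS.**  Classical (Torgerson) scaling: eigen-decomposition of the
   double-centered squared distance matrix; coordinates are eigenvectors
   scaled by √eigenvalue, in descending order; non-positive-eigenvalue
   dimensions are dropped and counted.  Classical MDS is deterministic
   (no random initialization), which keeps whole-pipeline runs
   bit-reproducible; axis signs are canonicalized by making the
   largest-magnitude loading positive.
3. **Discriminants with leave-one-out CV.**  Linear (pooled-covariance)
   and pseudo-quadratic (per-class covariance with Moore–Penrose
   pseudo-inverse and pseudo-log-determinant, tolerating singular class
   scatters) Gaussian discriminants; priors are the training-fold class
   frequencies.  All leave-one-out folds are evaluated in one batched
   computation using rank-one downdates of the class sums and scatter
   matrices, which is what makes the exhaustive subset search tractable.
4. **Subset search.**  All coordinate subsets of size 1–6 from the first
   15 MDS dimensions (9,948 subsets per discriminant), in
   size-then-lexicographic order.  Selection: highest accuracy, ties
   broken by precision, residual ties fused by majority vote over the
   tied classifiers; between discriminants, higher accuracy then higher
   precision, with the linear discriminant preferred on a full tie.
5. **Majority rule.**  A subject is labeled patient only when strictly
   more than half of the channel-level classifiers vote patient (ties go
   to control).  The avatar analysis fuses the three solo channels, the
   two dyad channels, and all five.
6. **Questionnaire variant.**  Ordinal item scores are used directly as
   coordinates.  With more than 15 items, a two-sided rank-sum test per
   item keeps the 15 lowest p-values among those with p < 0.3 (the
   intersection reading: lowest-15 among qualifying); with 10 items all
   847 subsets of size ≤ 6 are enumerated.  Constant columns are
   excluded.

### Selection optimism (important caveat)

The MDS embedding is computed once on all subjects and leave-one-out
applies to the discriminant only; more importantly, the reported
accuracy is that of the subset/discriminant combination *selected to
maximize* leave-one-out accuracy.  This max-statistic is optimistically
biased: on label-free (null) synthetic cohorts the selected fused
accuracy concentrates around 0.7–0.8, not 0.5 (with ~200–20,000 subsets
searched, depending on configuration).  The same optimism is visible in
the coordinate-selection diagnostic (`diagnostics.accuracy_vs_subset_size`),
where the best-k curve sits above the first-k curve.  The pipeline
reproduces the procedure as defined and documents the bias rather than
redesigning the validation (nested re-selection per fold is out of
scope); absolute accuracies from this pipeline should be read as
training-selected figures, and group differences should be judged
against a matched null (e.g. identical-phenotype cohorts or label
permutations), which is exactly how the package's own calibration
experiments are framed.

## Synthetic cohorts

No public recordings exist, so the generator emulates the two protocols:

* **avatar** — 4 solo trials × 60 s + 12 leader–follower trials × 30 s
  at 40 Hz; each subject's leaders are fresh draws from that subject's
  own segment parameters (individualized leaders).
* **icub** — 15 leader–follower trials × 60 s at 20 Hz; one shared set
  of 5 reference leaders (3 with segment durations ×2, 2 with ×1.3
  relative to control solo defaults — all slower than typical solo
  motion), replayed 3 times each.

Solo motion is a segment process: durations ~ Uniform(0.6, 1.4) s and
unsigned lengths ~ Uniform(0.2, 0.6) for controls, alternating
direction, minimum-jerk profile within each segment
(x(s) = x₀ + L(10s³ − 15s⁴ + 6s⁵)); a segment that would exit [0, 1] is
truncated at the bound and the alternation reflects the motion back.
These ranges put the dominant movement tempo near 0.4–0.8 Hz, which is
comfortably inside the 2 Hz analysis band.  The follower is a
first-order delayed pursuit process,
dx_f/dt = g·(x_L(t − τ) − x_f) + σ·dW, integrated by Euler–Maruyama on
substeps h = dt/⌈dt·g/0.5⌉ (plain Euler at the sample rate is unstable
for dt·g > 2) and decimated to the leader grid.  Default phenotypes,
fixture parameters rather than clinical claims: controls τ = 0.2 s,
g = 8 /s, σ = 0.02; patients τ = 0.6 s, g = 4 /s, σ = 0.05 with 0.05 s
reaction jitter, plus slower segments (durations ×1.5).  These mirror
the qualitative phenotype the features must detect — psychomotor slowing
and weaker interpersonal coordination.

What the generator does **not** emulate: bi-directional feedback between
agent and human (the artificial agent's adaptive architecture is
deliberately replaced by one-directional pursuit), 2-D/3-D kinematics,
tracker noise and dropouts, session effects, and the heterogeneity of a
clinical population (every synthetic patient shares one parameter set
plus noise).  Passing calibration experiments therefore show that the
pipeline detects the encoded lag/coordination/tempo differences and
reports chance-consistent behavior under a matched null — not that the
published clinical accuracies are reproducible, which would require the
original recordings.

The questionnaire generator draws integer item scores 0–3 from a
discretized Gaussian with a group shift on the informative items.

## Problem sizes used by the test and acceptance runs

The published protocols are the generator defaults.  The repeated
end-to-end calibration experiments run at reduced sizes chosen to keep
a full run on one CPU short while leaving the group effect detectable:
iCub-style dyad-only cohorts of 8 + 8 subjects, 6 trials × 30 s at
20 Hz, subset search over up to 3 of the first 8 MDS dimensions, 80
surrogates for significance, 20 cohorts per condition.  The acceptance
script repeats the same experiment with 3 cohorts per condition.

## Known limitations

* The per-window damped-linear-oscillator fit is a concrete stand-in for
  the full generative motion model of the original experiments; the module
  boundary (`fit_motion_model` → coefficient pairs → shared-support 2-D
  histogram) is the swap-in point for any richer model.
* |φr(f)| is compared by EMD after unit-mass normalization over
  frequency bins — the profile is treated as a distribution over
  frequencies.  A config-level alternative (comparing raw lag values)
  was considered and not implemented; normalization is the only reading
  under which a mass-transport distance applies directly.
* The phase-lag profile tracks the delay law 2πfτ only at frequencies
  where the signals genuinely carry power; with narrow-band motion,
  neighboring scales inherit the dominant component's phase through
  spectral leakage and smoothing.
* Scale-axis smoothing biases the coherence phase toward the
  power-weighted neighborhood mean (~0.1 rad for red spectra at the
  band edges).
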