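# Methods

This note documents the models, estimators and numerical choices behind
`wavegait`, in the order data flows through the package.

## Conventions

Frames are 0-based; intervals are half-open `[start, end)` in frames;
durations are seconds. Raw coordinates are pixels; `mm_per_px` converts
to mm, and every derived quantity is reported in mm, s, mm/s or degrees.
Leg ids are `T1L…T3R` (T1 = prothorax, anterior; T3 = metathorax,
posterior). Body-bending angle follows the larva-tracker convention:
180° = straight, >180° bends left, <180° right.

## Synthetic gait generator (`simulate.GaitParams`, `simulate_gait`)

The generator is the ground-truth source for every estimator and encodes
the metachronal wave-gait model:

* Leg *k*'s swing onsets sit at `n·T + (φ_k/360)·T + jitter` with
  segment phases φ(T3) = 0, φ(T2) = lag, φ(T1) = 2·lag (default lag
  120°); left and right legs of a segment share the phase, so bilateral
  pairs are synchronous up to the intrasegmental jitter (Gaussian, sd in
  degrees of the cycle).
* Swing velocity is a half-sine pulse over the swing duration `s_w`:
  smooth, zero at both endpoints, peak speed `π·stride/(2·s_w)`
  analytic. The leg tip is stationary in the lab frame during stance and
  advances by one stride per swing; `stride = stride_gain · speed`.
* A scheduled swing is dropped with probability `skip_prob` (the
  slow-walking regime combines a longer period at constant `s_w` with
  dropout and jitter).
* Each swing onset triggers a pygopod plant event with probability
  `pygopod_prob`, jittered by a Gaussian of sd `pygopod_jitter_sd`
  seconds.
* Tracking noise is white on velocity: the added 2-D velocity
  perturbation vector has sd `noise_sd` mm/s (i.e. `noise_sd/√2` per
  component), integrated to per-frame displacement perturbations.
* A trailing T3 onset (both sides, never dropped) closes the final
  cycle, so a bout of `n_cycles` contains `n_cycles` complete
  extractable walk cycles.

Defaults describe fast straight walking at 60 frames/s: T = 0.2 s,
s_w = 0.07 s, lag 120°, no jitter/dropout/noise. The slow regime used in
degradation experiments is T = 0.7 s with the same s_w.
`pygopod_prob = 0.089` is calibrated so that slow (0.7 s period)
climbing-style bouts — six legs stepping at ~8.6 onsets/s — emit plant
events at ~0.76 Hz, the planting rate typical of overhang climbing.

What the generator does *not* emulate: body translation and leg
placement geometry (legs advance along a fixed axis), substrate slip,
tracking outliers/gaps, smoothly varying speed within a bout, and any
coupling between the six legs beyond the fixed phase schedule. Passing
recovery tests therefore demonstrates correctness of the estimators
under the stated statistical structure, not robustness to every artefact
of real video tracking.

## Leg speed (`kinematics.leg_speed`)

Speed is the magnitude of forward-difference velocity, scaled by
`fps · mm_per_px`. A Savitzky–Golay filter (window
`max(5, odd(0.05 s · fps))`, order 2 by default — wide enough to pass
~5 Hz stepping while suppressing frame-to-frame tracking jitter) is
applied to the *vector components before rectification*. Filtering the
rectified magnitude instead would turn zero-mean tracking noise into a
positive speed floor during stance that no threshold can remove; applied
to the components, the same filter cancels the noise and leaves the
swing pulses intact. The result is non-negative by construction.

## Swing/stance segmentation (`kinematics.segment_swings`)

Two-threshold hysteresis on the smoothed speed: entry threshold
θ_hi = 0.3 × the leg's 95th-percentile speed (a robust per-leg peak),
exit threshold θ_lo = θ_hi/2; a swing is a maximal run of samples
≥ θ_lo containing at least one sample ≥ θ_hi; runs shorter than two
frames are discarded. An all-zero trace yields an empty series (a
stationary leg is not an error). On noise-free pulse trains the
procedure reduces to single-threshold crossing, which the tests exploit
as a brute-force oracle. At velocity noise of 10% of the peak swing
speed, frame-wise swing/stance agreement with generator ground truth is
≳96% (boundary frames account for the residual).

## Periods, duties, strides, phases

* Per-leg cycle frequency = (n_onsets − 1)/(last − first onset); the
  per-animal period is the reciprocal of the mean per-leg frequency.
* Swing duty = mean swing duration per segment / period; stance duty is
  defined as the complement so the two always sum to 1.
* Stride length is the net leg-tip displacement over a swing, in mm.
  Note this is leg-tip advance per swing, not body advance per cycle;
  the two differ on slipping substrates.
* Intrasegmental phase: each left onset is paired with the nearest right
  onset (ties to the earlier); Δt is mapped to 360°·Δt/T, wrapped to
  [−180°, 180°); the segment value is the circular mean of the
  magnitudes. Under swing dropout the estimated period inflates (fewer
  onsets over the same span), so surviving matches no longer wrap to
  zero — the estimator degrades exactly as left–right coordination
  degrades, which is the phenotype it is meant to quantify.
* Intersegmental phase: from each anchor (default T3L) onset to the next
  ipsilateral onset of the target segment, circularly averaged in
  [0°, 360°). Negative phase means temporally earlier.

## Spectral analysis (`coherence`)

The anchor leg's fundamental frequency is the highest-power bin of the
periodogram of its (mean-removed) speed trace, DC excluded. Near-ties
are resolved on raw power with a relative plateau tolerance (default
5%): bins within tolerance of the maximum form plateaus; the middle bin
of the peak plateau is returned; with exactly two plateaus the
higher-frequency one is used; with more, the plateau containing the
global maximum.

Coherence uses DPSS multitapers (default NW = 4, K = 7) on R
non-overlapping segments (default one per second of data), demeaned per
segment. Cross- and auto-spectra are summed over all R·K taper-segment
products; magnitude `|S_xy|/√(S_xx·S_yy)` is in [0, 1] by
Cauchy–Schwarz and invariant to amplitude scaling. The reported phase is
`arg Σ conj(X)·Y` in degrees, so a signal that is a pure delay of the
anchor has negative phase (−90° for a quarter-period delay) and
`phase(x,y) = −phase(y,x)`. With dof = 2RK, the significance threshold

    sqrt(1 − α^(1/(dof/2 − 1)))

is the exact null quantile of the magnitude for independent Gaussian
signals estimated from dof/2 independent products (|γ|² ~ Beta(1,
dof/2 − 1)); Monte-Carlo calibration in the tests confirms a false
positive rate of α ± 0.02 at dof ∈ {8, 40, 100}. A boxcar/K = 1 mode
reduces the estimator to plain segment-averaged periodogram coherence
and is cross-checked against an independent implementation in the tests.

## Walk-cycle extraction (`cycles`)

A candidate cycle starts at any T3 onset; it is accepted iff the
contralateral T3 onset, then both T2 onsets, then both T1 onsets occur —
in segment-blockwise order, with the left/right order free within a
segment — before the following T3 onset, which closes the span. Scanning
is greedy left-to-right, so accepted cycles never overlap. Candidates at
the end of a record with no closing T3 onset are dropped.

Pause filtering discards stance durations above the animal's
median + 1 sample s.d. The upper bound is used because a lower bound
would re-admit long stances and defeat the purpose of removing pauses.
The filter is applied per animal. On the canonical pause fixture
(uniform stances plus ~10× outliers) the filter removes exactly the
outliers and is idempotent; on continuously varying stance distributions
a second application can remove further values (the median and s.d.
shrink), which is an inherent property of the rule, not of this
implementation.

## Pygopod events (`events`)

Event-to-swing offsets are signed (positive = event after onset) and
taken against the globally closest swing onset over all six legs; the
segment of that swing classifies the event. Histograms use the
Freedman–Diaconis width `2·IQR·n^(−1/3)` with bin edges anchored at 0;
with a degenerate IQR of 0 the width falls back to Sturges-count binning
(range/(⌈log₂ n⌉ + 1)), or unit width when the range is also zero.
Planting rate is events per tracked second. The event-triggered average
extracts velocity on a ±window around each event (boundary events
dropped), averages across events and divides by the trace's own mean
('mean' mode; a z-score mode is available), so a constant velocity gives
a flat trace at 1.

## Path behaviour (`path`)

Centroid speed uses forward differences; the last frame inherits the
final step for per-frame classification. States: still when speed ≤
0.05 mm/s (a tracking-noise floor, since a literal 0 mm/s never occurs
in floating point); otherwise straight when |angle − 180°| ≤ 30° and
bent beyond that. The 30° default makes "bent" coincide with the
headsweep thresholds (≥210° left, ≤150° right), which flag frames
independently of the three-state label. The headsweep bias test fits an
intercept-only binomial GLM to left/right counts (equivalent to a test
of proportion = 0.5), with an exact binomial p-value when the counts are
completely one-sided and the Wald test degenerates.

Curviness is total path length over net displacement (≥ 1, straight
path = 1, semicircle = π/2), invariant to rotation, translation and
uniform scaling; it is undefined (raised as such) for zero net
displacement. Body-angle histograms bin every 10° over [0°, 360°).

The backtrack-and-redirect detector pairs *consecutive* headsweep
episodes of opposite sides (pairing non-adjacent sweeps admits false
positives from intervening turns) and requires, between them, net
displacement projected on the pre-episode heading (the displacement
direction over the preceding 0.5 s) below −0.3 mm while the body is
near-straight on at least half the frames, all within 8 s of the first
sweep. Left/right labels flip under mirror reflection of the path, and a
straight constant-velocity path yields no detections.

## Path generator (`simulate.PathParams`, `simulate_path`)

A frame-wise state machine: cruising (heading random walk, body angle
wobbling around 180°) interrupted by Poisson-initiated headsweeps
(smooth angular excursions past the 210°/150° thresholds at half cruise
speed, rotating the heading 30–60°), pauses (speed 0, 0.5–2 s), and
backtrack-and-redirect episodes (turn at 0.4× speed, backwards run at
0.6× with straight body, contralateral turn, forward resumption; total
duration uniform on 3–6 s). `mean_speed` (default 1.8 mm/s) is the
*bout-average* instantaneous velocity — the quantity a tracker measures —
so the cruise speed is solved analytically from the expected episode
time budget to keep the emitted time average on target. Ground truth
carries per-frame state labels, headsweep flags and the episode list.

## Problem sizes and runtime

Default analyses use bouts of 20 cycles (fast, ~4 s) or 10–12 cycles
(slow, ~8 s) at 60 frames/s, paths of 120 s at 30 frames/s, 20 seeds per
recovery experiment and 1000 replicates per calibration — sizes at which
every Monte-Carlo margin in the test suite is several standard errors
wide while the whole suite runs in well under a minute. All randomness
flows through explicit integer seeds (`numpy.random.default_rng`).

## Known limitations

* Stride length is leg-tip displacement per swing; body-advance stride
  would require centroid data aligned with the leg clock.
* The fundamental-frequency plateau rules operate on raw power; spectra
  judged on log power could resolve ties differently.
* The intrasegmental-phase estimator's sensitivity to dropout operates
  through period inflation (see above); with an externally supplied true
  period it would be blind to pure dropout.
* Multitaper defaults (NW = 4, K = 7, 1 s segments, no overlap) are
  exposed in `RunConfig` but not auto-tuned; very short traces need
  fewer observations or tapers.
* The pause filter is not idempotent on continuous stance distributions
  (property of the median + s.d. rule itself).
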