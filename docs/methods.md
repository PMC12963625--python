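# Methods

This note records the models, parameter choices and numerical decisions
behind `respirad`, and what the synthetic validation does and does not
demonstrate about real recordings.

## Radar signal model

A continuous-wave radar at carrier frequency f_c = 24 GHz (wavelength
λ = c/f_c ≈ 12.49 mm) illuminates the chest.  For a two-way path the
baseband phase is

    φ(t) = 4π · (d₀ + x(t)) / λ,

with d₀ the static standoff and x(t) the chest displacement.  An ideal
quadrature receiver outputs I = cos φ, Q = sin φ.  Real hardware adds DC
offsets (o_I, o_Q), a gain ratio g between channels and a quadrature phase
error ψ:

    I = cos φ + o_I,     Q = g·sin(φ + ψ) + o_Q.

This maps the unit circle to an ellipse.  The forward model, its inversion
and the displacement law Δx = Δφ/2π · λ/2 are exact inverses: with ideal
channels the package recovers displacement to < 1e-9 mm (tested).

### Ellipse reconstruction

The ellipse is fitted with the numerically stable direct least-squares
conic fit (Halir–Flusser variant of Fitzgibbon's method): the data are
centred and scaled, the scatter matrix is split into quadratic and linear
blocks, and the ellipse constraint 4ac − b² = 1 is imposed through a 3×3
eigenproblem, guaranteeing an ellipse (never a hyperbola) and a
deterministic result.  One ellipse is fitted per recording, since hardware
imbalances are static over minutes.  Degenerate inputs raise explicitly
rather than returning a silently bad fit: fewer than 6 samples, a
collinear cloud (axis ratio > 1e4), or an arc narrower than `min_arc_deg`
(default 90°) around the fitted centre.

The correction maps points by translate(−centre) → rotate(−θ) → scale axes
to 1.  Because that affine map has positive determinant and carries the
ellipse onto the unit circle, the composition with the hardware distortion
is a pure rotation (for g > 0, |ψ| < 90°): the corrected phase equals the
true propagation phase up to an additive constant — exactly what
displacement estimation needs, since only phase *changes* matter.  The
corrected phase is also invariant under any common positive gain on both
channels (tested).

Sign convention: increasing phase = inspiration.  A config flag
(`displacement_sign`) flips it; the sign is irrelevant downstream once
extremum roles are assigned consistently.

### Unwrapping

Standard jump-threshold unwrapping (±2π correction when a successive
difference exceeds π).  At 2000 Hz a physiological chest cannot move λ/4
between samples, so the threshold is never legitimately crossed by
breathing.  Unwrapping is idempotent (tested).

## Respiratory band

Both channels are filtered with a Butterworth bandpass, design order 4,
passband 0.07–0.4 Hz (4–24 breaths/min), realised in second-order sections
— at 3.5·10⁻⁵ of the radar Nyquist frequency a polynomial transfer
function is numerically unusable.  The filter is applied forward–backward
(zero phase): every downstream metric is an extremum *timing*, and a causal
application would delay extrema by the group delay (seconds at these
frequencies) and bias TI/TE directly.  Reflection padding is used at the
record edges, and one period of the low band edge (1/0.07 ≈ 14.3 s) at
each end is flagged as filter transient and excluded from cycle detection.
Each filtered trace is z-scored over the whole recording (not per window),
making mm-scale radar and Ω-scale impedance directly comparable.

### Band-limiting and the TI/TE split point

A periodic waveform whose peak sits off-centre within the cycle needs
second-harmonic content in exact proportion to that asymmetry.  At resting
rates (RR 11–15 brpm, fundamental 0.19–0.25 Hz) the second harmonic
(0.38–0.5 Hz) lies at or beyond the 0.4 Hz band edge and is attenuated to
roughly 45–65 % amplitude by the forward–backward pass.  The filtered
waveform is therefore partially symmetrized: peaks shift late, valleys
shift early, by ~0.1–0.2 s at physiological asymmetry (TI 2.4 s /
TE 2.9 s).  Consequences, verified by the test suite and the acceptance
script:

* **RR is unbiased** — valley-to-valley durations are preserved, so
  window RR recovers ground truth to ≤ 0.3 brpm at 20 dB SNR.
* **Absolute TI/TE carry a common-mode bias** of ~0.1–0.2 s relative to the
  true displacement extrema (TI high, TE low, I:E high).  This is a
  property of the band, not of either sensor: both modalities share the
  filter, so radar-vs-reference TI/TE agreement is tight (≤ 0.05 s per
  window at 20 dB SNR, ~3 ms noiseless).
* Any validation against an identically filtered reference is blind to
  this bias; claims about *absolute* phase durations would require a wider
  band or harmonic-preserving segmentation.

## Cycle segmentation

Peaks and valleys are detected independently (`scipy.signal.find_peaks` on
the signal and its negation) under three constraints with package-chosen
defaults, all exposed in `DetectionConfig`:

* prominence ≥ 0.3 × SD of candidate extremum amplitudes, computed in a
  first pass constrained only by distance/width (two-pass scheme; the SD is
  per recording);
* spacing ≥ 1.5 s between same-kind extrema — consistent with the 0.4 Hz
  band edge, whose shortest credible cycle is 2.5 s;
* width ≥ 0.5 s at half prominence, rejecting ripple-scale wiggles.

Alternation is then enforced: within a run of consecutive peaks the first
survives, within a run of consecutive valleys the last survives, and the
sequence is trimmed to start and end on a valley.  Keeping first-PK /
last-VL preserves the physiological TE > TI asymmetry.  The rule is
idempotent and is verified against an exhaustive enumerator over all
peak/valley strings up to length 6.  Cycles with total duration strictly
greater than 10 s (< 6 brpm) are excluded as outliers; a boundary cycle of
exactly 10 s is kept.

## Windowed metrics

Windows of 120 s step by 30 s from t = 0 while they fit inside the
recording.  A cycle belongs to a window iff both bounding valleys fall in
the half-open interval [start, start+120) — half-open so a valley on the
boundary is counted once.  Within a window the cycles carrying min TI,
max TI, min TE and max TE are removed (a union of 2–4 distinct cycles) to
suppress occasional extreme values while retaining sensitivity that a
median would lose.  Ties resolve to the earliest cycle, except that when a
metric is constant within the window the "max" pick falls back to the last
cycle so that two distinct cycles are always removed.  A window is valid
only with ≥ 6 complete cycles before trimming and ≥ 2 after; invalid
windows stay in the table with a reason code so radar and reference tables
share an identical grid, and the comparison uses only windows valid in
both.

Window means are computed per cycle first: RR = mean(60/(TI+TE)) and
I:E = mean(TI/TE), which differ from 60/mean(TI+TE) and
mean(TI)/mean(TE) — the order matters and is tested.

## Statistics

Paired window means pooled across subjects are compared four ways:

* **Descriptives**: min/max/mean/SE/SD per source (sample SD, ddof 1).
* **Repeated-measures correlation**: ANCOVA with subject intercepts and a
  common slope, computed in closed form as the Pearson correlation of
  within-subject-centred values, sign from the common slope, df = N−k−1,
  p from the t distribution.  It matches a normal-equations ANCOVA oracle
  to < 1e-10 and `pingouin.rm_corr` to the same precision (both tested).
  Subjects with constant values contribute nothing; all-constant input is
  an error.
* **Modified Bland–Altman**: differences d = radar − reference plotted
  against the reference; bias µ, σ = SD(d), LoA = µ ± 1.96σ; 95 % CIs
  µ ± t·σ/√n for the bias and LoA ± t·σ·√(3/n) for the limits; fractions
  of intervals within the clinical bounds and within the LoA.
* **TOST**: one-sided t tests against symmetric margins
  (RR ±2 brpm, TI ±0.3 s, TE ±0.3 s, I:E ±0.2; α = 0.05), df = n−1 over
  pooled intervals.  Equivalence ⇔ both p < α ⇔ the 90 % CI of µ inside
  the bounds (asserted as a property on randomized inputs).  Degenerate
  σ = 0 resolves by direct comparison of µ with the bounds (p = 0 or 1).
  Cohen's d_z = µ/σ with a 90 % CI from inverting the noncentral-t CDF
  (Brent root-finding; a normal approximation of the noncentral-t CDF
  substitutes where scipy's implementation loses accuracy at large
  noncentrality).  Empirical type-I error at a bound is ≈ 0.05 over 2000
  simulated replicates (tested).

Pooling overlapping windows across subjects with df = n−1 ignores
within-subject correlation and is anti-conservative; it is retained
deliberately as the comparison design this package reproduces, with
mixed-effects alternatives out of scope.

## Synthetic recordings

The generator is the package's test bed and defines its study conditions.

* **Cycle timing**: per-cycle TI and TE are independent gamma draws with
  means 2.4 s and 2.9 s (cohort-typical resting values, RR ≈ 11 brpm,
  I:E ≈ 0.83) and a common CV of 0.10 — resting breath-to-breath timing
  variability is conventionally ~10 %.  Gamma gives positive support and
  direct CV parameterization.  Configurations whose mean cycle exceeds 10 s
  are rejected (they would be excluded wholesale by the outlier rule).
* **Waveform**: asymmetric raised-cosine half-waves — a piecewise-linear
  phase ramp hitting 0/π/2π at valley/peak/valley, passed through
  (1−cos)/2 — so the true extremum lands exactly on the ground-truth grid
  and TI/TE are unambiguous.  Peak-to-peak amplitude 4 mm (conventional
  resting chest excursion).  An exponential-decay expiration is available
  as an option but not default.
* **Disturbances**: optional cardiac ripple (default 0.3 mm at 1.1 Hz,
  removed almost entirely by the respiratory band — verified against the
  filter's analytic response) and sparse double-exponential motion pulses
  at a Poisson rate (default 0: resting baseline).
* **Radar channel**: the forward model above with defaults g = 0.9,
  ψ = 5°, offsets (0.2, −0.15) and white noise of SNR 20 dB relative to
  the unit carrier (`noise_std = 10^(−SNR/20)`).
* **Reference channel**: impedance Z = 25 Ω + 0.05 Ω/mm · x(t) plus
  independent noise (0.005 Ω), decimated by simple striding from the radar
  grid to 100 Hz — the excursion is band-limited far below the reference
  Nyquist frequency, so striding preserves timing without an anti-alias
  filter.
* **Reproducibility**: one `numpy` Generator seeded per recording; a fixed
  seed reproduces the recording bit-for-bit (tested).

What the generator does *not* emulate: irregular or pathological patterns
(apnoea, Cheyne–Stokes), posture changes, RF multipath or interference,
electrode artifacts in the impedance channel, and drift in the hardware
imbalances.  Passing the synthetic suite therefore demonstrates the
pipeline's correctness and noise robustness under quasi-regular resting
breathing, not performance on disturbed clinical recordings.

## Numerical and interface choices

* Displacement comparisons at the demodulation stage are made on the
  respiratory band (the signal the pipeline consumes); the unwrapping
  constant drops out with the band's DC rejection.  The round-trip error
  budget at 30 dB SNR is < 0.02 mm.
* `sliding_window_metrics` uses a 1 ns tolerance when deciding whether a
  window fits the recording, so a 120 s recording yields exactly one
  window despite float accumulation; the cycle tiler uses the same
  tolerance at the recording end.
* Problem sizes in the test suite and acceptance script — 5–10 min single
  recordings and an 8-subject cohort — are the package's chosen desk-scale
  validation conditions; all statistics scale unchanged to larger cohorts.
* Per-subject containers are HDF5 (`/radar/i`, `/radar/q`, `/reference/z`,
  optional `/truth/*`, config embedded as JSON attrs) with a CSV cycle
  table alongside; a best-effort `.mat` reader supports deposit-style
  layouts and names the missing variable explicitly when the layout is
  unknown.  Only resting-scenario recordings are processed.  The reference
  channel is consumed at its native 100 Hz — no resampling anywhere, to
  avoid interpolation-induced timing distortion.
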