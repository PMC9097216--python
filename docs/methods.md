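# Methods

`swaylab` implements a complete postural-complexity analysis of trunk-worn
IMU acceleration during quiet bilateral standing, together with a synthetic
sway-cohort generator so that every stage — preprocessing, the four sway
measures, and the reliability/inference layer — can be exercised and
validated without access to raw participant data.

## Measurement model and preprocessing

A trunk-mounted IMU samples tri-axial acceleration at 500 Hz for 60 s per
trial. Preprocessing proceeds in the following fixed order:

1. **Downsampling to 100 Hz.** Integer-factor decimation preceded by a
   zero-phase 8th-order Chebyshev-I low-pass (0.05 dB ripple, cutoff at
   0.8× the target Nyquist). The anti-aliasing stage matters: naive sample
   picking would fold broadband sensor noise into the 0.3–10 Hz sway band.
2. **Cropping to the middle 50 s**, i.e. exactly 5,000 samples. The crop is
   applied after downsampling; the 5,000-point contract holds either way,
   but this order keeps the filter transients of step 1 outside the
   analysed block.
3. **Static tilt correction.** The per-trial mean acceleration is taken as
   the gravity direction (quiet-stance assumption) and two sequential
   rotations are applied: about the ML axis to null the mean AP component,
   then about the AP axis to null the mean ML component. The vertical
   channel is discarded. The rotation order (AP-first) is a convention; for
   the small static tilts involved (≲10°) the alternative order differs
   only at second order in the tilt angles.
4. **Band-pass filtering**, 4th-order Butterworth, 0.3–10 Hz, applied
   forward–backward (zero lag; effective 8th-order magnitude). The low cut
   removes respiration and drift, the high cut low-amplitude measurement
   noise. A finite 50 s window of a zero-DC process still carries a sample
   mean of order SD/√(number of cycles at the low cutoff) — about 1 % of SD
   here — so the filtered signals are explicitly demeaned to honour the
   zero-mean contract of the clean signal. This is inconsequential for all
   four measures.
5. **Artifact screen.** The resultant horizontal acceleration
   √(ML² + AP²) is split into five consecutive 10 s windows; the trial
   fails when the largest window SD *strictly exceeds* five times the
   smallest (the boundary value passes). The screen runs on the filtered
   resultant: the order of description in the source protocol places the
   abnormality inspection after filtering, and an in-band criterion is
   invariant to out-of-band sensor noise. A failing trial excludes its
   whole subject, and the subject's matched control is dropped with it so
   the between-group design stays balanced; both exclusions are recorded
   in the run manifest with reasons.

## Sway measures

All measures operate on one 5,000-sample, 100 Hz clean signal (ML or AP).

**RMS** — √(mean x²), reported ×1000 as mm·s⁻² (internal units are m·s⁻²).

**Sample entropy (SEn)** — −ln(A/B), where B counts unordered pairs of
M-sample templates within Chebyshev distance r = r_frac·SD (inclusive,
self-pairs excluded) and A counts the pairs whose (M+1)-sample extensions
also match. Defaults: M = 3, r_frac = 0.07 (ML) and 0.06 (AP). Counting
uses k-d trees under the infinity norm and is exactly equal to the O(N²)
scan (asserted in tests). A = 0 yields a +inf sentinel treated as missing
downstream, with a logged warning, rather than an arbitrary cap. The
parameter-selection helper reproduces the efficiency criterion used to fix
(M, r): for each candidate, the conditional probability CP = A/B has the
binomial error surrogate σ = √(CP(1−CP)/B), the relative-error metric is
max(σ/CP, σ/(CP·|ln CP|)), and the candidate minimising the median metric
across records wins (ties: smaller M, then larger r). The binomial
surrogate treats template matches as independent, which they are not; it
is a documented approximation adequate for ranking candidates. SEn is
computed with the natural logarithm even though the reporting convention
labels the unit "bit"; the label is metadata only.

**Largest Lyapunov exponent (LyE)** — Rosenstein's method on a delay
embedding (defaults m = 4; τ = 17 samples ML, 20 AP). Each delay vector is
paired with its nearest Euclidean neighbour outside a Theiler window of
(m−1)·τ samples (excluding exact duplicates); the divergence curve is the
mean of log₂ pair distance i steps ahead, pairs dropped once either
trajectory runs off the series. LyE is the least-squares slope of the
curve over steps 0–75 inclusive (0–0.75 s), multiplied by the sampling
frequency — hence bits·s⁻¹, with base-2 logs making the unit literal.
Supporting parameter-selection tools are included: the delay from the
first minimum of the average mutual information (equiprobable-bin
histogram estimator, ⌈N^{1/3}⌉ bins, tie-aware average ranks) and the
dimension from false-nearest-neighbour analysis (Kennel criteria,
R_tol = 15, A_tol = 2, "near zero" = 1 %). The AMI first-minimum scan runs
on a 5-point moving average of the curve: histogram AMI carries sampling
jitter that otherwise triggers spurious early minima on plateau-shaped
curves. On a noise-free strictly periodic signal the AMI curve has
deterministic resonance micro-structure, so the quarter-period property of
the sinusoid is only realised (and tested) with a small noise floor added.

**DFA scaling exponent (α)** — first-order detrended fluctuation analysis:
integrate the mean-centred series, split into non-overlapping boxes from
the start (trailing remainder discarded), remove a per-box linear trend,
F(n) = RMS residual, α = OLS slope of log F(n) vs log n over 10 log-spaced
box sizes. The analysis band 2–10 Hz maps to period-equivalent box sizes
n = fs/f, i.e. 10–50 samples at 100 Hz, targeting the proprioceptive
timescales of sway. White noise gives α ≈ 0.5, 1/f noise ≈ 1.0, integrated
white noise ≈ 1.5 (all verified to those values in the tests and the
acceptance script).

## Statistics

Measure values are transformed by ln(x+1) before inference; descriptives
are reported anti-logged. The design is 2 (group: YO vs YN, between) ×
2 (condition: firm vs foam, within) × 2 (visit, within) with one
observation per cell. The mixed ANOVA uses the balanced univariate
decomposition: the between effect is tested against the
subjects-within-groups mean square and each within effect against its own
interaction with subjects-within-groups; with 19 subjects per group every
effect has df = (1, 36). All factors have two levels, so sphericity
corrections are moot. Cohen's f = √(η²ₚ/(1−η²ₚ)) from the partial η² of
each effect. Tests verify every F against an independent
projection-matrix oracle and against R's `aov` error-strata output.
Unbalanced or incomplete designs raise errors naming the offending cells
rather than switching silently to an approximate method; a subject with
any missing cell is dropped together with its matched control.

Post-hoc pairwise comparisons (group within condition: independent t;
condition within group: paired t) form one family per measure × axis and
are controlled by the Benjamini–Hochberg step-up at α = 0.05. When every
visit-involving ANOVA term has p > α, cell values are pooled across visit
before post-hoc testing.

Test–retest reliability uses the one-way random, single-measure
intraclass correlation ICC(1,1) = (MSB − MSW)/(MSB + MSW) for k = 2
visits, banded as poor (≤ 0.40), fair (≤ 0.60), good (≤ 0.75), excellent
(≤ 1.00). Any measure × axis with a poor cell in the group × condition
grid is excluded from inference (descriptives are still reported) — the
boundary 0.40 counts as poor.

Group-characteristic comparisons from summary statistics use the
pooled-variance two-sample t (identical to the unpooled t at equal n);
BCa bootstrap CIs for mean differences (bias correction from the fraction
of bootstrap statistics below the observed value, acceleration from
jackknife skewness) default to B = 10,000 seeded resamples. Pediatric
weight status follows the CDC percentile bands with half-open intervals:
underweight < 5 ≤ normal < 85 ≤ overweight < 95 ≤ obese.

## Synthetic cohort generator

Horizontal sway per axis is modelled as
√(1−w)·(band-limited colored noise, power ∝ f^−β, support 0.5–8 Hz) +
√w·(oscillation at 1 Hz), scaled to a target RMS `amp`, plus broadband
white sensor noise of SD `noise_floor`; the AP axis is `ap_gain` larger.
The three body-frame axes (ML, AP, vertical = g) are rotated by a static
sensor tilt, giving raw 500 Hz tri-axial records that exercise the whole
preprocessing chain (the noise floor is chosen large enough that the
band-pass visibly matters). The spectral support sits inside the analysis
band so the pipeline preserves the target RMS within a few percent.

Measured knob→measure responses (each Spearman-monotone across seeds):
`amp` → RMS; `beta` → higher α-DFA, lower SEn, *higher* LyE (stronger
persistence pulls nearest neighbours closer, so the divergence curve
starts lower and climbs more steeply over the fixed fit window);
`periodic_weight` → lower SEn, higher α; `noise_floor` → higher SEn and a
*flatter* divergence slope (in-band noise lifts the curve's start). Note
that raising in-band noise therefore lowers the Rosenstein LyE estimate —
the generator achieves the empirical "more regular yet less locally
stable" signature through β and the oscillation weight, not through noise.

Cohorts impose multiplicative effects on knobs, never on measures, so
recovering imposed structure through the pipeline is a genuine inverse
problem. Defaults: 19 subjects per group; the YO-like arm gets
periodic_weight ×1.5, β ×1.12 and ap_gain ×1.2 (reproducing the
directional pattern lower SEn / higher LyE / higher α / higher AP RMS);
the foam condition gets amp ×1.5, periodic_weight ×1.25 and β ×1.06.
Between-subject heterogeneity is log-normal with SD 0.15 on the log scale
per knob; each visit applies a shared log-normal retest jitter with SD
0.06, which lands the ICC grid in the fair-to-excellent range. The
imposed group effects are deliberately on the strong side so that the
directional contract holds in nearly all replicates at n = 19; the
generator is a validation instrument, not a calibrated digital twin.

What the generator does *not* emulate: inverted-pendulum biomechanics,
foot–foam mechanical coupling, non-stationary strategy switches within a
trial, or sensor drift. Passing tests therefore show that the estimators
and inference recover structure of this stochastic class — not that the
pipeline is validated against human sway.

## Numerical choices and degenerate inputs

- All randomness flows from a single seed through named
  `numpy.random.SeedSequence` sub-streams; identical (inputs, config,
  seed) give byte-identical reports.
- Distance metrics: Chebyshev for SEn (the standard for the algorithm),
  Euclidean for FNN and Rosenstein.
- Strict ">" in the fivefold artifact rule; ties pass.
- DFA requires ≥ 4 usable scales and N ≥ 4·n_max; box sizes are clipped to
  [4, N/4].
- Constant signals are rejected by SEn/AMI (SD = 0); zero-distance
  neighbour pairs are skipped in divergence averaging.
- Simulation study sizes: the type-I calibration uses 200 null cohorts of
  8 subjects per group with the RMS measure (the rate is size-independent),
  the power check 50 cohorts at the full 19 per group, and the
  sign-pattern check 5 full cohorts on the ML axis of visit-1 trials.

## Known limitations

- The tilt correction assumes a static sensor; slow orientation drift
  within a trial is not tracked.
- The SEn relative-error selection metric uses the binomial variance
  surrogate described above.
- The mixed ANOVA requires equal group sizes (guaranteed here by
  matched-pair exclusion); general unbalanced mixed designs are out of
  scope.
- LyE on stochastic signals is an operational index (slope of a bounded
  divergence curve over a fixed window), not an estimate of a dynamical
  invariant; comparisons are only meaningful at fixed estimator settings.
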