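# Methods

This note records the models, conventions and numerical choices behind
usvkit, and what the synthetic benchmark does and does not demonstrate.

## The synthetic USV generator

The generator emulates 5-minute male–female encounter sessions for four
experimental groups (control female/male, testosterone-propionate-treated
female/male). It is the oracle for the whole pipeline: every call carries
its exact onset, offset, contour and generating parameters.

**Group presets.** Each group has calibrated means for the per-call
parameters — duration (ms), minimum/maximum/mean frequency (Hz) and delta
frequency (end minus start, Hz) — together with the number of animals
(7/15/14/7) and the median per-animal call count (332/522/614/1,249).
Per-call draws are truncated normals with sd = cv × mean, cv = 0.10 by
default. The frequency dynamic is max − min by construction. Truncation
enforces feasibility only far in the tails (the dynamic must contain the
delta; the band must stay within 32–105 kHz; the mean target must be
realizable by the contour family), so group means are preserved to well
under the 1% calibration tolerance.

**Contour family.** A call's frequency trace must hit five mutually
constrained values at once: first = f_start, last = f_end, min, max, and
time-average = mean target. A fixed symmetric chirp cannot do this (the
mean is generally off the band midpoint), so the base contour is piecewise
linear through two interior knots pinned to the band extremes; the knot
times are the free parameters. The time-average is linear in the knot
times, so the solver intersects the target level set with the feasible
triangle {ε ≤ t₁ ≤ t₂ ≤ 1−ε} analytically (ε = 0.02). Sinusoidal
modulation cycles are superimposed with an envelope that vanishes toward
the band edges (zero-mean over whole cycles, so the time-average is barely
disturbed); jump discontinuities shift an 8%-of-duration window toward the
band side with more headroom, clipped to the band. After assembly a short
damped fixed-point loop re-solves the knot times to absorb the residual
mean error (jump directions are frozen after the first pass to keep the
loop contractive). The samples realizing the extremes and endpoints are
re-asserted exactly. Achieved accuracy on random draws: min/max/start/end
exact, mean within 0.3% worst-case (0.5% is the contract).

**Archetypes.** Nine qualitative call shapes (jump call; high-frequency
short; short flat; long small-slope; high-frequency slope; high-TV; upward
modulated; low-band short slope; long modulated) are realized as shape
signatures (modulation cycles and depth, jump windows) plus scale effects:
multiplicative factors on duration and frequency dynamic, an additive band
offset, and a multiplier on delta. All scale effects are re-normalized per
group against the archetype mixture so the mixture-weighted means reproduce
the group means exactly; dynamic multipliers are floored per archetype so
every archetype's dynamic can contain its own delta, then rescaled by
bisection. The archetype numeric centres are generator configuration, not
measured values; they are chosen so the nine classes are separable in the
12-feature space (the typing benchmark's "default separation"). In
archetype-scale mode the within-archetype band-centre spread is 0.4 × the
group-level spread — the remainder of the group variance is carried by the
between-archetype offsets. The *calibration mode* (`archetype_scale=False`)
disables all scale effects and draws every parameter from its plain
truncated normal; this is the mode used for the round-trip calibration and
the acceptance script.

**Sequencing.** The archetype mixture of each group is the stationary
distribution of that group's 9×9 call-type transition matrix, so i.i.d.
sampling and Markov-chain session simulation share marginals. Matrices are
a uniform background plus boosted cells encoding the qualitative group
patterns: females favour 5→2, males show a strong 2→9 flow, type-2 and
type-7 occupancy is highest in TP females, type-8 occupancy highest in
controls. Inter-call intervals are a mixture: 80% uniform(0.05, 0.5) s
within bouts, 20% uniform(2.5, 10) s between bouts, exercising both sides
of the 2-s gap rule. Per-animal call counts are the group median times a
lognormal factor (log-sd 0.15, median-preserving; group sample medians then
stay within ~20% of the configured medians with high probability).

**Audio rendering.** Calls are rendered as sin of the numerically
integrated instantaneous frequency with raised-cosine 1-ms ramps, in white
Gaussian noise. `snr_db` is defined per analysis bin: the ratio of a
unit-amplitude tone's peak-bin power (Hann, 512 samples) to the expected
per-bin noise power. Cohort-scale audio is opt-in (a full-size cohort is
tens of minutes of 250 kHz audio per session); the default cohort writes
truth tables only, and the audio path is exercised by a scaled benchmark
(4 groups × 3 animals × 200 calls).

## Detection

The detector is a deliberately simple, deterministic substitute for
cloud/ML detectors: median-floor spectral thresholding is fully auditable
and adequate for the synthetic benchmark. Design points:

- The voicing statistic is max over in-band bins of power/floor. Applied
  frame-wise to raw STFT power this statistic hugs a high baseline (the max
  of ~160 exponential variates), so the per-bin ratio is averaged over 5
  frames before thresholding; run boundaries are then refined with the
  unsmoothed ratio restricted to a few bins around the run's edge peak, so
  onsets are not blurred by the averaging. Onset is the left edge of the
  first voiced frame (half-open frame intervals throughout).
- Contours: in-band argmax refined by 3-point parabolic interpolation on
  log power (≈ sub-100-Hz accuracy for steady tones at 488-Hz bins), after
  a light 3-frame temporal smoothing of power. The first/last few frames of
  a call carry little energy (the window only grazes the call), so their
  peak search is constrained to ±4 bins around the interior ridge.
- Known limitation: the number of detected calls is monotone in the SNR
  threshold only in the operating regime. Far below it, spurious voiced
  noise frames bridge neighbouring calls via the merge rule and the count
  is no longer monotone. Benchmarks measure contour error inside the true
  call interval and excluding ±3 frames around jump discontinuities, where
  the instantaneous-frequency step is not resolvable within one window.

Measured on the scaled audio benchmark at 20 dB SNR: recall and precision
1.00, mean onset error ≈ 0.45 ms, aggregate non-jump contour RMSE < 500 Hz
(the tests assert the contractual ≥ 0.99 / < 500 Hz / < 1 ms).

## Feature conventions

Four features have no universal formula; the conventions used here (all
configurable) are: linearity index = TV / dynamic (path-length-to-range
ratio, ≥ 1, defined as 1 for a constant contour to avoid 0/0); mean
frequency TV = TV/(n−1) (per-step mean, hop-dependent); nb jumps =
inter-frame steps above 10 kHz; nb modulation = local extrema of the
5-frame moving-average contour with prominence ≥ 1 kHz. Peak frequency
uses the single highest-amplitude frame, earliest frame on ties. These
magnitudes are consistent with conventional group-level reports (linearity
~5–8, mean TV ~350–550 Hz at sub-ms hops) but are declared conventions,
not reverse-engineered formulas.

## Variable clustering

The split/rotate/reassign loop is the normative algorithm for this
package: standardize; repeatedly split the cluster with the largest second
eigenvalue ≥ 1 (quartimax rotation of the first two PCs, assignment by
larger squared loading, ties to the first component); after each split,
sweep every variable to the cluster whose first principal component it
correlates with best (≤ 20 sweeps; a move that would empty a cluster is
skipped). Scoring weights are the unit-norm first-PC loadings of the
member correlation submatrix, sign-fixed so the largest-|loading| variable
is positive; scores of the fitting data are exactly centred. Whether
cluster scores are compared at call or animal level is configurable; both
are supported because group-level reports are ambiguous about the unit.

## Call typing

k-means (k-means++, 25 restarts, fixed seed) in z-space; the standard
workflow fits k = 10 and removes one noise cluster. The removal rule —
the cluster ranking first on both shortest mean duration and smallest mean
frequency dynamic, falling back to lowest mean silhouette, with a manual
override — is this package's declaration; no published criterion exists.
Type indices are renumbered by descending centroid peak frequency, so they
are internally stable but need not match any published figure's numbering.
The fit is global (shared types across groups), since group comparison of
occurrences requires a common type space.

## Transitions

"Frequency of occurrence of a transition" is interpreted as the joint
frequency (cell / total transitions); row-conditional probabilities are
also emitted, but the joint matrix is what is averaged across animals
(unweighted, so prolific callers do not dominate) and thresholded at 5%
(strict). Inter-call interval is onset(next) − offset(current); the 2-s
gap is strict ("more than"). Gaps are bout boundaries only, never a
transition state. No hypothesis test is attached to transition matrices —
only descriptive matrices and graphs are produced.

## Statistics

Kruskal-Wallis uses midranks with the standard tie correction. Steel-Dwass
ranks each pair separately, uses the tie-corrected rank-sum variance, and
refers √2·|z| to the studentized range with k groups and infinite df (the
asymptotic reference; exact small-sample tables are out of scope). At
k = 2 this reduces to the two-sided normal rank-sum test, which the tests
verify to 1e-6. Tukey-Kramer uses the unequal-n standard error and
studentized range df = N − k, reducing to the pooled t test at balanced
k = 2. Roy's largest root is θ = λ_max(E⁻¹H) with the upper-bound
approximation F = θ·df₂/df₁, df₁ = r = max(p, k−1), df₂ = N − k − r +
(k−1) — conventions for this F differ across software, so the formula is
pinned here; at p = 1, k = 2 it reduces to the one-way ANOVA F. Nearly
dependent responses (occurrence probabilities sum to 1) are dropped
lowest-variance-first until E is invertible. Compact letter displays use
insert-and-absorb; sharing a letter is equivalent to "not significantly
different". No multiple-testing correction is applied across the 12
features, matching the conventional reporting of this battery.

Calibration (asserted in the tests): familywise type-I error of both
post-hoc procedures ≤ 0.06 at nominal 0.05 under the null (k = 4, n = 15,
5,000 replicates), and agreement with independent implementations
(scipy's Kruskal-Wallis and Tukey HSD, statsmodels' MANOVA) to 1e-8 or
better on random data.

## Problem sizes and determinism

The test suite uses: 1,000 calls per group for calibration round-trips;
4 groups × 3 animals × 200 calls for the rendered-audio detection
benchmark; 200 calls per archetype (plus 200 noise blobs) for typing
recovery; 50,000 transitions for chain recovery; 5,000 replicates for
statistical calibration; 20 seeds for planted-block variable clustering.
Every artifact is a pure function of (config, master seed): sessions are
seeded via spawned `SeedSequence` children, k-means via its fixed seed,
and reports are byte-reproducible (asserted in the tests).

## What passing does and does not show

The generator produces clean frequency-modulated tones in stationary white
noise, one emitter per session, no harmonics, no reverberation, no
overlapping calls, and no attribution ambiguity between paired animals.
Passing the benchmark therefore validates the algorithmic chain —
constraint-solved synthesis, detection, feature definitions, clustering,
typing, transitions, statistics — not performance on real recordings,
where noise is coloured and non-stationary, calls overlap, harmonics and
echoes deform contours, and two animals vocalize. The detector in
particular replaces a trained ML detector and should be expected to need
retuning (band, threshold, merge gap) on real data.
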