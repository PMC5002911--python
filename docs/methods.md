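# Methods

## The measurement model

A BOLD acquisition of the calf during a cuff paradigm yields a 4-D series
`SI(x, t)` in arbitrary scanner units, one volume per repetition time
(TR = 3 s by default; 300 frames over 15 min). Frame `i` covers
`[i·TR, (i+1)·TR)` and is timestamped at its window center `(i+0.5)·TR`, so
event times estimated from frames are unbiased. The protocol timeline has
three phases on this axis — baseline `[0, 300)` s, cuff occlusion
`[300, 600)` s, reactive hyperemia `[600, 900)` s — with a frame belonging
to the phase containing its center.

Muscle VOIs come as integer label volumes (manual segmentation guided by
coregistered anatomy is assumed upstream); the VOI signal is the
**unweighted mean** over the label's voxels, per frame. No registration,
motion or bias-field correction is attempted, and masks are never
resampled: a float-typed mask is rejected outright, because non-integral
values are evidence of interpolation that would corrupt VOI membership.

Percent-change normalization uses the mean baseline signal after dropping
the first `baseline_discard = 5` baseline frames. The discard skips T1
saturation transients at the start of a gradient-echo series; it is
configurable because its ideal value depends on the sequence. No drift
correction is applied by default (an optional baseline-fitted linear
detrend exists, off by default), because the standard analysis this
package implements applies none.

## The four indices

With `pct(t)` the normalized VOI course and `w = max(1, round(window_s/TR))`
the smoothing window (default `window_s = 3` s, i.e. a single frame at
TR = 3 s):

- **PHV** = max of the trailing `w`-frame means over the post-deflation
  segment; **TTP** = center timestamp of the *first* maximal window minus
  the deflation time. Resolving ties to the earliest window makes TTP
  deterministic.
- **MIV** = min of the same window means over the occlusion segment. The
  smoothing is applied for symmetry and noise robustness even though the
  window is conventionally defined only for the peak; `window_s = 0`
  recovers the single-frame minimum.
- **TTR**: scanning the *unsmoothed* `pct` forward from the peak frame, the
  first frame at or below 0 % (the baseline level by construction) marks
  recovery; the crossing is linearly interpolated between the bracketing
  frame centers. The threshold is exactly 0 by default; a tolerance band
  (e.g. `+0.5 · baseline SD`) is available but off, since any nonzero band
  is an arbitrary choice that changes TTR's meaning. A series that never
  returns to baseline is flagged `recovered=False` and carries no TTR —
  cohort statistics average TTR over recovered cases only and report the
  counts, rather than imputing the acquisition end.

All estimators are local to their protocol phase: PHV/TTP ignore baseline
and occlusion values, MIV ignores the post-deflation segment. Property
tests assert this locality, the exhaustive-scan equivalence of the rolling
extremum detection, and noise-free recovery to within one TR across the
admissible truth range.

## The generative model

The synthetic curve is piecewise and continuous:

- 0 during baseline;
- `MIV·(1 − exp(−(t − t_occ)/τ))` during occlusion, with
  `τ = (t_defl − t_occ)/5` by default so the ischemic plateau reaches
  > 99 % of MIV by deflation (the observed decline is saturating);
- a half-cosine rise from the value at deflation to PHV over TTP;
- a half-cosine decay from PHV to 0 over `[TTP, TTR]`, 0 afterward.

Half-cosines were chosen over a gamma-variate because they place the peak
at TTP and the zero crossing at TTR *exactly*, making every truth parameter
recoverable by definition — the right property for a validation phantom.
The cost is realism at the recovery tail: the half-cosine meets zero with
zero slope, which is also why noisy estimates of TTR cross early (below).
Frame noise is white Gaussian in percent units; real BOLD noise is
temporally autocorrelated and partly physiological, so noisy-phantom
results bound estimator error under ideal noise only.

The 4-D phantom paints four non-overlapping elliptic cylinders
(semi-axes 16 × 12 mm) on a calf-like disc at the target geometry
(2.8125 mm in-plane, six 5-mm contiguous slices — slice gaps are ignored),
modulates the muscle baseline intensity (480 units; non-muscle tissue 320)
by each muscle's curve coherently across its voxels, and adds independent
per-voxel Gaussian background noise (default 0: the phantom's default role
is noise-free end-to-end validation).

## Cohort simulation

Per-subject truth parameters are drawn from group-level truncated normal
distributions (bounds: PHV ∈ [0.5, 60] %, MIV ∈ [−40, −0.5] %,
TTP ∈ [6, 120] s, TTR ∈ [15, 294] s, with TTR forced above TTP + 6 s).
Default moments describe three groups of 12/11/10 subjects in which only
PHV separates trained athletes from sedentary controls (e.g. gastrocnemius
PHV 15.8 ± 9.1, 17.9 ± 5.1 and 7.4 ± 3.5 % for the two athlete groups and
controls); the ischemic depth and both timing parameters share one
distribution per muscle across groups. Controls are simulated at two
visits: the visit value is subject truth plus within-subject noise with SD
`0.3 ×` the population SD — a typical test-retest fraction for an imaging
biomarker, chosen once since no within-subject variance decomposition is
available to fit. Jump distances are coupled to the gastrocnemius PHV
truth within group at ρ = 0.56 (vertical) and 0.47 (broad). Note that the
*pooled* PHV–jump correlation exceeds the within-group ρ whenever group
means differ, so pooled correlations mix training-status contrast with
individual coupling; the null-ρ test therefore uses a single group.

By default each simulated subject's indices are *estimated* — the noisy
curve (σ = 1 % per frame) is pushed through the same extraction and index
code as real data — so cohort-level results inherit realistic estimation
error. An index-level mode (`simulate_curves=False`) records the truth
parameters directly for large Monte-Carlo designs.

## Statistical layer

Sample SDs use the n−1 denominator throughout; CV = 100·SD/|mean| so the
negative-valued MIV yields a positive CV. The paired visit comparison is a
two-sided paired t-test (Wilcoxon signed-rank available when normality is
doubtful); zero-variance differences make the test undefined and are
reported as NaN rather than 1. Group and muscle effects use one-way ANOVA
with D'Agostino–Pearson omnibus normality per cell (not assessable below
n = 8, reported NaN) and Tukey HSD post hocs gated on omnibus p < α
(Bonferroni-corrected t-tests as the configurable alternative — Tukey is
the standard companion of a one-way ANOVA and is the default). Outlier
exclusion is only ever an explicit user-supplied subject list with reasons,
never automatic. The muscle-factor ANOVA treats muscles as independent
cells, ignoring their within-subject pairing, to match the analysis
convention this pipeline reproduces; a repeated-measures model would be
more powerful.

## Numerical choices and scale of the validation runs

- Peak/min ties resolve to the earliest window; TTR interpolation is exact
  for a frame landing on zero.
- ANOVA on exactly tied group means can return a tiny negative F and NaN p
  from floating-point cancellation; F is clamped at 0 and p recomputed.
- Monte-Carlo problem sizes: 100 replicates for estimator-error summaries,
  1000 random series for oracle equivalence, 2000 cohort replicates for
  type-I calibration, 100 for detection power, 2000 for correlation
  recovery — sizes at which binomial/sampling error is small relative to
  the effects being checked while the whole validation stays inexpensive.

## Known limitations

- At σ = 1 % frame noise the single-frame extremum estimators are biased by
  order statistics: PHV high by ≈ +1 % and TTP late by several seconds
  (the decay side of the peak is much flatter than the rise), MIV low by
  ≈ −2 % (a min over ~100 near-plateau frames), and TTR early by ≈ −12 s
  (noise crosses the tangentially-approaching decay before its true zero).
  These are properties of the extremum/threshold definitions themselves,
  not of the implementation — the same estimators are exact to within one
  frame at σ = 0. Comparisons *between* groups measured at equal noise are
  unaffected, since the bias is common; absolute index values at high noise
  should be interpreted with this in mind.
- White noise, coherent per-muscle curves, and contiguous-slice geometry
  are simplifications; passing tests demonstrate correctness of the
  computation, not robustness to physiologic noise, motion or segmentation
  error.
- Masks are trusted as coregistered; there is no registration QC beyond
  grid equality.
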