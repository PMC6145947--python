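# Methods

This note documents the models, calibrations and design choices behind
`adaptdecorr`, and what the synthetic-data tests do and do not establish
about real data.

## Shape space

Shapes are radial-frequency patterns: the radius of a unit sphere is
modulated as

r(d) = 1 + Σᵢ Aᵢ · sin(fᵢ · ψᵢ(d) + φᵢ),   i = 1..6,

where ψᵢ(d) is the azimuth of direction d about an axis obtained by rotating
the z-axis by the component's orientation oᵢ within the xz-plane.  One
orientation angle per component matches the single orientation parameter of
the 24-vector (6 components × frequency, amplitude, phase, orientation).
Validity requires Σ Aᵢ < 1 (radius strictly positive) and fᵢ ≥ 2 (closed
surface).  Integer frequencies are required only of the prototypes: shapes
derived by morphing or by random displacement in the 24-space (probes) may
carry fractional frequencies, because a probe pair is constructed by adding
±offset along a direction drawn uniformly on the unit sphere of the full
24-space, which generically perturbs every coordinate.  The two default
prototypes share the integer frequency ladder 3–8 cycles/revolution (so
morphs stay integer-frequency and probes stay ≥ 2 under the default offset)
and differ in amplitudes, phases and orientations; their phases lie in a
common half-turn, making linear (non-circular) phase interpolation along the
morph continuum unambiguous.

**Metric.**  Distances are Euclidean on the 24-vector after dividing each
parameter family by a fixed scale — frequency 1, amplitude 0.05, phase π/4,
orientation π/4 — so that no family dominates.  The scales are a declared
convention (roughly, one "just-noticeable-ish" excursion per family); all
derived quantities (adaptor radius, probe offset, tuning widths) live in
this scaled metric.

**Derived stimulus sets.**  Morph continuum: 80 equal intervals, 81 levels,
both prototypes included; one level step is the "morph unit" used
throughout the behavioral arm.  Adaptors: 50 per class, obtained by
perturbing only the 12 amplitude/orientation coordinates with a zero-mean
Gaussian draw rescaled to an exact radius, default 0.25 × d(A, B); the
constructor refuses radii ≥ d(A, B)/2 so the two class clouds cannot
overlap.  Probes: ±0.15 × d(A, B) about each prototype.

## Behavioral arm

**Observer.**  The psychometric function is a renormalised cumulative
Gaussian

p(x) = 0.5 + (0.5 − λ) · (Φ((x − μ)/s) − Φ(−μ/s)) / (1 − Φ(−μ/s)),

with chance floor 0.5 at morph level 0, lapse-limited ceiling 1 − λ, free
slope s (morph units), and location μ solved (bisection, cached) from the
calibration p(threshold) = 0.5^(1/3), so the `base_threshold` parameter *is*
the level the 1-up/3-down staircase targets.  A single-parameter folded
Gaussian cannot decouple threshold from steepness — calibrating a threshold
of 15 forces a width of ~18 morph units, an absurdly shallow observer whose
errors far above threshold exhaust the 8-reversal staircase during its
initial descent and bias estimates by 7 morph units.  The renormalised
two-parameter family avoids this.  Defaults: slope 2.5, lapse 0.01,
thresholds ~14 (class A) and ~19 (class B) with SD 3 across subjects, and
adaptation gains 4.6 / 6.4 morph units (SD 1.5) subtracted from the
effective threshold when the trial's class matches the adapted class.
With these defaults the 8-reversal estimator has bias +0.67 morph units
(1000 staircases), below the 1-unit target.

**Staircase.**  1-up/3-down, step 1 morph unit, start level 30, clamped to
[1, 40] (the 40 morph steps nearest the prototype).  A reversal is logged at
the turning level when an up-move follows a down-move or vice versa; flat
repeats (clamped moves) are not direction changes.  Staircases stop after 8
reversals; the threshold is the mean of the last 5.  Steady-state accuracy,
measured as the empirical fraction correct over 10,000 trials after burn-in,
reproduces the analytic fixed point p³ = 1/2 (79.37%); the probability
correct at the mean reversal level sits slightly above it (~+0.3 morph
units) because the staircase's excursions above threshold are corrected more
slowly (three correct responses per down-step) than those below (one error
per up-step).  The empirical accuracy is therefore the convergence measure
reported by `scripts/acceptance.py`.

**Session and analysis.**  Each subject runs each adaptation class twice in
ABAB/BABA order (counterbalanced by subject parity); within a run the two
prototype staircases are interleaved and the one matching the adaptor class
is "adapted".  The threshold table is analysed with a canonical three-way
repeated-measures ANOVA: explicit cell-mean sums of squares with the
factor × subject interaction as each factor's error term, df = (levels−1),
(levels−1)(n−1).  For 20 subjects this gives denominator df 19; the
implementation is cross-checked in the tests against statsmodels' AnovaRM.
Zero-effect factors report F = 0 even when the error SS is also zero.

## Encoding simulation

Units have Gaussian tuning over shape-space distance,
r(u, s) = gain · exp(−d²/2w²), preferred points drawn along the
inter-prototype segment (extended 20% each side) with isotropic scatter of
expected norm `spread` = 1.0, width 1.5, gains ~N(1, 0.2) clipped positive.
`spread = 0` degenerates to all units at the segment midpoint.  Voxels pool
20 random units with exponential weights normalised to sum 1; the mixing
matrix is fixed per subject across runs.

**Adaptation mechanisms.**
- `uniform_gain`: all gains × (1 − strength).  With zero measurement noise
  this provably leaves every pattern correlation unchanged (Pearson affine
  invariance), so Δr ≡ 0 — the key null mechanism.
- `graded_gain` (default, strength 0.18): homeostatic non-homogeneous
  scaling.  With w = the unit's adaptor drive rank-normalised to [0, 1],
  gain × (1 − strength·(2w − 1)): the most-driven units are scaled by 0.82,
  the least-driven facilitated up to 1.18.  This suppresses adapted-class
  responses (mean adapted/unadapted amplitude ratio ≈ 0.87 at defaults),
  spreads voxel scaling factors across suppression and enhancement, and —
  with measurement noise — decorrelates adapted probe-pair patterns
  (cohort-mean Δr ≈ 0.1 in the default ROI pipeline).  A "fatigue-only"
  variant (reduction proportional to drive, no facilitation) produces the
  same signs with smaller effects; a variant that suppresses *weakly* driven
  units more produces inverted signs (adapted responses enhanced, Δr < 0)
  and is therefore not offered.
- `sharpening`: tuning widths × (1 − strength) for units whose preferred
  point lies within the adaptor-cloud radius of the adapted prototype.
  Also yields suppression of adapted responses and Δr > 0, with smaller
  effect sizes than graded gain.

**BOLD and GLM.**  Runs follow the event schedule exactly (60 s
pre-adaptation; 16 trials: 4 s top-up, 1–4 s jittered ISI, 1 s probe; 14 s
trial spacing; 142 volumes at TR 2 s; the ±10% size modulation tags the
cover task only and does not drive voxels).  Boxcars are convolved on a
0.1 s grid with a canonical double-gamma HRF (peak 6 s, undershoot 16 s,
dispersions 1 s, ratio 6, 32 s kernel).  The GLM has 13 columns: 6
convolved covariates (pre-adaptation, pooled top-ups, four probes), their
temporal derivatives, and an intercept.  High-pass filtering is a
Gaussian-weighted running-line fit (σ = 50 s) subtracted identically from
data and regressors (an approximation of FSL's filter; exact FSL numerics
are out of scope), followed by demeaning of the non-intercept columns.
Noise is i.i.d. Gaussian per volume — no temporal autocorrelation, so no
prewhitening.  OLS recovers noiseless amplitudes to machine precision and
is unbiased under noise (verified to <2% over 100 runs).

**Beta cohorts.**  `simulate_beta_cohort(route="glm")` runs the full BOLD +
GLM stage; `route="direct"` (default) draws betas as ground-truth amplitudes
plus i.i.d. Gaussian noise of SD 0.06, the estimation noise the GLM stage
would leave.  The two routes agree (tested noiselessly); the direct route
makes cohort-scale calibration studies cheap.  The noise SD was chosen so
unadapted probe-pair correlations in a 100-voxel ROI fall near 0.7, the
range typical of run-wise pattern correlations in object-selective cortex;
it is part of the study conditions, not a tuning knob.

## Pattern analyses

Run-wise Pearson correlations r(A1,A2) and r(B1,B2) over ROI voxels are
labeled adapted when the pair's class matches the run's adaptor; Fisher z
values are averaged within label across runs, back-transformed, and
Δr = r_unadapted − r_adapted per subject (per-prototype values are averaged
via z to the headline per-subject statistic).  ROI selection takes the
top-100 localizer-contrast voxels within a (synthetic) parcel, ties broken
by linear voxel index.  PSC uses the per-voxel run mean as denominator.
Suppression scaling factors are per-voxel ratios of run-averaged adapted to
unadapted responses; bins (default width 0.1 over [0.5, 1.5]) enter the
group analysis only with ≥ 10 voxels and ≥ 7 subjects.  In this encoding
model the decorrelation effect is present and significant across the
admissible suppression range, including enhancement bins; the bin-wise
*gradient* of Δr is not a robust model prediction at realistic SNR, because
observed-ratio bin assignment is dominated by estimation noise that is
shared with the correlation estimates — a selection caveat that applies
equally to empirical versions of this analysis.

## Searchlight and inference

Spheres of 5 mm radius (center-to-center voxel distance, clipped at mask
edges, centers restricted to the mask, minimum 5 voxels) feed the same
decorrelation statistic; each subject contributes a Δr volume.  Group
inference is one-sided on positive Δr (the hypothesis is directional):
pseudo-t with the sample variance Gaussian-smoothed at 10 mm FWHM
(mask-normalised), TFCE with E = 0.5, H = 2, 26-connectivity, and the
sign-flip max-statistic null.  Exhaustive mode enumerates all 2ⁿ sign
vectors, identity included, so FWER p ≥ 2⁻ⁿ; Monte-Carlo flips are offered
for n > 20.  TFCE values depend on the integration step dh; within one
permutation test dh is fixed from the observed map (default max/100) so all
permutations are comparable.  Null calibration: with 8 subjects on a 12³
grid over 500 null cohorts the probability that any voxel passes α = 0.05
is within ±0.02 of 0.05.

## Pipeline, seeding, problem sizes

`ExperimentConfig` holds every study constant (60 s, 4 s, 5 Hz, 14 s, 16
trials, 142 volumes, 8 runs, 100 voxels, 50 adaptors, 80 steps, ±10%, 20
behavioral / 10 fMRI subjects) in one serialisable schema; a config + master
seed reproduces every output file bit-for-bit (manifests record sha256
checksums).  All randomness derives from `numpy` `SeedSequence` keyed by
(master seed, stage, subject, run), so adding subjects never perturbs
existing ones.  The default simulation grid is 20³ voxels at 1.5 mm — a
desk-scale stand-in for a whole-brain matrix — and the test suite uses 5³–8³
grids and 3–10 subjects, sizes chosen so the full suite exercises every
stage, including the 500-cohort permutation calibration, in a few minutes.

## What passing tests show — and what they do not

The synthetic observer and encoding model are stand-ins with known ground
truth: tests demonstrate that the *analysis machinery* is correct (estimator
calibration, invariances, type-I error control, oracle agreement) and that
the *qualitative* signatures of adaptation-induced decorrelation follow from
the implemented mechanisms under realistic noise.  They do not validate the
mechanisms against real cortex: real BOLD noise is temporally and spatially
correlated, voxel selectivity is not a random pooling of idealised Gaussian
tuning curves, real psychometric functions drift with fatigue and learning,
and anatomical parcels are not synthetic cubes.  Effect magnitudes printed
by the pipeline report are therefore comparable to published human values
only in direction and rough scale.

## Known limitations

- No temporal autocorrelation or prewhitening in the GLM stage.
- Localizer simulation covers a single shapes-vs-scrambled contrast.
- Phase interpolation along morphs is linear, not circular.
- The suppression-bin gradient (see above) is reported but not a tested
  model prediction.
- Exhaustive permutation is limited to 2²⁰ assignments.
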