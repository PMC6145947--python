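# adaptdecorr

Simulation and analysis pipeline for studying how **visual adaptation
decorrelates shape representations** — the efficient-coding account under
which brief exposure to a class of similar stimuli both improves perceptual
discrimination of class members and makes their neural activity patterns
more distinct.

The package is aimed at psychophysicists and fMRI methodologists who want a
fully synthetic, seeded, desk-scale twin of this experimental paradigm: every
stage, from stimulus construction to group-level permutation inference, is
exercisable in seconds and validated against independent oracles.

## What it implements

**Stimuli** (`adaptdecorr.shape_space`).  3D radial-frequency shapes: a unit
sphere modulated by six sinusoids, each with a frequency, amplitude, phase
and orientation — a 24-dimensional shape space.  Two fixed prototypes A and
B span an 80-step morph continuum; 50 adaptors per class are jittered on the
amplitude/orientation coordinates at an exact Euclidean radius; probe pairs
(A1, A2, B1, B2) sit symmetrically about each prototype along a random
direction.  Shapes render to watertight triangle meshes (OBJ export).

**Behavior** (`adaptdecorr.psychophysics`).  A delayed match-to-sample task
driven by a 1-up/3-down staircase (converging at the 0.5^(1/3) ≈ 79.4%
correct level; 8 reversals, threshold = mean of the last 5).  The synthetic
observer has a renormalised cumulative-Gaussian psychometric function whose
threshold parameter is exactly its 79.4% point; adapting to a shape class
lowers that class's threshold by `adaptation_gain` morph units (defaults 4.6
and 6.4 for A and B).  Sessions are analysed with a three-way
repeated-measures ANOVA (condition × prototype × run) and paired t-tests.

**Neural simulation** (`adaptdecorr.encoding_sim`).  Gaussian-tuned units in
shape space pool into voxels through fixed sparse non-negative weights.
Candidate adaptation mechanisms: uniform gain scaling, homeostatic graded
gain (suppression grows with adaptor drive, default strength 0.18),
tuning-curve sharpening, or none.  Runs follow the event schedule (60 s
pre-adaptation, 16 trials with 4 s top-up at 14 s spacing, 142 volumes at
TR = 2 s), convolved with a canonical double-gamma HRF; the GLM uses 6
covariates + temporal derivatives + intercept with σ = 50 s Gaussian
running-line high-pass filtering.

**Pattern analyses** (`adaptdecorr.pattern_analysis`,
`adaptdecorr.searchlight_tfce`).  Top-100 localizer ROI selection; run-wise
Pearson correlations of probe-pair patterns labeled adapted/unadapted by the
run's adaptor class; Fisher-z averaging; the decorrelation effect
Δr = r_unadapted − r_adapted; percent signal change; per-voxel suppression
scaling factors and suppression-binned decorrelation (bins admitted with
≥ 10 voxels and ≥ 7 subjects); 5 mm spherical searchlight maps; TFCE
(E = 0.5, H = 2) and one-sample sign-flip permutation FWER inference with
10 mm FWHM variance smoothing, exhaustive over all 2^n sign assignments.

## Worked example

```python
from adaptdecorr import psychophysics as psy

table = psy.run_session(master_seed=3)          # 20 subjects x 2 runs x 2 staircases
stats = psy.analyze_thresholds(table)
print(stats["anova"]["condition"])
print({p: round(stats["paired_tests"][p]["mean_decrease"], 2) for p in "AB"})
```

prints

```
{'F': 383.60778750587383, 'df1': 1, 'df2': 19, 'p': 4.65702426073015e-14}
{'A': 4.53, 'B': 6.25}
```

i.e. adaptation lowers discrimination thresholds (a large main effect of
condition), and the recovered mean threshold decreases (4.53 and 6.25 morph
units) match the effect sizes the observers were given (4.6 and 6.4).  The
fMRI arm is one call away:

```python
from adaptdecorr.pipeline import ExperimentConfig, run_experiment
manifest = run_experiment(ExperimentConfig(master_seed=3), "out/")
```

which writes stimulus tables, the threshold table, beta-pattern NIfTIs, the
decorrelation and suppression-bin CSVs, searchlight volumes, and
`report.json`.  A command-line interface mirrors the library
(`adaptdecorr run|shapes|psycho|sim|analyze|searchlight ...`).

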