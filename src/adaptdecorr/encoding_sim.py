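"""Synthetic fMRI arm: tuned neural populations, adaptation, BOLD and GLM.

A population of Gaussian-tuned units in the 24-dimensional shape space drives
voxels through a fixed, sparse, non-negative mixing matrix (one per subject).
Adaptation to an adaptor class alters the population according to one of four
candidate mechanisms:

``uniform_gain``
    every unit's gain is scaled by (1 - strength);
``graded_gain``
    homeostatic non-homogeneous scaling: gain reduction grows with the
    unit's mean drive by the adaptor set (strongly driven units suppressed,
    weakly driven units facilitated), so adapted-class responses drop most;
``sharpening``
    tuning widths narrow for units preferring shapes inside the adaptor cloud;
``none``
    identity.

Each simulated run follows the event schedule of the experiment: 60 s
pre-adaptation, then 16 trials (4 s top-up, jittered 1–4 s ISI, 1 s probe)
spaced 14 s apart, 142 volumes at TR = 2 s.  Probe amplitudes are convolved
with a canonical double-gamma HRF; the GLM includes six convolved covariates,
their temporal derivatives and an intercept, with Gaussian running-line
high-pass filtering (sigma = 50 s) applied to data and regressors alike.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import stats

from .shape_space import (
    PARAM_SCALES,
    AdaptorSet,
    ShapeParams,
    default_prototypes,
    jitter_adaptors,
    probe_pair,
    shape_distance,
)

__all__ = [
    "NeuralUnit",
    "AdaptationMode",
    "VoxelGrid",
    "EventSchedule",
    "BetaPatterns",
    "StimulusSet",
    "SubjectEncoding",
    "CONDITIONS",
    "build_population",
    "unit_response",
    "population_responses",
    "apply_adaptation",
    "mixing_matrix",
    "voxel_amplitudes",
    "make_stimulus_set",
    "build_subject",
    "make_trial_sequence",
    "hrf_kernel",
    "highpass_matrix",
    "highpass",
    "design_matrix",
    "fit_glm",
    "simulate_run",
    "fit_run",
    "simulate_localizer",
    "simulate_beta_cohort",
    "default_run_adaptors",
]

CONDITIONS = ("A1", "A2", "B1", "B2")


@dataclass(frozen=True)
class NeuralUnit:
    preferred_point: np.ndarray  # raw 24-vector in shape space
    tuning_width: float  # in shape-space (scaled Euclidean) distance units
    gain: float

    def __post_init__(self):
        if self.tuning_width <= 0:
            raise ValueError("tuning_width must be positive")
        if self.gain < 0:
            raise ValueError("gain must be non-negative")


@dataclass(frozen=True)
class AdaptationMode:
    mode: str = "graded_gain"  # {none, uniform_gain, graded_gain, sharpening}
    strength: float = 0.18

    def __post_init__(self):
        if self.mode not in ("none", "uniform_gain", "graded_gain", "sharpening"):
            raise ValueError(f"unknown adaptation mode: {self.mode!r}")
        if not (0.0 <= self.strength <= 1.0):
            raise ValueError("strength must lie in [0, 1]")


@dataclass(frozen=True)
class VoxelGrid:
    shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size: float = 1.5  # mm, isotropic
    mask: np.ndarray | None = None  # boolean lattice; None = full grid

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.mask is not None:
            if self.mask.shape != tuple(self.shape):
                raise ValueError("mask shape mismatch")
            if not self.mask.any():
                raise ValueError("mask is empty")

    def get_mask(self) -> np.ndarray:
        return np.ones(self.shape, dtype=bool) if self.mask is None else self.mask

    @property
    def n_voxels(self) -> int:
        return int(self.get_mask().sum())

    def flat_indices(self) -> np.ndarray:
        return np.flatnonzero(self.get_mask().ravel())

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        return aff


@dataclass(frozen=True)
class EventSchedule:
    """Timing of one experimental run (defaults are the study conditions)."""

    pre_adapt_s: float = 60.0
    topup_s: float = 4.0
    probe_s: float = 1.0
    trial_spacing_s: float = 14.0
    n_trials: int = 16
    tr_s: float = 2.0
    n_volumes: int = 142
    isi_jitter_s: tuple[float, float] = (1.0, 4.0)
    size_modulation: float = 0.10  # cover-task tag only; does not drive voxels

    def __post_init__(self):
        end = self.pre_adapt_s + self.n_trials * self.trial_spacing_s
        if end > self.n_volumes * self.tr_s + 1e-9:
            raise ValueError(
                f"schedule overflow: events span {end:.1f} s but only "
                f"{self.n_volumes * self.tr_s:.1f} s are acquired"
            )
        last_probe = (
            self.pre_adapt_s
            + (self.n_trials - 1) * self.trial_spacing_s
            + self.topup_s
            + self.isi_jitter_s[1]
            + self.probe_s
        )
        if last_probe > self.n_volumes * self.tr_s:
            raise ValueError("schedule overflow: last probe exceeds acquisition")

    @property
    def duration_s(self) -> float:
        return self.n_volumes * self.tr_s


@dataclass
class BetaPatterns:
    """Per subject x run x probe-condition x voxel response amplitudes."""

    values: np.ndarray  # (n_subjects, n_runs, 4, n_voxels)
    run_adaptor: np.ndarray  # (n_subjects, n_runs) of "A"/"B"
    noise_sd: float
    conditions: tuple[str, ...] = CONDITIONS
    grid: VoxelGrid | None = None

    def __post_init__(self):
        if self.values.ndim != 4 or self.values.shape[2] != len(self.conditions):
            raise ValueError("values must be (subjects, runs, conditions, voxels)")
        if self.run_adaptor.shape != self.values.shape[:2]:
            raise ValueError("run_adaptor shape mismatch")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_runs(self) -> int:
        return self.values.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[3]


# ---------------------------------------------------------------------------
# population


def build_population(
    n_units: int,
    spread: float,
    seed: int,
    prototypes: tuple[ShapeParams, ShapeParams] | None = None,
    tuning_width: float = 1.5,
    gain_sd: float = 0.2,
) -> list[NeuralUnit]:
    """Sample units whose preferred points cover the stimulus region.

    Preferred points are drawn by picking a position uniformly along the
    segment joining the two prototypes (extended 20% beyond each end) and
    adding isotropic Gaussian scatter whose expected *norm* in the scaled
    space is ``spread`` (shape-space distance units).
    """
    if n_units < 10:
        raise ValueError("n_units must be >= 10")
    a, b = prototypes or default_prototypes()
    va, vb = a.to_vector() / PARAM_SCALES, b.to_vector() / PARAM_SCALES
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 11]))
    if spread == 0:  # degenerate: every unit at the stimulus-region centroid
        ts = np.full(n_units, 0.5)
    else:
        ts = rng.uniform(-0.2, 1.2, size=n_units)
    pts = va[None, :] + ts[:, None] * (vb - va)[None, :]
    pts = pts + (spread / np.sqrt(len(va))) * rng.standard_normal((n_units, len(va)))
    gains = np.clip(rng.normal(1.0, gain_sd, size=n_units), 0.05, None)
    return [
        NeuralUnit(preferred_point=pts[i] * PARAM_SCALES, tuning_width=tuning_width, gain=float(gains[i]))
        for i in range(n_units)
    ]


def unit_response(unit: NeuralUnit, stim: ShapeParams) -> float:
    """Gaussian tuning over shape-space distance: gain * exp(-d^2 / 2w^2).

    Preferred points may drift outside the stimulus invariants (they are
    neural labels, not displayed shapes); distance uses the scaled metric.
    """
    d = np.linalg.norm((unit.preferred_point - stim.to_vector()) / PARAM_SCALES)
    return float(unit.gain * np.exp(-(d**2) / (2 * unit.tuning_width**2)))


def _pref_matrix(units: list[NeuralUnit]) -> np.ndarray:
    return np.stack([u.preferred_point for u in units]) / PARAM_SCALES


def population_responses(units: list[NeuralUnit], stims: list[ShapeParams]) -> np.ndarray:
    """(n_units, n_stims) response matrix."""
    prefs = _pref_matrix(units)
    svecs = np.stack([s.to_vector() / PARAM_SCALES for s in stims])
    d2 = ((prefs[:, None, :] - svecs[None, :, :]) ** 2).sum(axis=2)
    widths = np.array([u.tuning_width for u in units])[:, None]
    gains = np.array([u.gain for u in units])[:, None]
    return gains * np.exp(-d2 / (2 * widths**2))


def apply_adaptation(
    units: list[NeuralUnit], adaptor_set: AdaptorSet, mode: AdaptationMode
) -> list[NeuralUnit]:
    """Return the adapted population under the chosen mechanism."""
    if mode.mode == "none" or mode.strength == 0.0:
        return list(units)
    if mode.mode == "uniform_gain":
        return [replace(u, gain=u.gain * (1 - mode.strength)) for u in units]
    if mode.mode == "graded_gain":
        # homeostatic non-homogeneous scaling: gain reduction grows with the
        # unit's mean drive by the adaptor set (normalised rank w in [0, 1]);
        # the most-driven units are scaled by (1 - strength), the least-driven
        # facilitated up to (1 + strength).  Suppresses adapted-class
        # responses, spreads voxel scaling factors across suppression and
        # enhancement, and decorrelates adapted-pair patterns.
        drives = population_responses(units, list(adaptor_set.adaptors)).mean(axis=1)
        lo, hi = drives.min(), drives.max()
        if hi == lo:
            w = np.full(len(units), 0.5)
        else:
            w = (drives - lo) / (hi - lo)
        return [
            replace(u, gain=u.gain * (1 - mode.strength * (2 * wi - 1))) for u, wi in zip(units, w)
        ]
    if mode.mode == "sharpening":
        proto_v = adaptor_set.prototype.to_vector() / PARAM_SCALES
        out = []
        for u in units:
            d = np.linalg.norm(u.preferred_point / PARAM_SCALES - proto_v)
            if d <= adaptor_set.radius:
                out.append(replace(u, tuning_width=u.tuning_width * (1 - mode.strength)))
            else:
                out.append(u)
        return out
    raise ValueError(f"unknown adaptation mode: {mode.mode!r}")


# ---------------------------------------------------------------------------
# voxels


def mixing_matrix(n_voxels: int, n_units: int, seed: int, n_pool: int = 20) -> np.ndarray:
    """Sparse non-negative unit-to-voxel weights, rows normalised to sum 1.

    Fixed per subject (same seed) across runs, so condition differences in
    voxel space reflect only population changes and noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 23]))
    n_pool = min(n_pool, n_units)
    W = np.zeros((n_voxels, n_units))
    for v in range(n_voxels):
        idx = rng.choice(n_units, size=n_pool, replace=False)
        w = rng.exponential(1.0, size=n_pool)
        W[v, idx] = w / w.sum()
    return W


def voxel_amplitudes(
    units: list[NeuralUnit], stim: ShapeParams, mixing_seed: int, grid: VoxelGrid
) -> np.ndarray:
    """Per-voxel amplitude map for one stimulus: W @ unit responses."""
    W = mixing_matrix(grid.n_voxels, len(units), mixing_seed)
    r = population_responses(units, [stim])[:, 0]
    return W @ r


# ---------------------------------------------------------------------------
# stimuli for the fMRI arm


@dataclass(frozen=True)
class StimulusSet:
    prototypes: tuple[ShapeParams, ShapeParams]
    adaptors: dict  # {"A": AdaptorSet, "B": AdaptorSet}
    probes: dict  # {"A1": ShapeParams, ...}


def make_stimulus_set(
    adaptor_radius_frac: float = 0.25,
    probe_offset_frac: float = 0.15,
    n_adaptors: int = 50,
    seed: int = 0,
) -> StimulusSet:
    """Prototypes, 50-adaptor clouds, and the four probe stimuli A1..B2."""
    a, b = default_prototypes()
    d = shape_distance(a, b)
    radius = adaptor_radius_frac * d
    offset = probe_offset_frac * d
    adaptors = {
        "A": jitter_adaptors(a, n=n_adaptors, radius=radius, seed=seed * 7 + 1, other_prototype=b),
        "B": jitter_adaptors(b, n=n_adaptors, radius=radius, seed=seed * 7 + 2, other_prototype=a),
    }
    pa = probe_pair(a, offset=offset, seed=seed * 7 + 3)
    pb = probe_pair(b, offset=offset, seed=seed * 7 + 4)
    probes = {"A1": pa.probes[0], "A2": pa.probes[1], "B1": pb.probes[0], "B2": pb.probes[1]}
    return StimulusSet(prototypes=(a, b), adaptors=adaptors, probes=probes)


@dataclass
class SubjectEncoding:
    """Everything fixed for one simulated subject across runs."""

    units: list[NeuralUnit]
    mixing: np.ndarray  # (n_voxels, n_units)
    grid: VoxelGrid
    stimuli: StimulusSet
    mode: AdaptationMode
    baseline: float = 100.0  # raw-signal baseline level

    def adapted_units(self, run_adaptor: str) -> list[NeuralUnit]:
        return apply_adaptation(self.units, self.stimuli.adaptors[run_adaptor], self.mode)

    def probe_amplitude_maps(self, run_adaptor: str) -> np.ndarray:
        """(4, n_voxels) ground-truth probe amplitudes under this run's adaptor."""
        units = self.adapted_units(run_adaptor)
        r = population_responses(units, [self.stimuli.probes[c] for c in CONDITIONS])
        return (self.mixing @ r).T

    def adaptor_drive_map(self, units: list[NeuralUnit], cls: str) -> np.ndarray:
        r = population_responses(units, list(self.stimuli.adaptors[cls].adaptors)).mean(axis=1)
        return self.mixing @ r


def build_subject(
    subject: int,
    master_seed: int,
    grid: VoxelGrid,
    stimuli: StimulusSet | None = None,
    mode: AdaptationMode | None = None,
    n_units: int = 200,
    spread: float = 1.0,
) -> SubjectEncoding:
    stimuli = stimuli or make_stimulus_set(seed=master_seed)
    mode = mode or AdaptationMode()
    pop_seed = int(np.random.SeedSequence([master_seed & 0x7FFFFFFF, 31, subject]).generate_state(1)[0] & 0x7FFFFFFF)
    mix_seed = int(np.random.SeedSequence([master_seed & 0x7FFFFFFF, 37, subject]).generate_state(1)[0] & 0x7FFFFFFF)
    units = build_population(n_units, spread=spread, seed=pop_seed, prototypes=stimuli.prototypes)
    W = mixing_matrix(grid.n_voxels, n_units, seed=mix_seed)
    return SubjectEncoding(units=units, mixing=W, grid=grid, stimuli=stimuli, mode=mode)


# ---------------------------------------------------------------------------
# event schedule and HRF


def make_trial_sequence(schedule: EventSchedule, seed: int) -> list[dict]:
    """Counterbalanced trial order: 4 instances of each probe, two tagged
    smaller and two larger (the +-10% cover-task modulation)."""
    n_per = schedule.n_trials // len(CONDITIONS)
    labels = []
    for c in CONDITIONS:
        for i in range(n_per):
            labels.append((c, "smaller" if i % 2 == 0 else "larger"))
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 41]))
    order = rng.permutation(len(labels))
    lo, hi = schedule.isi_jitter_s
    trials = []
    for i, k in enumerate(order):
        cond, size = labels[k]
        onset = schedule.pre_adapt_s + i * schedule.trial_spacing_s
        isi = float(rng.uniform(lo, hi))
        trials.append(
            {
                "trial": i,
                "condition": cond,
                "size": size,
                "topup_onset": onset,
                "probe_onset": onset + schedule.topup_s + isi,
            }
        )
    return trials


def hrf_kernel(dt: float = 0.1, length_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``dt``.

    Peak at 6 s, undershoot at 16 s, both with dispersion 1 s, peak-to-
    undershoot ratio 6; kernel truncated at 32 s.
    """
    t = np.arange(0, length_s + dt / 2, dt)
    peak = stats.gamma.pdf(t, a=6, scale=1.0)
    under = stats.gamma.pdf(t, a=16, scale=1.0)
    return peak - under / 6.0


@lru_cache(maxsize=8)
def _hp_residual_matrix(n: int, sigma_vols: float) -> np.ndarray:
    """I - S for the Gaussian-weighted running-line smoother (FSL-style)."""
    t = np.arange(n)
    S = np.zeros((n, n))
    for i in range(n):
        x = t - i
        w = np.exp(-(x**2) / (2 * sigma_vols**2))
        sw, swx = w.sum(), (w * x).sum()
        swx2 = (w * x * x).sum()
        denom = sw * swx2 - swx**2
        S[i] = w * (swx2 - x * swx) / denom
    return np.eye(n) - S


def highpass_matrix(n_volumes: int, tr_s: float, sigma_s: float = 50.0) -> np.ndarray:
    return _hp_residual_matrix(n_volumes, sigma_s / tr_s)


def highpass(series: np.ndarray, tr_s: float, sigma_s: float = 50.0) -> np.ndarray:
    """Remove slow drift by subtracting a Gaussian-weighted running-line fit.

    Operates along the first axis.  Linear, removes constants and straight
    lines exactly; applied identically to data and regressors.
    """
    R = highpass_matrix(series.shape[0], tr_s, sigma_s)
    return R @ series


_REGRESSORS = ["pre_adapt", "topup"] + list(CONDITIONS)


def design_matrix(
    schedule: EventSchedule,
    trial_sequence: list[dict],
    dt: float = 0.1,
    apply_highpass: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """GLM design: 6 convolved covariates + 6 temporal derivatives + intercept.

    Boxcars (pre-adaptation phase, all top-up phases, one per probe condition)
    are convolved with the double-gamma HRF on a fine grid, sampled at volume
    acquisition times, high-pass filtered and demeaned; the intercept column
    is appended last.
    """
    n_fine = int(round(schedule.duration_s / dt))
    tfine = np.arange(n_fine) * dt
    boxcars = {name: np.zeros(n_fine) for name in _REGRESSORS}
    boxcars["pre_adapt"][(tfine >= 0) & (tfine < schedule.pre_adapt_s)] = 1.0
    for tr in trial_sequence:
        on = tr["topup_onset"]
        boxcars["topup"][(tfine >= on) & (tfine < on + schedule.topup_s)] = 1.0
        on = tr["probe_onset"]
        boxcars[tr["condition"]][(tfine >= on) & (tfine < on + schedule.probe_s)] = 1.0
    h = hrf_kernel(dt)
    vol_idx = np.round(np.arange(schedule.n_volumes) * schedule.tr_s / dt).astype(int)
    cols, names = [], []
    for name in _REGRESSORS:
        conv = np.convolve(boxcars[name], h)[:n_fine] * dt
        cols.append(conv[vol_idx])
        names.append(name)
    for name in _REGRESSORS:
        conv = np.convolve(boxcars[name], h)[:n_fine] * dt
        deriv = np.gradient(conv, dt)
        cols.append(deriv[vol_idx])
        names.append(name + "_deriv")
    X = np.column_stack(cols)
    if apply_highpass:
        X = highpass(X, schedule.tr_s)
        X = X - X.mean(axis=0, keepdims=True)
    X = np.column_stack([X, np.ones(schedule.n_volumes)])
    names.append("intercept")
    return X, names


def fit_glm(timeseries: np.ndarray, design: np.ndarray, names: list[str] | None = None) -> np.ndarray:
    """Ordinary least squares betas, (n_regressors, n_voxels).

    ``timeseries`` is (n_volumes, n_voxels).  Raises on rank deficiency,
    naming the collinear columns.
    """
    n, k = design.shape
    rank = np.linalg.matrix_rank(design)
    if rank < k:
        # identify dependent columns via QR with pivoting
        from scipy.linalg import qr

        _, r, piv = qr(design, pivoting=True)
        bad = sorted(piv[rank:])
        labels = [names[i] if names else str(i) for i in bad]
        raise np.linalg.LinAlgError(f"rank-deficient design; collinear columns: {labels}")
    beta, *_ = np.linalg.lstsq(design, timeseries, rcond=None)
    return beta


def simulate_run(
    subject: SubjectEncoding,
    run_adaptor: str,
    schedule: EventSchedule,
    noise_sd: float,
    seed: int,
) -> tuple[np.ndarray, dict]:
    """Forward-model one run: (timeseries (n_volumes, n_voxels), truth record).

    The noiseless signal is baseline + sum over covariates of the convolved
    boxcar times its per-voxel amplitude: probe amplitudes from the adapted
    population, pre-adaptation drive from the unadapted population, top-up
    drive from the adapted population.  I.i.d. Gaussian noise of SD
    ``noise_sd`` is added per volume and voxel.
    """
    trials = make_trial_sequence(schedule, seed)
    X_raw, names = design_matrix(schedule, trials, apply_highpass=False)
    adapted = subject.adapted_units(run_adaptor)
    amps = np.zeros((len(_REGRESSORS), subject.grid.n_voxels))
    amps[0] = subject.adaptor_drive_map(subject.units, run_adaptor)  # pre-adapt
    amps[1] = subject.adaptor_drive_map(adapted, run_adaptor)  # top-up
    amps[2:] = subject.probe_amplitude_maps(run_adaptor)
    signal = X_raw[:, : len(_REGRESSORS)] @ amps + subject.baseline
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 43]))
    noise = rng.normal(0.0, noise_sd, size=signal.shape) if noise_sd > 0 else 0.0
    truth = {
        "probe_amplitudes": amps[2:].copy(),
        "run_adaptor": run_adaptor,
        "trials": trials,
        "conditions": CONDITIONS,
    }
    return signal + noise, truth


def fit_run(
    timeseries: np.ndarray, schedule: EventSchedule, trials: list[dict]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """High-pass filter data, fit the GLM, return (betas, baseline, names).

    Baseline is the per-voxel run mean (used downstream as the percent-
    signal-change denominator).
    """
    X, names = design_matrix(schedule, trials)
    baseline = timeseries.mean(axis=0)
    Y = highpass(timeseries, schedule.tr_s)
    betas = fit_glm(Y, X, names)
    return betas, baseline, names


def simulate_localizer(
    subject: SubjectEncoding,
    grid: VoxelGrid | None = None,
    seed: int = 0,
    control_fraction: float = 0.3,
    noise_sd: float = 0.05,
) -> np.ndarray:
    """Shapes-vs-scrambled contrast map for ROI ranking.

    Scrambled control drives units at ``control_fraction`` of the intact
    shape drive, so the contrast is (1 - fraction) * mean shape amplitude
    plus measurement noise.
    """
    grid = grid or subject.grid
    stims = [subject.stimuli.probes[c] for c in CONDITIONS] + list(subject.stimuli.prototypes)
    r = population_responses(subject.units, stims).mean(axis=1)
    shape_amp = subject.mixing @ r
    contrast = (1.0 - control_fraction) * shape_amp
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 47]))
    if noise_sd > 0:
        contrast = contrast + rng.normal(0.0, noise_sd, size=contrast.shape)
    return contrast


# ---------------------------------------------------------------------------
# cohort-level beta generation


def default_run_adaptors(n_runs: int = 8, subject: int = 0) -> list[str]:
    """Counterbalanced run order (four runs per adaptor class)."""
    base = ["A", "B", "B", "A", "B", "A", "A", "B"]
    order = base if subject % 2 == 0 else [("A" if x == "B" else "B") for x in base]
    reps = -(-n_runs // len(order))
    return (order * reps)[:n_runs]


def simulate_beta_cohort(
    n_subjects: int = 10,
    n_runs: int = 8,
    grid: VoxelGrid | None = None,
    mode: AdaptationMode | None = None,
    noise_sd: float = 0.06,
    master_seed: int = 0,
    route: str = "direct",
    schedule: EventSchedule | None = None,
    bold_noise_sd: float = 1.0,
    n_units: int = 200,
    stimuli: StimulusSet | None = None,
) -> tuple[BetaPatterns, dict]:
    """Simulate beta patterns for a cohort.

    ``route="direct"`` draws betas as ground-truth amplitudes plus i.i.d.
    Gaussian noise of SD ``noise_sd`` (the estimation noise a GLM would
    leave); ``route="glm"`` synthesises BOLD time series per run and recovers
    betas by the full GLM stage (slower, used to validate the direct route).

    Returns the :class:`BetaPatterns` plus extras (per-subject localizer
    contrast maps, truth amplitudes, the stimulus set).
    """
    grid = grid or VoxelGrid()
    mode = mode or AdaptationMode()
    stimuli = stimuli or make_stimulus_set(seed=master_seed)
    schedule = schedule or EventSchedule()
    nvox = grid.n_voxels
    values = np.zeros((n_subjects, n_runs, len(CONDITIONS), nvox))
    run_adaptor = np.empty((n_subjects, n_runs), dtype="<U1")
    localizers = np.zeros((n_subjects, nvox))
    truth = np.zeros((n_subjects, 2, len(CONDITIONS), nvox))  # per adaptor class
    for s in range(n_subjects):
        subj = build_subject(s, master_seed, grid, stimuli=stimuli, mode=mode, n_units=n_units)
        loc_seed = int(np.random.SeedSequence([master_seed & 0x7FFFFFFF, 53, s]).generate_state(1)[0] & 0x7FFFFFFF)
        localizers[s] = simulate_localizer(subj, seed=loc_seed)
        amp = {cls: subj.probe_amplitude_maps(cls) for cls in ("A", "B")}
        truth[s, 0], truth[s, 1] = amp["A"], amp["B"]
        adaptors = default_run_adaptors(n_runs, subject=s)
        for r, cls in enumerate(adaptors):
            run_adaptor[s, r] = cls
            run_seed = int(
                np.random.SeedSequence([master_seed & 0x7FFFFFFF, 59, s, r]).generate_state(1)[0] & 0x7FFFFFFF
            )
            if route == "direct":
                rng = np.random.default_rng(run_seed)
                values[s, r] = amp[cls] + rng.normal(0.0, noise_sd, size=(len(CONDITIONS), nvox))
            elif route == "glm":
                Y, tru = simulate_run(subj, cls, schedule, bold_noise_sd, run_seed)
                betas, baseline, names = fit_run(Y, schedule, tru["trials"])
                probe_rows = [names.index(c) for c in CONDITIONS]
                values[s, r] = betas[probe_rows]
            else:
                raise ValueError(f"unknown route: {route!r}")
    patterns = BetaPatterns(values=values, run_adaptor=run_adaptor, noise_sd=noise_sd, grid=grid)
    extras = {"localizers": localizers, "truth": truth, "stimuli": stimuli}
    return patterns, extras
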