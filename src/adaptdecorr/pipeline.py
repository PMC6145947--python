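"""End-to-end experiment orchestration.

``run_experiment`` executes the stages in dependency order — stimulus
construction, behavioral staircase session + threshold analysis, fMRI beta
simulation, ROI decorrelation / percent signal change / suppression binning,
and (optionally) the searchlight + TFCE permutation inference — writing tidy
CSV/JSON outputs, a report juxtaposing the simulated effects with the
reference human effect sizes the defaults emulate, and a manifest with a
checksum for every output file.  Identical config + master seed reproduce
every output bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import encoding_sim, pattern_analysis, psychophysics, searchlight_tfce, shape_space
from .encoding_sim import AdaptationMode, EventSchedule, VoxelGrid
from .io import save_beta_patterns, save_volume

__all__ = [
    "StimulusConfig",
    "BehaviorConfig",
    "FmriConfig",
    "AnalysisConfig",
    "ExperimentConfig",
    "RunManifest",
    "run_experiment",
    "make_fixtures",
    "REFERENCE_EFFECTS",
]

#: Reference human effect sizes that the simulation defaults emulate; the
#: report compares simulated outcomes to these **qualitatively** only.
REFERENCE_EFFECTS = {
    "threshold_decrease_A_morph_units": 4.6,
    "threshold_decrease_B_morph_units": 6.4,
    "psc_adapted_pct": 1.30,
    "psc_unadapted_pct": 1.45,
    "suppression_lowest50": 0.82,
    "suppression_highest50": 1.17,
}


@dataclass
class StimulusConfig:
    n_adaptors: int = 50
    morph_steps: int = 80
    adaptor_radius_frac: float = 0.25  # fraction of the inter-prototype distance
    probe_offset_frac: float = 0.15
    adapt_rate_hz: float = 5.0  # schedule metadata
    adaptor_duration_ms: float = 150.0
    adaptor_isi_ms: float = 50.0


@dataclass
class BehaviorConfig:
    n_subjects: int = 20
    n_repetitions: int = 2
    step_size: float = 1.0
    start_level: float = 30.0
    max_level: float = 40.0
    stop_reversals: int = 8
    threshold_reversals: int = 5
    mean_threshold_a: float = 14.0
    mean_threshold_b: float = 19.0
    threshold_sd: float = 3.0
    adaptation_gain_a: float = 4.6
    adaptation_gain_b: float = 6.4
    gain_sd: float = 1.5
    lapse_rate: float = 0.01


@dataclass
class FmriConfig:
    n_subjects: int = 10
    n_runs: int = 8
    grid_shape: tuple = (20, 20, 20)
    voxel_size_mm: float = 1.5
    mode: str = "graded_gain"
    strength: float = 0.18
    noise_sd: float = 0.06
    n_units: int = 200
    route: str = "direct"  # "direct" betas or full "glm" stage
    n_trials: int = 16
    n_volumes: int = 142
    tr_s: float = 2.0
    pre_adapt_s: float = 60.0
    topup_s: float = 4.0
    probe_s: float = 1.0
    trial_spacing_s: float = 14.0
    size_modulation: float = 0.10


@dataclass
class AnalysisConfig:
    roi_k: int = 100
    bin_lo: float = 0.5
    bin_hi: float = 1.5
    bin_width: float = 0.1
    searchlight_radius_mm: float = 5.0
    variance_fwhm_mm: float = 10.0
    alpha: float = 0.01
    effect_threshold: float = 0.10
    run_searchlight: bool = True


@dataclass
class ExperimentConfig:
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    fmri: FmriConfig = field(default_factory=FmriConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    master_seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fmri"]["grid_shape"] = list(d["fmri"]["grid_shape"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(
            stimulus=StimulusConfig(**d.get("stimulus", {})),
            behavior=BehaviorConfig(**d.get("behavior", {})),
            fmri=FmriConfig(**{**d.get("fmri", {}), "grid_shape": tuple(d.get("fmri", {}).get("grid_shape", (20, 20, 20)))}),
            analysis=AnalysisConfig(**d.get("analysis", {})),
            master_seed=int(d.get("master_seed", 0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    files: dict  # relative path -> sha256
    wall_time_s: dict  # stage -> seconds

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _grid(cfg: FmriConfig) -> VoxelGrid:
    return VoxelGrid(shape=tuple(cfg.grid_shape), voxel_size=cfg.voxel_size_mm)


def run_experiment(config: ExperimentConfig, outdir: str | Path) -> RunManifest:
    """Execute every stage; reproducible bit-for-bit from the master seed."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    times: dict[str, float] = {}
    report: dict = {"master_seed": config.master_seed, "reference_effects": REFERENCE_EFFECTS}
    config.to_yaml(outdir / "config.yaml")

    # --- stimuli -----------------------------------------------------------
    t0 = time.perf_counter()
    stimuli = encoding_sim.make_stimulus_set(
        adaptor_radius_frac=config.stimulus.adaptor_radius_frac,
        probe_offset_frac=config.stimulus.probe_offset_frac,
        n_adaptors=config.stimulus.n_adaptors,
        seed=config.master_seed,
    )
    a, b = stimuli.prototypes
    continuum = shape_space.morph_continuum(a, b, config.stimulus.morph_steps)
    shapes = {"prototype_A": a, "prototype_B": b}
    shapes.update({k: v for k, v in stimuli.probes.items()})
    shape_space.shapes_to_csv(shapes, outdir / "stimuli.csv")
    shape_space.shapes_to_json(
        {f"adaptor_A_{i:02d}": s for i, s in enumerate(stimuli.adaptors["A"].adaptors)}
        | {f"adaptor_B_{i:02d}": s for i, s in enumerate(stimuli.adaptors["B"].adaptors)},
        outdir / "adaptors.json",
    )
    report["stimuli"] = {
        "n_free_parameters": a.n_free_parameters,
        "inter_prototype_distance": shape_space.shape_distance(a, b),
        "morph_levels": len(continuum.levels),
        "n_adaptors_per_class": len(stimuli.adaptors["A"].adaptors),
    }
    times["stimuli"] = time.perf_counter() - t0

    # --- behavior ----------------------------------------------------------
    t0 = time.perf_counter()
    bc = config.behavior
    cohort = psychophysics.CohortConfig(
        n_subjects=bc.n_subjects,
        n_repetitions=bc.n_repetitions,
        mean_threshold_a=bc.mean_threshold_a,
        mean_threshold_b=bc.mean_threshold_b,
        threshold_sd=bc.threshold_sd,
        adaptation_gain_a=bc.adaptation_gain_a,
        adaptation_gain_b=bc.adaptation_gain_b,
        gain_sd=bc.gain_sd,
        lapse_rate=bc.lapse_rate,
    )
    stair = psychophysics.StaircaseConfig(
        step_size=bc.step_size,
        start_level=bc.start_level,
        max_level=bc.max_level,
        stop_reversals=bc.stop_reversals,
        threshold_reversals=bc.threshold_reversals,
    )
    table = psychophysics.run_session(cohort, stair, master_seed=config.master_seed)
    table.to_csv(outdir / "thresholds.csv", index=False)
    stats = psychophysics.analyze_thresholds(table)
    wide = table.groupby(["subject", "condition"])["threshold"].mean().unstack()
    n_improved = int((wide["unadapted"] > wide["adapted"]).sum())
    report["behavior"] = {
        "analysis": stats,
        "n_subjects_improved": n_improved,
        "n_subjects": bc.n_subjects,
        "null_effect": stats["anova"]["condition"]["p"] >= 0.05,
    }
    times["behavior"] = time.perf_counter() - t0

    # --- fMRI simulation ---------------------------------------------------
    t0 = time.perf_counter()
    fc = config.fmri
    grid = _grid(fc)
    schedule = EventSchedule(
        pre_adapt_s=fc.pre_adapt_s,
        topup_s=fc.topup_s,
        probe_s=fc.probe_s,
        trial_spacing_s=fc.trial_spacing_s,
        n_trials=fc.n_trials,
        tr_s=fc.tr_s,
        n_volumes=fc.n_volumes,
        size_modulation=fc.size_modulation,
    )
    mode = AdaptationMode(mode=fc.mode, strength=fc.strength)
    betas, extras = encoding_sim.simulate_beta_cohort(
        n_subjects=fc.n_subjects,
        n_runs=fc.n_runs,
        grid=grid,
        mode=mode,
        noise_sd=fc.noise_sd,
        master_seed=config.master_seed,
        route=fc.route,
        schedule=schedule,
        n_units=fc.n_units,
        stimuli=stimuli,
    )
    save_beta_patterns(betas, grid, outdir / "betas")
    times["fmri_sim"] = time.perf_counter() - t0

    # --- ROI analyses ------------------------------------------------------
    t0 = time.perf_counter()
    ac = config.analysis
    parcel = np.ones(grid.n_voxels, dtype=bool)  # synthetic parcel = whole grid
    rois = [
        pattern_analysis.select_roi(extras["localizers"][s], parcel, k=min(ac.roi_k, grid.n_voxels))
        for s in range(fc.n_subjects)
    ]
    # subject-specific ROIs: run per subject and combine
    decorr_frames = []
    for s, roi in enumerate(rois):
        sub = encoding_sim.BetaPatterns(
            values=betas.values[s : s + 1],
            run_adaptor=betas.run_adaptor[s : s + 1],
            noise_sd=betas.noise_sd,
        )
        res = pattern_analysis.decorrelation(sub, roi)
        frame = res.per_subject.assign(subject=s)
        decorr_frames.append(frame)
    decorr = pd.concat(decorr_frames, ignore_index=True)
    decorr.to_csv(outdir / "decorrelation.csv", index=False)
    dtest = pattern_analysis.paired_t(decorr["z_unadapted"], decorr["z_adapted"])
    # suppression profile per subject within that subject's own ROI
    profiles = [pattern_analysis.scaling_factors(betas, rois[s])[s] for s in range(fc.n_subjects)]
    low = float(np.mean([np.nanmean(p.scaling_factor[p.lowest_k]) for p in profiles]))
    high = float(np.mean([np.nanmean(p.scaling_factor[p.highest_k]) for p in profiles]))
    try:
        bins = pattern_analysis.binned_decorrelation(
            profiles, betas, np.arange(ac.bin_lo, ac.bin_hi + ac.bin_width / 2, ac.bin_width)
        )
        bins.to_csv(outdir / "binned_decorrelation.csv", index=False)
        bin_summary = bins[bins["included"]][["bin_lo", "bin_hi", "n_subjects", "mean_delta_r"]].to_dict("records")
    except ValueError:
        bin_summary = []
    report["fmri"] = {
        "mode": fc.mode,
        "strength": fc.strength,
        "mean_delta_r": float(decorr["delta_r"].mean()),
        "n_subjects_decorrelated": int((decorr["delta_r"] > 0).sum()),
        "n_subjects": fc.n_subjects,
        "paired_t_fisher_z": dtest,
        "null_effect": bool(dtest["p"] >= 0.05),
        "suppression_lowest50_mean": low,
        "suppression_highest50_mean": high,
        "bins": bin_summary,
    }
    times["roi_analysis"] = time.perf_counter() - t0

    # --- searchlight + inference ------------------------------------------
    if ac.run_searchlight:
        t0 = time.perf_counter()
        sl_cfg = searchlight_tfce.SearchlightConfig(radius_mm=ac.searchlight_radius_mm)
        maps = searchlight_tfce.searchlight_map(betas, grid, sl_cfg)
        mean_map, thresh_mask = searchlight_tfce.group_effect_map(maps, threshold=ac.effect_threshold)
        save_volume(np.nan_to_num(mean_map), grid, outdir / "searchlight_mean_delta_r.nii.gz")
        perm = searchlight_tfce.permutation_fwer(
            maps,
            variance_fwhm_mm=ac.variance_fwhm_mm,
            voxel_size=grid.voxel_size,
            exhaustive=fc.n_subjects <= 12,
            n_perm=1024,
            seed=config.master_seed,
        )
        sig = searchlight_tfce.significance_map(perm, alpha=ac.alpha)
        save_volume(perm.fwer_p_map, grid, outdir / "searchlight_fwer_p.nii.gz")
        report["searchlight"] = {
            "n_permutations": perm.n_permutations,
            "n_voxels_above_effect_threshold": int(thresh_mask.sum()),
            "n_significant_voxels": int(sig.sum()),
            "min_fwer_p": float(perm.fwer_p_map.min()),
        }
        times["searchlight"] = time.perf_counter() - t0

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)

    files = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config_hash=config.config_hash(), package_version=__version__, files=files, wall_time_s=times
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest


def make_fixtures(size: str = "tiny", outdir: str | Path = "fixtures", master_seed: int = 7) -> RunManifest:
    """Deterministic miniature datasets for the test suite.

    ``tiny``: 3 subjects, 6^3 grid, 2 runs per adaptor class, no searchlight.
    ``small``: 3 subjects, 8^3 grid, searchlight + exhaustive 2^3 permutations.
    """
    if size not in ("tiny", "small"):
        raise ValueError("size must be 'tiny' or 'small'")
    cfg = ExperimentConfig(master_seed=master_seed)
    cfg.behavior.n_subjects = 4
    cfg.fmri.n_subjects = 3
    cfg.fmri.n_runs = 4
    cfg.fmri.n_units = 60
    cfg.analysis.roi_k = 40
    if size == "tiny":
        cfg.fmri.grid_shape = (6, 6, 6)
        cfg.analysis.run_searchlight = False
    else:
        cfg.fmri.grid_shape = (8, 8, 8)
        cfg.analysis.run_searchlight = True
    return run_experiment(cfg, outdir)
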