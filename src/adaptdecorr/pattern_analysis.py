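"""ROI-level multivoxel decorrelation analyses.

The core statistic is the decorrelation effect Δr: within an ROI, the two
probe patterns of a shape class are correlated (Pearson) run by run; a run
where the probes' class matches the run's adaptor class contributes an
"adapted" correlation, otherwise an "unadapted" one.  Correlations are
Fisher z-transformed, averaged across runs within label, back-transformed,
and Δr = r_unadapted - r_adapted per subject (and per prototype).

Also implemented: top-k localizer ROI selection, percent signal change,
per-voxel suppression scaling factors (adapted/unadapted response ratio),
and the suppression-binned decorrelation analysis (bins admitted only with
>= 10 voxels and >= 7 contributing subjects).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding_sim import CONDITIONS, BetaPatterns
from .psychophysics import paired_t

__all__ = [
    "ROISelection",
    "DecorrResult",
    "SuppressionProfile",
    "select_roi",
    "pattern_correlation",
    "fisher_z",
    "inverse_fisher",
    "decorrelation",
    "percent_signal_change",
    "scaling_factors",
    "binned_decorrelation",
    "paired_t",
]

_PAIRS = {"A": ("A1", "A2"), "B": ("B1", "B2")}


@dataclass(frozen=True)
class ROISelection:
    indices: np.ndarray  # voxel indices into the flattened beta arrays
    k: int
    source: str = "localizer"

    def __post_init__(self):
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("ROI indices must be unique")


def select_roi(contrast_map: np.ndarray, parcel_mask: np.ndarray, k: int = 100) -> ROISelection:
    """Top-``k`` voxels of the localizer contrast within the parcel.

    Ties are broken by ascending linear voxel index, making the selection
    fully deterministic.
    """
    contrast_map = np.asarray(contrast_map).ravel()
    parcel = np.flatnonzero(np.asarray(parcel_mask).ravel())
    if len(parcel) < k:
        raise ValueError(f"parcel has {len(parcel)} voxels, fewer than k={k}")
    vals = contrast_map[parcel]
    order = np.lexsort((parcel, -vals))  # by value desc, then index asc
    chosen = np.sort(parcel[order[:k]])
    return ROISelection(indices=chosen, k=k)


def pattern_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation between two voxel patterns."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-d patterns with >= 3 voxels")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant pattern")
    return float(np.corrcoef(x, y)[0, 1])


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Variance-stabilising transform z = atanh(r)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1 for the Fisher transform")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher(z: float | np.ndarray) -> float | np.ndarray:
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclass
class DecorrResult:
    """Per-subject adapted/unadapted correlations and the Δr effect."""

    per_run: pd.DataFrame  # subject, run, pair_class, condition, r
    per_subject: pd.DataFrame  # subject, r_adapted, r_unadapted, delta_r (+ z columns)
    per_prototype: pd.DataFrame  # subject, prototype, r_adapted, r_unadapted, delta_r

    @property
    def delta_r(self) -> np.ndarray:
        return self.per_subject["delta_r"].to_numpy()


def _run_correlations(betas: BetaPatterns, voxels: np.ndarray) -> pd.DataFrame:
    rows = []
    ci = {c: i for i, c in enumerate(betas.conditions)}
    for s in range(betas.n_subjects):
        for r in range(betas.n_runs):
            adaptor = betas.run_adaptor[s, r]
            for cls, (p1, p2) in _PAIRS.items():
                x = betas.values[s, r, ci[p1], voxels]
                y = betas.values[s, r, ci[p2], voxels]
                rows.append(
                    {
                        "subject": s,
                        "run": r,
                        "pair_class": cls,
                        "condition": "adapted" if cls == adaptor else "unadapted",
                        "r": pattern_correlation(x, y),
                    }
                )
    return pd.DataFrame(rows)


def _aggregate(per_run: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    per_run = per_run.assign(z=fisher_z(per_run["r"].to_numpy()))
    proto_rows = []
    subj_rows = []
    for s, g in per_run.groupby("subject"):
        zbar = g.groupby("condition")["z"].mean()
        subj_rows.append(
            {
                "subject": s,
                "z_adapted": zbar["adapted"],
                "z_unadapted": zbar["unadapted"],
                "r_adapted": inverse_fisher(zbar["adapted"]),
                "r_unadapted": inverse_fisher(zbar["unadapted"]),
                "delta_r": inverse_fisher(zbar["unadapted"]) - inverse_fisher(zbar["adapted"]),
            }
        )
        for cls, gc in g.groupby("pair_class"):
            zc = gc.groupby("condition")["z"].mean()
            proto_rows.append(
                {
                    "subject": s,
                    "prototype": cls,
                    "r_adapted": inverse_fisher(zc["adapted"]),
                    "r_unadapted": inverse_fisher(zc["unadapted"]),
                    "delta_r": inverse_fisher(zc["unadapted"]) - inverse_fisher(zc["adapted"]),
                }
            )
    return pd.DataFrame(subj_rows), pd.DataFrame(proto_rows)


def decorrelation(betas: BetaPatterns, roi: ROISelection | np.ndarray) -> DecorrResult:
    """ROI decorrelation analysis over all subjects and runs.

    Per run, r(A1,A2) and r(B1,B2) are computed over the ROI voxels and
    labeled adapted/unadapted by the run's adaptor class; z-averaged within
    label across runs; Δr = r_unadapted - r_adapted.
    """
    voxels = roi.indices if isinstance(roi, ROISelection) else np.asarray(roi)
    for s in range(betas.n_subjects):
        classes = set(betas.run_adaptor[s])
        if classes != {"A", "B"}:
            raise ValueError(f"subject {s} is missing runs for one adaptor class")
    per_run = _run_correlations(betas, voxels)
    per_subject, per_prototype = _aggregate(per_run)
    return DecorrResult(per_run=per_run, per_subject=per_subject, per_prototype=per_prototype)


def percent_signal_change(
    betas: BetaPatterns, baseline: np.ndarray, roi: ROISelection | np.ndarray
) -> pd.DataFrame:
    """PSC = 100 * beta / baseline, averaged over ROI voxels and runs.

    ``baseline`` is a per-voxel positive denominator (the GLM run-mean).
    Returns one row per subject x condition label (adapted/unadapted), plus
    a per-prototype breakdown.
    """
    voxels = roi.indices if isinstance(roi, ROISelection) else np.asarray(roi)
    baseline = np.asarray(baseline, dtype=float)
    if np.any(baseline[voxels] <= 0):
        raise ValueError("baseline must be positive for every ROI voxel")
    ci = {c: i for i, c in enumerate(betas.conditions)}
    rows = []
    for s in range(betas.n_subjects):
        acc: dict[tuple[str, str], list[float]] = {}
        for r in range(betas.n_runs):
            adaptor = betas.run_adaptor[s, r]
            for cls, pair in _PAIRS.items():
                label = "adapted" if cls == adaptor else "unadapted"
                for c in pair:
                    psc = 100.0 * betas.values[s, r, ci[c], voxels] / baseline[voxels]
                    acc.setdefault((label, cls), []).append(psc.mean())
        for (label, cls), vals in sorted(acc.items()):
            rows.append({"subject": s, "condition": label, "prototype": cls, "psc": float(np.mean(vals))})
    return pd.DataFrame(rows)


@dataclass
class SuppressionProfile:
    """Per-voxel adapted/unadapted response ratios for one subject."""

    subject: int
    scaling_factor: np.ndarray  # per ROI voxel
    voxels: np.ndarray
    excluded: np.ndarray  # voxels dropped for a non-positive/zero denominator
    lowest_k: np.ndarray  # indices (into voxels) of the k most suppressed
    highest_k: np.ndarray


def scaling_factors(betas: BetaPatterns, roi: ROISelection | np.ndarray, k: int = 50) -> list[SuppressionProfile]:
    """Per-voxel suppression index: mean adapted / mean unadapted response.

    Responses are averaged over both probes of a class and over runs.  Voxels
    with a non-positive unadapted mean are flagged and excluded.  The ``k``
    lowest- and highest-ratio subsets are reported per subject.
    """
    voxels = roi.indices if isinstance(roi, ROISelection) else np.asarray(roi)
    ci = {c: i for i, c in enumerate(betas.conditions)}
    out = []
    for s in range(betas.n_subjects):
        num = np.zeros(len(voxels))
        den = np.zeros(len(voxels))
        n_num = n_den = 0
        for r in range(betas.n_runs):
            adaptor = betas.run_adaptor[s, r]
            for cls, pair in _PAIRS.items():
                vals = betas.values[s, r][[ci[c] for c in pair]][:, voxels].mean(axis=0)
                if cls == adaptor:
                    num += vals
                    n_num += 1
                else:
                    den += vals
                    n_den += 1
        num /= n_num
        den /= n_den
        ok = den > 0
        ratio = np.full(len(voxels), np.nan)
        ratio[ok] = num[ok] / den[ok]
        order = np.argsort(ratio[ok])
        ok_idx = np.flatnonzero(ok)
        kk = min(k, ok.sum())
        out.append(
            SuppressionProfile(
                subject=s,
                scaling_factor=ratio,
                voxels=voxels,
                excluded=np.flatnonzero(~ok),
                lowest_k=ok_idx[order[:kk]],
                highest_k=ok_idx[order[-kk:]],
            )
        )
    return out


def binned_decorrelation(
    profiles: list[SuppressionProfile],
    betas: BetaPatterns,
    bin_edges: np.ndarray | None = None,
    min_voxels: int = 10,
    min_subjects: int = 7,
) -> pd.DataFrame:
    """Decorrelation computed within suppression bins.

    Voxels are grouped per subject by scaling factor; Δr is computed within
    each bin containing >= ``min_voxels`` voxels; a bin enters the group
    analysis only when >= ``min_subjects`` subjects contribute, and then a
    paired t-test on Fisher z values across subjects is attached.
    """
    if bin_edges is None:
        bin_edges = np.arange(0.5, 1.5001, 0.1)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing")
    rows = []
    for prof in profiles:
        sf = prof.scaling_factor
        which = np.digitize(sf, bin_edges) - 1  # bin b covers [edge_b, edge_b+1)
        for b in range(len(bin_edges) - 1):
            sel = prof.voxels[(which == b) & np.isfinite(sf)]
            if len(sel) < max(min_voxels, 3):
                continue
            try:
                res = decorrelation(
                    BetaPatterns(
                        values=betas.values[prof.subject : prof.subject + 1],
                        run_adaptor=betas.run_adaptor[prof.subject : prof.subject + 1],
                        noise_sd=betas.noise_sd,
                        conditions=betas.conditions,
                    ),
                    sel,
                )
            except ValueError:  # constant pattern inside a tiny bin
                continue
            row = res.per_subject.iloc[0]
            rows.append(
                {
                    "subject": prof.subject,
                    "bin": b,
                    "bin_lo": bin_edges[b],
                    "bin_hi": bin_edges[b + 1],
                    "n_voxels": len(sel),
                    "z_adapted": row["z_adapted"],
                    "z_unadapted": row["z_unadapted"],
                    "delta_r": row["delta_r"],
                }
            )
    per_subj = pd.DataFrame(rows)
    if per_subj.empty:
        raise ValueError("no admissible bins")
    group_rows = []
    for b, g in per_subj.groupby("bin"):
        included = len(g) >= min_subjects
        entry = {
            "bin": b,
            "bin_lo": g["bin_lo"].iloc[0],
            "bin_hi": g["bin_hi"].iloc[0],
            "n_subjects": len(g),
            "included": included,
            "mean_delta_r": g["delta_r"].mean(),
        }
        if included and len(g) >= 3:
            test = paired_t(g["z_unadapted"], g["z_adapted"])
            entry.update({"t": test["t"], "p": test["p"]})
        group_rows.append(entry)
    group = pd.DataFrame(group_rows)
    if not group["included"].any():
        raise ValueError("no admissible bins")
    group.attrs["per_subject"] = per_subj
    return group
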