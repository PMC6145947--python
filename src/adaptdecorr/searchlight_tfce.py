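"""Whole-volume searchlight decorrelation maps with TFCE permutation inference.

A spherical searchlight (default radius 5 mm) slides over the in-mask voxel
lattice; at each center the ROI decorrelation statistic Δr is computed over
the sphere's voxels, producing one Δr volume per subject.  Group inference
uses a one-sample sign-flip permutation test on the subject maps: each sign
assignment yields a pseudo-t map (variance Gaussian-smoothed at 10 mm FWHM),
enhanced with threshold-free cluster enhancement (TFCE, E=0.5, H=2); the
null distribution of the volume-wise maximum controls the family-wise error
rate.  With n subjects the exhaustive test enumerates all 2^n sign vectors
(identity included), so the smallest attainable p is 1/2^n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .encoding_sim import BetaPatterns, VoxelGrid
from .pattern_analysis import decorrelation

__all__ = [
    "SearchlightConfig",
    "TFCEConfig",
    "PermutationResult",
    "sphere_offsets",
    "sphere_indices",
    "searchlight_map",
    "group_effect_map",
    "tfce",
    "permutation_fwer",
    "significance_map",
]


@dataclass(frozen=True)
class SearchlightConfig:
    radius_mm: float = 5.0
    min_voxels_per_sphere: int = 5

    def __post_init__(self):
        if self.radius_mm < 0:
            raise ValueError("radius_mm must be non-negative")


@dataclass(frozen=True)
class TFCEConfig:
    E: float = 0.5
    H: float = 2.0
    dh: float | None = None  # None -> max(map)/100
    connectivity: int = 26  # {6, 18, 26}

    def __post_init__(self):
        if self.E <= 0 or self.H <= 0:
            raise ValueError("E and H must be positive")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class PermutationResult:
    n_permutations: int
    max_stat_null: np.ndarray
    fwer_p_map: np.ndarray  # volume of FWER-corrected p-values
    observed_tfce: np.ndarray
    variance_smoothing_fwhm_mm: float
    exhaustive: bool


# ---------------------------------------------------------------------------
# searchlight


def sphere_offsets(radius_mm: float, voxel_size: float) -> np.ndarray:
    """Integer voxel offsets whose center-to-center distance <= radius_mm."""
    r_vox = int(np.floor(radius_mm / voxel_size))
    rng = np.arange(-r_vox, r_vox + 1)
    dx, dy, dz = np.meshgrid(rng, rng, rng, indexing="ij")
    dist = voxel_size * np.sqrt(dx**2 + dy**2 + dz**2)
    keep = dist <= radius_mm + 1e-9
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


def sphere_indices(
    grid: VoxelGrid, center: tuple[int, int, int], radius_mm: float
) -> np.ndarray:
    """Flat indices of in-mask voxels within ``radius_mm`` of ``center``.

    Spheres at mask edges are clipped to the grid, not discarded.
    """
    center = np.asarray(center, dtype=int)
    if np.any(center < 0) or np.any(center >= np.asarray(grid.shape)):
        raise ValueError("center outside grid")
    coords = center[None, :] + sphere_offsets(radius_mm, grid.voxel_size)
    inside = np.all((coords >= 0) & (coords < np.asarray(grid.shape)[None, :]), axis=1)
    coords = coords[inside]
    flat = np.ravel_multi_index((coords[:, 0], coords[:, 1], coords[:, 2]), grid.shape)
    mask_flat = grid.get_mask().ravel()
    return np.sort(flat[mask_flat[flat]])


def searchlight_map(
    betas: BetaPatterns,
    grid: VoxelGrid,
    cfg: SearchlightConfig | None = None,
) -> np.ndarray:
    """Per-subject Δr volumes, shape (n_subjects,) + grid.shape.

    Beta voxel axis must correspond to ``grid.flat_indices()``.  Centers
    whose sphere holds fewer than ``min_voxels_per_sphere`` in-mask voxels
    are set to NaN.
    """
    cfg = cfg or SearchlightConfig()
    mask = grid.get_mask()
    mask_flat_idx = grid.flat_indices()
    pos_of_flat = -np.ones(int(np.prod(grid.shape)), dtype=int)
    pos_of_flat[mask_flat_idx] = np.arange(len(mask_flat_idx))
    offsets = sphere_offsets(cfg.radius_mm, grid.voxel_size)
    shape = np.asarray(grid.shape)
    out = np.full((betas.n_subjects,) + tuple(grid.shape), np.nan)
    centers = np.argwhere(mask)
    for center in centers:
        coords = center[None, :] + offsets
        ok = np.all((coords >= 0) & (coords < shape[None, :]), axis=1)
        coords = coords[ok]
        flat = np.ravel_multi_index((coords[:, 0], coords[:, 1], coords[:, 2]), grid.shape)
        pos = pos_of_flat[flat]
        pos = pos[pos >= 0]
        if len(pos) < max(cfg.min_voxels_per_sphere, 3):
            continue
        try:
            res = decorrelation(betas, pos)
        except ValueError:  # constant pattern in a degenerate sphere
            continue
        out[(slice(None),) + tuple(center)] = res.per_subject["delta_r"].to_numpy()
    return out


def group_effect_map(subject_maps: np.ndarray, threshold: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise mean Δr over subjects and a strict-inequality threshold mask.

    The mask is ``mean > threshold`` (values exactly at the threshold are
    excluded).
    """
    if subject_maps.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    mean = np.nanmean(subject_maps, axis=0)
    with np.errstate(invalid="ignore"):
        mask = mean > threshold
    return mean, mask


# ---------------------------------------------------------------------------
# TFCE


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])


def _tfce_one_sided(vol: np.ndarray, cfg: TFCEConfig) -> np.ndarray:
    vmax = float(vol.max(initial=0.0))
    if vmax <= 0:
        return np.zeros_like(vol)
    dh = cfg.dh if cfg.dh is not None else vmax / 100.0
    structure = _structure(cfg.connectivity)
    out = np.zeros_like(vol, dtype=float)
    h = dh
    while h <= vmax + 1e-12:
        above = vol >= h
        labels, n = ndimage.label(above, structure=structure)
        if n == 0:
            break
        sizes = np.bincount(labels.ravel())
        extent = sizes[labels]  # extent of each voxel's component
        out[above] += (extent[above] ** cfg.E) * (h**cfg.H) * dh
        h += dh
    return out


def tfce(volume: np.ndarray, cfg: TFCEConfig | None = None) -> np.ndarray:
    """Threshold-free cluster enhancement.

    TFCE(v) = sum over thresholds h (step dh, up to max) of e_h(v)^E * h^H * dh,
    where e_h(v) is the voxel count of the connected component containing v
    at threshold h.  Positive and negative lobes are enhanced separately and
    recombined with sign.
    """
    cfg = cfg or TFCEConfig()
    vol = np.nan_to_num(np.asarray(volume, dtype=float))
    pos = _tfce_one_sided(np.clip(vol, 0, None), cfg)
    neg = _tfce_one_sided(np.clip(-vol, 0, None), cfg)
    return pos - neg


# ---------------------------------------------------------------------------
# sign-flip permutation inference


def _fwhm_to_sigma_vox(fwhm_mm: float, voxel_size: float) -> float:
    return fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size


def _pseudo_t(
    mean_map: np.ndarray,
    sum_sq: np.ndarray,
    n: int,
    sigma_vox: float,
    mask: np.ndarray,
) -> np.ndarray:
    """One-sample pseudo-t with spatially smoothed variance.

    var = (sum m_i^2 - n mean^2)/(n-1), Gaussian-smoothed within the mask
    (mask-normalised to avoid edge attenuation).
    """
    var = (sum_sq - n * mean_map**2) / (n - 1)
    var = np.clip(var, 0.0, None)
    if sigma_vox > 0:
        m = mask.astype(float)
        sm = ndimage.gaussian_filter(var * m, sigma_vox)
        norm = ndimage.gaussian_filter(m, sigma_vox)
        with np.errstate(invalid="ignore", divide="ignore"):
            var = np.where(mask, sm / norm, 0.0)
    eps = 1e-12 + 1e-6 * float(var[mask].mean() if mask.any() else 0.0)
    t = np.zeros_like(mean_map)
    t[mask] = mean_map[mask] / np.sqrt(var[mask] / n + eps)
    return t


def permutation_fwer(
    subject_maps: np.ndarray,
    cfg: TFCEConfig | None = None,
    variance_fwhm_mm: float = 10.0,
    exhaustive: bool = True,
    voxel_size: float = 1.5,
    mask: np.ndarray | None = None,
    n_perm: int = 1024,
    seed: int = 0,
    max_exhaustive_subjects: int = 20,
) -> PermutationResult:
    """One-sample sign-flip permutation test with TFCE and variance smoothing.

    ``subject_maps`` is (n_subjects, nx, ny, nz).  One-sided on positive
    effects (the directional hypothesis that adaptation decreases pattern
    correlation).  Exhaustive mode enumerates all 2^n sign vectors, identity
    included; FWER p(v) is the proportion of null maxima >= the observed
    TFCE value at v, so p >= 1/2^n everywhere.
    """
    cfg = cfg or TFCEConfig()
    maps = np.nan_to_num(np.asarray(subject_maps, dtype=float))
    n = maps.shape[0]
    if mask is None:
        mask = np.any(np.isfinite(subject_maps) & (subject_maps != 0), axis=0)
        if not mask.any():
            mask = np.ones(maps.shape[1:], dtype=bool)
    if exhaustive:
        if n > max_exhaustive_subjects:
            raise ValueError(
                f"2^{n} sign assignments is too many to enumerate; "
                "call with exhaustive=False and choose n_perm for Monte-Carlo flips"
            )
        # all 2^n sign vectors; the identity (all +1) is the last one
        signs = ((np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1) * 2 - 1
    else:
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 61]))
        signs = rng.choice([-1, 1], size=(n_perm - 1, n))
        signs = np.vstack([np.ones((1, n), dtype=int), signs])
    sigma_vox = _fwhm_to_sigma_vox(variance_fwhm_mm, voxel_size)
    sum_sq = (maps**2).sum(axis=0)  # invariant under sign flips
    flat = maps.reshape(n, -1)
    identity = np.ones(n, dtype=int)
    t_obs = _pseudo_t(flat.mean(axis=0).reshape(maps.shape[1:]), sum_sq, n, sigma_vox, mask)
    if cfg.dh is None:
        # one fixed dh for every permutation (TFCE values depend on dh)
        dh = max(float(np.clip(t_obs, 0, None).max(initial=0.0)), 1e-6) / 100.0
        cfg = TFCEConfig(E=cfg.E, H=cfg.H, dh=dh, connectivity=cfg.connectivity)
    observed_tfce = _tfce_one_sided(np.clip(t_obs, 0, None), cfg)
    max_null = np.empty(len(signs))
    for i, s in enumerate(signs):
        if np.array_equal(s, identity):
            max_null[i] = observed_tfce.max(initial=0.0)
            continue
        mean_map = (s @ flat).reshape(maps.shape[1:]) / n
        t = _pseudo_t(mean_map, sum_sq, n, sigma_vox, mask)
        enh = _tfce_one_sided(np.clip(t, 0, None), cfg)
        max_null[i] = enh.max(initial=0.0)
    p_map = (max_null[None, None, None, :] >= observed_tfce[..., None]).mean(axis=-1)
    p_map = np.where(mask, p_map, 1.0)
    return PermutationResult(
        n_permutations=len(signs),
        max_stat_null=max_null,
        fwer_p_map=p_map,
        observed_tfce=observed_tfce,
        variance_smoothing_fwhm_mm=variance_fwhm_mm,
        exhaustive=exhaustive,
    )


def significance_map(perm: PermutationResult, alpha: float = 0.01) -> np.ndarray:
    """Binary volume of voxels with FWER-corrected p < alpha."""
    return perm.fwer_p_map < alpha
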