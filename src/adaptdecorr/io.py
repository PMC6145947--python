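"""NIfTI and tabular I/O for beta patterns and statistic volumes."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .encoding_sim import CONDITIONS, BetaPatterns, VoxelGrid

__all__ = ["save_volume", "load_volume", "save_beta_patterns", "load_beta_patterns", "volume_to_csv"]


def save_volume(volume: np.ndarray, grid: VoxelGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), grid.affine())
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def volume_to_csv(volume: np.ndarray, path: str | Path) -> None:
    """(x, y, z, value) rows for in-volume finite voxels."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x", "y", "z", "value"])
        for (x, y, z), v in np.ndenumerate(volume):
            if np.isfinite(v):
                w.writerow([x, y, z, f"{v:.9g}"])


def save_beta_patterns(betas: BetaPatterns, grid: VoxelGrid, outdir: str | Path) -> None:
    """One 3D volume per subject/run/condition plus a JSON sidecar manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    flat_idx = grid.flat_indices()
    files = []
    for s in range(betas.n_subjects):
        for r in range(betas.n_runs):
            for ci, cond in enumerate(betas.conditions):
                vol = np.zeros(int(np.prod(grid.shape)), dtype=np.float32)
                vol[flat_idx] = betas.values[s, r, ci]
                name = f"sub-{s:02d}_run-{r:02d}_cond-{cond}.nii.gz"
                save_volume(vol.reshape(grid.shape), grid, outdir / name)
                files.append(name)
    manifest = {
        "n_subjects": betas.n_subjects,
        "n_runs": betas.n_runs,
        "conditions": list(betas.conditions),
        "run_adaptor": betas.run_adaptor.tolist(),
        "noise_sd": betas.noise_sd,
        "grid_shape": list(grid.shape),
        "voxel_size": grid.voxel_size,
        "mask_indices": grid.flat_indices().tolist(),
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_beta_patterns(indir: str | Path) -> tuple[BetaPatterns, VoxelGrid]:
    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        m = json.load(fh)
    shape = tuple(m["grid_shape"])
    mask = np.zeros(int(np.prod(shape)), dtype=bool)
    mask[np.asarray(m["mask_indices"], dtype=int)] = True
    grid = VoxelGrid(shape=shape, voxel_size=m["voxel_size"], mask=mask.reshape(shape))
    flat_idx = grid.flat_indices()
    values = np.zeros((m["n_subjects"], m["n_runs"], len(m["conditions"]), len(flat_idx)))
    for s in range(m["n_subjects"]):
        for r in range(m["n_runs"]):
            for ci, cond in enumerate(m["conditions"]):
                vol, _ = load_volume(indir / f"sub-{s:02d}_run-{r:02d}_cond-{cond}.nii.gz")
                values[s, r, ci] = vol.ravel()[flat_idx]
    betas = BetaPatterns(
        values=values,
        run_adaptor=np.asarray(m["run_adaptor"], dtype="<U1"),
        noise_sd=m["noise_sd"],
        conditions=tuple(m["conditions"]),
        grid=grid,
    )
    return betas, grid
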