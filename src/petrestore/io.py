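"""On-disk exchange formats: NIfTI volumes, HDF5 sinograms, JSON metadata."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import TumourRecord, VoxelGrid
from .projector import SinoGeometry, Sinogram

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_sinogram",
    "load_sinogram",
    "tumour_record_sidecar",
    "write_manifest",
]


def save_nifti(values: np.ndarray, voxel_size, path) -> None:
    """Write a volume as NIfTI with the voxel size in the affine."""
    affine = np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine)
    img.header.set_zooms(tuple(float(s) for s in voxel_size))
    nib.save(img, str(path))


def load_nifti(path, expected_grid: VoxelGrid | None = None):
    """Read a NIfTI volume; returns (values, voxel_size).

    If ``expected_grid`` is given, the stored shape and voxel size must
    match it (voxel size to 1e-3 mm).
    """
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=np.float64)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    if expected_grid is not None:
        if tuple(values.shape) != expected_grid.shape:
            raise ValueError(
                f"{path}: shape {values.shape} does not match grid {expected_grid.shape}"
            )
        if any(abs(a - b) > 1e-3 for a, b in zip(voxel_size, expected_grid.voxel_size)):
            raise ValueError(
                f"{path}: voxel size {voxel_size} does not match grid "
                f"{expected_grid.voxel_size}"
            )
    return values, voxel_size


def save_sinogram(sino: Sinogram, path) -> None:
    with h5py.File(str(path), "w") as f:
        ds = f.create_dataset("sinogram", data=sino.values, compression="gzip")
        g = sino.geometry
        ds.attrs["n_angles"] = g.n_angles
        ds.attrs["n_bins"] = g.n_bins
        ds.attrs["bin_spacing_mm"] = g.bin_spacing
        ds.attrs["n_slices"] = g.n_slices


def load_sinogram(path) -> Sinogram:
    with h5py.File(str(path), "r") as f:
        ds = f["sinogram"]
        geometry = SinoGeometry(
            n_angles=int(ds.attrs["n_angles"]),
            n_bins=int(ds.attrs["n_bins"]),
            bin_spacing=float(ds.attrs["bin_spacing_mm"]),
            n_slices=int(ds.attrs["n_slices"]),
        )
        return Sinogram(values=ds[...], geometry=geometry)


def tumour_record_sidecar(record: TumourRecord, path=None) -> dict:
    """JSON-serialisable tumour metadata (masks excluded); optionally written."""
    doc = {
        "pattern": record.pattern,
        "volume_ml": record.volume_ml,
        "sphericity": record.sphericity,
        "activities": {k: v for k, v in record.activities.items() if v is not None},
        "centroid_voxels": [float(c) for c in record.centroid],
        "half_ratio": record.half_ratio,
        "background_activity": record.background_activity,
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=2))
    return doc


def write_manifest(rows: list[dict], path) -> pd.DataFrame:
    """Dataset manifest: one row per case, written as CSV."""
    df = pd.DataFrame(rows)
    df.to_csv(str(path), index=False)
    return df
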