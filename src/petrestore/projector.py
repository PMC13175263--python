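"""Analytic PET raw-data simulation.

Slice-wise 2D parallel-beam forward projection with object attenuation, an
anisotropic spatially invariant Gaussian point-spread function applied in
image space, scaling of the true-coincidence sinogram to a target prompt
count with a uniform scatter+randoms background, and Poisson sampling.

Both annihilation photons traverse the full line of response, so the
attenuation factor of a line is exp(-integral of mu along the whole line),
independent of the emission point; the trues sinogram therefore factorises
into (line integral of activity) x (line attenuation factor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import ActivityVolume, AttenuationVolume, VoxelGrid

__all__ = [
    "PSFSpec",
    "AcquisitionSpec",
    "SinoGeometry",
    "Sinogram",
    "ContaminatedSinogram",
    "FWHM_TO_SIGMA",
    "AXIAL_PSF_RATIO",
    "DEFAULT_TRUES_FRACTION",
    "default_geometry",
    "forward_project",
    "backproject",
    "apply_image_psf",
    "scale_and_contaminate",
    "poisson_sample",
    "sample_psf_dataset2",
    "compute_nec",
]

#: conversion FWHM -> Gaussian sigma, 2 sqrt(2 ln 2)
FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))
#: fixed ratio between transaxial and axial PSF FWHM of the modelled scanner
AXIAL_PSF_RATIO = 1.125
#: fraction of prompts that are true coincidences; chosen so that 100e6
#: prompts correspond to 12.4e6 noise-equivalent counts (NEC = T^2 / P)
DEFAULT_TRUES_FRACTION = 0.352


@dataclass(frozen=True)
class PSFSpec:
    """Anisotropic Gaussian PSF: transaxial (x, y) and axial (z) FWHM in mm."""

    fwhm_transaxial: float
    fwhm_axial: float

    def __post_init__(self) -> None:
        if self.fwhm_transaxial < 0 or self.fwhm_axial < 0:
            raise ValueError("PSF FWHM must be non-negative")

    @classmethod
    def from_transaxial(cls, fwhm_transaxial: float) -> "PSFSpec":
        return cls(fwhm_transaxial, fwhm_transaxial / AXIAL_PSF_RATIO)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Counting statistics of one simulated acquisition."""

    total_prompts: float
    trues_fraction: float = DEFAULT_TRUES_FRACTION
    psf: PSFSpec = PSFSpec(4.5, 4.0)
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if self.total_prompts <= 0:
            raise ValueError("total prompts must be positive")
        if not (0 < self.trues_fraction <= 1):
            raise ValueError("trues fraction must be in (0, 1]")

    @property
    def expected_trues(self) -> float:
        return self.trues_fraction * self.total_prompts


@dataclass(frozen=True)
class SinoGeometry:
    """Parallel-beam sinogram geometry: angles over [0, 180) degrees."""

    n_angles: int
    n_bins: int
    bin_spacing: float  # mm
    n_slices: int

    def __post_init__(self) -> None:
        if self.n_angles < 1 or self.n_bins < 1 or self.n_slices < 1:
            raise ValueError("sinogram geometry dimensions must be >= 1")
        if self.bin_spacing <= 0:
            raise ValueError("bin spacing must be positive")

    @property
    def angles_deg(self) -> np.ndarray:
        return np.linspace(0.0, 180.0, self.n_angles, endpoint=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_angles, self.n_bins, self.n_slices)


@dataclass
class Sinogram:
    """Counts (or expected counts) indexed (angle, radial bin, axial slice)."""

    values: np.ndarray
    geometry: SinoGeometry

    def __post_init__(self) -> None:
        if tuple(self.values.shape) != self.geometry.shape:
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry "
                f"{self.geometry.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("sinogram values must be non-negative")

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class ContaminatedSinogram:
    """Expected prompts = scaled trues + uniform scatter/randoms background."""

    expected: Sinogram
    background: Sinogram
    trues_scale: float


def default_geometry(grid: VoxelGrid, n_angles: int = 168) -> SinoGeometry:
    """Radial bins at the transaxial voxel pitch spanning the grid diagonal."""
    nx, ny, nz = grid.shape
    n_bins = int(math.ceil(math.hypot(nx, ny)))
    return SinoGeometry(
        n_angles=n_angles,
        n_bins=n_bins,
        bin_spacing=grid.voxel_size[0],
        n_slices=nz,
    )


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def _pad_to_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    nx, ny, nz = values.shape
    out = np.zeros((n_bins, n_bins, nz), dtype=np.float32)
    ox = (n_bins - nx) // 2
    oy = (n_bins - ny) // 2
    out[ox : ox + nx, oy : oy + ny, :] = values
    return out


def _crop_from_bins(values: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = shape
    n_bins = values.shape[0]
    ox = (n_bins - nx) // 2
    oy = (n_bins - ny) // 2
    return values[ox : ox + nx, oy : oy + ny, :]


def _rotate(vol: np.ndarray, angle_deg: float) -> np.ndarray:
    return ndimage.rotate(
        vol, angle_deg, axes=(0, 1), reshape=False, order=1, mode="constant",
        cval=0.0, prefilter=False,
    )


def attenuation_factors(mu: AttenuationVolume, geometry: SinoGeometry) -> np.ndarray:
    """Per-LOR attenuation factors exp(-integral mu dl), shape (angle, bin, slice)."""
    grid = mu.grid
    dl = grid.voxel_size[1]  # ray step along the (rotated) y axis, mm
    mu_p = _pad_to_bins(mu.values.astype(np.float32), geometry.n_bins)
    att = np.empty(geometry.shape, dtype=np.float32)
    for i, ang in enumerate(geometry.angles_deg):
        line = _rotate(mu_p, ang).sum(axis=1) * dl
        att[i] = np.exp(-line)
    return att


def forward_project(
    activity: ActivityVolume,
    mu: AttenuationVolume | None,
    geometry: SinoGeometry,
    att: np.ndarray | None = None,
) -> Sinogram:
    """Expected (unscaled) true-coincidence sinogram.

    Linear in the activity; attenuation factors lie in (0, 1].  Precomputed
    attenuation factors can be passed to avoid re-rotating the mu map.
    """
    grid = activity.grid
    if mu is not None and mu.grid != grid:
        raise ValueError("activity and attenuation grids differ")
    if att is None:
        if mu is None:
            att = np.ones(geometry.shape, dtype=np.float32)
        else:
            att = attenuation_factors(mu, geometry)
    dl = grid.voxel_size[1]
    act_p = _pad_to_bins(activity.values.astype(np.float32), geometry.n_bins)
    values = np.empty(geometry.shape, dtype=np.float32)
    for i, ang in enumerate(geometry.angles_deg):
        values[i] = _rotate(act_p, ang).sum(axis=1) * dl
    values *= att
    np.maximum(values, 0.0, out=values)
    return Sinogram(values=values, geometry=geometry)


def backproject(
    values: np.ndarray,
    angle_indices,
    geometry: SinoGeometry,
    grid: VoxelGrid,
) -> np.ndarray:
    """Adjoint of :func:`forward_project` restricted to a set of angles.

    ``values`` holds one (bin, slice) plane per listed angle.
    """
    dl = grid.voxel_size[1]
    n = geometry.n_bins
    acc = np.zeros((n, n, grid.shape[2]), dtype=np.float32)
    angles = geometry.angles_deg
    for plane, idx in zip(values, angle_indices):
        smear = np.broadcast_to(
            plane[:, None, :] * dl, (n, n, grid.shape[2])
        ).astype(np.float32)
        acc += _rotate(smear, -angles[idx])
    return _crop_from_bins(acc, grid.shape).astype(np.float64)


# ---------------------------------------------------------------------------
# PSF
# ---------------------------------------------------------------------------

def apply_image_psf(values: np.ndarray, psf: PSFSpec, voxel_size) -> np.ndarray:
    """Gaussian blur with sigma = FWHM / (2 sqrt(2 ln 2)) per axis.

    Transaxial FWHM applies along x and y, axial along z.  A zero FWHM is
    the identity.  Integral mass is preserved for interior sources (the
    filter uses zero boundary, so only flux leaving the volume is lost).
    """
    if psf.fwhm_transaxial < 0 or psf.fwhm_axial < 0:
        raise ValueError("PSF FWHM must be non-negative")
    if psf.fwhm_transaxial == 0 and psf.fwhm_axial == 0:
        return values.copy()
    st = psf.fwhm_transaxial / FWHM_TO_SIGMA
    sa = psf.fwhm_axial / FWHM_TO_SIGMA
    sigma_vox = (st / voxel_size[0], st / voxel_size[1], sa / voxel_size[2])
    return ndimage.gaussian_filter(values, sigma=sigma_vox, mode="constant", truncate=4.0)


# ---------------------------------------------------------------------------
# counting statistics
# ---------------------------------------------------------------------------

def scale_and_contaminate(trues: Sinogram, acq: AcquisitionSpec) -> ContaminatedSinogram:
    """Scale trues to the target statistics and add scatter+randoms.

    The trues sinogram is scaled so its expected total equals
    ``trues_fraction * total_prompts``; a spatially uniform background
    supplies the remaining prompts, so the expected prompt total equals
    ``total_prompts`` exactly.
    """
    total = trues.total
    if total <= 0:
        raise ValueError("trues sinogram is identically zero")
    scale = acq.expected_trues / total
    n_lor = float(np.prod(trues.geometry.shape))
    bg_level = (1.0 - acq.trues_fraction) * acq.total_prompts / n_lor
    background = np.full(trues.geometry.shape, bg_level, dtype=np.float64)
    expected = trues.values.astype(np.float64) * scale + background
    return ContaminatedSinogram(
        expected=Sinogram(values=expected, geometry=trues.geometry),
        background=Sinogram(values=background, geometry=trues.geometry),
        trues_scale=scale,
    )


def poisson_sample(expected: Sinogram, seed: int) -> Sinogram:
    """Independent Poisson draws per sinogram bin; reproducible from the seed."""
    if np.any(~np.isfinite(expected.values)) or np.any(expected.values < 0):
        raise ValueError("expected sinogram must be finite and non-negative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected.values).astype(np.float64)
    return Sinogram(values=counts, geometry=expected.geometry)


def sample_psf_dataset2(rng: np.random.Generator) -> PSFSpec:
    """Draw a per-case PSF: transaxial ~ N(4.5, 0.2^2) mm, axial = transaxial/1.125."""
    t = float(rng.normal(4.5, 0.2))
    while t <= 0:  # negligible probability; resample for safety
        t = float(rng.normal(4.5, 0.2))
    return PSFSpec.from_transaxial(t)


def compute_nec(trues_total: float, prompts_total: float) -> float:
    """Noise-equivalent counts NEC = T^2 / P."""
    if prompts_total <= 0:
        raise ValueError("prompt total must be positive")
    if trues_total < 0 or trues_total > prompts_total:
        raise ValueError("trues must lie in [0, prompts]")
    return trues_total**2 / prompts_total
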