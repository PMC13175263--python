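"""Ground-truth phantom generation.

Builds a procedural torso (body, lungs, heart, spine and ribs) on a voxel
grid, samples tumour-like 3D shapes with controllable volume and sphericity,
fills them with one of three activity patterns (uniform, split in halves,
hollow with a necrotic core) and places them at random positions inside the
left lung.  The background activity of every assembled ground-truth image is
scaled so that the tumour-to-background activity ratio is exactly 10.

Activity is expressed in kBq/ml, attenuation as 511 keV linear attenuation
coefficients in 1/mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

__all__ = [
    "VoxelGrid",
    "TumourSpec",
    "TumourRecord",
    "ActivityVolume",
    "AttenuationVolume",
    "TorsoPhantom",
    "DEFAULT_ORGAN_TABLE",
    "TUMOUR_ACTIVITY_RANGE",
    "TUMOUR_VOLUME_RANGE",
    "TBR",
    "make_torso_phantom",
    "sample_tumour_shape",
    "apply_pattern",
    "assemble_ground_truth",
    "crop_around_tumour",
    "embed_patch",
]

#: tumour-to-background activity ratio enforced on every ground-truth image
TBR = 10.0
#: tumour activity sampling range, kBq/ml
TUMOUR_ACTIVITY_RANGE = (6.0, 35.0)
#: representable tumour volume range, ml
TUMOUR_VOLUME_RANGE = (0.01, 200.0)

#: per-organ (activity kBq/ml, linear attenuation 1/mm) defaults at 511 keV.
#: Activities are relative levels; the whole background field is rescaled at
#: assembly time so the lung background is 1/10 of the maximum tumour activity.
DEFAULT_ORGAN_TABLE: Mapping[str, tuple[float, float]] = {
    "soft_tissue": (2.0, 0.0096),
    "lung": (0.8, 0.0026),
    "heart": (6.0, 0.0096),
    "bone": (1.5, 0.0150),
}

_26CONN = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D voxel grid: shape in voxels and voxel size in mm."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"grid shape must be three dimensions >= 1, got {self.shape}")
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(s) for s in self.voxel_size))

    @property
    def voxel_volume_ml(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz / 1000.0

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.voxel_size))

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre world coordinates (origin at the volume corner)."""
        axes = [
            (np.arange(n, dtype=np.float64) + 0.5) * s
            for n, s in zip(self.shape, self.voxel_size)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))


@dataclass(frozen=True)
class ActivityVolume:
    """Radioactivity concentration field (kBq/ml) on a voxel grid."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_field(self.values, self.grid)


@dataclass(frozen=True)
class AttenuationVolume:
    """511 keV linear attenuation coefficient field (1/mm) on a voxel grid."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_field(self.values, self.grid)


def _check_field(values: np.ndarray, grid: VoxelGrid) -> None:
    if tuple(values.shape) != grid.shape:
        raise ValueError(f"field shape {values.shape} does not match grid {grid.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError("field contains non-finite values")
    if np.any(values < 0):
        raise ValueError("field contains negative values")


@dataclass(frozen=True)
class TumourSpec:
    """Parameters of one simulated tumour."""

    pattern: str
    target_volume_ml: float
    primary_activity: float
    secondary_activity: float | None = None
    elongation: float = 0.0
    perturbation: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in ("uniform", "halves", "hollow"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        lo, hi = TUMOUR_VOLUME_RANGE
        if not (lo <= self.target_volume_ml <= hi):
            raise ValueError(
                f"target volume {self.target_volume_ml} ml outside [{lo}, {hi}] ml"
            )
        if self.primary_activity <= 0:
            raise ValueError("primary activity must be positive")
        if self.pattern == "halves":
            if self.secondary_activity is None or self.secondary_activity <= 0:
                raise ValueError("halves pattern requires a positive secondary activity")
        if self.elongation < 0:
            raise ValueError("elongation must be >= 0")

    @property
    def max_activity(self) -> float:
        if self.secondary_activity is None:
            return self.primary_activity
        return max(self.primary_activity, self.secondary_activity)


@dataclass
class TumourRecord:
    """A realised tumour: mask on the full grid plus metadata."""

    mask: np.ndarray
    pattern: str
    volume_ml: float
    sphericity: float
    activities: dict
    centroid: tuple[float, float, float]
    half_ratio: float | None = None
    half_masks: tuple[np.ndarray, np.ndarray] | None = None
    core_mask: np.ndarray | None = None
    shell_mask: np.ndarray | None = None
    background_activity: float | None = None


@dataclass
class TorsoPhantom:
    activity: ActivityVolume
    attenuation: AttenuationVolume
    lung_mask: np.ndarray
    organ_masks: dict = field(default_factory=dict)
    organ_table: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ORGAN_TABLE)
    )


# ---------------------------------------------------------------------------
# torso phantom
# ---------------------------------------------------------------------------

def _ellipsoid(grid: VoxelGrid, centre_frac, semi_frac) -> np.ndarray:
    """Boolean ellipsoid mask; centre and semi-axes as fractions of the extent."""
    xs, ys, zs = grid.coords_mm()
    ex, ey, ez = grid.extent_mm
    cx, cy, cz = centre_frac[0] * ex, centre_frac[1] * ey, centre_frac[2] * ez
    ax, ay, az = semi_frac[0] * ex, semi_frac[1] * ey, semi_frac[2] * ez
    return ((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2 + ((zs - cz) / az) ** 2 <= 1.0


def make_torso_phantom(
    grid: VoxelGrid,
    organ_table: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> TorsoPhantom:
    """Procedural torso: body ellipse, two lungs, heart, spine and ribs.

    The +x direction is the patient's left, +y posterior.  Returns the
    activity and attenuation volumes together with the left-lung mask used
    for tumour placement.  Raises if the grid is too small to hold the
    organs.
    """
    if min(grid.shape[:2]) < 16 or grid.shape[2] < 8:
        raise ValueError(f"grid {grid.shape} too small to contain the torso organs")
    table = dict(DEFAULT_ORGAN_TABLE)
    if organ_table:
        table.update(organ_table)

    xs, ys, zs = grid.coords_mm()
    ex, ey, ez = grid.extent_mm

    # body: elliptic cylinder spanning the full axial extent
    body = ((xs - 0.5 * ex) / (0.47 * ex)) ** 2 + ((ys - 0.5 * ey) / (0.42 * ey)) ** 2 <= 1.0

    lung_l = _ellipsoid(grid, (0.70, 0.46, 0.50), (0.18, 0.30, 0.44))
    lung_r = _ellipsoid(grid, (0.30, 0.46, 0.50), (0.18, 0.30, 0.44))
    heart = _ellipsoid(grid, (0.44, 0.40, 0.42), (0.11, 0.13, 0.22))

    # spine: posterior cylinder through the whole volume
    spine = ((xs - 0.5 * ex) / (0.06 * ex)) ** 2 + ((ys - 0.82 * ey) / (0.07 * ey)) ** 2 <= 1.0
    # ribs: thin shell just inside the body outline, in periodic axial bands
    rho = ((xs - 0.5 * ex) / (0.45 * ex)) ** 2 + ((ys - 0.5 * ey) / (0.40 * ey)) ** 2
    band = np.sin(zs / max(ez / 6.0, 1.0) * 2.0 * np.pi) > 0.2
    ribs = (rho >= 0.86) & (rho <= 1.0) & band & body
    bone = (spine & body) | ribs

    # priority: bone > heart > lung > soft tissue
    lungs = (lung_l | lung_r) & body & ~bone & ~heart
    heart_m = heart & body & ~bone
    soft = body & ~lungs & ~heart_m & ~bone

    left_lung = lung_l & lungs
    if not left_lung.any() or not heart_m.any() or not bone.any():
        raise ValueError(f"grid {grid.shape} too small to contain the torso organs")

    activity = np.zeros(grid.shape, dtype=np.float64)
    mu = np.zeros(grid.shape, dtype=np.float64)
    for name, mask in (
        ("soft_tissue", soft),
        ("lung", lungs),
        ("heart", heart_m),
        ("bone", bone & body),
    ):
        a, m = table[name]
        activity[mask] = a
        mu[mask] = m

    organ_masks = {
        "body": body,
        "lung_left": left_lung,
        "lung_right": lung_r & lungs,
        "heart": heart_m,
        "bone": bone & body,
        "soft_tissue": soft,
    }
    return TorsoPhantom(
        activity=ActivityVolume(grid, activity),
        attenuation=AttenuationVolume(grid, mu),
        lung_mask=left_lung,
        organ_masks=organ_masks,
        organ_table=table,
    )


# ---------------------------------------------------------------------------
# tumour shape sampling
# ---------------------------------------------------------------------------

def _rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _smooth_noise(shape: tuple[int, int, int], rng: np.random.Generator) -> np.ndarray:
    """Smooth random field in [-1, 1]: low-pass filtered white noise."""
    white = rng.normal(size=shape)
    sigma = [max(n / 5.0, 1.0) for n in shape]
    f = ndimage.gaussian_filter(white, sigma=sigma, mode="nearest")
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_26CONN)
    if n <= 1:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == np.argmax(counts)


def sample_tumour_shape(spec: TumourSpec, grid: VoxelGrid) -> np.ndarray:
    """Sample a single connected tumour mask with the requested volume.

    The shape is an ellipsoid (axis ratio set by ``spec.elongation``) with a
    smooth random radial perturbation, voxelized on ``grid`` and centred in
    it.  A bisection on the global scale factor matches the voxelized volume
    to ``spec.target_volume_ml`` to within roughly one surface layer of
    voxels.  Deterministic given (spec, spec.seed).
    """
    vox_ml = grid.voxel_volume_ml
    target_vox = spec.target_volume_ml / vox_ml
    if target_vox < 1.0:
        raise ValueError(
            f"target volume {spec.target_volume_ml} ml is below the minimum representable "
            f"volume of one voxel ({vox_ml:.4g} ml) on this grid"
        )
    rng = np.random.default_rng(spec.seed)

    r_eq = (3.0 * spec.target_volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)  # mm
    f = 1.0 + spec.elongation
    semi = np.array([r_eq * f, r_eq, r_eq / f])  # volume-preserving axis ratios
    rot = _rotation_matrix(rng)

    # local cube: generous bounding box around the largest possible shape
    margin = 1.6 * (1.0 + spec.perturbation)
    half_mm = semi.max() * margin
    half_vox = [int(math.ceil(half_mm / s)) + 2 for s in grid.voxel_size]
    half_vox = [min(h, (n - 1) // 2) for h, n in zip(half_vox, grid.shape)]
    if min(half_vox) < 1:
        raise ValueError(
            f"tumour of {spec.target_volume_ml} ml does not fit on grid {grid.shape}"
        )
    local_shape = tuple(2 * h + 1 for h in half_vox)

    axes = [
        (np.arange(n) - n // 2) * s
        for n, s in zip(local_shape, grid.voxel_size)
    ]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)  # (...,3) mm
    local = pts @ rot  # rotate into the ellipsoid frame
    quad = np.sum((local / semi) ** 2, axis=-1)

    noise = _smooth_noise(local_shape, rng)
    # implicit surface: quad <= s^2 * (1 + p * noise); monotone in s
    field = quad / np.clip(1.0 + spec.perturbation * noise, 0.2, None)

    def count(s: float) -> int:
        return int(np.count_nonzero(field <= s * s))

    lo, hi = 0.05, margin
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if count(mid) < target_vox:
            lo = mid
        else:
            hi = mid
    best = min((lo, hi), key=lambda s: abs(count(s) - target_vox))
    local_mask = _largest_component(field <= best * best)
    if not local_mask.any():
        local_mask = quad <= np.partition(quad.ravel(), 0)[0] + 1e-12  # centre voxel

    mask = np.zeros(grid.shape, dtype=bool)
    centre = [n // 2 for n in grid.shape]
    sl = tuple(
        slice(c - h, c + h + 1) for c, h in zip(centre, half_vox)
    )
    mask[sl] = local_mask
    return mask


# ---------------------------------------------------------------------------
# activity patterns
# ---------------------------------------------------------------------------

def _equivalent_radius_mm(mask: np.ndarray, grid: VoxelGrid) -> float:
    v_mm3 = np.count_nonzero(mask) * grid.voxel_volume_ml * 1000.0
    return (3.0 * v_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)


def apply_pattern(
    mask: np.ndarray,
    spec: TumourSpec,
    background_activity: float,
    grid: VoxelGrid,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Fill a tumour mask with its activity pattern.

    Returns the full-grid activity patch (zero outside the mask) and a dict
    of pattern bookkeeping (half masks and ratio for ``halves``, core and
    shell masks for ``hollow``).

    * uniform -- every mask voxel gets the primary activity.
    * halves  -- the mask is split by a plane through its centroid with a
      random orientation; each side gets one of the two activities.
    * hollow  -- voxels deeper than half the equivalent-sphere radius from
      the surface form a necrotic core at background activity; the outer
      shell gets the primary activity.
    """
    if not mask.any():
        raise ValueError("tumour mask is empty")
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    patch = np.zeros(grid.shape, dtype=np.float64)
    info: dict = {}

    if spec.pattern == "uniform":
        patch[mask] = spec.primary_activity
        return patch, info

    if spec.pattern == "halves":
        if np.count_nonzero(mask) < 2:
            raise ValueError("cannot split a single-voxel tumour into halves")
        idx = np.argwhere(mask).astype(np.float64) * np.asarray(grid.voxel_size)
        centroid = idx.mean(axis=0)
        for _ in range(64):
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            side = (idx - centroid) @ n >= 0.0
            if side.any() and not side.all():
                break
        else:
            raise ValueError("could not split tumour mask into two non-empty halves")
        half_a = np.zeros(grid.shape, dtype=bool)
        half_b = np.zeros(grid.shape, dtype=bool)
        coords = np.argwhere(mask)
        half_a[tuple(coords[side].T)] = True
        half_b[tuple(coords[~side].T)] = True
        patch[half_a] = spec.primary_activity
        patch[half_b] = spec.secondary_activity
        hi = max(spec.primary_activity, spec.secondary_activity)
        lo = min(spec.primary_activity, spec.secondary_activity)
        info["half_masks"] = (half_a, half_b)
        info["half_ratio"] = hi / lo
        return patch, info

    # hollow
    depth = ndimage.distance_transform_edt(mask, sampling=grid.voxel_size)
    core = depth > _equivalent_radius_mm(mask, grid) / 2.0
    shell = mask & ~core
    patch[shell] = spec.primary_activity
    patch[core] = background_activity
    info["core_mask"] = core
    info["shell_mask"] = shell
    return patch, info


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _translate_mask(mask: np.ndarray, shift: tuple[int, int, int]) -> np.ndarray:
    out = np.zeros_like(mask)
    src = []
    dst = []
    for n, s in zip(mask.shape, shift):
        lo_src = max(0, -s)
        hi_src = min(n, n - s)
        if hi_src <= lo_src:
            return out
        src.append(slice(lo_src, hi_src))
        dst.append(slice(lo_src + s, hi_src + s))
    out[tuple(dst)] = mask[tuple(src)]
    return out


def assemble_ground_truth(
    torso: TorsoPhantom,
    mask: np.ndarray,
    spec: TumourSpec,
    placement_seed: int = 0,
) -> tuple[ActivityVolume, TumourRecord]:
    """Place a tumour in the left lung and build the ground-truth activity.

    The torso background activity field is rescaled so the lung tissue
    activity equals one tenth of the maximum tumour activity (tumour to
    background ratio exactly 10); the tumour pattern then overwrites the
    background inside the mask.  Placement is uniform over all positions at
    which the translated mask lies entirely inside the left lung.
    """
    from . import quantify  # metric helpers; no circular import at module level

    grid = torso.activity.grid
    if mask.shape != grid.shape:
        raise ValueError("tumour mask is not on the torso grid")
    if not mask.any():
        raise ValueError("tumour mask is empty")
    rng = np.random.default_rng(placement_seed)

    # admissible centre shifts: translated mask must stay inside the lung
    outside = (~torso.lung_mask).astype(np.float32)
    kernel = mask[::-1, ::-1, ::-1].astype(np.float32)
    overlap = fftconvolve(outside, kernel, mode="same")
    admissible = overlap < 0.5
    if not admissible.any():
        raise ValueError(
            f"tumour ({np.count_nonzero(mask)} voxels) does not fit inside the left lung"
        )
    centres = np.argwhere(admissible)
    centre = centres[rng.integers(len(centres))]

    com = np.argwhere(mask).mean(axis=0)
    anchor = np.array([n // 2 for n in grid.shape])
    # fftconvolve('same') centres the flipped kernel on the array midpoint,
    # so the admissible map is indexed by the position of the mask's centre voxel
    shift = tuple(int(c - a) for c, a in zip(centre, anchor))
    placed = _translate_mask(mask, shift)
    if np.count_nonzero(placed) != np.count_nonzero(mask):
        raise ValueError("tumour placement clipped the mask; lung region too small")

    background = spec.max_activity / TBR
    patch, info = apply_pattern(placed, spec, background, grid)

    lung_activity = torso.organ_table["lung"][0]
    scale = background / lung_activity
    values = torso.activity.values * scale
    values[placed] = patch[placed]

    volume_ml = np.count_nonzero(placed) * grid.voxel_volume_ml
    record = TumourRecord(
        mask=placed,
        pattern=spec.pattern,
        volume_ml=volume_ml,
        sphericity=quantify.sphericity(placed, grid.voxel_size),
        activities={
            "primary": spec.primary_activity,
            "secondary": spec.secondary_activity,
            "background": background,
        },
        centroid=tuple(np.argwhere(placed).mean(axis=0)),
        half_ratio=info.get("half_ratio"),
        half_masks=info.get("half_masks"),
        core_mask=info.get("core_mask"),
        shell_mask=info.get("shell_mask"),
        background_activity=background,
    )
    return ActivityVolume(grid, values), record


# ---------------------------------------------------------------------------
# cropping
# ---------------------------------------------------------------------------

def crop_around_tumour(
    values: np.ndarray,
    centroid: tuple[float, float, float],
    crop_shape: tuple[int, int, int],
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Crop a box of ``crop_shape`` centred on the tumour centroid.

    The crop is clamped to stay inside the volume, so the output shape is
    exactly ``crop_shape``.  Returns the patch and its corner offset, so the
    patch can be embedded back with :func:`embed_patch`.
    """
    if any(c > n for c, n in zip(crop_shape, values.shape)):
        raise ValueError(f"crop shape {crop_shape} larger than volume {values.shape}")
    offset = []
    for c, n, ctr in zip(crop_shape, values.shape, centroid):
        start = int(round(ctr)) - c // 2
        start = min(max(start, 0), n - c)
        offset.append(start)
    sl = tuple(slice(o, o + c) for o, c in zip(offset, crop_shape))
    return values[sl].copy(), tuple(offset)


def embed_patch(values: np.ndarray, patch: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    """Write ``patch`` back into a copy of ``values`` at ``offset``."""
    out = values.copy()
    sl = tuple(slice(o, o + c) for o, c in zip(offset, patch.shape))
    out[sl] = patch
    return out
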