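"""On-the-fly 3D augmentation for brain derivative volumes.

Five augmentation families, each drawn fresh per training sample per epoch:

* **Flipping** — mirror the x-axis with probability ``flip_probability``.
* **Rotation** — per-axis angles drawn uniformly from ±``rotation_max_deg``
  (the studied bounds are 7.5, 15, 30 and 45 degrees).
* **Scaling** — per-axis zoom factors drawn uniformly from
  1 ± ``scale_max_fraction`` (±10% or ±20%).
* **Brightness** — power-law intensity change ``I_new = g * I**gamma`` with
  gain g and exponent gamma drawn uniformly from [0.8, 1.2].
* **Elastic deformation** — per-voxel displacements interpolated (order-3
  spline) from a coarse square control grid whose displacements are drawn
  i.i.d. Normal(0, sigma^2) per axis, sigma in {2, 4, 6, 8} voxels.

Rotation and scaling are realized as a single pull-back affine resampling
(one interpolation); the full pipeline composes flip, then affine, then
elastic warp, then brightness. Every stage reduces to the exact identity at
its identity parameters (0 degrees, unit scale, sigma = 0, g = gamma = 1),
so an all-identity configuration is a bitwise no-op.

All functions accept either a :class:`~augbench.volumes.BrainVolume` or a
bare 3D array and return the same kind.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .volumes import BrainVolume

ROTATION_BOUNDS_DEG = (0.0, 7.5, 15.0, 30.0, 45.0)
SCALE_BOUNDS_FRACTION = (0.0, 0.1, 0.2)
ELASTIC_SIGMAS_VOXELS = (0.0, 2.0, 4.0, 6.0, 8.0)


def _unwrap(volume) -> tuple[np.ndarray, Optional[BrainVolume]]:
    if isinstance(volume, BrainVolume):
        return volume.data, volume
    arr = np.asarray(volume)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {arr.shape}")
    return arr, None


def _rewrap(data: np.ndarray, template: Optional[BrainVolume]):
    if template is None:
        return data
    return template.with_data(data)


@dataclass
class AugmentationConfig:
    """Which augmentation families are active and their parameter ranges."""

    flip_enabled: bool = False
    flip_probability: float = 0.5
    rotation_max_deg: float = 0.0
    scale_max_fraction: float = 0.0
    brightness_enabled: bool = False
    gain_range: tuple[float, float] = (0.8, 1.2)
    gamma_range: tuple[float, float] = (0.8, 1.2)
    elastic_sigma_voxels: float = 0.0
    elastic_grid_spacing_voxels: int = 8
    resample_order: int = 1
    field_spline_order: int = 3
    fill_value: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip_probability must lie in [0, 1]")
        if self.rotation_max_deg < 0 or self.scale_max_fraction < 0:
            raise ValueError("rotation/scale bounds must be non-negative")
        if self.elastic_sigma_voxels < 0:
            raise ValueError("elastic_sigma_voxels must be non-negative")
        if self.elastic_grid_spacing_voxels < 1:
            raise ValueError("elastic_grid_spacing_voxels must be positive")
        for name, rng_ in (("gain_range", self.gain_range), ("gamma_range", self.gamma_range)):
            lo, hi = rng_
            if lo > hi:
                raise ValueError(f"{name} lower bound exceeds upper bound")
            if lo <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def affine_active(self) -> bool:
        return self.rotation_max_deg > 0 or self.scale_max_fraction > 0

    @property
    def identity(self) -> bool:
        return not (
            self.flip_enabled
            or self.affine_active
            or self.brightness_enabled
            or self.elastic_sigma_voxels > 0
        )


@dataclass
class DisplacementField:
    """Per-voxel displacement 3-vectors in voxel units, shape (3, x, y, z)."""

    displacements: np.ndarray

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.ndim != 4 or self.displacements.shape[0] != 3:
            raise ValueError(
                f"displacements must have shape (3, x, y, z), got {self.displacements.shape}"
            )

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.displacements.shape[1:]  # type: ignore[return-value]


@dataclass
class AugmentationSample:
    """One concrete random draw from an :class:`AugmentationConfig`."""

    flip_applied: bool = False
    angles_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale_factors: tuple[float, float, float] = (1.0, 1.0, 1.0)
    gain: float = 1.0
    gamma: float = 1.0
    field: Optional[DisplacementField] = None


def sample_augmentation(
    config: AugmentationConfig,
    rng: np.random.Generator,
    shape: Sequence[int],
) -> AugmentationSample:
    """Draw one concrete augmentation from the configured uniform ranges.

    Disabled families keep their identity value and consume no random
    numbers, so adding a family never perturbs the draws of the others
    retroactively within a single call.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise ValueError(f"shape must be 3 positive integers, got {shape}")

    flip_applied = bool(config.flip_enabled and rng.random() < config.flip_probability)

    if config.rotation_max_deg > 0:
        a = config.rotation_max_deg
        angles = tuple(rng.uniform(-a, a, size=3))
    else:
        angles = (0.0, 0.0, 0.0)

    if config.scale_max_fraction > 0:
        f = config.scale_max_fraction
        scales = tuple(rng.uniform(1.0 - f, 1.0 + f, size=3))
    else:
        scales = (1.0, 1.0, 1.0)

    if config.brightness_enabled:
        gain = float(rng.uniform(*config.gain_range))
        gamma = float(rng.uniform(*config.gamma_range))
    else:
        gain, gamma = 1.0, 1.0

    field = None
    if config.elastic_sigma_voxels > 0:
        field = make_displacement_field(
            shape,
            sigma=config.elastic_sigma_voxels,
            grid_spacing=config.elastic_grid_spacing_voxels,
            rng=rng,
            spline_order=config.field_spline_order,
        )

    return AugmentationSample(
        flip_applied=flip_applied,
        angles_deg=angles,  # type: ignore[arg-type]
        scale_factors=scales,  # type: ignore[arg-type]
        gain=gain,
        gamma=gamma,
        field=field,
    )


def flip_x(volume):
    """Mirror the volume along the first (x) axis. Involution."""
    data, template = _unwrap(volume)
    return _rewrap(data[::-1].copy(), template)


def _rotation_matrix(axis: int, angle_deg: float) -> np.ndarray:
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    m = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    m[i, i] = c
    m[j, j] = c
    # right-handed rotation about the given axis
    sign = -1.0 if axis == 1 else 1.0
    m[i, j] = -s * sign
    m[j, i] = s * sign
    return m


def build_affine(sample: AugmentationSample, center_voxel: Sequence[float]) -> np.ndarray:
    """4x4 matrix mapping *output* voxel coordinates to *input* coordinates.

    Forward transform: rotate about the volume center, axes composed in the
    fixed order x, then y, then z, followed by per-axis scaling about the
    same center. The returned pull-back matrix is its inverse, ready for
    resampling. Zero angles and unit scales give the exact identity.
    """
    center = np.asarray(center_voxel, dtype=float)
    angles = sample.angles_deg
    scales = np.asarray(sample.scale_factors, dtype=float)

    if all(a == 0.0 for a in angles) and np.all(scales == 1.0):
        return np.eye(4)

    r = (
        _rotation_matrix(2, angles[2])
        @ _rotation_matrix(1, angles[1])
        @ _rotation_matrix(0, angles[0])
    )
    forward = np.diag(scales) @ r
    inv = np.linalg.inv(forward)

    out = np.eye(4)
    out[:3, :3] = inv
    out[:3, 3] = center - inv @ center
    return out


def apply_affine(volume, matrix: np.ndarray, order: int = 1, fill: float = 0.0):
    """Resample a volume through an output-to-input 4x4 voxel map.

    Identity matrices short-circuit to an exact copy; voxels mapping outside
    the input grid receive ``fill``.
    """
    data, template = _unwrap(volume)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (4, 4):
        raise ValueError("matrix must be 4x4")
    if abs(np.linalg.det(matrix[:3, :3])) < 1e-12:
        raise np.linalg.LinAlgError("affine matrix is singular")
    if np.array_equal(matrix, np.eye(4)):
        return _rewrap(data.copy(), template)
    out = ndimage.affine_transform(
        data.astype(float, copy=False),
        matrix=matrix[:3, :3],
        offset=matrix[:3, 3],
        output_shape=data.shape,
        order=order,
        mode="grid-constant",
        cval=fill,
        prefilter=order > 1,
    )
    return _rewrap(out.astype(data.dtype, copy=False), template)


def brightness_transform(volume, gain: float, gamma: float):
    """Power-law intensity change ``v -> gain * max(v, 0)**gamma``.

    Negative inputs are clamped to 0 first (derivative maps such as REHO are
    non-negative; non-integer powers of negatives are undefined). Exact
    identity at gain = gamma = 1 on non-negative data.
    """
    if gain <= 0 or gamma <= 0:
        raise ValueError("gain and gamma must be strictly positive")
    data, template = _unwrap(volume)
    if gain == 1.0 and gamma == 1.0 and data.min() >= 0:
        return _rewrap(data.copy(), template)
    out = gain * np.power(np.maximum(data.astype(float, copy=False), 0.0), gamma)
    return _rewrap(out.astype(data.dtype, copy=False), template)


def make_displacement_field(
    shape: Sequence[int],
    sigma: float,
    grid_spacing: int,
    rng: np.random.Generator,
    spline_order: int = 3,
) -> DisplacementField:
    """Random smooth displacement field from a coarse control grid.

    Control points sit on a square grid with the given spacing (voxels);
    each control displacement is drawn i.i.d. Normal(0, sigma^2) per axis
    and the field is upsampled to full resolution by spline interpolation
    of ``spline_order``, so the field passes exactly through the control
    values at grid locations.
    """
    shape = tuple(int(s) for s in shape)
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if any(grid_spacing > s for s in shape):
        raise ValueError(
            f"grid_spacing {grid_spacing} exceeds a volume axis of shape {shape}"
        )
    if sigma == 0:
        return DisplacementField(np.zeros((3,) + shape))

    n_ctrl = tuple(int(np.ceil((s - 1) / grid_spacing)) + 1 for s in shape)
    control = rng.normal(0.0, sigma, size=(3,) + n_ctrl)

    coords = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    )
    coords /= float(grid_spacing)  # full-resolution voxel -> control-grid units
    disp = np.empty((3,) + shape)
    for axis in range(3):
        disp[axis] = ndimage.map_coordinates(
            control[axis], coords, order=spline_order, mode="nearest"
        )
    return DisplacementField(disp)


def apply_displacement(volume, field: DisplacementField, order: int = 1, fill: float = 0.0):
    """Warp a volume: output voxel x takes the input value at x + d(x)."""
    data, template = _unwrap(volume)
    if field.spatial_shape != data.shape:
        raise ValueError(
            f"field shape {field.spatial_shape} does not match volume shape {data.shape}"
        )
    if not np.any(field.displacements):
        return _rewrap(data.copy(), template)
    coords = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in data.shape], indexing="ij")
    )
    coords += field.displacements
    out = ndimage.map_coordinates(
        data.astype(float, copy=False),
        coords,
        order=order,
        mode="grid-constant",
        cval=fill,
        prefilter=order > 1,
    )
    return _rewrap(out.astype(data.dtype, copy=False), template)


def apply_sample(volume, sample: AugmentationSample, config: AugmentationConfig):
    """Apply a concrete draw: flip -> affine -> elastic -> brightness."""
    data, template = _unwrap(volume)
    out = data
    if sample.flip_applied:
        out = flip_x(out)
    if config.affine_active:
        center = tuple((s - 1) / 2.0 for s in out.shape)
        matrix = build_affine(sample, center)
        out = apply_affine(out, matrix, order=config.resample_order, fill=config.fill_value)
    if sample.field is not None:
        out = apply_displacement(
            out, sample.field, order=config.resample_order, fill=config.fill_value
        )
    if config.brightness_enabled:
        out = brightness_transform(out, sample.gain, sample.gamma)
    if out is data:
        out = data.copy()
    return _rewrap(out, template)


def augment(volume, config: AugmentationConfig, rng: np.random.Generator):
    """Draw a fresh random augmentation and apply it to one volume."""
    data, template = _unwrap(volume)
    sample = sample_augmentation(config, rng, data.shape)
    return _rewrap(_unwrap(apply_sample(data, sample, config))[0], template)
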