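"""Synthetic REHO-like phantom datasets.

Real inputs are regional-homogeneity (REHO) derivative maps: for each voxel,
Kendall's coefficient of concordance (W) between that voxel's resting-state
time series and those of its cube neighbours. This module produces labelled
stand-ins with the same qualitative structure — non-negative, spatially
smooth scalar fields inside a brain-shaped mask, with a localized class
effect and optional multiplicative per-site intensity gains — either

* ``direct``: smooth noise fields with an additive class effect, or
* ``via_timeseries``: simulated 4D series run through a real Kendall's-W
  regional-homogeneity computation (:func:`compute_reho`).

Everything is a pure function of (spec, seed), so classifier and benchmark
code is testable without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, stats

from .volumes import BrainVolume, LabelledDataset, SubjectRecord, write_manifest, write_volume

#: neighbourhood size -> voxel offsets (face / face+edge / full 3x3x3 cube)
_NEIGHBORHOODS = {
    7: [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if abs(dx) + abs(dy) + abs(dz) <= 1
    ],
    19: [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if abs(dx) + abs(dy) + abs(dz) <= 2
    ],
    27: [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    ],
}


@dataclass
class EffectRegion:
    """Ellipsoidal region where the ASD class differs (voxel coordinates)."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    magnitude: float = 0.15

    def indicator(self, shape: Sequence[int]) -> np.ndarray:
        grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
        d2 = sum(
            ((g - c) / r) ** 2 for g, c, r in zip(grids, self.center, self.radii)
        )
        return d2 <= 1.0


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic dataset.

    ``noise_sd`` is the standard deviation of the smoothed within-subject
    field inside the mask (the raw white noise is smoothed, then rescaled),
    so effect magnitudes read directly in within-region SD units:
    the default magnitude 0.15 with noise_sd 0.1 is a 1.5 SD effect.
    """

    shape: tuple[int, int, int] = (32, 38, 32)
    n_per_class: int = 10
    effect_regions: Optional[list[EffectRegion]] = None
    noise_sd: float = 0.1
    smoothness_voxels: float = 2.0
    site_gain_range: tuple[float, float] = (0.8, 1.2)
    n_sites: int = 3
    timeseries_length: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.site_gain_range[0] <= 0:
            raise ValueError("site gains must be positive")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.effect_regions is None:
            self.effect_regions = [default_effect_region(self.shape)]
        for reg in self.effect_regions:
            if not np.isfinite(reg.magnitude):
                raise ValueError("effect magnitudes must be finite")
            for c, r, s in zip(reg.center, reg.radii, self.shape):
                if not (0 <= c - r and c + r <= s - 1):
                    raise ValueError(
                        f"effect region (center {reg.center}, radii {reg.radii}) "
                        f"extends outside shape {self.shape}"
                    )


def default_effect_region(shape: Sequence[int], magnitude: float = 0.15) -> EffectRegion:
    """A centred ellipsoid with semi-axes 18% of each dimension."""
    return EffectRegion(
        center=tuple((s - 1) / 2.0 for s in shape),
        radii=tuple(max(1.5, 0.18 * s) for s in shape),
        magnitude=magnitude,
    )


def separable_phantom_spec(
    shape: tuple[int, int, int] = (24, 24, 24),
    n_per_class: int = 100,
    seed: int = 0,
) -> PhantomSpec:
    """Strong-effect, single-site phantom for desk-scale classifier checks.

    One centred ellipsoidal region (semi-axes 22% of each dimension) whose
    additive class effect is 1.5 within-region standard deviations — large
    enough that the two classes are cleanly separable, so a working training
    pipeline should approach perfect test accuracy and a broken one will not.
    """
    return PhantomSpec(
        shape=shape,
        n_per_class=n_per_class,
        effect_regions=[
            EffectRegion(
                center=tuple((s - 1) / 2 for s in shape),
                radii=tuple(0.22 * s for s in shape),
                magnitude=0.15,
            )
        ],
        noise_sd=0.1,
        smoothness_voxels=2.0,
        site_gain_range=(1.0, 1.0),
        n_sites=1,
        seed=seed,
    )


def make_brain_mask(shape: Sequence[int]) -> np.ndarray:
    """Solid axis-aligned ellipsoid inscribed in the grid (semi-axes 0.45*shape)."""
    shape = tuple(int(s) for s in shape)
    if any(s < 1 for s in shape):
        raise ValueError(f"shape must be positive, got {shape}")
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    d2 = sum(
        ((g - (s - 1) / 2.0) / (0.45 * s)) ** 2 for g, s in zip(grids, shape)
    )
    return (d2 <= 1.0).astype(np.uint8)


def _smooth_unit_field(rng: np.random.Generator, shape, smoothness: float, mask: np.ndarray):
    """Smoothed white noise rescaled to unit SD inside the mask."""
    raw = rng.normal(size=shape)
    if smoothness > 0:
        raw = ndimage.gaussian_filter(raw, sigma=smoothness)
    sd = raw[mask > 0].std()
    return raw / sd if sd > 0 else raw


@dataclass
class TimeSeriesVolume:
    """4D (x, y, z, time) BOLD-like simulated series."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"time series volume must be 4D, got {self.data.shape}")
        if self.data.shape[3] < 3:
            raise ValueError("need at least 3 time points")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in time series")


def simulate_subject_timeseries(
    spec: PhantomSpec, label: int, rng: np.random.Generator
) -> TimeSeriesVolume:
    """Simulate one subject's 4D series.

    Each frame is spatially smoothed white noise (frames rescaled to unit SD
    in-mask), so neighbouring voxels share spatially — but not temporally —
    correlated structure. Inside each effect region a shared regional time
    course is mixed in with coupling weight proportional to the region's
    effect magnitude and stronger for label 1 (weight = magnitude for ASD,
    magnitude/2 for controls), which raises local temporal concordance and
    hence REHO. Outside the brain mask everything is 0.
    """
    mask = make_brain_mask(spec.shape)
    T = spec.timeseries_length
    data = np.zeros(spec.shape + (T,))
    for t in range(T):
        data[..., t] = _smooth_unit_field(rng, spec.shape, spec.smoothness_voxels, mask)
    for region in spec.effect_regions:
        weight = region.magnitude * (1.0 if label == 1 else 0.5)
        if weight == 0:
            continue
        course = rng.normal(size=T)
        data[region.indicator(spec.shape)] += weight * course
    data *= mask[..., None]
    return TimeSeriesVolume(data)


def compute_reho(
    ts: TimeSeriesVolume, mask: np.ndarray, neighborhood: int = 27
) -> BrainVolume:
    """Regional homogeneity: Kendall's W over each voxel's cube neighbourhood.

    For each in-mask voxel, the K <= ``neighborhood`` in-mask voxels of its
    cube neighbourhood (itself included) are ranked over the n time points
    (midranks on ties, no tie-correction term) and

        W = 12 * sum_t (R_t - mean(R))^2 / (K^2 * (n^3 - n))

    where R_t is the cross-voxel rank sum at time t. Edge and mask-boundary
    voxels use only their in-mask, in-grid neighbours (K shrinks). Output is
    in [0, 1] and exactly 0 outside the mask.
    """
    if neighborhood not in _NEIGHBORHOODS:
        raise ValueError(f"neighborhood must be one of {sorted(_NEIGHBORHOODS)}")
    data = ts.data
    n = data.shape[3]
    if n < 3:
        raise ValueError("need at least 3 time points for Kendall's W")
    mask = np.asarray(mask).astype(bool)
    if mask.shape != data.shape[:3]:
        raise ValueError("mask shape does not match time series")
    if not mask.any():
        raise ValueError("mask is empty")

    ranks = stats.rankdata(data, axis=3, method="average")
    ranks = ranks * mask[..., None]
    maskf = mask.astype(float)

    rank_sum = np.zeros_like(ranks)
    k_count = np.zeros(mask.shape)
    for offset in _NEIGHBORHOODS[neighborhood]:
        shifted_r = _shift3(ranks, offset)
        shifted_m = _shift3(maskf[..., None], offset)[..., 0]
        rank_sum += shifted_r
        k_count += shifted_m

    mean_rank_sum = rank_sum.mean(axis=3, keepdims=True)
    s = ((rank_sum - mean_rank_sum) ** 2).sum(axis=3)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 12.0 * s / (k_count**2 * (n**3 - n))
    w = np.where(mask, w, 0.0)
    w = np.clip(w, 0.0, 1.0)
    return BrainVolume(data=w, is_reho=True)


def _shift3(arr: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    """Shift the three leading spatial axes, zero-filling vacated voxels."""
    out = arr
    for axis, d in enumerate(offset):
        if d == 0:
            continue
        out = np.roll(out, d, axis=axis)
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(0, d) if d > 0 else slice(d, None)
        out = out.copy() if out is arr else out
        out[tuple(sl)] = 0
    return out if out is not arr else arr.copy()


def generate_derivative_dataset(
    spec: PhantomSpec,
    rng: Optional[np.random.Generator] = None,
    mode: str = "direct",
    out_dir=None,
) -> LabelledDataset:
    """Generate ``2 * n_per_class`` labelled REHO-like volumes.

    ``direct`` draws smoothed non-negative fields (shared base pattern +
    per-subject noise) with an additive class effect inside the effect
    regions; ``via_timeseries`` simulates 4D series and computes real
    Kendall's-W REHO maps. Subjects are assigned round-robin to ``n_sites``
    sites, each with a multiplicative gain drawn once from
    ``site_gain_range``. If ``out_dir`` is given, NIfTI volumes and a CSV
    ``manifest.csv`` are written there; otherwise the dataset stays
    in memory. Fully reproducible from (spec, seed).
    """
    if mode not in ("direct", "via_timeseries"):
        raise ValueError(f"unknown mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    mask = make_brain_mask(spec.shape)

    site_gains = rng.uniform(*spec.site_gain_range, size=spec.n_sites)
    base = None
    effect_map = np.zeros(spec.shape)
    for region in spec.effect_regions:
        effect_map += region.magnitude * region.indicator(spec.shape)
    if mode == "direct":
        # shared anatomy-like background, positive inside the mask
        base = 0.5 + 0.15 * _smooth_unit_field(rng, spec.shape, spec.smoothness_voxels, mask)

    records: list[SubjectRecord] = []
    volumes: list[BrainVolume] = []
    labels = [0] * spec.n_per_class + [1] * spec.n_per_class
    for idx, label in enumerate(labels):
        site = idx % spec.n_sites
        gain = site_gains[site]
        if mode == "direct":
            noise = _smooth_unit_field(rng, spec.shape, spec.smoothness_voxels, mask)
            img = base + spec.noise_sd * noise + label * effect_map
            img = np.clip(img, 0.0, None) * mask * gain
            vol = BrainVolume(data=img.astype(np.float32), is_reho=True)
        else:
            ts = simulate_subject_timeseries(spec, label, rng)
            vol = compute_reho(ts, mask)
            vol = BrainVolume(data=(vol.data * gain).astype(np.float32), is_reho=True)
        sid = f"sub-{idx:04d}"
        vol.subject_id = sid
        records.append(SubjectRecord(subject_id=sid, label=label, site_id=f"site{site}"))
        volumes.append(vol)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec, vol in zip(records, volumes):
            path = out_dir / f"{rec.subject_id}.nii.gz"
            write_volume(vol, path)
            # manifest-relative, so the dataset directory stays relocatable
            rec.volume_path = path.name
        write_manifest(records, out_dir / "manifest.csv")

    return LabelledDataset(records=records, volumes=volumes)
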