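import numpy as np
import pytest

from augbench import BrainVolume, EffectRegion, LabelledDataset, PhantomSpec, SubjectRecord


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume(rng):
    """A non-negative random 11x12x13 derivative-like volume."""
    return BrainVolume(np.abs(rng.normal(size=(11, 12, 13))).astype(np.float32))


def make_tiny_dataset(n_per_class=6, shape=(10, 10, 10), seed=0, magnitude=0.3):
    """In-memory phantom dataset small enough for fast training tests."""
    from augbench import generate_derivative_dataset

    spec = PhantomSpec(
        shape=shape,
        n_per_class=n_per_class,
        effect_regions=[
            EffectRegion(
                center=tuple((s - 1) / 2 for s in shape),
                radii=tuple(0.25 * s for s in shape),
                magnitude=magnitude,
            )
        ],
        noise_sd=0.1,
        smoothness_voxels=1.0,
        site_gain_range=(1.0, 1.0),
        n_sites=1,
        seed=seed,
    )
    return generate_derivative_dataset(spec, mode="direct")


def make_label_only_dataset(labels, shape=(2, 2, 2)):
    """Dataset with trivial constant volumes, for split/protocol tests."""
    records = [SubjectRecord(subject_id=f"s{i:05d}", label=int(l)) for i, l in enumerate(labels)]
    volumes = [BrainVolume(np.zeros(shape, dtype=np.float32)) for _ in labels]
    return LabelledDataset(records=records, volumes=volumes)


def trilinear_lookup(data, point, fill=0.0):
    """Reference trilinear interpolation with constant fill outside the grid."""
    base = np.floor(point).astype(int)
    frac = point - base
    value = 0.0
    for corner in np.ndindex(2, 2, 2):
        idx = base + np.array(corner)
        weight = np.prod([f if c else 1.0 - f for c, f in zip(corner, frac)])
        inside = all(0 <= i < s for i, s in zip(idx, data.shape))
        value += weight * (data[tuple(idx)] if inside else fill)
    return value


def nearest_lookup(data, point, fill=0.0):
    idx = np.floor(point + 0.5).astype(int)
    if all(0 <= i < s for i, s in zip(idx, data.shape)):
        return data[tuple(idx)]
    return fill


def affine_oracle(data, matrix, order=1, fill=0.0):
    """Brute-force per-voxel pull-back resampling (order 0 or 1)."""
    out = np.zeros(data.shape, dtype=float)
    lookup = nearest_lookup if order == 0 else trilinear_lookup
    for idx in np.ndindex(data.shape):
        point = (matrix @ np.array([*idx, 1.0]))[:3]
        out[idx] = lookup(data, point, fill)
    return out


def warp_oracle(data, displacements, order=1, fill=0.0):
    """Brute-force per-voxel warp: out(x) = in(x + d(x))."""
    out = np.zeros(data.shape, dtype=float)
    lookup = nearest_lookup if order == 0 else trilinear_lookup
    for idx in np.ndindex(data.shape):
        point = np.array(idx, dtype=float) + displacements[(slice(None),) + idx]
        out[idx] = lookup(data, point, fill)
    return out


def kendalls_w_oracle(data4d, mask, neighborhood_offsets):
    """Naive ranked-loop Kendall's W regional homogeneity."""
    from scipy.stats import rankdata

    shape = data4d.shape[:3]
    n = data4d.shape[3]
    out = np.zeros(shape)
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        series = []
        for off in neighborhood_offsets:
            q = tuple(i + o for i, o in zip(idx, off))
            if all(0 <= qi < s for qi, s in zip(q, shape)) and mask[q]:
                series.append(data4d[q])
        k = len(series)
        ranks = np.array([rankdata(s) for s in series])  # (k, n)
        rank_sums = ranks.sum(axis=0)
        s_stat = ((rank_sums - rank_sums.mean()) ** 2).sum()
        out[idx] = 12.0 * s_stat / (k**2 * (n**3 - n))
    return out
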