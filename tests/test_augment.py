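import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import ndimage, stats

from augbench import (
    AugmentationConfig,
    AugmentationSample,
    BrainVolume,
    apply_affine,
    apply_displacement,
    apply_sample,
    augment,
    brightness_transform,
    build_affine,
    flip_x,
    make_displacement_field,
    sample_augmentation,
)

from conftest import affine_oracle, warp_oracle

volumes3d = hnp.arrays(
    np.float64,
    hnp.array_shapes(min_dims=3, max_dims=3, min_side=2, max_side=8),
    elements=st.floats(0, 10, allow_nan=False),
)


class TestSampling:
    def test_rotation_draws_respect_bounds(self):
        cfg = AugmentationConfig(rotation_max_deg=15.0)
        rng = np.random.default_rng(0)
        angles = np.array(
            [sample_augmentation(cfg, rng, (8, 8, 8)).angles_deg for _ in range(10_000)]
        )
        assert angles.min() >= -15.0 and angles.max() <= 15.0
        # all four studied bounds behave the same way
        for bound in (7.5, 30.0, 45.0):
            s = sample_augmentation(
                AugmentationConfig(rotation_max_deg=bound), rng, (8, 8, 8)
            )
            assert all(abs(a) <= bound for a in s.angles_deg)

    def test_scale_draws_respect_bounds(self):
        cfg = AugmentationConfig(scale_max_fraction=0.2)
        rng = np.random.default_rng(1)
        scales = np.array(
            [sample_augmentation(cfg, rng, (8, 8, 8)).scale_factors for _ in range(10_000)]
        )
        assert scales.min() >= 0.8 and scales.max() <= 1.2

    def test_gamma_draws_are_uniform_on_their_range(self):
        cfg = AugmentationConfig(brightness_enabled=True)
        rng = np.random.default_rng(2)
        gammas = np.array(
            [sample_augmentation(cfg, rng, (8, 8, 8)).gamma for _ in range(10_000)]
        )
        assert 0.8 <= gammas.min() and gammas.max() <= 1.2
        assert abs(gammas.mean() - 1.0) < 0.01
        pvalue = stats.kstest(gammas, stats.uniform(loc=0.8, scale=0.4).cdf).pvalue
        assert pvalue > 0.01

    def test_flip_frequency_matches_probability(self):
        cfg = AugmentationConfig(flip_enabled=True, flip_probability=0.5)
        rng = np.random.default_rng(3)
        flips = [sample_augmentation(cfg, rng, (8, 8, 8)).flip_applied for _ in range(10_000)]
        assert 0.47 < np.mean(flips) < 0.53

    def test_disabled_config_yields_identity_sample(self, rng):
        s = sample_augmentation(AugmentationConfig(), rng, (8, 8, 8))
        assert s == AugmentationSample()

    def test_same_seed_same_sample(self):
        cfg = AugmentationConfig(
            flip_enabled=True, rotation_max_deg=15, scale_max_fraction=0.1,
            brightness_enabled=True, elastic_sigma_voxels=2.0,
        )
        s1 = sample_augmentation(cfg, np.random.default_rng(9), (9, 9, 9))
        s2 = sample_augmentation(cfg, np.random.default_rng(9), (9, 9, 9))
        assert s1.angles_deg == s2.angles_deg and s1.gain == s2.gain
        np.testing.assert_array_equal(s1.field.displacements, s2.field.displacements)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            AugmentationConfig(flip_probability=1.5)
        with pytest.raises(ValueError):
            AugmentationConfig(gain_range=(0.0, 1.2))
        with pytest.raises(ValueError):
            AugmentationConfig(gamma_range=(1.2, 0.8))


class TestFlip:
    @settings(max_examples=25, deadline=None)
    @given(volumes3d)
    def test_involution_and_multiset_preserved(self, data):
        flipped = flip_x(data)
        np.testing.assert_array_equal(flip_x(flipped), data)
        np.testing.assert_array_equal(np.sort(flipped.ravel()), np.sort(data.ravel()))

    def test_three_voxel_line_reverses(self):
        np.testing.assert_array_equal(
            flip_x(np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)).ravel(), [3.0, 2.0, 1.0]
        )

    def test_blob_center_of_mass_reflects_about_volume_center(self):
        data = np.zeros((61, 20, 20))
        data[8:13, 9:12, 9:12] = 1.0  # blob centered at x = 10
        com_x = ndimage.center_of_mass(flip_x(data))[0]
        assert com_x == pytest.approx(2 * 30 - 10, abs=1e-9)

    def test_brain_volume_wrapper_preserved(self, small_volume):
        out = flip_x(small_volume)
        assert isinstance(out, BrainVolume)
        assert out.shape == small_volume.shape


class TestAffine:
    def test_identity_sample_gives_identity_matrix(self):
        m = build_affine(AugmentationSample(), center_voxel=(5, 5, 5))
        np.testing.assert_array_equal(m, np.eye(4))

    def test_z_rotation_90_maps_x_offset_to_y_offset(self):
        c = np.array([5.0, 5.0, 5.0])
        m = build_affine(AugmentationSample(angles_deg=(0, 0, 90)), c)
        # pull-back of the forward target recovers the source point
        fwd = np.linalg.inv(m)
        moved = (fwd @ np.array([*(c + (1, 0, 0)), 1.0]))[:3]
        assert np.allclose(np.abs(moved - c), (0, 1, 0), atol=1e-12)

    def test_pure_scaling_inverts_on_diagonal(self):
        m = build_affine(AugmentationSample(scale_factors=(2.0, 1.0, 1.0)), (0, 0, 0))
        assert m[0, 0] == pytest.approx(0.5)
        assert m[1, 1] == m[2, 2] == 1.0

    def test_identity_matrix_resamples_exactly(self, small_volume):
        for order in (0, 1, 3):
            out = apply_affine(small_volume, np.eye(4), order=order)
            np.testing.assert_array_equal(out.data, small_volume.data)

    def test_singular_matrix_rejected(self, small_volume):
        m = np.eye(4)
        m[0, 0] = 0.0
        with pytest.raises(np.linalg.LinAlgError):
            apply_affine(small_volume, m)

    def test_90deg_rotation_matches_per_voxel_oracle_order0(self):
        rng = np.random.default_rng(7)
        data = rng.uniform(size=(11, 11, 11))
        center = (5.0, 5.0, 5.0)
        m = build_affine(AugmentationSample(angles_deg=(0, 0, 90)), center)
        out = apply_affine(data, m, order=0)
        np.testing.assert_allclose(out, affine_oracle(data, m, order=0), atol=1e-6)

    def test_random_affine_matches_per_voxel_oracle_order1(self):
        rng = np.random.default_rng(8)
        data = rng.uniform(size=(11, 10, 9))
        sample = AugmentationSample(angles_deg=(9.0, -14.0, 23.0), scale_factors=(1.1, 0.9, 1.05))
        m = build_affine(sample, tuple((s - 1) / 2 for s in data.shape))
        out = apply_affine(data, m, order=1)
        np.testing.assert_allclose(out, affine_oracle(data, m, order=1), atol=1e-6)

    def test_zoom_out_halves_linear_size_so_volume_drops_8x(self):
        shape = (40, 40, 40)
        grids = np.meshgrid(*[np.arange(s) - 19.5 for s in shape], indexing="ij")
        ellipsoid = (sum((g / 14.0) ** 2 for g in grids) <= 1).astype(float)
        # scale factor 0.5 on all axes (zoom out): pull-back doubles coordinates
        m = build_affine(
            AugmentationSample(scale_factors=(0.5, 0.5, 0.5)), (19.5, 19.5, 19.5)
        )
        out = apply_affine(ellipsoid, m, order=0)
        ratio = out.sum() / ellipsoid.sum()
        assert abs(ratio - 0.125) < 0.0125

    def test_small_rotation_preserves_interior_mean_of_smooth_volume(self):
        shape = (24, 24, 24)
        grids = np.meshgrid(*[np.arange(s) - 11.5 for s in shape], indexing="ij")
        r2 = sum(g**2 for g in grids)
        smooth = np.exp(-r2 / 60.0)
        ball = r2 <= 36.0
        m = build_affine(
            AugmentationSample(angles_deg=(15.0, -10.0, 12.0)), (11.5, 11.5, 11.5)
        )
        rotated = apply_affine(smooth, m, order=1)
        change = abs(rotated[ball].mean() - smooth[ball].mean()) / smooth[ball].mean()
        assert change < 0.02


class TestBrightness:
    def test_unit_parameters_are_identity(self, small_volume):
        out = brightness_transform(small_volume, 1.0, 1.0)
        np.testing.assert_array_equal(out.data, small_volume.data)

    @pytest.mark.parametrize(
        "value,gain,gamma,expected",
        [
            (4.0, 1.0, 0.5, 2.0),
            (2.0, 1.2, 1.2, 1.2 * 2.0**1.2),  # ~2.7569
            (0.0, 1.1, 0.9, 0.0),
        ],
    )
    def test_pointwise_power_law(self, value, gain, gamma, expected):
        out = brightness_transform(np.full((2, 2, 2), value), gain, gamma)
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_nonpositive_parameters_rejected(self, small_volume):
        with pytest.raises(ValueError):
            brightness_transform(small_volume, 0.0, 1.0)
        with pytest.raises(ValueError):
            brightness_transform(small_volume, 1.0, -0.5)

    @settings(max_examples=25, deadline=None)
    @given(volumes3d, st.floats(0.5, 2.0), st.floats(0.5, 2.0))
    def test_monotone_and_nonnegative(self, data, gain, gamma):
        out = brightness_transform(data, gain, gamma)
        assert out.min() >= 0
        flat_in, flat_out = data.ravel(), out.ravel()
        order = np.argsort(flat_in, kind="stable")
        assert np.all(np.diff(flat_out[order]) >= -1e-12)

    def test_negative_values_clamped_to_zero_before_power(self):
        out = brightness_transform(np.array([[[-3.0, 4.0]]]), 1.0, 0.5)
        np.testing.assert_allclose(out, [[[0.0, 2.0]]])


class TestDisplacementField:
    def test_sigma_zero_gives_zero_field(self, rng):
        field = make_displacement_field((6, 7, 8), sigma=0.0, grid_spacing=4, rng=rng)
        assert field.spatial_shape == (6, 7, 8)
        assert not field.displacements.any()

    def test_control_point_sd_and_interpolation_consistency(self):
        # the upsampled field must pass exactly through the control values,
        # whose empirical sd must match the requested sigma = 4
        shape, spacing, sigma = (81, 81, 81), 4, 4.0
        field = make_displacement_field(
            shape, sigma=sigma, grid_spacing=spacing, rng=np.random.default_rng(11), spline_order=3
        )
        n_ctrl = tuple(int(np.ceil((s - 1) / spacing)) + 1 for s in shape)
        control = np.random.default_rng(11).normal(0.0, sigma, size=(3,) + n_ctrl)
        at_grid = field.displacements[:, ::spacing, ::spacing, ::spacing]
        np.testing.assert_allclose(at_grid, control[:, :21, :21, :21], atol=1e-8)
        sd = at_grid.std()
        assert 3.8 <= sd <= 4.2

    def test_grid_spacing_exceeding_axis_rejected(self, rng):
        with pytest.raises(ValueError, match="grid_spacing"):
            make_displacement_field((6, 6, 6), sigma=2.0, grid_spacing=7, rng=rng)

    def test_same_seed_same_field(self):
        f1 = make_displacement_field((9, 9, 9), 2.0, 4, np.random.default_rng(5))
        f2 = make_displacement_field((9, 9, 9), 2.0, 4, np.random.default_rng(5))
        np.testing.assert_array_equal(f1.displacements, f2.displacements)


class TestApplyDisplacement:
    def test_zero_field_is_exact_identity(self, small_volume):
        field = make_displacement_field(
            small_volume.shape, 0.0, 4, np.random.default_rng(0)
        )
        out = apply_displacement(small_volume, field)
        np.testing.assert_array_equal(out.data, small_volume.data)

    def test_constant_volume_preserved_where_lookups_stay_in_grid(self):
        rng = np.random.default_rng(13)
        data = np.full((12, 12, 12), 7.5)
        field = make_displacement_field((12, 12, 12), 1.0, 4, rng)
        out = apply_displacement(data, field, order=1)
        coords = np.stack(np.meshgrid(*[np.arange(12.0)] * 3, indexing="ij"))
        lookup = coords + field.displacements
        in_grid = np.all((lookup >= 0) & (lookup <= 11), axis=0)
        np.testing.assert_allclose(out[in_grid], 7.5, rtol=1e-12)

    def test_matches_brute_force_trilinear_oracle(self):
        rng = np.random.default_rng(17)
        data = rng.uniform(size=(9, 9, 9))
        field = make_displacement_field((9, 9, 9), 2.0, 4, rng)
        out = apply_displacement(data, field, order=1)
        np.testing.assert_allclose(out, warp_oracle(data, field.displacements), atol=1e-6)

    def test_shape_mismatch_rejected(self, small_volume, rng):
        field = make_displacement_field((5, 5, 5), 1.0, 4, rng)
        with pytest.raises(ValueError, match="shape"):
            apply_displacement(small_volume, field)


class TestComposition:
    def test_all_disabled_config_is_exact_identity(self, small_volume, rng):
        out = augment(small_volume, AugmentationConfig(), rng)
        np.testing.assert_array_equal(out.data, small_volume.data)

    def test_flip_only_config_equals_flip_x(self, small_volume):
        cfg = AugmentationConfig(flip_enabled=True, flip_probability=1.0)
        out = augment(small_volume, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(out.data, flip_x(small_volume).data)

    def test_fixed_seed_gives_identical_output(self, small_volume):
        cfg = AugmentationConfig(rotation_max_deg=15.0, elastic_sigma_voxels=2.0)
        out1 = augment(small_volume, cfg, np.random.default_rng(21))
        out2 = augment(small_volume, cfg, np.random.default_rng(21))
        np.testing.assert_array_equal(out1.data, out2.data)

    @pytest.mark.parametrize(
        "cfg",
        [
            AugmentationConfig(flip_enabled=True),
            AugmentationConfig(rotation_max_deg=45.0),
            AugmentationConfig(scale_max_fraction=0.2),
            AugmentationConfig(brightness_enabled=True),
            AugmentationConfig(elastic_sigma_voxels=8.0, elastic_grid_spacing_voxels=4),
            AugmentationConfig(
                flip_enabled=True,
                rotation_max_deg=15.0,
                scale_max_fraction=0.1,
                brightness_enabled=True,
                elastic_sigma_voxels=2.0,
                elastic_grid_spacing_voxels=4,
            ),
        ],
    )
    def test_every_stage_preserves_shape(self, cfg, small_volume, rng):
        out = augment(small_volume, cfg, rng)
        assert out.shape == small_volume.shape

    def test_combined_strategy_applies_stage_order(self, rng):
        # flip + brightness on an asymmetric ramp: flip first, then power law
        data = np.zeros((3, 1, 1))
        data[:, 0, 0] = (1.0, 2.0, 3.0)
        cfg = AugmentationConfig(
            flip_enabled=True, flip_probability=1.0, brightness_enabled=True,
            gain_range=(1.2, 1.2), gamma_range=(1.0, 1.0),
        )
        out = augment(data, cfg, np.random.default_rng(0))
        np.testing.assert_allclose(out.ravel(), [3.6, 2.4, 1.2])
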