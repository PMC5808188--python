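import numpy as np
import pytest
from dataclasses import replace

from seagrass import OpticalConstants, SceneSpec
from seagrass.optics import correct_water_column
from seagrass.synthetic import (
    DEFAULT_CLASS_SPECTRA,
    generate_depth_surface,
    generate_habitat_map,
    make_scene,
    render_surface_reflectance,
)


class TestSceneSpec:
    def test_defaults_valid(self):
        spec = SceneSpec()
        assert spec.depth_min == 0.8 and spec.depth_max == 18.9
        assert spec.n_train_per_class == spec.n_val_per_class == 50

    def test_invalid_spectra(self):
        with pytest.raises(ValueError):
            SceneSpec(class_spectra={1: (2.0, 0.1, 0.1), 2: (0.1,) * 3, 3: (0.2,) * 3, 4: (0.3,) * 3})

    def test_duplicate_spectra_rejected(self):
        spectra = dict(DEFAULT_CLASS_SPECTRA)
        spectra[1] = spectra[2]
        with pytest.raises(ValueError, match="distinct"):
            SceneSpec(class_spectra=spectra)

    def test_depth_order(self):
        with pytest.raises(ValueError):
            SceneSpec(depth_min=5.0, depth_max=1.0)

    def test_dict_roundtrip(self):
        spec = SceneSpec(rows=50, cols=60, rng_seed=9)
        assert SceneSpec.from_dict(spec.to_dict()) == spec


class TestDepthSurface:
    def test_zero_width_range_constant(self):
        spec = SceneSpec(rows=20, cols=20, depth_min=5.0, depth_max=5.0)
        d = generate_depth_surface(spec)
        assert np.all(d.values == 5.0)

    def test_range_clamp(self):
        spec = SceneSpec(rng_seed=42)
        d = generate_depth_surface(spec)
        assert d.values.min() >= 0.8 and d.values.max() <= 18.9

    def test_deterministic(self):
        spec = SceneSpec(rng_seed=42)
        np.testing.assert_array_equal(
            generate_depth_surface(spec).values, generate_depth_surface(spec).values
        )

    def test_monotone_trend_across_columns(self):
        spec = SceneSpec(rows=60, cols=60, rng_seed=1)
        d = generate_depth_surface(spec)
        col_means = d.values.mean(axis=0)
        slope = np.polyfit(np.arange(60), col_means, 1)[0]
        assert slope > 0

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            generate_depth_surface(SceneSpec(rows=4, cols=4))


class TestHabitatMap:
    def test_single_class_prior(self):
        spec = SceneSpec(rows=30, cols=30, class_prior=(0, 0, 0, 1), n_train_per_class=5,
                         n_val_per_class=5)
        habitat = generate_habitat_map(spec, generate_depth_surface(spec))
        assert np.all(habitat.labels == 4)

    def test_all_classes_present(self):
        spec = SceneSpec(rng_seed=42)
        habitat = generate_habitat_map(spec, generate_depth_surface(spec))
        assert set(np.unique(habitat.labels)) == {1, 2, 3, 4}

    def test_minimum_pixels_per_class(self):
        spec = SceneSpec(rng_seed=42)
        habitat = generate_habitat_map(spec, generate_depth_surface(spec))
        needed = spec.n_train_per_class + spec.n_val_per_class
        assert all(n >= needed for n in habitat.class_counts().values())

    def test_deterministic(self):
        spec = SceneSpec(rng_seed=5)
        d = generate_depth_surface(spec)
        np.testing.assert_array_equal(
            generate_habitat_map(spec, d).labels, generate_habitat_map(spec, d).labels
        )

    def test_insufficient_pixels_rejected(self):
        spec = SceneSpec(rows=10, cols=10, n_train_per_class=50, n_val_per_class=50)
        with pytest.raises(ValueError, match="required"):
            generate_habitat_map(spec, generate_depth_surface(spec))


class TestRender:
    def test_zero_depth_zero_noise_equals_class_means(self):
        # at Z = 0 only the shallow-tolerant classes occur; restrict to them
        spec = SceneSpec(
            rows=30, cols=30, depth_min=0.0, depth_max=0.0, class_sd=0.0,
            sensor_noise_sd=0.0, class_prior=(0, 0, 1, 1),
            n_train_per_class=5, n_val_per_class=5, rng_seed=2,
        )
        scene = make_scene(spec)
        for c, spectrum in spec.class_spectra.items():
            sel = scene.truth_habitat.labels == c
            if not sel.any():
                continue
            for b in range(3):
                np.testing.assert_allclose(scene.surface.values[b][sel], spectrum[b])

    def test_bottom_equal_to_r_inf_is_invisible(self):
        optics = OpticalConstants()
        spectra = dict(DEFAULT_CLASS_SPECTRA)
        spectra[4] = optics.r_inf  # render only this class
        spec = SceneSpec(
            rows=30, cols=30, class_spectra=spectra, class_prior=(0, 0, 0, 1),
            class_sd=0.0, sensor_noise_sd=0.0, n_train_per_class=5, n_val_per_class=5,
        )
        scene = make_scene(spec)
        for b, r in enumerate(optics.r_inf):
            np.testing.assert_allclose(scene.surface.values[b], r, atol=1e-12)

    def test_signal_decays_with_depth_for_sand(self):
        spec = SceneSpec(rng_seed=42)
        scene = make_scene(spec)
        optics = spec.optics
        sel = scene.truth_habitat.labels == 4
        z = scene.truth_depth.values[sel]
        signal = np.abs(scene.surface.values[0][sel] - optics.r_inf[0])
        # oracle: bin by depth decile, mean |R - R_inf| must decrease
        deciles = np.quantile(z, np.linspace(0, 1, 11))
        means = [
            signal[(z >= deciles[i]) & (z < deciles[i + 1])].mean() for i in range(10)
        ]
        assert all(a > b for a, b in zip(means[:-1], means[1:]))

    def test_round_trip_reproduces_truth_bottom(self):
        spec = SceneSpec(rows=60, cols=60, class_sd=0.0, sensor_noise_sd=0.0, rng_seed=11,
                         n_train_per_class=10, n_val_per_class=10)
        scene = make_scene(spec)
        back = correct_water_column(scene.surface, scene.truth_depth, spec.optics)
        np.testing.assert_allclose(back.values, scene.truth_bottom.values, atol=1e-10)


class TestPoints:
    def test_counts_exact(self, scene, small_spec):
        assert scene.train_points.class_counts() == {c: 50 for c in (1, 2, 3, 4)}
        assert scene.val_points.class_counts() == {c: 50 for c in (1, 2, 3, 4)}
        assert scene.depth_points.shape == (small_spec.n_depth_points, 3)

    def test_disjoint_train_val(self, scene):
        train = set(zip(scene.train_points.x, scene.train_points.y))
        val = set(zip(scene.val_points.x, scene.val_points.y))
        assert not train & val

    def test_points_lie_on_their_class(self, scene):
        grid = scene.truth_habitat.grid
        for pts in (scene.train_points, scene.val_points):
            row, col = grid.rowcol(pts.x, pts.y)
            np.testing.assert_array_equal(scene.truth_habitat.labels[row, col], pts.label)

    def test_depth_points_carry_truth_depth(self, scene):
        grid = scene.truth_depth.grid
        row, col = grid.rowcol(scene.depth_points[:, 0], scene.depth_points[:, 1])
        np.testing.assert_allclose(scene.truth_depth.values[row, col], scene.depth_points[:, 2])

    def test_geographic_split(self):
        spec = SceneSpec(rows=120, cols=120, geographic_split=True, rng_seed=4,
                         n_train_per_class=10, n_val_per_class=10)
        scene = make_scene(spec)
        # train in the top half (larger y), validation in the bottom half
        mid_y = spec.grid.y_origin - (spec.rows // 2) * spec.pixel_size
        assert scene.train_points.y.min() > mid_y
        assert scene.val_points.y.max() <= mid_y


class TestReproducibility:
    def test_scene_bit_reproducible(self):
        spec = SceneSpec(rows=50, cols=50, rng_seed=21, n_train_per_class=10, n_val_per_class=10)
        a, b = make_scene(spec), make_scene(spec)
        np.testing.assert_array_equal(a.surface.values, b.surface.values)
        np.testing.assert_array_equal(a.truth_habitat.labels, b.truth_habitat.labels)
        np.testing.assert_array_equal(a.depth_points, b.depth_points)
        np.testing.assert_array_equal(a.train_points.x, b.train_points.x)

    def test_seed_changes_scene(self):
        spec = SceneSpec(rows=50, cols=50, rng_seed=21, n_train_per_class=10, n_val_per_class=10)
        other = make_scene(replace(spec, rng_seed=22))
        base = make_scene(spec)
        assert not np.array_equal(base.surface.values, other.surface.values)

    def test_noise_level_does_not_perturb_habitat(self):
        spec = SceneSpec(rows=50, cols=50, rng_seed=8, n_train_per_class=10, n_val_per_class=10)
        noisy = make_scene(spec)
        clean = make_scene(replace(spec, sensor_noise_sd=0.0))
        np.testing.assert_array_equal(noisy.truth_habitat.labels, clean.truth_habitat.labels)
        np.testing.assert_array_equal(noisy.truth_bottom.values, clean.truth_bottom.values)
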