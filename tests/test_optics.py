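import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from seagrass import DepthRaster, Grid, OpticalConstants
from seagrass.optics import (
    apply_deep_mask,
    correct_water_column,
    estimate_deep_reflectance,
    forward_shallow_reflectance,
    surface_to_rrs,
)
from seagrass.rasters import STAGE_BOTTOM, STAGE_RRS, ReflectanceScene

from .conftest import make_flat_scene


def _bottom(values, optics, grid=None, mask=None):
    grid = grid or Grid(rows=values.shape[1], cols=values.shape[2], pixel_size=5.0)
    return ReflectanceScene(values=values, bands=optics.bands, grid=grid, mask=mask, stage=STAGE_BOTTOM)


def _depth(z, grid, mask=None):
    return DepthRaster(values=np.full(grid.shape, float(z)), grid=grid, mask=mask)


class TestOpticalConstants:
    def test_defaults(self, optics):
        assert optics.bands == (475.0, 555.0, 658.0)
        assert optics.kd == (0.067, 0.078, 0.134)
        assert optics.r_inf == (0.033, 0.024, 0.017)
        assert optics.t == 0.54
        assert optics.q == pytest.approx(math.pi)

    @pytest.mark.parametrize(
        "kw",
        [
            {"kd": (0.0, 0.1, 0.1)},
            {"r_inf": (1.0, 0.1, 0.1)},
            {"t": 0.0},
            {"q": -1.0},
            {"kd": (0.1, 0.1)},
        ],
    )
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            OpticalConstants(**kw)

    def test_dict_roundtrip(self, optics):
        assert OpticalConstants.from_dict(optics.to_dict()) == optics


class TestSurfaceToRrs:
    def test_zero_maps_to_zero(self, optics, flat_scene_factory):
        assert np.all(surface_to_rrs(flat_scene_factory(0.0), optics).values == 0.0)

    def test_r_equal_q_cancels(self, optics, flat_scene_factory):
        rrs = surface_to_rrs(flat_scene_factory(math.pi), optics)
        assert rrs.values == pytest.approx(0.54)

    def test_direct_evaluation(self, optics, flat_scene_factory):
        rrs = surface_to_rrs(flat_scene_factory(0.033), optics)
        assert rrs.values == pytest.approx(0.54 * 0.033 / math.pi)
        assert rrs.stage == STAGE_RRS

    def test_wrong_stage_rejected(self, optics, flat_scene_factory):
        scene = flat_scene_factory(0.1, stage=STAGE_BOTTOM)
        with pytest.raises(ValueError, match="expected"):
            surface_to_rrs(scene, optics)

    @given(a=st.floats(0.1, 10.0), r=st.floats(1e-6, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_linearity(self, a, r):
        optics = OpticalConstants()
        s1 = make_flat_scene(r, optics, rows=3, cols=3)
        s2 = make_flat_scene(min(a * r, 1.0), optics, rows=3, cols=3)
        if a * r <= 1.0:
            np.testing.assert_allclose(
                surface_to_rrs(s2, optics).values, a * surface_to_rrs(s1, optics).values,
                rtol=1e-12,
            )


class TestDeepReflectance:
    def test_constant_raster(self, optics, flat_scene_factory):
        scene = flat_scene_factory(0.05)
        est = estimate_deep_reflectance(scene, box(0, 0, 50, 50))
        assert est.r_inf == pytest.approx((0.05, 0.05, 0.05))
        assert est.n_pixels == 100

    def test_four_pixel_mean(self, optics):
        grid = Grid(rows=2, cols=2, pixel_size=5.0)
        vals = np.array([[0.02, 0.02], [0.04, 0.04]])
        scene = ReflectanceScene(
            values=np.stack([vals] * 3), bands=optics.bands, grid=grid, stage="surface_R"
        )
        est = estimate_deep_reflectance(scene, box(0, 0, 10, 10))
        assert est.r_inf == pytest.approx((0.03, 0.03, 0.03))
        assert est.n_pixels == 4

    def test_recovers_configured_r_inf_from_deep_render(self, optics):
        # a scene whose bottom equals r_inf renders to r_inf at any depth
        grid = Grid(rows=8, cols=8, pixel_size=5.0)
        rb = np.stack([np.full(grid.shape, r) for r in optics.r_inf])
        surface = forward_shallow_reflectance(_bottom(rb, optics, grid), _depth(30.0, grid), optics)
        est = estimate_deep_reflectance(surface, box(0, 0, 40, 40))
        np.testing.assert_allclose(est.r_inf, optics.r_inf, atol=1e-12)

    def test_empty_intersection(self, optics, flat_scene_factory):
        with pytest.raises(ValueError):
            estimate_deep_reflectance(flat_scene_factory(0.1), box(1000, 1000, 1010, 1010))


class TestForwardModel:
    def test_zero_depth_identity(self, optics):
        grid = Grid(rows=4, cols=4, pixel_size=5.0)
        rng = np.random.default_rng(0)
        rb = rng.uniform(0, 0.3, size=(3, 4, 4))
        surface = forward_shallow_reflectance(_bottom(rb, optics, grid), _depth(0.0, grid), optics)
        np.testing.assert_allclose(surface.values, rb, rtol=0, atol=1e-15)

    def test_r_inf_fixed_point(self, optics):
        grid = Grid(rows=4, cols=4, pixel_size=5.0)
        rb = np.stack([np.full(grid.shape, r) for r in optics.r_inf])
        for z in (0.0, 5.0, 18.9):
            surface = forward_shallow_reflectance(_bottom(rb, optics, grid), _depth(z, grid), optics)
            for b, r in enumerate(optics.r_inf):
                np.testing.assert_allclose(surface.values[b], r, atol=1e-15)

    def test_hand_evaluation(self, optics):
        grid = Grid(rows=1, cols=1, pixel_size=5.0)
        rb = np.full((3, 1, 1), 0.20)
        surface = forward_shallow_reflectance(_bottom(rb, optics, grid), _depth(10.0, grid), optics)
        expected = 0.033 + (0.20 - 0.033) * math.exp(-2 * 0.067 * 10)
        assert surface.values[0, 0, 0] == pytest.approx(expected, rel=1e-12)

    def test_negative_depth_rejected(self, optics):
        grid = Grid(rows=2, cols=2, pixel_size=5.0)
        rb = np.full((3, 2, 2), 0.1)
        with pytest.raises(ValueError, match="negative depth"):
            forward_shallow_reflectance(_bottom(rb, optics, grid), _depth(-1.0, grid), optics)

    def test_monotone_towards_r_inf(self, optics):
        grid = Grid(rows=1, cols=1, pixel_size=5.0)
        depths = np.linspace(0, 20, 30)
        bright = np.full((3, 1, 1), 0.5)
        dark = np.full((3, 1, 1), 0.001)
        for rb, sign in ((bright, -1), (dark, 1)):
            vals = np.array(
                [
                    forward_shallow_reflectance(
                        _bottom(rb, optics, grid), _depth(z, grid), optics
                    ).values[0, 0, 0]
                    for z in depths
                ]
            )
            assert np.all(sign * np.diff(vals) > 0)
            # approaches the deep-water asymptote
            assert abs(vals[-1] - optics.r_inf[0]) < 0.1 * abs(vals[0] - optics.r_inf[0])


class TestWaterColumnCorrection:
    def test_zero_depth_identity(self, optics, flat_scene_factory):
        scene = flat_scene_factory(0.2)
        grid = scene.grid
        rb = correct_water_column(scene, _depth(0.0, grid), optics)
        np.testing.assert_allclose(rb.values, 0.2, atol=1e-15)
        assert rb.stage == STAGE_BOTTOM

    def test_r_inf_fixed_point(self, optics):
        grid = Grid(rows=3, cols=3, pixel_size=5.0)
        vals = np.stack([np.full(grid.shape, r) for r in optics.r_inf])
        scene = ReflectanceScene(values=vals, bands=optics.bands, grid=grid, stage="surface_R")
        rb = correct_water_column(scene, _depth(12.0, grid), optics)
        for b, r in enumerate(optics.r_inf):
            np.testing.assert_allclose(rb.values[b], r, atol=1e-12)

    def test_round_trip_random(self, optics):
        rng = np.random.default_rng(123)
        grid = Grid(rows=20, cols=20, pixel_size=5.0)
        rb = rng.uniform(0.0, 0.3, size=(3,) + grid.shape)
        z = DepthRaster(values=rng.uniform(0, 18.9, size=grid.shape), grid=grid)
        surface = forward_shallow_reflectance(_bottom(rb, optics, grid), z, optics)
        back = correct_water_column(surface, z, optics)
        np.testing.assert_allclose(back.values, rb, atol=1e-10)

    def test_missing_depth_rejected(self, optics, flat_scene_factory):
        scene = flat_scene_factory(0.1)
        grid = scene.grid
        dmask = np.zeros(grid.shape, dtype=bool)
        dmask[0, 0] = True
        with pytest.raises(ValueError, match="depth missing"):
            correct_water_column(scene, _depth(5.0, grid, mask=dmask), optics)

    def test_out_of_range_policies(self, optics, flat_scene_factory):
        scene = flat_scene_factory(0.9)  # inverts far above 1 at depth
        grid = scene.grid
        z = _depth(15.0, grid)
        clamped = correct_water_column(scene, z, optics, out_of_range="clamp")
        assert clamped.values.max() <= 1.0
        assert not clamped.mask.any()
        masked = correct_water_column(scene, z, optics, out_of_range="mask")
        assert masked.mask.all()

    def test_mask_conservation(self, optics):
        grid = Grid(rows=4, cols=4, pixel_size=5.0)
        mask = np.zeros(grid.shape, dtype=bool)
        mask[1, 2] = True
        vals = np.full((3,) + grid.shape, 0.1)
        scene = ReflectanceScene(values=vals, bands=optics.bands, grid=grid, mask=mask, stage="surface_R")
        for out in (
            surface_to_rrs(scene, optics),
            correct_water_column(scene, _depth(3.0, grid), optics),
            apply_deep_mask(scene, _depth(3.0, grid)),
        ):
            assert out.mask[1, 2]


class TestDeepMask:
    def test_all_shallow_unchanged(self, optics, flat_scene_factory):
        scene = flat_scene_factory(0.1)
        out = apply_deep_mask(scene, _depth(5.0, scene.grid), limit_m=16.5)
        assert not out.mask.any()
        np.testing.assert_array_equal(out.values, scene.values)

    def test_all_deep_fully_masked(self, optics, flat_scene_factory):
        scene = flat_scene_factory(0.1)
        out = apply_deep_mask(scene, _depth(17.0, scene.grid), limit_m=16.5)
        assert out.mask.all()

    def test_count_matches_threshold(self, optics, flat_scene_factory):
        scene = flat_scene_factory(0.1)
        rng = np.random.default_rng(7)
        zvals = rng.uniform(0, 25, size=scene.grid.shape)
        z = DepthRaster(values=zvals, grid=scene.grid)
        out = apply_deep_mask(scene, z, limit_m=16.5)
        assert (~out.mask).sum() == np.count_nonzero(zvals <= 16.5)

    def test_bad_limit(self, optics, flat_scene_factory):
        scene = flat_scene_factory(0.1)
        with pytest.raises(ValueError):
            apply_deep_mask(scene, _depth(5.0, scene.grid), limit_m=0)


@given(
    rb=st.floats(0.0, 1.0),
    z=st.floats(0.0, 18.9),
    band=st.integers(0, 2),
)
@settings(max_examples=60, deadline=None)
def test_round_trip_property(rb, z, band):
    optics = OpticalConstants()
    kd, rinf = optics.kd[band], optics.r_inf[band]
    r = rinf + (rb - rinf) * math.exp(-2 * kd * z)
    back = rinf + (r - rinf) * math.exp(2 * kd * z)
    assert back == pytest.approx(rb, abs=1e-10)
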