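"""Phantom generation, sub-pixel widening and stack I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rhinoflow import (GeometryError, ImageStack, PhantomSpec,
                       ResolutionError, airway_metrics, generate_phantom,
                       read_stack, widen_airway, write_stack)


def small_spec(**kw):
    base = dict(total_length=2_000, inlet_height=1_700, dorsal_width=500,
                ventral_width=900, fin_start=500, fin_end=1_800,
                fin_thickness=300, squamous_end=400, respiratory_end=600,
                olfactory_end=1_700, pixel_spacing=50, slice_thickness=500,
                depth=1_000)
    base.update(kw)
    return PhantomSpec(**base)


def rectangle_stack(width_px=5, pixel_um=100.0, n_slices=3):
    sl = np.zeros((n_slices, 20, 30), np.uint8)
    sl[:, 5:5 + width_px, 5:25] = 1
    return ImageStack(sl, pixel_um, 300.0)


class TestPhantomSpec:
    def test_invalid_specs_rejected(self):
        with pytest.raises(GeometryError):
            small_spec(fin_thickness=2_000, dorsal_width=500,
                       ventral_width=900)  # fin wider than lumen tiling
        with pytest.raises(GeometryError):
            small_spec(dorsal_width=900, ventral_width=500,
                       fin_thickness=300)  # dorsal channel must be narrower
        with pytest.raises((ResolutionError, GeometryError)):
            small_spec(pixel_spacing=200)  # cannot resolve channels
        with pytest.raises(GeometryError):
            small_spec(squamous_end=700, respiratory_end=600)

    def test_widened_spec_conserves_tiling(self):
        spec = small_spec()
        wide = spec.widened(34.0, "total-width")
        assert wide.dorsal_width == spec.dorsal_width + 34
        assert wide.ventral_width == spec.ventral_width + 34
        assert wide.fin_thickness == spec.fin_thickness - 34
        assert np.isclose(wide.dorsal_width + wide.ventral_width
                          + wide.fin_thickness, wide.inlet_height)
        # per-wall mode recedes twice as far
        pw = spec.widened(17.0, "per-wall")
        assert pw.dorsal_width == wide.dorsal_width

    def test_widening_cannot_consume_fin(self):
        with pytest.raises(GeometryError):
            small_spec().widened(400.0)


class TestGeneratePhantom:
    def test_default_phantom_has_100_slices(self):
        stack = generate_phantom(PhantomSpec())
        assert stack.n_slices == 100

    def test_deterministic_bitwise(self):
        a = generate_phantom(small_spec())
        b = generate_phantom(small_spec())
        assert np.array_equal(a.slices, b.slices)

    def test_channel_width_by_column_count(self):
        spec = small_spec(pixel_spacing=10)
        stack = generate_phantom(spec)
        # mid-olfactory slice, central column: dorsal channel pixel count
        sl = stack.slices[2]                 # x = 1250 µm, inside fin extent
        col = sl[:, sl.shape[1] // 2]
        runs = np.diff(np.concatenate([[0], col, [0]]))
        lengths = (np.nonzero(runs == -1)[0]
                   - np.nonzero(runs == 1)[0]) * spec.pixel_spacing
        assert len(lengths) == 2             # dorsal + ventral channels
        assert abs(lengths[0] - spec.dorsal_width) <= spec.pixel_spacing

    def test_unresolvable_channels_raise(self):
        with pytest.raises(ResolutionError):
            generate_phantom(small_spec(pixel_spacing=90, dorsal_width=160,
                                        ventral_width=1240))


class TestWidenAirway:
    def test_identity_at_zero_delta(self):
        stack = rectangle_stack()
        out = widen_airway(stack, 0.0, upsample_factor=1)
        assert np.array_equal(out.slices, stack.slices)
        assert out.pixel_spacing == stack.pixel_spacing

    def test_output_spacing(self):
        out = widen_airway(rectangle_stack(), 34.0, upsample_factor=50)
        assert out.pixel_spacing == pytest.approx(2.0)

    def test_rectangle_total_width_mode(self):
        out = widen_airway(rectangle_stack(), 34.0, "total-width", 50)
        col = out.slices[1, :, out.slices.shape[2] // 2]
        assert abs(col.sum() * out.pixel_spacing - 534.0) <= out.pixel_spacing

    def test_rectangle_per_wall_mode(self):
        out = widen_airway(rectangle_stack(), 34.0, "per-wall", 50)
        col = out.slices[1, :, out.slices.shape[2] // 2]
        assert abs(col.sum() * out.pixel_spacing - 568.0) <= out.pixel_spacing

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            widen_airway(rectangle_stack(), -1.0)
        with pytest.raises(ValueError):
            widen_airway(rectangle_stack(), 10.0, "sideways", 50)
        with pytest.raises(ResolutionError):
            widen_airway(rectangle_stack(), 34.0, upsample_factor=2)

    def test_merge_across_septum_warns(self):
        sl = np.zeros((1, 30, 30), np.uint8)
        sl[0, 5:10, 5:25] = 1
        sl[0, 12:17, 5:25] = 1               # two bars 200 µm apart
        stack = ImageStack(sl, 100.0, 300.0)
        with pytest.warns(UserWarning, match="topology"):
            out = widen_airway(stack, 300.0, "total-width", 10)
        assert out.meta["topology_warnings"]

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(width=st.integers(3, 8),
           delta=st.one_of(st.just(0.0), st.floats(40.0, 200.0)))
    def test_monotone_growth(self, width, delta):
        stack = rectangle_stack(width_px=width)
        out = widen_airway(stack, delta, "total-width", 10)
        base = np.repeat(np.repeat(stack.slices, 10, axis=1), 10, axis=2)
        assert (out.slices >= base).all()    # airway never shrinks
        if delta / 2 >= 2 * out.pixel_spacing:
            assert out.slices.sum() > base.sum()

    def test_composition_within_one_pixel(self):
        stack = rectangle_stack()
        direct = widen_airway(stack, 34.0, "total-width", 50)
        step1 = widen_airway(stack, 20.0, "total-width", 50)
        two_step = widen_airway(step1, 14.0, "total-width", 1)
        diff = direct.slices.astype(int) - two_step.slices.astype(int)
        # any disagreement must lie within a one-pixel shell of the boundary
        from scipy import ndimage
        shell = ndimage.binary_dilation(direct.slices[1]) \
            ^ ndimage.binary_erosion(direct.slices[1])
        assert np.abs(diff[1])[~shell].sum() == 0


class TestStackIO:
    def test_round_trip_bitwise(self, tmp_path):
        stack = generate_phantom(small_spec())
        write_stack(stack, tmp_path / "s")
        back = read_stack(tmp_path / "s")
        assert np.array_equal(back.slices, stack.slices)
        assert back.pixel_spacing == stack.pixel_spacing
        assert back.slice_thickness == stack.slice_thickness

    def test_missing_sidecar(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(FileNotFoundError):
            read_stack(tmp_path / "empty")

    def test_shape_mismatch_and_bad_values(self, tmp_path):
        import imageio.v3 as iio
        import json
        d = tmp_path / "bad"
        d.mkdir()
        iio.imwrite(d / "a.png", np.zeros((8, 8), np.uint8) + 255)
        iio.imwrite(d / "b.png", np.zeros((8, 9), np.uint8) + 255)
        sidecar = {"pixel_spacing_um": 50.0, "slice_thickness_um": 200.0,
                   "slices": ["a.png", "b.png"]}
        (d / "stack.json").write_text(json.dumps(sidecar))
        with pytest.raises(ValueError, match="shape"):
            read_stack(d)
        iio.imwrite(d / "b.png", np.full((8, 8), 7, np.uint8))
        with pytest.raises(ValueError, match="non-binary.*b.png"):
            read_stack(d)
        sidecar["pixel_spacing_um"] = -1.0
        (d / "stack.json").write_text(json.dumps(sidecar))
        with pytest.raises(ValueError, match="spacing"):
            read_stack(d)


class TestAirwayMetrics:
    def test_full_slice_closed_form(self):
        stack = ImageStack(np.ones((1, 10, 10), np.uint8), 100.0, 300.0)
        m = airway_metrics(stack)
        assert m["volume_m3"] == pytest.approx(100 * (1e-4) ** 2 * 3e-4)

    def test_box_volume_matches_analytic(self):
        stack = rectangle_stack(n_slices=10)   # 500 µm x 2000 µm x 10 slices
        m = airway_metrics(stack)
        pixel_vol = (100e-6) ** 2 * 300e-6
        assert abs(m["volume_m3"] - 500e-6 * 2000e-6 * 10 * 300e-6) \
            <= 2 * pixel_vol

    def test_widening_increases_volume(self):
        stack = generate_phantom(small_spec())
        wide = widen_airway(stack, 34.0, "total-width", 10)
        assert airway_metrics(wide)["volume_m3"] \
            > airway_metrics(stack)["volume_m3"]
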