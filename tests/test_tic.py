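"""TIC extraction: dilation, LUT decoding, sampling rule, smoothing, parameters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import savgol_filter

from ceustic.frame_io import DEFAULT_REGIONS, crop_region
from ceustic.segmentation import GroundTruthMaskProvider
from ceustic.tic import (
    BinaryMask,
    ColorLUT,
    EmptyMaskError,
    StructuringElement,
    TICParams,
    TimeIntensityCurve,
    accept_sample,
    build_lut,
    dilate,
    extract_params,
    mean_intensity,
    parenchyma_ring,
    read_tic_csv,
    sample_tic,
    smooth_tic,
    write_tic_csv,
)


from oracles import brute_force_dilate


class TestDilate:
    def test_empty_mask_stays_empty(self):
        out = dilate(BinaryMask(np.zeros((20, 20), bool), "b_mode_panel"), 10)
        assert out.area == 0

    def test_single_pixel_block(self):
        """One on-pixel dilated by an all-true 10x10 kernel anchored at (5,5)
        becomes the 10x10 block with rows/cols 45..54."""
        mask = np.zeros((100, 100), bool)
        mask[50, 50] = True
        out = dilate(BinaryMask(mask, "b_mode_panel"), 10)
        expected = np.zeros((100, 100), bool)
        expected[45:55, 45:55] = True
        assert np.array_equal(out.data, expected)

    @settings(max_examples=30, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        ksize=st.integers(1, 12),
        density=st.floats(0.02, 0.3),
    )
    def test_matches_set_union_oracle(self, seed, ksize, density):
        rng = np.random.default_rng(seed)
        mask = rng.random((30, 30)) < density
        kernel = rng.random((ksize, ksize)) < 0.7
        if not kernel.any():
            kernel[0, 0] = True
        anchor = (ksize // 2, ksize // 2)
        se = StructuringElement(kernel, anchor)
        fast = dilate(BinaryMask(mask, "b_mode_panel"), se)
        slow = brute_force_dilate(mask, kernel, anchor)
        assert np.array_equal(fast.data, slow)

    def test_output_superset_of_input(self):
        rng = np.random.default_rng(1)
        mask = rng.random((40, 40)) > 0.9
        out = dilate(BinaryMask(mask, "b_mode_panel"), 10)
        assert np.all(out.data[mask])

    def test_empty_kernel_rejected(self):
        with pytest.raises(ValueError):
            StructuringElement(np.zeros((3, 3), bool), (1, 1))


class TestParenchymaRing:
    def test_partition_identities(self):
        rng = np.random.default_rng(5)
        mask = BinaryMask(rng.random((50, 50)) > 0.85, "contrast_panel")
        dil = dilate(mask, 10)
        ring = parenchyma_ring(mask, dil)
        assert not np.any(ring.data & mask.data)
        assert np.array_equal(ring.data | mask.data, dil.data)

    def test_disc_ring_area_by_pixel_count(self):
        yy, xx = np.mgrid[:100, :100]
        disc = (yy - 50) ** 2 + (xx - 50) ** 2 <= 25
        mask = BinaryMask(disc, "contrast_panel")
        se = StructuringElement(np.ones((11, 11), bool), (5, 5))
        dil = dilate(mask, se)
        ring = parenchyma_ring(mask, dil)
        assert ring.area == dil.area - mask.area

    def test_equal_masks_give_empty_ring(self):
        mask = BinaryMask(np.ones((10, 10), bool), "contrast_panel")
        assert parenchyma_ring(mask, mask).area == 0

    def test_empty_mask_ring_is_dilated(self):
        empty = BinaryMask(np.zeros((10, 10), bool), "contrast_panel")
        dil = BinaryMask(np.ones((10, 10), bool), "contrast_panel")
        assert np.array_equal(parenchyma_ring(empty, dil).data, dil.data)

    def test_non_superset_rejected(self):
        mask = BinaryMask(np.ones((10, 10), bool), "contrast_panel")
        other = BinaryMask(np.zeros((10, 10), bool), "contrast_panel")
        with pytest.raises(ValueError, match="superset"):
            parenchyma_ring(mask, other)


class TestColorLUT:
    def test_grayscale_ramp_strip(self):
        levels = np.linspace(255, 0, 70).round().astype(np.uint8)
        strip = np.repeat(levels[:, None, None], 5, axis=1).repeat(3, axis=2)
        lut = build_lut(strip)
        assert len(lut.colors) == 70
        assert lut.intensities[0] == 255.0
        assert lut.intensities[-1] == 0.0
        assert np.all(np.diff(lut.intensities) < 0)

    def test_two_row_strip(self):
        strip = np.stack([np.full((1, 3), 255, np.uint8).repeat(4, 0)[None, :, :][0],
                          np.zeros((4, 3), np.uint8)])[:, None, :] \
            if False else np.array([[[255, 255, 255]], [[0, 0, 0]]], np.uint8)
        lut = build_lut(strip)
        assert lut.decode(np.array([[250, 250, 250]]))[0] == 255.0
        assert lut.decode(np.array([[5, 5, 5]]))[0] == 0.0

    def test_constant_strip_rejected(self):
        strip = np.full((10, 5, 3), 42, np.uint8)
        with pytest.raises(ValueError, match="constant"):
            build_lut(strip)

    def test_mean_intensity_uniform_and_mixture(self):
        colors = np.array([[0, 0, 0], [100, 100, 100], [255, 255, 255]], float)
        lut = ColorLUT(colors, np.array([0.0, 200.0, 255.0]))
        panel = np.full((4, 4, 3), 100, np.uint8)
        mask = np.ones((4, 4), bool)
        assert mean_intensity(panel, mask, lut) == 200.0
        half = panel.copy()
        half[:2] = 0
        half[2:] = 255
        lut2 = ColorLUT(np.array([[0, 0, 0], [255, 255, 255]], float), np.array([0.0, 255.0]))
        assert mean_intensity(half, mask, lut2) == 127.5

    def test_empty_mask_raises_distinct_error(self):
        lut = ColorLUT(np.array([[0, 0, 0], [255, 255, 255]], float), np.array([0.0, 255.0]))
        with pytest.raises(EmptyMaskError):
            mean_intensity(np.zeros((4, 4, 3), np.uint8), np.zeros((4, 4), bool), lut)

    def test_decode_matches_per_pixel_brute_force(self):
        rng = np.random.default_rng(9)
        colors = rng.integers(0, 255, (16, 3)).astype(float)
        lut = ColorLUT(colors, np.linspace(255, 0, 16))
        pixels = rng.integers(0, 255, (200, 3))
        fast = lut.decode(pixels)
        for px, value in zip(pixels, fast):
            d2 = ((px - colors) ** 2).sum(axis=1)
            assert value == lut.intensities[int(np.argmin(d2))]


class TestValidityRule:
    def test_first_sample_always_accepted(self):
        assert accept_sample(None, 5.0)

    def test_rule_arithmetic(self):
        # |30 - 100| = 70 < 75 -> accepted; |10 - 100| = 90 > 75 -> rejected
        assert accept_sample(100.0, 30.0)
        assert not accept_sample(100.0, 10.0)

    def test_zero_previous_accepts(self):
        assert accept_sample(0.0, 50.0)

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 1000), f_lo=st.floats(0.3, 0.7))
    def test_monotone_in_reject_fraction_on_smooth_curves(self, seed, f_lo):
        """On smooth perfusion-like series with dropout transients, raising
        the acceptance threshold never reduces the accepted count.

        (For arbitrary series this need not hold — the rule is stateful, so
        accepting an outlier changes the reference for later samples — but
        on curves whose valid samples vary slowly it does.)
        """
        rng = np.random.default_rng(seed)
        t = np.arange(60.0)
        series = 20.0 + 100.0 * np.exp(-((t - 30.0) / 15.0) ** 2)
        drop = rng.random(60) < 0.1
        series[drop] *= 0.02  # probe-lift-like transients

        def n_accepted(fraction):
            prev, n = None, 0
            for v in series:
                if accept_sample(prev, v, fraction):
                    prev = v
                    n += 1
            return n

        assert n_accepted(0.75) >= n_accepted(min(f_lo, 0.75))


class TestSampleTic:
    def test_probe_lift_seconds_invalid_then_recovers(self, lift_phantom):
        ph = lift_phantom
        provider = GroundTruthMaskProvider(ph.masks, DEFAULT_REGIONS["b_mode"])
        curve = sample_tic(ph.frames, provider)
        invalid = set(np.flatnonzero(~curve.valid).tolist())
        assert {60, 61, 62} <= invalid
        assert curve.valid[59] and curve.valid[64]

    def test_parenchyma_from_same_frame(self, lift_phantom):
        ph = lift_phantom
        provider = GroundTruthMaskProvider(ph.masks, DEFAULT_REGIONS["b_mode"])
        curve = sample_tic(ph.frames, provider)
        sel = curve.valid
        assert np.all(np.isfinite(curve.parenchyma[sel]))
        assert np.all(curve.frame_index[sel] >= 0)

    def test_raising_fraction_keeps_or_adds_valid_seconds(self, lift_phantom):
        ph = lift_phantom
        provider = GroundTruthMaskProvider(ph.masks, DEFAULT_REGIONS["b_mode"])
        strict = sample_tic(ph.frames, provider, reject_fraction=0.3)
        loose = sample_tic(ph.frames, provider, reject_fraction=0.95)
        assert loose.n_valid >= strict.n_valid


def make_curve(values, times=None, valid=None):
    values = np.asarray(values, float)
    n = len(values)
    times = np.arange(n, dtype=float) if times is None else np.asarray(times, float)
    valid = np.ones(n, bool) if valid is None else np.asarray(valid, bool)
    vals = values.copy()
    vals[~valid] = np.nan
    return TimeIntensityCurve(times, vals, vals.copy(), valid, np.arange(n))


class TestSmoothTic:
    def test_cubic_polynomial_passes_unchanged(self):
        t = np.arange(120.0)
        y = 1e-4 * t**3 - 0.02 * t**2 + 1.5 * t + 7
        out = smooth_tic(make_curve(y), window=51, polyorder=3)
        np.testing.assert_allclose(out.lesion, y, rtol=1e-8)

    def test_constant_curve_unchanged(self):
        out = smooth_tic(make_curve(np.full(60, 42.0)))
        np.testing.assert_allclose(out.lesion, 42.0)

    def test_window_shrinks_to_odd_length(self):
        """A 30-sample curve is filtered with the largest odd window <= 30."""
        rng = np.random.default_rng(0)
        y = rng.uniform(10, 100, 30)
        out = smooth_tic(make_curve(y), window=51, polyorder=3)
        ref = savgol_filter(y, 29, 3, mode="interp")
        np.testing.assert_allclose(out.lesion, ref, rtol=1e-10)

    def test_invalid_gaps_interpolated_then_reflagged(self):
        t = np.arange(40.0)
        y = 2.0 * t + 5
        valid = np.ones(40, bool)
        valid[10:13] = False
        out = smooth_tic(make_curve(y, valid=valid), window=11, polyorder=3)
        assert not out.valid[11]
        assert np.isnan(out.lesion[11])
        np.testing.assert_allclose(out.lesion[out.valid], y[out.valid], rtol=1e-8)

    def test_too_few_valid_samples_rejected(self):
        with pytest.raises(ValueError, match="valid samples"):
            smooth_tic(make_curve([1.0, 2.0, 3.0, 4.0]))


class TestExtractParams:
    def test_constant_curve_degenerate_forms(self):
        with pytest.warns(UserWarning, match="flat"):
            p = extract_params(make_curve(np.full(21, 50.0)))
        assert p.max_intensity == 50.0
        assert p.ttp == 0.0
        assert p.auc == pytest.approx(50.0 * 20)
        assert np.isnan(p.mtt)

    def test_symmetric_triangle(self):
        t = np.arange(21.0)
        y = 100.0 - 10.0 * np.abs(t - 10.0)
        p = extract_params(make_curve(y))
        assert p.ttp == 10.0
        assert p.mtt == pytest.approx(10.0)
        assert p.max_intensity == 100.0

    def test_max_dominates_series(self, clean_phantom):
        ph = clean_phantom
        provider = GroundTruthMaskProvider(ph.masks, DEFAULT_REGIONS["b_mode"])
        smoothed = smooth_tic(sample_tic(ph.frames, provider))
        p = extract_params(smoothed)
        assert p.max_intensity >= np.nanmax(smoothed.lesion) - 1e-9
        assert 0 <= p.ttp <= smoothed.time[-1]
        assert p.auc >= 0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            extract_params(make_curve([1.0, 2.0]))


class TestCsvRoundtrip:
    def test_write_read_identity(self, tmp_path):
        rng = np.random.default_rng(4)
        values = rng.uniform(0, 255, 30)
        valid = rng.random(30) > 0.2
        curve = make_curve(values, valid=valid)
        params = TICParams(123.4, 17.0, 4567.8, 41.2)
        path = write_tic_csv(curve, params, tmp_path / "tic.csv")
        back, back_params = read_tic_csv(path)
        np.testing.assert_allclose(back.time, curve.time)
        np.testing.assert_allclose(back.lesion, curve.lesion)
        np.testing.assert_array_equal(back.valid, curve.valid)
        assert back_params == params

    def test_invalid_rows_have_empty_cells(self, tmp_path):
        curve = make_curve([10.0, 20.0, 30.0, 40.0, 50.0],
                           valid=[True, False, True, True, True])
        path = write_tic_csv(curve, None, tmp_path / "tic.csv")
        lines = path.read_text().splitlines()
        assert lines[0] == "time_s,lesion_intensity,parenchyma_intensity,valid,frame_index"
        assert ",,," in lines[2]  # the invalid second carries no intensities

    def test_params_file_has_exactly_four_values(self, tmp_path):
        import pandas as pd

        curve = make_curve(np.linspace(1, 9, 9))
        params = extract_params(curve)
        write_tic_csv(curve, params, tmp_path / "tic.csv")
        df = pd.read_csv(tmp_path / "tic_params.csv")
        assert list(df.columns) == ["max_intensity", "ttp_s", "auc", "mtt_s"]
        assert len(df) == 1
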