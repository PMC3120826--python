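"""Stimulus generator: geometry, densities, contrast, flicker, ST plots."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moonwalk import (
    GeometryError,
    StimulusSpec,
    coherence_to_survival,
    generate_sequence,
    make_center_mask,
    measure_density,
    measure_michelson,
    measure_survival,
    set_region_contrast,
    st_plot,
)


class TestCenterMask:
    def test_zero_perturbation_is_exact_disc(self):
        mask = make_center_mask((128, 128), 4.0, 25.0, 0, outline_perturbation=0.0)
        cy = cx = 63.5
        rows, cols = np.mgrid[0:128, 0:128]
        expected = np.hypot(rows - cy, cols - cx) < 50.0
        assert np.array_equal(mask, expected)

    def test_same_seed_bit_identical(self):
        a = make_center_mask((128, 128), 4.0, 25.0, 7)
        b = make_center_mask((128, 128), 4.0, 25.0, 7)
        assert np.array_equal(a, b)

    def test_seeds_differ_but_areas_close(self):
        areas = []
        masks = []
        for seed in range(30):
            m = make_center_mask((256, 256), 6.2, 25.0, seed)
            masks.append(m)
            areas.append(m.sum())
        assert not np.array_equal(masks[0], masks[1])
        areas = np.asarray(areas, dtype=float)
        # calibrated: outline phases barely move the enclosed area
        assert areas.max() / areas.min() < 1.10

    def test_oversized_diameter_rejected(self):
        with pytest.raises(GeometryError):
            make_center_mask((100, 100), 6.2, 25.0, 0)


class TestCoherenceMapping:
    @pytest.mark.parametrize(
        "value,expected",
        [(1.0, 1.0), (0.5, 0.5), (0.75, 0.75), (100, 1.0), (50, 0.5), (75, 0.75)],
    )
    def test_identity_mapping(self, value, expected):
        assert coherence_to_survival(value) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [0.3, 40.0, 101.0, 1.2, -0.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            coherence_to_survival(bad)


class TestSpecInvariants:
    def test_default_spec_timing(self):
        spec = StimulusSpec()
        assert spec.n_frames == 300  # 4 s at 75 Hz
        assert spec.displacement_px == 2  # 6 deg/s at 25 px/deg, 75 Hz

    def test_non_integer_displacement_rejected(self):
        spec = StimulusSpec(center_speed_deg_per_s=5.0)  # 1.67 px/frame
        with pytest.raises(GeometryError):
            spec.validate()

    def test_oblique_direction_off_grid_rejected(self):
        spec = StimulusSpec(motion_direction_deg=45.0)
        with pytest.raises(GeometryError):
            spec.validate()


class TestGeneratedSequences:
    def test_static_surround_is_constant(self, small_seq):
        sur = small_seq.frames[:, small_seq.surround_mask]
        assert np.array_equal(sur, np.broadcast_to(sur[0], sur.shape))

    def test_zero_speed_static_surround_all_frames_identical(self):
        spec = StimulusSpec(
            frame_size_px=(96, 96),
            stimulus_diameter_deg=3.0,
            duration_s=0.4,
            center_speed_deg_per_s=0.0,
        )
        seq = generate_sequence(spec)
        assert np.array_equal(
            seq.frames, np.broadcast_to(seq.frames[0], seq.frames.shape)
        )

    def test_dot_density_near_half(self, small_seq):
        for region in ("center", "surround"):
            assert measure_density(small_seq, region) == pytest.approx(0.5, abs=0.01)

    def test_center_stream_independent_of_surround_flicker(
        self, small_seq, small_seq_flicker
    ):
        a = small_seq.frames[:, small_seq.center_mask]
        b = small_seq_flicker.frames[:, small_seq_flicker.center_mask]
        assert np.array_equal(a, b)

    def test_masks_disjoint_and_static(self, small_seq):
        assert not np.any(small_seq.center_mask & small_seq.surround_mask)

    def test_center_translates_through_static_outline(self, small_seq):
        # interior content moves up 2 px/frame; the mask itself does not move
        drow, dcol = small_seq.spec.displacement_vector
        assert (drow, dcol) == (-2, 0)
        h0 = small_seq.hidden_frame(0)
        h1 = small_seq.hidden_frame(1)
        assert np.array_equal(h1[:-2], h0[2:])


class TestSurvival:
    def test_static_survival_exact_one(self, small_seq):
        assert measure_survival(small_seq) == pytest.approx(1.0, abs=0.0)

    def test_flicker_survival_recovered(self):
        # 300 frames, ample surround: chance-corrected estimate within 0.02
        spec = StimulusSpec(
            frame_size_px=(128, 128),
            stimulus_diameter_deg=3.0,
            duration_s=4.0,
            surround_temporal_coherence=0.5,
            rng_seed=2,
        )
        seq = generate_sequence(spec)
        assert measure_survival(seq) == pytest.approx(0.5, abs=0.02)

    def test_raw_agreement_is_chance_inflated(self):
        # at survival 0.5 and density 0.5 raw agreement sits near 0.75
        spec = StimulusSpec(
            frame_size_px=(128, 128),
            stimulus_diameter_deg=3.0,
            duration_s=2.0,
            surround_temporal_coherence=0.5,
            rng_seed=3,
        )
        seq = generate_sequence(spec)
        states = seq.frames[:, seq.surround_mask] > 0.5
        raw = (states[1:] == states[:-1]).mean()
        assert raw == pytest.approx(0.75, abs=0.02)


class TestContrast:
    def test_default_michelson_unity(self, small_seq):
        assert measure_michelson(small_seq, "center") == 1.0
        assert measure_michelson(small_seq, "surround") == 1.0

    def test_half_contrast_levels(self, small_seq):
        seq = set_region_contrast(small_seq, "surround", 0.5)
        levels = np.unique(seq.frames[:, seq.surround_mask])
        assert np.allclose(sorted(levels), [0.25, 0.75])
        assert measure_michelson(seq, "surround") == pytest.approx(0.5)

    def test_identity_contrast_unchanged(self, small_seq):
        seq = set_region_contrast(small_seq, "center", 1.0)
        assert np.array_equal(seq.frames, small_seq.frames)

    def test_dot_pattern_and_flicker_untouched(self, small_seq_flicker):
        seq = set_region_contrast(small_seq_flicker, "surround", 0.3)
        for t in (0, 10, 59):
            assert np.array_equal(
                seq.binary_states(t, "surround"),
                small_seq_flicker.binary_states(t, "surround"),
            )

    def test_unknown_region_rejected(self, small_seq):
        with pytest.raises(ValueError):
            set_region_contrast(small_seq, "background", 0.5)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(contrast=st.floats(min_value=0.05, max_value=1.0))
    def test_region_mean_conserved(self, small_seq, contrast):
        seq = set_region_contrast(small_seq, "center", contrast)
        levels = np.unique(seq.frames[:, seq.center_mask]).astype(np.float64)
        assert np.allclose(levels.mean(), 0.5, atol=1e-6)  # symmetric levels
        before = float(small_seq.frames[:, small_seq.center_mask].mean())
        after = float(seq.frames[:, seq.center_mask].mean())
        assert after == pytest.approx(before, abs=0.01)


class TestStPlot:
    def test_static_scene_traces_parallel_to_time_axis(self):
        spec = StimulusSpec(
            frame_size_px=(96, 96),
            stimulus_diameter_deg=3.0,
            duration_s=0.4,
            center_speed_deg_per_s=0.0,
        )
        seq = generate_sequence(spec)
        st_img = st_plot(seq)
        assert np.array_equal(st_img, np.broadcast_to(st_img[0], st_img.shape))

    def test_moving_center_trace_slope_matches_displacement(self, small_seq):
        st_img = st_plot(small_seq)  # single central column, upward motion
        col = small_seq.spec.frame_size_px[1] // 2
        inside = small_seq.center_mask[:, col]
        ok = inside & np.roll(inside, -2)
        ok[-2:] = False
        ys = np.flatnonzero(ok)
        for t in range(0, 20):
            assert np.array_equal(st_img[t + 1, ys], st_img[t, ys + 2])

    def test_center_band_identical_across_surround_flicker(
        self, small_seq, small_seq_flicker
    ):
        a = st_plot(small_seq)
        b = st_plot(small_seq_flicker)
        col = small_seq.spec.frame_size_px[1] // 2
        inside = small_seq.center_mask[:, col]
        assert np.array_equal(a[:, inside], b[:, inside])

    def test_band_outside_frame_rejected(self, small_seq):
        with pytest.raises(ValueError):
            st_plot(small_seq, (90, 200))
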