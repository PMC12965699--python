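"""Stimulus generator and retinal preprocessing tests."""

import numpy as np
import pytest

from mlsod.stimuli import (
    BackgroundSpec,
    FlickerSpec,
    FrameSequence,
    HighContrastObjectSpec,
    ObjectSpec,
    downsample_ground_truth,
    flicker_value,
    generate_sequence,
    gaussian_kernel_1d,
    make_procedural_background,
    retina_preprocess,
    weber_contrast,
)

BG = BackgroundSpec(seed=3, shape=(120, 200))


class TestGenerateSequence:
    def test_object_shifts_two_px_per_frame_at_200(self):
        # 200 px/s at dh = 10 ms -> 2 px leftward per frame
        obj = ObjectSpec(size_px=6, luminance=0.0, speed_px_s=200.0,
                         direction=(0.0, -1.0), start_position=(50.0, 150.0))
        _, gt = generate_sequence(obj, BG, n_frames=5, dt=0.010)
        cols = gt.centers[:, 1]
        np.testing.assert_array_equal(np.diff(cols), -2.0)

    def test_zero_speed_keeps_masks_identical(self):
        obj = ObjectSpec(size_px=6, speed_px_s=0.0,
                         start_position=(50.0, 100.0))
        _, gt = generate_sequence(obj, BG, n_frames=5, dt=0.010)
        for t in range(1, 5):
            np.testing.assert_array_equal(gt.masks[t], gt.masks[0])

    def test_mask_pixel_count_equals_size_squared_inside_frame(self):
        obj = ObjectSpec(size_px=7, speed_px_s=200.0,
                         start_position=(40.0, 150.0))
        _, gt = generate_sequence(obj, BG, n_frames=10, dt=0.010)
        assert (gt.masks.sum(axis=(1, 2)) == 49).all()

    def test_high_contrast_footprint_and_core(self):
        obj = HighContrastObjectSpec(core_size=10, border_size=40,
                                     core_luminance=0.0, border_luminance=1.0,
                                     speed_px_s=0.0,
                                     start_position=(30.0, 60.0))
        seq, gt = generate_sequence(obj, BG, n_frames=1, dt=0.010)
        frame = seq.frames[0]
        patch = frame[30:70, 60:100]
        assert patch.shape == (40, 40)
        # border white, 10x10 dark center
        np.testing.assert_array_equal(patch[15:25, 15:25], 0.0)
        border = patch.copy()
        border[15:25, 15:25] = 1.0
        np.testing.assert_array_equal(border, 1.0)
        # ground truth marks the core footprint only; the 10-px core center
        # is at half-integer (49.5, 79.5), rounded half-to-even
        assert gt.masks[0].sum() == 100
        np.testing.assert_array_equal(gt.centers[0], (50, 80))

    def test_luminances_stay_in_unit_interval_with_flicker(self):
        obj = ObjectSpec(size_px=6, speed_px_s=200.0,
                         start_position=(50.0, 150.0))
        flick = FlickerSpec(n_dots=10, dot_size=6, frequency=50.0, seed=2)
        seq, _ = generate_sequence(obj, BG, flicker=flick, n_frames=8,
                                   dt=0.010)
        assert seq.frames.min() >= 0.0 and seq.frames.max() <= 1.0

    def test_object_leaving_frame_clears_mask(self):
        obj = ObjectSpec(size_px=6, speed_px_s=1000.0,
                         direction=(0.0, -1.0), start_position=(50.0, 30.0))
        _, gt = generate_sequence(obj, BG, n_frames=10, dt=0.010)
        assert gt.present[0] and not gt.present[-1]
        assert not gt.masks[-1].any()
        assert np.isnan(gt.centers[-1]).all()

    def test_oversized_object_rejected(self):
        with pytest.raises(ValueError, match="larger than the frame"):
            generate_sequence(ObjectSpec(size_px=500), BG, n_frames=1,
                              dt=0.010)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError, match="dt"):
            generate_sequence(ObjectSpec(), BG, n_frames=1, dt=0.0)

    def test_background_translation_wraps(self):
        bg = BackgroundSpec(seed=3, shape=(60, 80), velocity=600.0)
        obj = ObjectSpec(size_px=2, luminance=0.0, speed_px_s=0.0,
                         start_position=(10.0, 10.0))
        seq, _ = generate_sequence(obj, bg, n_frames=3, dt=0.010)
        # 6 px/frame rigid roll: row 40 (away from object) shifted copy
        np.testing.assert_array_equal(seq.frames[1][40],
                                      np.roll(seq.frames[0][40], 6))


class TestFlickerTiming:
    def test_dots_start_black_and_alternate_every_half_period(self):
        flick = FlickerSpec(frequency=50.0)  # half period 10 ms = 1 frame
        vals = [flicker_value(flick, t, 0.010) for t in range(6)]
        assert vals == [0.0, 1.0, 0.0, 1.0, 0.0, 1.0]

    def test_slow_flicker_rounds_to_frames(self):
        flick = FlickerSpec(frequency=5.0)  # half period 100 ms = 10 frames
        vals = [flicker_value(flick, t, 0.010) for t in range(25)]
        assert vals[:10] == [0.0] * 10
        assert vals[10:20] == [1.0] * 10
        assert vals[20:25] == [0.0] * 5

    def test_dot_positions_fixed_over_sequence(self):
        obj = ObjectSpec(size_px=4, luminance=0.5, speed_px_s=0.0,
                         start_position=(100.0, 180.0))
        flick = FlickerSpec(n_dots=8, dot_size=4, frequency=25.0, seed=5)
        seq, _ = generate_sequence(obj, BG, flicker=flick, n_frames=5,
                                   dt=0.010)
        # 25 Hz at 10 ms frames: half period = 2 frames, full period = 4;
        # frames 0 and 4 share the flicker phase -> identical
        np.testing.assert_array_equal(seq.frames[0], seq.frames[4])
        assert not np.array_equal(seq.frames[0], seq.frames[2])


class TestWeberContrast:
    @pytest.mark.parametrize("ic,is_,expected",
                             [(0.5, 0.5, 0.0), (0.0, 1.0, 1.0),
                              (0.5, 1.0, 0.5)])
    def test_values(self, ic, is_, expected):
        assert weber_contrast(ic, is_) == pytest.approx(expected)

    def test_zero_border_rejected(self):
        with pytest.raises(ValueError):
            weber_contrast(0.5, 0.0)


class TestRetinaPreprocess:
    def test_constant_frame_invariant(self):
        seq = FrameSequence(frames=np.full((2, 60, 60), 0.3), dt=0.010)
        out = retina_preprocess(seq)
        np.testing.assert_allclose(out.frames, 0.3, atol=1e-12)
        assert out.resolution_tag == "retina"

    def test_output_grid_counts_retained_indices(self):
        seq = FrameSequence(frames=np.zeros((1, 675, 1024)), dt=0.010)
        out = retina_preprocess(seq, stride=6)
        assert out.shape == (int(np.ceil(675 / 6)), int(np.ceil(1024 / 6)))

    def test_kernel_is_unit_sum_and_symmetric(self):
        k = gaussian_kernel_1d(12, 3.5)
        assert k.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(k, k[::-1])

    def test_frame_smaller_than_kernel_rejected(self):
        seq = FrameSequence(frames=np.zeros((1, 8, 8)), dt=0.010)
        with pytest.raises(ValueError, match="kernel"):
            retina_preprocess(seq)

    def test_shift_equivariance_on_the_lattice(self, rng):
        # translating input by one stride shifts the retina image one pixel
        base = rng.random((90, 90))
        shifted = np.roll(base, 6, axis=1)
        seq = FrameSequence(frames=np.stack([base, shifted]), dt=0.010)
        out = retina_preprocess(seq, stride=6)
        interior = out.frames[0][:, 2:-2]
        np.testing.assert_allclose(out.frames[1][:, 3:-1], interior,
                                   atol=1e-10)


class TestDownsampleGroundTruth:
    def _gt(self, size, start):
        obj = ObjectSpec(size_px=size, speed_px_s=200.0,
                         start_position=start)
        _, gt = generate_sequence(obj, BG, n_frames=10, dt=0.010)
        return gt

    def test_six_px_object_never_lost(self):
        gt6 = downsample_ground_truth(self._gt(6, (50.0, 150.0)), stride=6)
        assert (gt6.masks.sum(axis=(1, 2)) >= 1).all()

    def test_one_px_object_lost_between_lattice_points(self):
        obj = ObjectSpec(size_px=1, speed_px_s=0.0,
                         start_position=(50.0, 100.0))  # col 100 % 6 != 0
        _, gt = generate_sequence(obj, BG, n_frames=2, dt=0.010)
        gt6 = downsample_ground_truth(gt, stride=6)
        assert not gt6.masks.any()
        assert gt6.present.all()  # object present, ground truth lost

    def test_stride_one_is_identity(self):
        gt = self._gt(6, (50.0, 150.0))
        gt1 = downsample_ground_truth(gt, stride=1)
        np.testing.assert_array_equal(gt1.masks, gt.masks)
        np.testing.assert_array_equal(gt1.centers, gt.centers)

    def test_centers_map_by_integer_division(self):
        gt = self._gt(6, (50.0, 150.0))
        gt6 = downsample_ground_truth(gt, stride=6)
        np.testing.assert_array_equal(gt6.centers, gt.centers // 6)

    def test_double_downsampling_rejected(self):
        gt6 = downsample_ground_truth(self._gt(6, (50.0, 150.0)), stride=6)
        with pytest.raises(ValueError):
            downsample_ground_truth(gt6)


class TestProceduralBackground:
    def test_deterministic_for_seed(self):
        a = make_procedural_background(64, 96, seed=9)
        b = make_procedural_background(64, 96, seed=9)
        np.testing.assert_array_equal(a, b)
        c = make_procedural_background(64, 96, seed=10)
        assert not np.array_equal(a, c)

    def test_zero_contrast_uniform(self):
        bg = make_procedural_background(32, 32, seed=0, contrast=0.0)
        np.testing.assert_array_equal(bg, 0.5)

    def test_full_contrast_spans_half_unit_range(self):
        bg = make_procedural_background(128, 128, seed=4, contrast=1.0)
        assert bg.min() >= 0.0 and bg.max() <= 1.0
        assert bg.max() - bg.min() >= 0.5

    def test_power_concentrated_at_low_frequencies(self):
        bg = make_procedural_background(128, 128, seed=4)
        spec = np.abs(np.fft.fft2(bg - bg.mean())) ** 2
        f = np.hypot(np.fft.fftfreq(128)[:, None],
                     np.fft.fftfreq(128)[None, :])
        low = spec[(f > 0) & (f < 0.1)].mean()
        high = spec[f > 0.3].mean()
        assert low > 10 * high
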