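import numpy as np
import pytest

from tauagg import cells, synth
from tauagg.io import ImageStack


class TestPreprocess:
    def test_constant_stack_becomes_zero(self):
        stack = ImageStack(np.full((3, 16, 16), 9.0))
        out = cells.preprocess(stack)
        np.testing.assert_allclose(out.data, 0.0)

    def test_uniform_flatfield_is_identity(self, rng):
        data = rng.uniform(10, 20, (2, 16, 16))
        a = cells.preprocess(ImageStack(data), flatfield=None)
        b = cells.preprocess(ImageStack(data), flatfield=np.ones((16, 16)))
        np.testing.assert_allclose(a.data, b.data)

    def test_matching_flatfield_flattens_vignetting(self):
        yy, xx = np.mgrid[0:32, 0:32]
        vignette = 1.0 - 0.5 * ((yy - 16) ** 2 + (xx - 16) ** 2) / 512.0
        frame = 100.0 * vignette
        frame[0, 0] = 0.0  # true zero background so subtraction is a no-op
        out = cells.preprocess(ImageStack(frame[None]), flatfield=vignette,
                               blur_sigma_px=0.0, background_percentile=0.0)
        corrected = out.data[0].ravel()[1:]  # exclude the zeroed pixel
        assert corrected.std() / corrected.mean() < 1e-6

    def test_nonpositive_flatfield_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            cells.preprocess(ImageStack(np.ones((1, 8, 8))),
                             flatfield=np.zeros((8, 8)))


class TestTracking:
    def cell_frame(self, centers, shape=(96, 96), amp=100.0):
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        img = np.zeros(shape)
        for (r, c) in centers:
            img += amp * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * 16.0))
        return img

    def test_single_stationary_cell(self):
        frames = np.stack([self.cell_frame([(40, 50)]) for _ in range(20)])
        tracks = cells.track_cells(ImageStack(frames), cell_radius_px=8)
        assert len(tracks) == 1
        assert np.hypot(tracks[0].position[0] - 40,
                        tracks[0].position[1] - 50) < 1.5

    def test_two_cells_no_identity_swap(self):
        frames = np.stack([self.cell_frame([(30, 30), (30, 80)])
                           for _ in range(20)])
        tracks = cells.track_cells(ImageStack(frames), cell_radius_px=8)
        assert len(tracks) == 2
        cols = sorted(t.position[1] for t in tracks)
        assert abs(cols[0] - 30) < 2 and abs(cols[1] - 80) < 2

    def test_jittery_maximum_discarded(self, rng):
        frames = np.stack([
            self.cell_frame([(48 + rng.normal(0, 10.0),
                              48 + rng.normal(0, 10.0))])
            for _ in range(30)])
        tracks = cells.track_cells(ImageStack(frames), cell_radius_px=8)
        assert tracks == []

    def test_intensity_rescaling_invariance(self):
        frames = np.stack([self.cell_frame([(40, 50)]) for _ in range(10)])
        t1 = cells.track_cells(ImageStack(frames), cell_radius_px=8)
        t2 = cells.track_cells(ImageStack(frames * 37.0), cell_radius_px=8)
        assert len(t1) == len(t2) == 1
        assert t1[0].position == t2[0].position


class TestTraces:
    def test_uniform_frames_give_constant_trace(self):
        stack = ImageStack(np.full((5, 32, 32), 4.0))
        tracks = [cells.CellTrack(0, (16.0, 16.0), 0.0, 5.0)]
        cells.extract_traces(stack, tracks, smooth_sigma=0.0)
        np.testing.assert_allclose(tracks[0].trace, 4.0)

    def test_disk_mean_matches_pixel_average_oracle(self, rng):
        data = rng.uniform(0, 10, (3, 32, 32))
        tracks = [cells.CellTrack(0, (16.0, 16.0), 0.0, 6.0)]
        cells.extract_traces(ImageStack(data), tracks, smooth_sigma=0.0)
        yy, xx = np.mgrid[0:32, 0:32]
        disk = np.hypot(yy - 16, xx - 16) <= 6.0
        for f in range(3):
            assert tracks[0].trace[f] == pytest.approx(data[f][disk].mean())

    def test_edge_clipped_disk_flagged(self):
        stack = ImageStack(np.ones((2, 32, 32)))
        tracks = [cells.CellTrack(0, (2.0, 16.0), 0.0, 6.0)]
        cells.extract_traces(stack, tracks, smooth_sigma=0.0)
        assert tracks[0].edge_clipped
        np.testing.assert_allclose(tracks[0].trace, 1.0)


class TestSpikeDetection:
    def test_constant_trace_no_spikes(self):
        assert cells.detect_spikes(np.ones(200), 0.01) == []

    def test_three_injected_spikes_called_at_onsets(self):
        trace = synth.gen_calcium_trace(600, [100, 250, 400], amplitude=0.2,
                                        noise_sd=0.005,
                                        rng=np.random.default_rng(3))
        thr = cells.calibrate_derivative_threshold(0.005, smooth_sigma=1.0)
        calls = cells.detect_spikes(trace, thr, min_amplitude=0.05,
                                    min_duration=2, smooth_sigma=1.0)
        assert len(calls) == 3
        for call, true_onset in zip(calls, [100, 250, 400]):
            assert abs(call.onset_frame - true_onset) <= 2

    def test_short_blip_rejected_by_min_duration(self):
        trace = np.ones(200)
        trace[100] = 1.5  # one-frame transient
        calls_loose = cells.detect_spikes(trace, 0.01, min_duration=0,
                                          smooth_sigma=1.0)
        calls_strict = cells.detect_spikes(trace, 0.01, min_duration=8,
                                           smooth_sigma=1.0)
        assert len(calls_loose) == 1 and calls_strict == []

    def test_small_spike_rejected_by_min_amplitude(self):
        trace = synth.gen_calcium_trace(300, [150], amplitude=0.04,
                                        noise_sd=0.0)
        calls = cells.detect_spikes(trace, 0.002, min_amplitude=0.1)
        assert calls == []

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            cells.detect_spikes(np.ones(10), 0.0)

    def test_recall_and_precision_on_noisy_traces(self):
        noise = 0.02
        thr = cells.calibrate_derivative_threshold(noise, smooth_sigma=2.0)
        rng = np.random.default_rng(77)
        tp = fp = fn = 0
        for _ in range(50):
            times = sorted(rng.integers(60, 520, 3).tolist())
            clean = []
            for s in times:
                if not clean or s - clean[-1] >= 50:
                    clean.append(int(s))
            trace = synth.gen_calcium_trace(600, clean, amplitude=0.10,
                                            noise_sd=noise, drift_amp=0.01,
                                            rng=rng)
            calls = cells.detect_spikes(trace, thr, min_amplitude=2.5 * noise,
                                        min_duration=2, smooth_sigma=2.0)
            matched = set()
            for c in calls:
                hit = [t for t in clean
                       if abs(c.onset_frame - t) <= 5 and t not in matched]
                if hit:
                    matched.add(hit[0])
                    tp += 1
                else:
                    fp += 1
            fn += len(clean) - len(matched)
        assert tp / (tp + fn) >= 0.95
        assert tp / (tp + fp) >= 0.95


class TestRosChange:
    def test_flat_trace_zero_change(self):
        assert cells.ros_percent_change(np.ones(600), 100, 550) == 0.0

    def test_direct_formula(self):
        trace = np.concatenate([np.full(100, 100.0), np.full(500, 118.0)])
        assert cells.ros_percent_change(trace, 100, 600) == pytest.approx(18.0)

    def test_linear_ramp_closed_form(self):
        s = 0.05
        trace = 100.0 + s * np.arange(600)
        out = cells.ros_percent_change(trace, 100, 550, window=50)
        f_init = 100.0 + s * np.mean(np.arange(50, 100))
        f_final = 100.0 + s * np.mean(np.arange(500, 550))
        assert out == pytest.approx(100 * (f_final - f_init) / f_init)

    @pytest.mark.parametrize("c", [0.5, 2.0, 100.0])
    def test_invariant_to_uniform_gain(self, c, rng):
        trace = 100.0 + rng.uniform(0, 20, 600)
        assert cells.ros_percent_change(c * trace, 100, 550) == pytest.approx(
            cells.ros_percent_change(trace, 100, 550))

    def test_window_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cells.ros_percent_change(np.ones(600), 20, 550)


class TestRespondingFraction:
    def test_no_spikes(self):
        assert cells.responding_fraction([], 10) == 0.0

    def test_all_cells_spike(self):
        calls = [cells.SpikeCall(i, 100, 105, 1.0, 5) for i in range(5)]
        assert cells.responding_fraction(calls, 5) == 1.0

    def test_seventeen_of_twenty(self):
        calls = [cells.SpikeCall(i, 100, 105, 1.0, 5) for i in range(17)]
        assert cells.responding_fraction(calls, 20) == pytest.approx(0.85)

    def test_pre_stimulus_spikes_not_counted(self):
        calls = [cells.SpikeCall(0, 10, 12, 1.0, 3)]
        assert cells.responding_fraction(calls, 4, stimulus_frame=50) == 0.0
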