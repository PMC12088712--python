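"""Grad-CAM, heatmap fusion, QRS detection and RR normalization."""
import numpy as np
import pytest

from ecgtraj.cohort import synthesize_ecg
from ecgtraj.interpret import (AttentionHeatmap, AveragedAttentionMap, QrsPeaks,
                               average_maps, detect_qrs, fuse_heatmap,
                               gradcam_time_map, qrs_window_ratio, rr_normalize,
                               sample_heatmap)
from ecgtraj.model import build_model, tiny_config


@pytest.fixture(scope="module")
def tiny_net():
    return build_model(tiny_config(n_lead_tokens=12, head="regression", seed=6))


@pytest.fixture(scope="module")
def tiny_net_cls():
    return build_model(tiny_config(n_lead_tokens=24, head="classification_3", seed=6))


class TestGradCam:
    def test_nonnegative_and_shaped(self, tiny_net, rng):
        win = rng.normal(0, 0.3, size=(12, 1000)).astype(np.float32)
        cam = gradcam_time_map(tiny_net, win)
        assert cam.shape == (12, 1000)
        assert np.all(cam >= 0)

    def test_zeroed_head_gives_zero_map(self, rng):
        net = build_model(tiny_config(n_lead_tokens=12, head="regression", seed=1))
        net.head.params["W"][...] = 0.0
        net.head.params["b"][...] = 0.0
        win = rng.normal(0, 0.3, size=(12, 1000)).astype(np.float32)
        assert not gradcam_time_map(net, win).any()

    def test_classification_target_selects_logit(self, tiny_net_cls, rng):
        win = rng.normal(0, 0.3, size=(24, 1000)).astype(np.float32)
        maps = [gradcam_time_map(tiny_net_cls, win, target=t) for t in range(3)]
        assert any(not np.allclose(maps[0], m) for m in maps[1:])


class TestFuseHeatmap:
    def test_uniform_weights_proportional(self, rng):
        cam = rng.uniform(size=(12, 100))
        fused = fuse_heatmap(cam, np.full(12, 1 / 12))
        np.testing.assert_allclose(fused.values, cam / cam.max(), atol=1e-12)

    def test_one_hot_selects_single_lead(self, rng):
        cam = rng.uniform(0.1, 1.0, size=(12, 100))
        w = np.zeros(12)
        w[3] = 1.0
        fused = fuse_heatmap(cam, w)
        assert fused.values[3].max() == 1.0
        assert not fused.values[np.arange(12) != 3].any()

    def test_max_is_exactly_one(self, rng):
        cam = rng.uniform(size=(24, 50))
        w = rng.uniform(size=24)
        assert fuse_heatmap(cam, w / w.sum()).values.max() == 1.0

    def test_all_zero_map_stays_zero(self):
        fused = fuse_heatmap(np.zeros((12, 50)), np.full(12, 1 / 12))
        assert not fused.values.any()

    def test_negative_weights_rejected(self, rng):
        with pytest.raises(ValueError):
            fuse_heatmap(rng.uniform(size=(12, 50)), np.linspace(-0.1, 1, 12))

    def test_negative_heatmap_rejected(self):
        with pytest.raises(ValueError):
            AttentionHeatmap(values=np.array([[-0.1, 0.2]]))

    def test_end_to_end_sample_heatmap(self, tiny_net_cls, rng):
        win = rng.normal(0, 0.3, size=(24, 1000)).astype(np.float32)
        heat = sample_heatmap(tiny_net_cls, win, target=1)
        assert heat.values.shape == (24, 1000)
        assert heat.values.max() == pytest.approx(1.0)


class TestDetectQrs:
    def test_sixty_bpm_noiseless(self, clean_spec):
        rec = synthesize_ecg(0.0, 60.0, clean_spec, np.random.default_rng(4))
        peaks = detect_qrs(rec.signal[1], clean_spec.fs)
        truth = np.asarray(rec.meta["r_peaks"])
        assert abs(len(peaks.indices) - len(truth)) <= 1
        for t in truth:
            assert np.min(np.abs(peaks.indices - t)) <= 10   # within 20 ms

    def test_flat_signal_no_peaks(self, caplog):
        with caplog.at_level("WARNING"):
            peaks = detect_qrs(np.zeros(2500), 500.0)
        assert peaks.indices.size == 0
        assert "flat" in caplog.text

    def test_deterministic(self, clean_spec):
        rec = synthesize_ecg(0.5, 75.0, clean_spec, np.random.default_rng(8))
        a = detect_qrs(rec.signal[1], clean_spec.fs).indices
        b = detect_qrs(rec.signal[1], clean_spec.fs).indices
        np.testing.assert_array_equal(a, b)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="2 s"):
            detect_qrs(np.zeros(400), 500.0)

    def test_refractory_invariant(self):
        with pytest.raises(ValueError, match="refractory"):
            QrsPeaks(indices=np.array([100, 150]), fs=500.0)


class TestRrNormalize:
    def _peaks(self, idx):
        return QrsPeaks(indices=np.array(idx), fs=500.0)

    def test_every_beat_has_exactly_500_samples(self, rng):
        values = rng.uniform(size=(12, 1500))
        beats = rr_normalize(values, self._peaks([100, 480, 1020, 1400]))
        assert len(beats) == 3
        assert all(b.shape == (12, 500) for b in beats)

    def test_constant_map_fixed_point(self):
        values = np.full((12, 1200), 0.7)
        for beat in rr_normalize(values, self._peaks([50, 420, 1100])):
            np.testing.assert_allclose(beat, 0.7, atol=1e-12)

    def test_exact_one_second_rr_is_identity(self, rng):
        values = rng.uniform(size=(3, 1200))
        beats = rr_normalize(values, self._peaks([100, 600, 1100]))
        np.testing.assert_allclose(beats[0], values[:, 100:600], atol=1e-12)
        np.testing.assert_allclose(beats[1], values[:, 600:1100], atol=1e-12)

    def test_periodic_map_gives_identical_beats(self):
        period = 400                         # RR = 0.8 s at 500 Hz
        pattern = np.sin(2 * np.pi * np.arange(period) / period) ** 2
        values = np.tile(pattern, (2, 4))
        beats = rr_normalize(values, self._peaks([0, 400, 800, 1200]))
        for b in beats[1:]:
            np.testing.assert_allclose(b, beats[0], atol=1e-6)

    def test_fewer_than_two_peaks_rejected(self, rng):
        with pytest.raises(ValueError, match="2 R peaks"):
            rr_normalize(rng.uniform(size=(2, 1000)), self._peaks([300]))


class TestAverageMaps:
    def test_mean_of_one_is_identity(self, rng):
        beat = rng.uniform(size=(12, 500))
        avg = average_maps([[beat]], "improved")
        np.testing.assert_array_equal(avg.values, beat)
        assert avg.n_beats == 1 and avg.n_samples == 1

    def test_idempotent_for_identical_inputs(self, rng):
        beat = rng.uniform(size=(12, 500))
        avg = average_maps([[beat], [beat]], "deteriorated")
        np.testing.assert_allclose(avg.values, beat, atol=1e-12)
        assert avg.n_beats == 2

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="no beats"):
            average_maps([], "no_change")


class TestQrsWindowRatio:
    def test_mass_at_r_peaks_scores_high(self):
        values = np.full((12, 500), 0.1)
        values[:, :30] = 1.0
        values[:, -30:] = 1.0
        amap = AveragedAttentionMap(values=values, class_label="x",
                                    n_samples=1, n_beats=1)
        assert qrs_window_ratio(amap) == pytest.approx(10.0)

    def test_uniform_map_is_one(self):
        amap = AveragedAttentionMap(values=np.full((12, 500), 0.4),
                                    class_label="x", n_samples=1, n_beats=1)
        assert qrs_window_ratio(amap) == pytest.approx(1.0)
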