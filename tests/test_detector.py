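"""Pipeline stages and end-to-end detection on synthetic records."""

import numpy as np
import pytest

from seizonset import (PipelineConfig, SeizureSpec, SynthConfig, detect,
                       generate_recording, match_events)
from seizonset.detector import (binarize_and_extract, estimate_threshold,
                                moving_average, run_stage1, run_stage2, run_stage3,
                                select_channels)
from seizonset.fuzzy import build_input_mfs, three_level_variable, two_level_variable
from seizonset.preprocess import make_segment_grid
from seizonset.recording import Recording


def _vars():
    out3 = three_level_variable("op")
    lv2 = two_level_variable("level", 0.3, 0.7)
    return out3, lv2


class TestStage1:
    def test_extreme_cores(self):
        out3, _ = _vars()
        ivars = [[build_input_mfs(0.3, 0.7) for _ in range(4)]]
        feats = np.array([[[1.0, 1.0, 1.0, 1.0]], [[0.0, 0.0, 0.0, 0.0]],
                          [[1.0, 1.0, 0.0, 0.0]]])
        op1 = run_stage1(feats, ivars, out3)
        assert op1[0, 0] > 0.5       # all four features high
        assert op1[1, 0] < 0.5       # all low
        assert abs(op1[2, 0] - 0.5) < 0.05   # exactly two high -> medium


class TestSelectChannels:
    def _rec(self, roles):
        n = len(roles)
        return Recording(np.zeros((n, 640)), 256.0, [f"c{i}" for i in range(n)], roles)

    def test_default_first_three_focal_first_remote(self):
        rec = self._rec(["focal", "focal", "focal", "remote", "remote", "remote"])
        assert select_channels(rec) == (0, 1, 2, 3)

    def test_remote_override(self):
        rec = self._rec(["focal", "focal", "focal", "remote", "remote", "remote"])
        assert select_channels(rec, remote_channel=5) == (0, 1, 2, 5)

    def test_too_few_focal_rejected(self):
        rec = self._rec(["focal", "focal", "remote", "remote"])
        with pytest.raises(ValueError):
            select_channels(rec)


class TestStage2:
    def test_all_high(self):
        out3, lv2 = _vars()
        op2 = run_stage2(np.array([[0.9, 0.9, 0.9, 0.9]]), lv2, lv2)
        assert op2[0] > 0.5

    def test_single_high_maps_low(self):
        out3, lv2 = _vars()
        op2 = run_stage2(np.array([[0.9, 0.1, 0.1, 0.1]]), lv2, lv2)
        assert op2[0] < 0.5

    def test_two_focal_high_fires(self):
        out3, lv2 = _vars()
        op2 = run_stage2(np.array([[0.9, 0.9, 0.1, 0.1]]), lv2, lv2)
        assert op2[0] > 0.5

    def test_misaligned_rejected(self):
        _, lv2 = _vars()
        with pytest.raises(ValueError):
            run_stage2(np.zeros((3, 5)), lv2, lv2)


class TestMovingAverage:
    def test_constant_series(self):
        np.testing.assert_allclose(moving_average(np.full(10, 0.3)), 0.3)

    def test_trailing_arithmetic(self):
        sa = moving_average(np.array([0.0, 0.0, 0.0, 0.0, 1.0]), w=5)
        assert sa[4] == pytest.approx(0.2)

    def test_prefix_convention(self):
        x = np.array([0.7, 0.1, 0.4])
        sa = moving_average(x, w=5)
        assert sa[0] == x[0]
        assert sa[1] == pytest.approx(0.4)


class TestStage3:
    def test_corner_cases(self):
        out3, lv2 = _vars()
        hh = run_stage3(np.array([0.9]), np.array([0.9]), lv2, out3)
        ll = run_stage3(np.array([0.1]), np.array([0.1]), lv2, out3)
        hl = run_stage3(np.array([0.9]), np.array([0.1]), lv2, out3)
        assert hh[0] > 0.5 and ll[0] < 0.5
        assert abs(hl[0] - 0.5) < 0.05


class TestThreshold:
    def test_moment_arithmetic(self, rng):
        sz = rng.normal(0.3, 0.05, 20_000)
        thr = estimate_threshold(sz, k=4.0)
        assert abs(thr - 0.5) < 0.01

    def test_monotone_in_k(self, rng):
        sz = rng.random(100)
        assert estimate_threshold(sz, 2.0) < estimate_threshold(sz, 6.0)

    @pytest.mark.parametrize("k", [1.9, 7.0])
    def test_k_outside_published_range_rejected(self, k, rng):
        with pytest.raises(ValueError):
            estimate_threshold(rng.random(10), k)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            estimate_threshold(np.full(10, 0.3), 3.0)


class TestBinarize:
    def _grid(self, n):
        return make_segment_grid(640 + 512 * (n - 1), 256.0)

    def test_short_run_deleted_at_default_minimum(self):
        # 4 segments span 8.5 s (3 strides + one window) < 9.5 s
        grid = self._grid(20)
        sz = np.zeros(20)
        sz[5:9] = 1.0
        events, raw, _ = binarize_and_extract(sz, 0.5, np.zeros(20, bool), grid)
        assert events == [] and len(raw) == 1

    def test_same_run_kept_at_lowered_minimum(self):
        grid = self._grid(20)
        sz = np.zeros(20)
        sz[5:9] = 1.0
        events, _, _ = binarize_and_extract(sz, 0.5, np.zeros(20, bool), grid,
                                            min_event_s=4.0)
        assert len(events) == 1
        assert events[0].onset_s == pytest.approx(grid.starts[5] / 256.0)

    def test_artifact_masked_run_produces_no_event(self):
        grid = self._grid(20)
        sz = np.ones(20)
        mask = np.ones(20, bool)
        events, raw, binary = binarize_and_extract(sz, 0.5, mask, grid)
        assert events == [] and raw == [] and not binary.any()

    def test_nearby_runs_merged(self):
        grid = self._grid(40)
        sz = np.zeros(40)
        sz[5:12] = 1.0
        sz[15:22] = 1.0  # ~6 s gap < 30 s merge window
        events, _, _ = binarize_and_extract(sz, 0.5, np.zeros(40, bool), grid)
        assert len(events) == 1


@pytest.fixture(scope="module")
def detection_30min():
    cfg = SynthConfig(duration=1800.0,
                      seizures=[SeizureSpec(500.0, 60.0, 20.0, 5.0),
                                SeizureSpec(1200.0, 60.0, 15.0, 5.0)],
                      seed=3)
    res = generate_recording(cfg)
    return res, detect(res.recording, annotations=res.annotations)


class TestEndToEnd:
    def test_both_seizures_detected(self, detection_30min):
        res, det = detection_30min
        match = match_events(det.events, res.annotations)
        assert match.tp == 2 and match.fn == 0
        assert all(abs(l) <= 30.0 for l in match.latencies)

    def test_no_false_positives(self, detection_30min):
        res, det = detection_30min
        match = match_events(det.events, res.annotations)
        assert len(match.fp_events) == 0

    def test_trace_alignment_and_bounds(self, detection_30min):
        _, det = detection_30min
        t = det.trace
        n = t.grid.n_segments
        assert t.op1.shape == (n, 4)
        assert t.op2.shape == t.sa.shape == t.sz.shape == (n,)
        for series in (t.op1, t.op2, t.sa, t.sz):
            assert series.min() >= 0.0 and series.max() <= 1.0
        assert not t.binary[det.artifact_mask.any_channel].any()

    def test_deterministic_given_config(self, detection_30min):
        res, det = detection_30min
        det2 = detect(res.recording, PipelineConfig(), annotations=res.annotations)
        np.testing.assert_array_equal(det.trace.sz, det2.trace.sz)
        assert det.events == det2.events

    def test_detection_survives_silent_remote_channel(self):
        """Stage 2 fires on >= 2 high channels, so an ictal-free remote
        channel must not abolish detection."""
        import seizonset.synthetic as syn

        cfg = SynthConfig(duration=900.0,
                          seizures=[SeizureSpec(400.0, 60.0, 20.0, 5.0)],
                          seed=11, remote_delay=1e6)  # delay pushes ictal content
        # past the record end on remote channels -> remote stays background-only
        res = generate_recording(cfg)
        det = detect(res.recording, annotations=res.annotations)
        match = match_events(det.events, res.annotations)
        assert match.tp == 1
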