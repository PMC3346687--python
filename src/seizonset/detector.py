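"""Three-stage detection pipeline.

Per segment and channel the four normalized features are fused by the
adaptive stage-1 fuzzy system into OP1; OP1 from three focal channels and
one remote channel is fused spatially into OP2 (stage 2); OP2 is smoothed
with a trailing 5-segment moving average SA; stage 3 combines (OP2, SA)
into the alarm series SZ.  The alarm threshold is mean(SZ) + k*SD(SZ) with
k in [2, 6]; supra-threshold segments not masked as artifacts become
candidate events, nearby events are merged, and events shorter than the
minimum length (default 9.5 s) are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import fuzzy
from .config import PipelineConfig
from .features import feature_matrix
from .fuzzy import (FuzzyVariable, build_input_mfs, make_rulebase,
                    mamdani_defuzz_batch, minmax_normalize, three_level_variable,
                    two_level_variable)
from .preprocess import (ArtifactMask, SegmentGrid, detect_artifacts,
                         filter_segments, make_segment_grid)
from .recording import Annotation, Recording

logger = logging.getLogger(__name__)


@dataclass
class DetectionTrace:
    """All intermediate series, aligned to the segment grid."""

    grid: SegmentGrid
    op1: np.ndarray          # (n_segments, 4 selected channels)
    op2: np.ndarray          # (n_segments,)
    sa: np.ndarray
    sz: np.ndarray
    threshold: float
    binary: np.ndarray       # {0, 1}, zero wherever an artifact was flagged


@dataclass(frozen=True)
class SeizureEvent:
    onset_s: float
    offset_s: float
    peak_sz: float
    n_segments: int

    @property
    def duration(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class DetectionResult:
    trace: DetectionTrace
    events: list[SeizureEvent]            # after minimum-length rejection
    events_raw: list[SeizureEvent]        # before it ("uninteresting" FP basis)
    artifact_mask: ArtifactMask
    features: np.ndarray                  # (n_segments, 4, 4) raw features
    channel_indices: tuple[int, int, int, int]
    cluster_centers: np.ndarray           # (4 channels, 4 features, 2)


def select_channels(recording: Recording, focal_channels=None, remote_channel=None
                    ) -> tuple[int, int, int, int]:
    """Three epileptogenic-zone channels + one remote channel.

    Defaults to the first three focal and the first remote channel.
    """
    focal = recording.focal_indices()
    remote = recording.remote_indices()
    if focal_channels is None:
        if len(focal) < 3:
            raise ValueError(f"need >= 3 focal channels, found {len(focal)}")
        focal_channels = focal[:3]
    if len(focal_channels) != 3:
        raise ValueError("exactly 3 focal channels required")
    if remote_channel is None:
        if not remote:
            raise ValueError("need at least one remote channel")
        remote_channel = remote[0]
    return (*focal_channels, remote_channel)


def run_stage1(norm_features: np.ndarray, input_vars: list[list[FuzzyVariable]],
               output_var: FuzzyVariable, grid_n: int = 1001) -> np.ndarray:
    """Feature combiner: (n_segments, n_channels, 4) -> OP1 (n_segments, n_channels)."""
    rb = make_rulebase(1)
    n_seg, n_ch, _ = norm_features.shape
    op1 = np.empty((n_seg, n_ch))
    for c in range(n_ch):
        op1[:, c] = mamdani_defuzz_batch(rb, norm_features[:, c, :], input_vars[c],
                                         output_var, grid_n=grid_n)
    return op1


def run_stage2(op1: np.ndarray, input_var: FuzzyVariable, output_var: FuzzyVariable,
               grid_n: int = 1001) -> np.ndarray:
    """Spatial combiner: OP1 on the 4 selected channels -> OP2 (n_segments,)."""
    if op1.ndim != 2 or op1.shape[1] != 4:
        raise ValueError(f"expected (n_segments, 4) OP1, got {op1.shape}")
    rb = make_rulebase(2)
    return mamdani_defuzz_batch(rb, op1, [input_var] * 4, output_var, grid_n=grid_n)


def moving_average(x: np.ndarray, w: int = 5) -> np.ndarray:
    """Trailing (causal) moving average; the prefix averages what is available."""
    if w < 1:
        raise ValueError("window must be >= 1")
    c = np.concatenate(([0.0], np.cumsum(x)))
    n = len(x)
    idx = np.arange(n)
    lo = np.maximum(idx - w + 1, 0)
    return (c[idx + 1] - c[lo]) / (idx + 1 - lo)


def run_stage3(op2: np.ndarray, sa: np.ndarray, input_var: FuzzyVariable,
               output_var: FuzzyVariable, grid_n: int = 1001) -> np.ndarray:
    """Alarm stage: (OP2, SA) -> SZ (n_segments,)."""
    if op2.shape != sa.shape:
        raise ValueError("OP2 and SA must be aligned")
    rb = make_rulebase(3)
    return mamdani_defuzz_batch(rb, np.stack([op2, sa], axis=1), [input_var] * 2,
                                output_var, grid_n=grid_n)


def estimate_threshold(sz: np.ndarray, k: float = 4.0) -> float:
    """Alarm threshold mean + k*SD, k restricted to [2, 6]."""
    if not 2.0 <= k <= 6.0:
        raise ValueError(f"threshold multiplier k must lie in [2, 6], got {k}")
    sd = float(np.std(sz))
    if sd <= 1e-12 * max(1.0, abs(float(np.mean(sz)))):
        raise ValueError("constant alarm series; threshold undefined")
    return float(np.mean(sz)) + k * sd


def binarize_and_extract(
    sz: np.ndarray,
    threshold: float,
    artifact_segments: np.ndarray,
    grid: SegmentGrid,
    min_event_s: float = 9.5,
    merge_gap_s: float = 30.0,
) -> tuple[list[SeizureEvent], list[SeizureEvent], np.ndarray]:
    """Threshold SZ, mask artifacts, merge nearby runs, reject short events.

    A segment's decision timestamp is its window start; an event spans from
    its first window start to its last window end.  Returns
    ``(events, events_raw, binary)`` where ``events_raw`` precedes the
    minimum-length rejection.
    """
    binary = (sz > threshold) & ~np.asarray(artifact_segments, dtype=bool)
    runs = _runs(binary)
    fs, wn, stride = grid.fs, grid.window_n, grid.stride_n
    # merge runs whose gap is shorter than merge_gap_s
    merged: list[list[int]] = []
    for i0, i1 in runs:
        if merged and (grid.starts[i0] - (grid.starts[merged[-1][1]] + wn)) / fs < merge_gap_s:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])
    events_raw = [
        SeizureEvent(
            onset_s=grid.starts[i0] / fs,
            offset_s=(grid.starts[i1] + wn) / fs,
            peak_sz=float(sz[i0:i1 + 1].max()),
            n_segments=i1 - i0 + 1,
        )
        for i0, i1 in merged
    ]
    events = [e for e in events_raw if e.duration >= min_event_s]
    for e in events_raw:
        if e.duration < min_event_s:
            logger.info("rejected %.1f s event at %.1f s (< %.1f s minimum)",
                        e.duration, e.onset_s, min_event_s)
    return events, events_raw, binary.astype(int)


def _runs(binary: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, end) index pairs of consecutive True runs."""
    b = np.asarray(binary, dtype=bool)
    edges = np.diff(np.concatenate(([0], b.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    return list(zip(starts, ends))


def detect(
    recording: Recording,
    config: PipelineConfig | None = None,
    annotations: list[Annotation] | None = None,
) -> DetectionResult:
    """Run the full pipeline on one recording.

    ``annotations``, when given, are used only for the movement-artifact
    guard (a flagged segment must exceed the largest envelope seen in
    annotated seizure segments).
    """
    cfg = config or PipelineConfig()
    pp, fe, fz, dt = cfg.preprocess, cfg.features, cfg.fuzzy, cfg.detector

    chans = select_channels(recording, dt.focal_channels, dt.remote_channel)
    sub = Recording(
        samples=recording.samples[list(chans)],
        fs=recording.fs,
        labels=[recording.labels[i] for i in chans],
        roles=[recording.roles[i] for i in chans],
        patient_id=recording.patient_id,
    )
    grid = make_segment_grid(sub.n_samples, sub.fs, pp.window_s, pp.overlap_s)

    seizure_segments = None
    if annotations:
        t0 = grid.times()
        t1 = t0 + grid.window_n / grid.fs
        seizure_segments = np.zeros(grid.n_segments, dtype=bool)
        for ann in annotations:
            seizure_segments |= (t0 < ann.offset) & (t1 > ann.onset)

    mask = detect_artifacts(sub, grid, pp, seizure_segments=seizure_segments)
    logger.info("segments=%d saturation-flagged=%d movement-flagged=%d",
                grid.n_segments, int(mask.saturation.any(axis=1).sum()),
                int(mask.movement.any(axis=1).sum()))

    segments = filter_segments(sub, grid, pp)
    feats = feature_matrix(segments, sub.fs, fe)

    # per-channel, per-feature normalization and FCM-adapted memberships
    n_seg, n_ch, n_feat = feats.shape
    norm = np.empty_like(feats)
    input_vars: list[list[FuzzyVariable]] = []
    centers = np.empty((n_ch, n_feat, 2))
    for c in range(n_ch):
        chan_vars = []
        for f in range(n_feat):
            norm[:, c, f] = minmax_normalize(feats[:, c, f])
            cc, _ = fuzzy.fcm(norm[:, c, f], c=2, m=fz.fcm_m, max_iter=fz.fcm_max_iter,
                              tol=fz.fcm_tol, seed=fz.fcm_seed + 101 * c + f)
            centers[c, f] = cc
            chan_vars.append(build_input_mfs(cc[0], cc[1], name=f"ch{c}_f{f}"))
        input_vars.append(chan_vars)

    out3 = three_level_variable("op", fz.th_l, fz.th_m, fz.th_h)
    lv2 = two_level_variable("level", fz.th_l, fz.th_h)

    op1 = run_stage1(norm, input_vars, out3, grid_n=fz.grid_n)
    op2 = run_stage2(op1, lv2, lv2, grid_n=fz.grid_n)
    sa = moving_average(op2, dt.sa_window)
    sz = run_stage3(op2, sa, lv2, out3, grid_n=fz.grid_n)

    threshold = estimate_threshold(sz, dt.threshold_k)
    events, events_raw, binary = binarize_and_extract(
        sz, threshold, mask.any_channel, grid,
        min_event_s=dt.min_event_s, merge_gap_s=dt.merge_gap_s,
    )
    logger.info("threshold=%.4f events=%d (raw %d)", threshold, len(events), len(events_raw))

    trace = DetectionTrace(grid=grid, op1=op1, op2=op2, sa=sa, sz=sz,
                           threshold=threshold, binary=binary)
    return DetectionResult(trace=trace, events=events, events_raw=events_raw,
                           artifact_mask=mask, features=feats,
                           channel_indices=chans, cluster_centers=centers)
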