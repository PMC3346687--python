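"""Preprocessing: segmentation, artifact detection, filtering.

The record is cut into 2.5 s windows (640 samples at 256 Hz) overlapping by
0.5 s (128 samples), i.e. a 2.0 s stride.  Saturation artifacts are found by
a derivative test (runs of exactly-zero first differences), movement
artifacts by thresholding the min-max normalized mean absolute Hilbert
envelope of each segment at 0.6.  Artifact detection runs on the raw
amplitudes; segments are band-pass filtered (0.5-100 Hz, 4th-order
Butterworth) and 50 Hz notch filtered afterwards, both applied forward and
backward so the filtering adds no group delay.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .config import PreprocessConfig
from .recording import Recording

logger = logging.getLogger(__name__)


@dataclass
class SegmentGrid:
    """Uniform moving-window grid; windows are half-open [start, start+window_n)."""

    window_s: float
    overlap_s: float
    fs: float
    window_n: int
    stride_n: int
    starts: np.ndarray

    @property
    def n_segments(self) -> int:
        return len(self.starts)

    def times(self) -> np.ndarray:
        """Window start times in seconds."""
        return self.starts / self.fs


def make_segment_grid(
    n_samples: int, fs: float, window_s: float = 2.5, overlap_s: float = 0.5
) -> SegmentGrid:
    window_n = int(round(window_s * fs))
    stride_n = window_n - int(round(overlap_s * fs))
    if stride_n <= 0:
        raise ValueError("overlap must be shorter than the window")
    if n_samples < window_n:
        raise ValueError(
            f"record of {n_samples} samples is shorter than one {window_n}-sample window"
        )
    starts = np.arange(0, n_samples - window_n + 1, stride_n)
    return SegmentGrid(window_s=window_s, overlap_s=overlap_s, fs=fs,
                       window_n=window_n, stride_n=stride_n, starts=starts)


def segment_view(samples: np.ndarray, grid: SegmentGrid) -> np.ndarray:
    """Stack windows: (n_channels, n_times) -> (n_segments, n_channels, window_n)."""
    return np.stack([samples[:, s:s + grid.window_n] for s in grid.starts], axis=0)


def bandpass_notch(
    segment: np.ndarray,
    fs: float,
    band: tuple[float, float] = (0.5, 100.0),
    notch_hz: float = 50.0,
    notch_q: float = 30.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase band-pass + notch along the last axis."""
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz needs fs > {2 * hi} Hz, got {fs}")
    segment = np.asarray(segment, dtype=float)
    # notch first, then band-pass with even-reflection padding: on 2.5 s
    # windows the zero-phase edge transients, not the steady-state response,
    # limit how much 50 Hz energy survives; this ordering and a moderate
    # notch width keep the transient short (the two LTI stages commute in
    # steady state)
    b, a = signal.iirnotch(notch_hz, notch_q, fs=fs)
    y = signal.filtfilt(b, a, segment, axis=-1)
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    padlen = min(400, segment.shape[-1] - 1)
    return signal.sosfiltfilt(sos, y, axis=-1, padtype="even", padlen=padlen)


def _max_zero_diff_run(x: np.ndarray) -> int:
    """Longest run of consecutive exactly-zero first differences."""
    z = np.diff(x) == 0.0
    if not z.any():
        return 0
    # run lengths of True in a boolean vector
    edges = np.diff(np.concatenate(([0], z.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return int((ends - starts).max())


def detect_saturation(
    recording: Recording,
    grid: SegmentGrid,
    run_fraction: float = 0.25,
    full_segment: bool = False,
    median_window: int = 5,
) -> np.ndarray:
    """Per-segment x per-channel saturation flags.

    A segment is flagged when it contains a run of at least
    ``run_fraction * fs`` consecutive exactly-zero first differences
    (saturation clamps produce bit-equal samples), or, with
    ``full_segment=True``, only when the entire segment is constant.
    Flags are then median filtered along time to drop single-segment hits.
    """
    min_run = int(round(run_fraction * recording.fs))
    flags = np.zeros((grid.n_segments, recording.n_channels), dtype=bool)
    for ch in range(recording.n_channels):
        x = recording.samples[ch]
        for i, s in enumerate(grid.starts):
            seg = x[s:s + grid.window_n]
            if full_segment:
                flags[i, ch] = np.all(np.diff(seg) == 0.0)
            else:
                flags[i, ch] = _max_zero_diff_run(seg) >= min_run
    for ch in range(recording.n_channels):
        flags[:, ch] = median_filter_flags(flags[:, ch], window=median_window)
    return flags


def median_filter_flags(flags: np.ndarray, window: int = 5) -> np.ndarray:
    """Binary median filter; removes isolated single-segment flags."""
    if window % 2 == 0:
        raise ValueError(f"median window must be odd, got {window}")
    f = np.asarray(flags, dtype=float)
    if len(f) < window:  # zero-pad explicitly; scipy would warn
        f = np.concatenate([f, np.zeros(window - len(f))])
        return (signal.medfilt(f, kernel_size=window) > 0.5)[: len(flags)]
    return signal.medfilt(f, kernel_size=window) > 0.5


def envelope_mean(segment: np.ndarray) -> float:
    """Mean absolute analytic (Hilbert) envelope of one segment."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValueError("empty segment")
    return float(np.mean(np.abs(signal.hilbert(segment))))


@dataclass
class EnvelopeSeries:
    """Per-segment mean absolute envelope, raw and min-max normalized."""

    e_mu: np.ndarray        # (n_segments, n_channels)
    e_mu_norm: np.ndarray   # same shape, each channel scaled to [0, 1]


def envelope_series(recording: Recording, grid: SegmentGrid) -> EnvelopeSeries:
    segs = segment_view(recording.samples, grid)
    env = np.abs(signal.hilbert(segs, axis=-1))
    e_mu = env.mean(axis=-1)  # (n_segments, n_channels)
    lo, hi = e_mu.min(axis=0), e_mu.max(axis=0)
    span = hi - lo
    norm = np.full_like(e_mu, 0.5)
    ok = span > 0
    norm[:, ok] = (e_mu[:, ok] - lo[ok]) / span[ok]
    return EnvelopeSeries(e_mu=e_mu, e_mu_norm=norm)


def detect_movement(
    envelopes: EnvelopeSeries,
    threshold: float = 0.6,
    seizure_segments: np.ndarray | None = None,
) -> np.ndarray:
    """Per-segment x per-channel movement-artifact flags.

    Flags segments whose normalized envelope exceeds the threshold.  When a
    per-segment seizure mask is supplied, a flagged segment must additionally
    exceed the largest envelope observed in seizure segments on that channel,
    so genuine ictal amplitude is never rejected as artifact.
    """
    e_mu, norm = envelopes.e_mu, envelopes.e_mu_norm
    if e_mu.shape[0] < 2:
        raise ValueError("need at least two segments for min-max normalization")
    span = e_mu.max(axis=0) - e_mu.min(axis=0)
    if np.any(span == 0):
        warnings.warn("constant envelope series on some channels; no movement flags there")
    flags = (norm > threshold) & (span > 0)[None, :]
    if seizure_segments is not None and seizure_segments.any():
        seiz_max = e_mu[seizure_segments].max(axis=0)  # per channel
        flags &= e_mu > seiz_max[None, :]
    return flags


@dataclass
class ArtifactMask:
    """Per-segment x per-channel artifact bookkeeping."""

    saturation: np.ndarray
    movement: np.ndarray

    @property
    def any(self) -> np.ndarray:
        return self.saturation | self.movement

    @property
    def any_channel(self) -> np.ndarray:
        """Per-segment flag: artifact on any channel."""
        return self.any.any(axis=1)


def detect_artifacts(
    recording: Recording,
    grid: SegmentGrid,
    config: PreprocessConfig | None = None,
    seizure_segments: np.ndarray | None = None,
) -> ArtifactMask:
    cfg = config or PreprocessConfig()
    sat = detect_saturation(
        recording, grid,
        run_fraction=cfg.saturation_run_fraction,
        full_segment=cfg.full_segment_saturation,
        median_window=cfg.median_window,
    )
    env = envelope_series(recording, grid)
    mov = detect_movement(env, threshold=cfg.movement_threshold,
                          seizure_segments=seizure_segments)
    return ArtifactMask(saturation=sat, movement=mov)


def sample_mask_to_segments(
    mask: np.ndarray, grid: SegmentGrid, min_overlap_n: int | None = None
) -> np.ndarray:
    """Project a (n_channels, n_times) sample mask onto segments.

    A segment/channel is marked when at least ``min_overlap_n`` affected
    samples fall inside the window (default fs/4, matching the saturation
    run criterion).
    """
    if min_overlap_n is None:
        min_overlap_n = int(round(grid.fs / 4))
    out = np.zeros((grid.n_segments, mask.shape[0]), dtype=bool)
    for i, s in enumerate(grid.starts):
        out[i] = mask[:, s:s + grid.window_n].sum(axis=1) >= min_overlap_n
    return out


def filter_segments(recording: Recording, grid: SegmentGrid,
                    config: PreprocessConfig | None = None) -> np.ndarray:
    """Band-pass + notch every segment; (n_segments, n_channels, window_n)."""
    cfg = config or PreprocessConfig()
    segs = segment_view(recording.samples, grid)
    return bandpass_notch(segs, recording.fs, band=(cfg.band_low_hz, cfg.band_high_hz),
                          notch_hz=cfg.notch_hz, notch_q=cfg.notch_q, order=cfg.filter_order)
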