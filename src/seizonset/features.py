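"""Per-segment characteristic features.

Four features feed the fuzzy system, computed per 2.5 s segment and channel:

* ENY — sample entropy SampEn(m, r): the negative natural log of the
  conditional probability that templates of length m matching within a
  Chebyshev tolerance r also match at length m+1.  Defaults m=2,
  r = 0.2 x segment SD.
* DMF — dominant frequency: the maximum-power peak of an AR(20) Burg
  spectrum, with its half-power band.
* AVA — average amplitude: mean half-wave amplitude of peaks found by
  zero-crossings of the first derivative after a 3 Hz high-pass.
* CVA — coefficient of variation of absolute amplitude, std(|x|)/mean(|x|),
  a rhythmicity/regularity measure.

A Shannon histogram entropy is also provided for completeness, but the
pipeline's entropy feature is SampEn.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from statsmodels.regression.linear_model import burg

from .config import FeatureConfig
from .preprocess import SegmentGrid

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("eny", "dmf", "ava", "cva")


def average_amplitude(segment: np.ndarray, fs: float, highpass_hz: float = 3.0) -> float:
    """Mean half-wave peak amplitude after a high-pass above ``highpass_hz``.

    Local extrema are located at sign changes of the first difference; each
    extremum's amplitude is the mean of its two half waves, i.e. the absolute
    excursions to the preceding and following opposite extrema.  Returns 0
    when fewer than three extrema exist.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < int(fs / 3):
        raise ValueError("segment shorter than one 3 Hz cycle")
    if np.ptp(x) == 0:
        return 0.0
    sos = signal.butter(4, highpass_hz, btype="highpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    d = np.diff(y)
    s = np.sign(d)
    # carry the last nonzero slope sign through flat stretches
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    ext = np.flatnonzero(s[1:] != s[:-1]) + 1  # extremum sample indices
    if len(ext) < 3:
        return 0.0
    v = y[ext]
    half_prev = np.abs(v[1:-1] - v[:-2])
    half_next = np.abs(v[1:-1] - v[2:])
    return float(np.mean((half_prev + half_next) / 2))


def cva(segment: np.ndarray) -> float:
    """Coefficient of variation of absolute amplitude, std(|x|)/mean(|x|)."""
    a = np.abs(np.asarray(segment, dtype=float))
    mu = a.mean()
    if mu == 0:
        warnings.warn("all-zero segment; CVA defined as 0")
        return 0.0
    return float(a.std() / mu)


def sample_entropy(segment: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r) with Chebyshev distance and self-matches excluded.

    ``r`` defaults to 0.2 x the segment's standard deviation.  A constant
    series returns 0; if no (m+1)-length match exists the +inf sentinel is
    returned.
    """
    x = np.asarray(segment, dtype=float)
    n = x.size
    if n <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples, got {n}")
    sd = x.std()
    if sd == 0:
        return 0.0
    if r is None:
        r = 0.2 * sd
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    # templates of length m and m+1, both counted over the first n-m origins;
    # Chebyshev distances built incrementally as a running max over the
    # single-sample distance matrix (O(m n^2) with small constants)
    n_t = n - m
    dist = np.abs(x[:, None] - x[None, :])
    dm = dist
    for k in range(1, m):
        dm = np.maximum(dm[:-1, :-1], dist[k:, k:])
    dm1 = np.maximum(dm[:-1, :-1], dist[m:, m:])   # the n-m length-(m+1) templates
    dm = dm[:n_t, :n_t]
    # matrices are symmetric with an all-True diagonal (self-distance 0 < r)
    b = (int(np.count_nonzero(dm < r)) - n_t) // 2
    a = (int(np.count_nonzero(dm1 < r)) - n_t) // 2
    if b == 0 or a == 0:
        return float("inf")
    return float(-np.log(a / b))


def shannon_entropy(segment: np.ndarray, n_bins: int = 10) -> float:
    """Histogram entropy -sum p_k ln p_k over equal-width bins on [min, max]."""
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    x = np.asarray(segment, dtype=float)
    if np.ptp(x) == 0:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


@dataclass(frozen=True)
class SpectralPeak:
    """Dominant spectral peak with its half-power band [f_l, f_h]."""

    f_peak: float
    power: float
    f_l: float
    f_h: float


def dominant_frequency(
    segment: np.ndarray, fs: float, ar_order: int = 20, grid_n: int = 1024
) -> SpectralPeak:
    """Dominant frequency from a Burg AR spectrum.

    Fits AR(``ar_order``) reflection coefficients (Burg recursion), evaluates
    the AR power spectral density on a uniform ``grid_n``-point grid over
    (0, fs/2], and returns the maximum-power peak; ties break toward the
    lowest frequency.  The half-power band brackets the peak at the
    frequencies where the density first falls below half the peak power.
    """
    x = np.asarray(segment, dtype=float)
    if x.size <= 2 * ar_order:
        raise ValueError(f"need more than {2 * ar_order} samples for AR({ar_order})")
    if np.ptp(x) == 0 or x.std() == 0:
        warnings.warn("zero-power segment; dominant frequency undefined, returning 0 Hz")
        return SpectralPeak(f_peak=0.0, power=0.0, f_l=0.0, f_h=0.0)
    rho, sigma2 = burg(x, order=ar_order, demean=True)
    freqs = np.arange(1, grid_n + 1) / grid_n * (fs / 2)
    w = 2 * np.pi * freqs / fs
    a = 1.0 - np.exp(-1j * np.outer(w, np.arange(1, ar_order + 1))) @ rho
    psd = sigma2 / np.abs(a) ** 2
    k = int(np.argmax(psd))          # argmax returns the first (lowest-f) tie
    half = psd[k] / 2
    i = k
    while i > 0 and psd[i - 1] >= half:
        i -= 1
    j = k
    while j < grid_n - 1 and psd[j + 1] >= half:
        j += 1
    return SpectralPeak(f_peak=float(freqs[k]), power=float(psd[k]),
                        f_l=float(freqs[i]), f_h=float(freqs[j]))


def feature_matrix(
    segments: np.ndarray, fs: float, config: FeatureConfig | None = None
) -> np.ndarray:
    """Compute the four features for every (segment, channel).

    Parameters
    ----------
    segments : ndarray, shape (n_segments, n_channels, window_n)
        Filtered segment stack.

    Returns
    -------
    ndarray, shape (n_segments, n_channels, 4)
        Features in the order ``(eny, dmf, ava, cva)``.  A non-finite SampEn
        sentinel is replaced by the largest finite SampEn in the same
        channel so downstream min-max normalization stays defined.
    """
    cfg = config or FeatureConfig()
    n_seg, n_ch, _ = segments.shape
    out = np.empty((n_seg, n_ch, 4))
    for c in range(n_ch):
        for s in range(n_seg):
            seg = segments[s, c]
            out[s, c, 0] = sample_entropy(seg, m=cfg.sampen_m,
                                          r=cfg.sampen_r_factor * seg.std() or None)
            out[s, c, 1] = dominant_frequency(seg, fs, ar_order=cfg.ar_order,
                                              grid_n=cfg.spectral_grid_n).f_peak
            out[s, c, 2] = average_amplitude(seg, fs, highpass_hz=cfg.ava_highpass_hz)
            out[s, c, 3] = cva(seg)
        col = out[:, c, 0]
        bad = ~np.isfinite(col)
        if bad.any():
            finite = col[~bad]
            col[bad] = finite.max() if finite.size else 0.0
    return out


def feature_table(features: np.ndarray, grid: SegmentGrid, labels: list[str]):
    """Long-format DataFrame (segment_index, channel, t_start_s, eny, dmf, ava, cva)."""
    import pandas as pd

    n_seg, n_ch, _ = features.shape
    rows = []
    times = grid.times()
    for s in range(n_seg):
        for c in range(n_ch):
            rows.append((s, labels[c], times[s], *features[s, c]))
    return pd.DataFrame(rows, columns=["segment_index", "channel", "t_start_s", *FEATURE_NAMES])
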