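"""Pipeline configuration.

Every tunable of the detector lives here with its published default where one
exists: 2.5 s windows with 0.5 s overlap, a 0.5-100 Hz band-pass with 50 Hz
notch, movement threshold 0.6, median window 5, AR order 20, fuzzy output
anchors 0.3/0.5/0.7, FCM fuzzifier 2.0 with at most 100 iterations, alarm
threshold mean + k*SD with k in [2, 6], and a 9.5 s minimum event length.
Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


@dataclass
class PreprocessConfig:
    window_s: float = 2.5
    overlap_s: float = 0.5
    band_low_hz: float = 0.5
    band_high_hz: float = 100.0
    notch_hz: float = 50.0
    notch_q: float = 5.0   # wide notch: short zero-phase transient on 2.5 s windows
    filter_order: int = 4
    # saturation = a run of >= saturation_run_fraction * fs consecutive zero
    # first-differences; full_segment_saturation instead requires the whole
    # segment to be constant (both readings of the derivative test).
    saturation_run_fraction: float = 0.25
    full_segment_saturation: bool = False
    movement_threshold: float = 0.6
    median_window: int = 5


@dataclass
class FeatureConfig:
    sampen_m: int = 2
    sampen_r_factor: float = 0.2   # tolerance r = factor * segment SD
    ar_order: int = 20
    n_bins: int = 10               # Shannon-entropy histogram bins
    spectral_grid_n: int = 1024
    ava_highpass_hz: float = 3.0


@dataclass
class FuzzyConfig:
    th_l: float = 0.3
    th_m: float = 0.5
    th_h: float = 0.7
    grid_n: int = 1001
    fcm_m: float = 2.0
    fcm_max_iter: int = 100
    fcm_tol: float = 1e-5
    fcm_seed: int = 0


@dataclass
class DetectorConfig:
    sa_window: int = 5             # segments in the trailing moving average
    threshold_k: float = 3.0       # alarm threshold = mean + k*SD, k in [2, 6]
    min_event_s: float = 9.5
    merge_gap_s: float = 30.0
    focal_channels: list[int] | None = None   # override; default first 3 focal
    remote_channel: int | None = None         # override; default first remote


@dataclass
class EvalConfig:
    pre_window_s: float = 60.0     # detections this far before onset count as TP


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    fuzzy: FuzzyConfig = field(default_factory=FuzzyConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        kwargs: dict[str, Any] = {}
        for name, sub_cls in (
            ("preprocess", PreprocessConfig),
            ("features", FeatureConfig),
            ("fuzzy", FuzzyConfig),
            ("detector", DetectorConfig),
            ("evaluation", EvalConfig),
        ):
            if name in d:
                kwargs[name] = sub_cls(**d.pop(name))
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d or {})
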