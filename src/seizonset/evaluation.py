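"""Event-based scoring against expert annotations.

A detection counts as a true positive for an annotated seizure when its
onset falls in ``[annotated onset - pre_window_s, annotated offset]``; each
annotation takes the earliest such detection, each detection matches at
most one annotation, and leftover detections are false positives.  Latency
is detected onset minus annotated onset (negative = detected before the
annotation).  Sensitivity is 100*TP/(TP+FN); false detection rates are
false positives per hour of analyzed data, counted both before
("uninteresting") and after ("interesting") the minimum-length rejection.

Per-patient reports aggregate into an overall report the way the published
summary table does: seizure counts and hours are summed, while sensitivity,
both FDRs and latency are unweighted means across patients (micro-averaged
sensitivity is also reported for transparency).
"""

from __future__ import annotations

from dataclasses import dataclass

from .detector import DetectionResult, SeizureEvent
from .recording import Annotation, check_annotations


@dataclass(frozen=True)
class MatchPolicy:
    pre_window_s: float = 60.0

    def __post_init__(self) -> None:
        if self.pre_window_s < 0:
            raise ValueError("pre_window_s must be non-negative")


@dataclass
class MatchResult:
    tp: int
    fn: int
    fp_events: list[SeizureEvent]
    latencies: list[float]


@dataclass
class EvalReport:
    patient_id: str
    n_seizures: int
    data_hours: float
    tp: int
    fn: int
    sensitivity_pct: float
    fdr_uninteresting_per_h: float
    fdr_interesting_per_h: float
    mean_latency_s: float | None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def match_events(
    detections: list[SeizureEvent],
    annotations: list[Annotation],
    policy: MatchPolicy = MatchPolicy(),
) -> MatchResult:
    """Greedy earliest-detection matching of annotations to detections."""
    anns = check_annotations(annotations)
    dets = sorted(detections, key=lambda e: e.onset_s)
    matched = [False] * len(dets)
    tp, latencies = 0, []
    for ann in anns:
        lo, hi = ann.onset - policy.pre_window_s, ann.offset
        for i, det in enumerate(dets):
            if not matched[i] and lo <= det.onset_s <= hi:
                matched[i] = True
                tp += 1
                latencies.append(det.onset_s - ann.onset)
                break
    fp = [d for d, m in zip(dets, matched) if not m]
    return MatchResult(tp=tp, fn=len(anns) - tp, fp_events=fp, latencies=latencies)


def sensitivity(tp: int, fn: int) -> float:
    """100 * TP / (TP + FN)."""
    if tp + fn == 0:
        raise ValueError("sensitivity undefined with no annotated seizures")
    return 100.0 * tp / (tp + fn)


def fdr_per_hour(fp_count: int, hours: float) -> float:
    """False detections per hour of analyzed data."""
    if hours <= 0:
        raise ValueError("data length must be positive")
    return fp_count / hours


def evaluate_detection(
    result: DetectionResult,
    annotations: list[Annotation],
    hours: float,
    policy: MatchPolicy = MatchPolicy(),
    patient_id: str = "",
) -> EvalReport:
    """Score one record's detection result against its annotations."""
    final = match_events(result.events, annotations, policy)
    raw = match_events(result.events_raw, annotations, policy)
    return EvalReport(
        patient_id=patient_id,
        n_seizures=len(annotations),
        data_hours=hours,
        tp=final.tp,
        fn=final.fn,
        sensitivity_pct=sensitivity(final.tp, final.fn),
        fdr_uninteresting_per_h=fdr_per_hour(len(raw.fp_events), hours),
        fdr_interesting_per_h=fdr_per_hour(len(final.fp_events), hours),
        mean_latency_s=(sum(final.latencies) / len(final.latencies))
        if final.latencies else None,
    )


def aggregate(reports: list[EvalReport]) -> EvalReport:
    """Overall report: counts/hours summed, rates macro-averaged.

    Sensitivity, both FDRs and latency are unweighted arithmetic means of
    the per-patient values (patients with no detected seizure contribute no
    latency term), rounded to 2 decimals for display.
    """
    if not reports:
        raise ValueError("cannot aggregate an empty report list")
    n = len(reports)
    lats = [r.mean_latency_s for r in reports if r.mean_latency_s is not None]
    return EvalReport(
        patient_id="overall",
        n_seizures=sum(r.n_seizures for r in reports),
        data_hours=round(sum(r.data_hours for r in reports), 2),
        tp=sum(r.tp for r in reports),
        fn=sum(r.fn for r in reports),
        sensitivity_pct=round(sum(r.sensitivity_pct for r in reports) / n, 2),
        fdr_uninteresting_per_h=round(
            sum(r.fdr_uninteresting_per_h for r in reports) / n, 2),
        fdr_interesting_per_h=round(
            sum(r.fdr_interesting_per_h for r in reports) / n, 2),
        mean_latency_s=round(sum(lats) / len(lats), 2) if lats else None,
    )


def micro_sensitivity(reports: list[EvalReport]) -> float:
    """Pooled 100*sum(TP)/sum(TP+FN) across patients."""
    return sensitivity(sum(r.tp for r in reports), sum(r.fn for r in reports))
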