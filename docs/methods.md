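# Methods

## Detection model

The detector treats seizure onset detection as a fuzzy decision problem:
instead of thresholding any single feature, per-segment evidence is fused
across features, channels and time with a three-stage Mamdani rule system,
and only the final alarm series is thresholded.

**Segmentation.** Moving windows of 2.5 s with 0.5 s overlap (stride 2.0 s);
at 256 Hz: 640-sample windows, 128-sample overlap, 512-sample stride.
Windows are half-open `[start, start + window_n)` with 0-based sample
indices; a trailing partial window is dropped. 2.5 s is short enough to
treat iEEG as quasi-stationary and long enough for stable feature
estimates.

**Artifact screening** runs on raw amplitudes, before filtering, because
both artifact signatures live in the raw signal. Saturation: a segment is
flagged when it contains a run of ≥ fs/4 consecutive *exactly zero* first
differences (clamped converters produce bit-equal samples; requiring a
quarter-second run also catches plateaus that only partially overlap a
window — a config switch restores the stricter whole-segment reading).
Flags are median-filtered (window 5) to drop single-segment hits. Movement:
the mean absolute analytic envelope E_mu of each segment is min-max
normalized per channel over the record and thresholded at 0.6; when
annotations are available a flagged segment must also exceed the largest
envelope seen in any annotated seizure segment, so ictal amplitude is never
discarded as artifact. Without annotations that guard is skipped —
min-max scope is per-record, consistent with offline operation.

**Filtering.** 4th-order Butterworth band-pass 0.5–100 Hz plus a 50 Hz
notch, both zero-phase (forward–backward; "4th order" names the prototype
before the doubling). Two deliberate deviations from the plain textbook
chain, both because 2.5 s windows are *transient-limited*: the notch is
applied before the band-pass, and the band-pass uses even-reflection
padding. Zero-phase LTI stages commute in steady state, but a narrow notch
after the band-pass leaves ~28 % RMS of pure edge transient on a 2.5 s
50 Hz segment regardless of the notch's stop-band depth; notch-first with a
moderate width (Q = 5) keeps the residual under 8 % while attenuating
10 Hz by < 1 %.

## Features

* **ENY — sample entropy.** SampEn(m, r), Chebyshev distance, self-matches
  excluded, both template lengths counted over the first N−m origins.
  m = 2 and r = 0.2× the segment SD (the field-standard defaults; both
  configurable). r proportional to SD makes ENY scale-invariant. The +inf
  sentinel (no length-(m+1) match) is replaced downstream by the largest
  finite channel value so min-max normalization stays defined. A Shannon
  histogram entropy is provided for completeness but the pipeline uses
  SampEn.
* **DMF — dominant frequency.** Burg AR(20) fit (reflection-coefficient
  recursion via statsmodels), power spectral density evaluated on a
  1024-point grid over (0, fs/2]; the maximum-power peak wins, ties break
  to the lowest frequency; the half-power band brackets the peak where the
  density first falls below half the peak power. Order 20 is fixed
  globally rather than re-selected per segment.
* **AVA — average amplitude.** 3 Hz 4th-order Butterworth high-pass
  (zero-phase), extrema at sign changes of the first difference, each
  extremum's amplitude = mean of its two half-wave excursions
  (|peak − preceding opposite extremum|, |peak − following|), averaged over
  all interior extrema. The half-wave convention makes a sinusoid of
  amplitude A score ≈ 2A.
* **CVA — rhythmicity.** std(|x|)/mean(|x|); 0 with a warning on an
  all-zero segment. For Gaussian noise this converges to
  √(π/2 − 1) ≈ 0.7555, which the tests use as a closed-form anchor.

## Fuzzy system

All variables live on [0, 1]. Input variables carry a complementary L/H
trapezoid pair whose shoulders sit at the two fuzzy c-means cluster centers
(μ_L + μ_H = 1 between the centers); FCM runs per feature and channel over
all segments of the record (offline adaptation, fixed seeds), c = 2,
fuzzifier 2.0, ≤ 100 iterations, tolerance 1e-5. The upper center is the
"seizure" side: every feature's high level supports detection in the
stage-1 rules. Output variables use fixed anchors Th_l/Th_m/Th_h =
0.3/0.5/0.7: three-level outputs are L = trap(0, 0, 0.3, 0.5),
M = tri(0.3, 0.5, 0.7), H = trap(0.5, 0.7, 1, 1); two-level variables
(stage-2/3 inputs and the stage-2 output) use the complementary pair
anchored at (0.3, 0.7). The same anchors are assumed for all stages.

Rule bases are generated from their counting logic (stage 1: H iff ≥ 3 of
4 high, M iff exactly 2; stage 2: H iff ≥ 2 of 4; stage 3: the 4-rule
alarm map) and verified row-for-row against hard-coded table fixtures in
the tests. Inference is Mamdani-minimum with max aggregation; the crisp
output is the centroid of the aggregated curve by trapezoidal quadrature
on a 1001-point grid (refining to 10 001 points moves outputs by < 1e-3,
asserted in tests).

A consequence worth knowing: the defuzzified output is **not** pointwise
monotone in each input — near membership crossovers the aggregated curve's
mass can shift against the input direction. The invariant that does hold,
and is tested, is monotonicity in the number of high-core inputs.

The temporal average SA is a trailing (causal) 5-segment mean of OP2, so
the detector never looks at future segments; the prefix averages what is
available.

## Thresholding and postprocessing

The alarm threshold is mean(SZ) + k·SD(SZ) with k restricted to [2, 6] and
patient-tunable. The default is k = 3: centroid defuzzification compresses
the alarm into roughly [0.19, 0.81], so once ictal segments contribute a
few percent of the alarm variance, mean + 4·SD already exceeds the
attainable maximum — k = 3 clears baseline fluctuation (whose 99th
percentile sits near mean + 3·SD of the baseline) while staying below the
ictal plateau. Artifact-flagged segments are forced to 0 before event
extraction. Supra-threshold runs closer than 30 s are merged (the gap is
config-exposed); events shorter than 9.5 s are rejected, and the rejection
threshold can be lowered per patient (e.g. to 4 s for unusually short
onset patterns). An event's onset is its first window's start time and its
offset the last window's end.

## Evaluation

Event-based matching: a detection is a true positive for an annotation if
its onset lies in [onset − pre_window, offset]; each annotation claims the
earliest unclaimed detection; leftovers are false positives. pre_window
defaults to 60 s — early electrographic detections shortly before the
annotated clinical onset count as hits with negative latency; the value is
config-exposed since no principled universal choice exists. False
detection rates are counted both before min-length rejection
("uninteresting") and after ("interesting"); rejection can only remove
false positives, so interesting ≤ uninteresting always. Multi-record
aggregation sums seizure counts and hours but macro-averages sensitivity,
both FDRs and latency (unweighted across records/patients); the pooled
micro-average is also available. The latency total is the mean over
patient means, not over individual seizures.

## Synthetic data

The generator produces what the detector needs to be testable, not a
physiological simulation:

* **Background**: per-channel independent AR(2) noise, pole radius 0.92 at
  10 Hz, driven by unit-variance white noise — a realistic dominant
  frequency for DMF to contrast against. Units are arbitrary (nominally
  µV); only relative amplitudes matter because features are normalized.
* **Seizures**: a sharpened rhythmic discharge sign(sin)·|sin|^5 whose
  instantaneous frequency glides linearly from the configured peak (3–30
  Hz) down to 0.45× the peak, amplitude ramping up over the first 5 s and
  releasing over the last 2 s, plus unit-normalized slow amplitude
  modulation (depth 0.3, clipped to [0.2, 2]) and a broadband component
  (0.5× the rhythm's RMS). The stochastic components exist so that signal
  complexity (ENY) rises during events, the spike sharpening raises CVA,
  the glide raises DMF, and the gain raises AVA — the qualitative ictal
  feature trajectories the detector is designed around. The template is
  scaled to gain × the channel's background SD; remote channels receive it
  delayed (default 2 s) and attenuated ×0.4.
* **Artifacts**: saturation clamps all channels to their value at interval
  start (exactly zero first differences); movement adds a fast-upstroke
  (50 ms rise, exponential decay) transient of 8× the 99th percentile of
  the pre-injection absolute signal.

Everything is drawn from one seeded generator; regeneration is
byte-identical. What passing tests on this data do **not** show: robustness
to real ictal pattern diversity (electrodecremental onsets, low-voltage
fast activity), inter-patient variability, drifting electrode baselines, or
artifact classes beyond the two modeled kinds.

## Benchmark sizes and numerical choices

The standard end-to-end benchmark is five 30-minute records with two 60 s
seizures each at gain 5 — large enough for stable FCM adaptation (~900
segments per record, ~7 % ictal) and small enough to run in a couple of
minutes on one CPU. Zero-distance points in FCM get crisp memberships;
FCM centers are returned sorted ascending. Degenerate inputs are defined
explicitly: constant series → SampEn 0, CVA 0 (warning), min-max → all 0.5
(warning), zero-area membership curve → centroid 0.5 (warning), zero-power
spectrum → 0 Hz peak (warning), constant alarm series → threshold error.

## Known limitations

* Per-record (offline) normalization and FCM adaptation; no streaming mode.
* The saturation test relies on bit-equal samples; resampled or dithered
  data would need a tolerance.
* EDF export writes standard 16-bit EDF with 1 s records and requires an
  integer sampling rate; quantization error is bounded by the per-channel
  physical range / 2^16.
* The movement-artifact guard presumes annotations (or prior detections)
  to define seizure amplitude; without them, high-amplitude ictal activity
  competes with the 0.6 envelope threshold.
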