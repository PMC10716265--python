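# Methods

`afhorizon` is a framework for estimating the probability that a person
monitored with a continuous single-lead ECG will show atrial fibrillation
(AF) during the monitoring period, using only intervals of the recording
that contain **no** AF. Because real ambulatory cohorts of this kind are
proprietary, the package ships a synthetic cohort generator that plays the
role of the data, and the whole chain — windowing, quality filtering,
feature extraction, two-stage model, calibration, stratified bootstrap
evaluation — runs end-to-end against it.

## Outcome and cohort rules

A recording is **AF-positive** if it contains at least one AF episode
(atrial fibrillation and flutter share a single label) lasting more than
30 s. AF **burden** is the fraction of monitored time labeled AF; episodes
of any length count toward burden, but only >30-s episodes determine the
outcome. Recordings with burden above 70% are treated as persistent or
near-persistent AF and excluded from modelling — prediction is only
meaningful for paroxysmal disease. Models, and their probability
calibration, are organised by age group (18–54, 55–64, 65–74, 75–84,
85–99); at desk scale the pipeline pools groups by default.

`assemble_cohorts` reproduces the enriched-training design: per age group,
a random draw plus up to the same number of additional AF-positive
recordings (so training prevalence approaches 50% when the outcome is
rare), then a natural-prevalence calibration cohort, then a held-out test
cohort, all subject-disjoint.

## Windowing and signal-quality rules

The analysis unit is a 10-minute window. An input of length `L` (10 min to
24 h) is the earliest grid-aligned interval in the recording whose every
window is AF-free and passes three independent quality rules:

* **LOW_HR** — mean heart rate below 20 bpm, computed as 60 / mean
  inter-peak interval over usable (non-artifact) R peaks. Using the
  inter-peak mean rather than peak count / window length keeps this rule
  independent of the sparsity rule: a window with few but normally spaced
  peaks is sparse, not bradycardic.
* **ARTIFACT_EXCESS** — more than 120 s of the window labeled artifact.
* **SPARSE_R** — fewer than 60 usable R peaks, or any inter-peak gap
  exceeding 30 s after subtracting artifact time. The "too few or too
  sparse" rule is stated qualitatively in the source design; the 60-peak
  and 30-s thresholds are this package's quantification and live in
  `ValidityConfig`.

The earliest-interval policy is deterministic and label-blind; a random
policy is available behind the same interface for sensitivity analysis.
R peaks and rhythm labels are consumed from the annotation stream (the
synthetic generator's ground truth), mirroring a workflow built on a
clinical annotation pipeline; no waveform R-peak detector is in scope.

## Features

Per window:

* **HRV** (15 metrics) on NN intervals — successive inter-beat intervals
  whose two endpoints are both normal beats; intervals adjacent to a PAC
  or PVC are dropped, not interpolated. Metrics: mean/median NN, SDNN,
  RMSSD, SDSD, pNN50, CV, mean/min/max HR, a triangular-index
  approximation (N over the modal 1/128-s histogram bin), and Lomb
  periodogram band powers (LF 0.04–0.15 Hz, HF 0.15–0.40 Hz, total, and
  LF/HF). The concrete list is this package's choice of a standard
  short-term set computable from a 10-minute NN series.
* **Ectopic** — PAC and PVC counts.
* **Rhythm** — time fractions of non-AF abnormal rhythms (SVT, AVB) and
  of artifact.
* **Embedding** — 128 values from the window encoder (below).
* **Demographics** — age and sex.

### Normalization

Fitted on training windows only. Burden/rate-like features (rhythm
burdens, ectopic counts, spectral powers) are approximately exponential:
they get offset removal (training minimum), scaling (training mean of the
offset-removed values), then `y = 1 − exp(−x)`, giving values in [0, 1) on
the training range, strictly increasing and bounded above by 1. Remaining
continuous features get a Box-Cox transform (maximum-likelihood λ after a
positivity shift) followed by standardization. Family membership is
decided by feature role, not by a distribution test, so the pipeline is
deterministic. Embeddings are standardized only; binary features pass
through. All linear and Box-Cox parts invert to ~1e−9 relative error,
which the tests assert.

Two numerical caveats discovered while validating: isotonic regression
(below) is inconsistent at its boundary blocks, so "fit ≈ prevalence under
independence" is asserted over the interior 5–95% of scores; and average
precision is *not* bounded below by prevalence for every ranking (with all
positives ranked last it equals `mean_k k/(N−P+k)`), only in expectation
over random rankings.

## Two-stage model

**Module A (window encoder).** A 1-D convolutional network over the raw
10-minute window (per-window standardized): a front-end average-pool
(factor 4, i.e. an effective 50 Hz at the default 200 Hz sampling), four
kernel-7 conv blocks with average pooling, global average pooling, a
128-unit fully connected layer, and a sigmoid output. It is trained with
the recording-level outcome broadcast to the recording's AF-free windows
(weak labels) under binary cross-entropy — the only label the problem
statement supports. The 128 activations of the second-last layer are the
window embedding. After training the weights are frozen; the pipeline
asserts this by SHA-256 checksum before and after stage-2 training. The
default widths (8, 16, 32, 32) are deliberately small so the stage trains
in about a minute on one CPU; widths are configurable.

**Module B (sequence model).** Per input configuration: the per-window
feature sequence (1 to 144 windows) feeds a 2-layer bidirectional LSTM
(hidden 16 per direction); the concatenated final states of the top
layer's two directions, with demographics appended, pass through two fully
connected layers to a sigmoid risk score. Appending demographics after the
recurrent stage (rather than broadcasting per timestep) is a design choice
made for the exact degeneracy of the demographics-only configuration: in
the **AG** configuration the recurrent stage is bypassed entirely, so two
subjects with equal age and sex receive equal scores regardless of their
ECGs. The **DL Only** configuration takes embeddings only, without
demographics. The six configurations (AG; AG+HRV; AG+Ectopic;
AG+HRV+Ectopic+Rhythm; DL Only; All Features) differ only in which feature
families enter.

Both networks are plain numpy with hand-written backpropagation (verified
against finite differences in the test suite) and Adam (lr 1e−3 encoder /
3e−3 sequence model, early stopping on validation loss for module B).
Everything is seeded; training is bit-reproducible, inference is
deterministic and batch-composition invariant.

## Calibration

Raw scores are mapped to probabilities by isotonic regression
(pool-adjacent-violators, sklearn's implementation) fitted on the
natural-prevalence calibration split, one map per age group (pooled at
desk scale). Evaluation between knots is stepwise-constant — each PAVA
block carries one probability — with clipping outside the knot range; ties
are pooled before fitting. Mean preservation (mean fitted value = cohort
prevalence) is exact and asserted exactly. Because every group is
calibrated against the same kind of natural cohort, calibrated
probabilities are comparable across groups even when raw score scales are
not.

## Evaluation protocol

AUC is computed as the Mann–Whitney statistic via mid-ranks (ties count
half); average precision as the step-wise precision × Δrecall sum with no
interpolation; both are cross-checked in tests against brute-force
enumeration and sklearn. Operating points are reported at sensitivity
0.80, taking the smallest threshold whose sensitivity reaches the target
(conservative specificity) when no threshold hits it exactly. Confidence
intervals use the percentile bootstrap; model comparisons evaluate both
models on identical resample indices and report a two-sided p-value with
add-one smoothing, `2·min(frac(Δ*≤0), frac(Δ*≥0))` at floor `1/(B+1)`.
Single-class resamples are redrawn and counted rather than skipped, so all
B iterations contribute. The desk-scale default is B = 1000–2000 (the
protocol's reference is 10,000; the interval widths are essentially
unchanged, the runtime is several times smaller). Reports stratify by age
(<65 / ≥65), input length (10 min / 1 h / 24 h supported), and AF-burden
range (<1%, 1–10%, >10%, estimated over the entire acquisition); burden
strata keep all AF-negative recordings in the denominator and restrict
only the positives, so row counts equal negatives + stratum positives.

## Synthetic cohorts: what they emulate and what they do not

Each subject is a parameter profile: mean RR, SDNN target, respiratory
modulation depth, PAC/PVC rates, AF episode rate and log-normal duration,
artifact rate/duration, optional SVT/AVB rates, a morphology-shift scalar,
age and sex. Generation is layered: the rhythm-episode timeline and beat
train are simulated for the whole recording (cheap), while voltage is
rendered lazily for exactly the spans analysed. Rendering is a pure
function of the annotations, profile and seed — any span matches the
corresponding slice of a full render to float32 accumulation error
(≈1e−9), with per-sample noise drawn from fixed seed-keyed tiles.

* **Sinus RR**: AR(1) (φ = 0.85) plus a respiratory sine, variance split
  by the modulation depth and tuned to the SDNN target (realized SDNN
  within 10%, lag-1 autocorrelation > 0.3).
* **AF RR**: i.i.d. shifted gamma, mean 0.8 × sinus RR, CV 0.25 — the
  "irregularly irregular" signature without an atrial model (lag-1 < 0.2).
* **AF episodes**: an alternating renewal process (exponential sinus gaps,
  log-normal episodes) whose mean cycle is 86400 / rate — chosen over
  Poisson placement with rejection because it realizes the target burden
  without thinning bias at high rates.
* **Waveform**: five Gaussian kernels (P, Q, R, S, T) per beat, PR roughly
  fixed, QT scaling with √RR; PACs are early with flattened P, PVCs early,
  wide and with discordant T; AF suppresses the P wave and adds a small
  fibrillatory oscillation; artifacts replace the signal with
  high-amplitude noise.
* **The learnable association**: AF-prone subjects carry, in their AF-free
  signal, an elevated PAC rate (×8), a shifted SDNN (×1.4) and a subtle
  P/T morphology change (0.3): flattened/broadened P and slightly reduced
  T. These three effect-size knobs are the package's design choices for
  what the predictive signal consists of, not estimates from any dataset;
  they are set once in `CohortConfig` and not tuned per experiment.
  AF-prone status is additionally age-associated (log-odds 0.05/year
  around 60) and mildly sex-associated, so demographics alone carry some
  signal.

What the generator does **not** emulate: real atrial electrograms, 12-lead
geometry, realistic noise/wander spectra, medication effects, or any
physiologic coupling beyond the stylised associations above. Passing tests
therefore demonstrate that the pipeline recovers the planted structure
under the stated conditions — an internal-validity statement — and say
nothing about performance on real ECGs.

## Reference study conditions (desk scale)

The default experiment simulates 1200 subjects (design prevalence 20%,
burden mix ⅓/⅓/⅓ across the <1% / 1–10% / >10% bands with targets drawn
log-uniformly inside band interiors), 12-hour recordings at 200 Hz, and a
1-hour AF-free input per subject, scored both as a 10-min (first window)
and a 1-h (six windows) scenario; splits are 600/300/300
train/calibration/test at natural prevalence. Subjects without a clean
AF-free hour drop out (about 1%, concentrated in high burden), mirroring
the length-equalization of the evaluation design. Observed prevalence runs
below the design value (~14–15%) because low-burden AF-prone subjects
often show no episode within a 12-hour wear — intended, as this is exactly
the paroxysmal-AF censoring the method targets; such subjects become
hard negatives. These sizes were chosen so the full study, including both
training stages, runs in roughly 4 minutes on a single CPU; every size is
a config field and scales up without code changes.

## Known limitations

* The encoder sees an effectively 50 Hz signal after front-end pooling;
  morphology cues narrower than ~40 ms are attenuated.
* Weak labels for module A assume the AF-free-signal shift is present in
  every window of an AF-prone subject; intermittent expression would
  dilute the embedding signal.
* Isotonic calibration with a few hundred calibration subjects produces
  coarse (few-block) maps; ties can shave a little AUC relative to raw
  scores (bounded in tests at 0.005 at n = 2000).
* The 24-h (144-window) scenario is supported and tested for shape, but
  the shipped reference study exercises 10-min and 1-h inputs only.
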