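# Methods

This note records what the package computes, the assumptions behind the
synthetic generator, the fixed numerical choices, and the known limitations.

## Problem

Fetal arrhythmia screening from non-invasive abdominal ECG (AECG). The
abdominal mixture is dominated by the maternal ECG; the fetal ECG (FECG) must
be extracted before fetal RR intervals (RRIs) can be measured. The method
then classifies fixed-length FECG segments with a small 1-D CNN trained on
*weak* labels derived from the cohort-level RRI distribution, and calls a
subject arrhythmic when the fraction of arrhythmia-classified segments
exceeds a threshold.

## Pipeline

1. **Preprocessing** (`fetalarr.pipeline.preprocess`). Non-finite samples and
   runs of at least 50 ms sitting within 0.1% of the observed amplitude rail
   are marked invalid; every channel is band-passed 3–45 Hz (order-4
   Butterworth, zero-phase); 1 kHz records are polyphase-resampled to the
   working rate of 500 Hz. Records more than half invalid are rejected.
2. **Maternal QRS detection** (`detect_maternal_rpeaks`). Pan–Tompkins on the
   maternal thoracic channel when present (otherwise the abdominal channel
   with the most 5–15 Hz energy): band-pass 5–15 Hz, derivative, squaring,
   150 ms moving-window integration, adaptive signal/noise running thresholds
   with a 200 ms refractory period, fiducial refinement to the local
   band-passed extremum.
3. **Maternal removal** (`subtract_maternal_template`). Per abdominal
   channel, a maternal template is the mean of R-aligned −250…+450 ms
   windows (edges tapered over 20 ms); it is scaled per beat by least squares
   and subtracted. The residual channel with the highest 10–45 Hz kurtosis —
   where sparse fetal complexes stand out most — becomes the FECG.
4. **Fetal R-peak detection** (`detect_fetal_rpeaks`). Candidates are local
   maxima of the smoothed squared derivative. Peaks are accepted greedily
   left to right: within each search window (200 ms refractory to 900 ms
   after the previous peak) the *earliest* candidate reaching 35% of the
   running QRS score level is accepted. A purely interval-prior-driven picker
   systematically skips alternate beats in tachycardic runs, because one
   500 ms "skip" scores as well as two 250 ms beats; taking the earliest
   unambiguous complex removes that failure mode. Only when no candidate is
   that strong does a Gaussian RR-interval prior (running mean/SD from
   400/50 ms, floor weight 0.1) arbitrate among weak candidates.
5. **RRIs** (`compute_rri`). Successive peak differences gated to the
   physiological 100–900 ms range.
6. **Segmentation** (`segmentation.segment_signal`). 3 s windows advanced by
   1 s (1500 samples at 500 Hz); a window owns exactly the intervals whose
   *both* defining peaks fall inside it. A `duration_s` signal yields
   `floor((duration_s − 3)/1) + 1` segments.
7. **Weak labeling** (`labeling`). All subjects' RRIs are pooled per class
   into 25 ms bins over 100–900 ms; each bin's healthy/arrhythmia count ratio
   classifies it as normal (ratio > 1), arrhythmic (ratio strictly below the
   threshold `x`, default 0.63) or moderate (in between). A segment takes the
   worst class among its intervals (arrhythmia > moderate > normal);
   arrhythmia labels on healthy subjects' segments are demoted to moderate;
   moderate segments are excluded from binary training. The strict `< x`
   reading is required for consistency with the published range table, whose
   boundary bin (ratio exactly 0.5000 at x = 0.50) stays moderate.
   Two alternatives are implemented: *simple* labeling (segments inherit the
   subject's class) and a *per-subject* variant that brackets each arrhythmic
   subject's intervals by mean ± y·SD (population SD; `calibrate_y` finds by
   bisection the smallest y reaching a target moderate fraction) and trains a
   ternary classifier.
8. **Classifier** (`cnn`). Two (conv + ReLU + max-pool 4) blocks with 8 and
   16 filters of width 9, a 64-unit dense ReLU layer and a softmax head,
   trained with class-weighted cross-entropy and Adam (lr 3·10⁻⁴, batch 64).
   Segments are z-scored individually so electrode-dependent amplitude cannot
   act as a class cue. The network is implemented directly on numpy (im2col
   convolutions, hand-derived backward pass, float32 parameters) because no
   deep-learning framework is available in the target environment; this also
   makes training bit-reproducible given the seed.
9. **Decision** (`metrics`). Subject ratio = fraction of segments classified
   arrhythmic (ternary variant: ARR/(ARR+NR), moderate leaves the
   denominator; all-moderate subjects default to a healthy call). A subject
   is called arrhythmic when the ratio strictly exceeds `th`, swept over
   0.00–1.00 in 0.05 steps. Evaluation is leave-one-subject-out with
   *per-fold relabeling*: the held-out subject never contributes to the range
   table or the training set of its own fold. Metrics are specificity
   TN/(TN+FP), recall TP/(TP+FN), accuracy (TP+TN)/all.

## What the generator emulates

`fetalarr.synthetic` builds deterministic cohorts with the statistical
structure the method relies on, not anatomically realistic waveforms:

- **Fetal RRI process.** Healthy subjects: i.i.d. truncated-normal intervals
  clipped to 200–700 ms, per-subject means near 400 ms (SD 12 ms across
  subjects) and spreads of 26–40 ms, so the pooled healthy SD lands near the
  ~34 ms seen in clinical RRI data. Arrhythmic subjects additionally carry
  frequent brief ectopic episodes: Poisson arrivals at 18–26 per minute,
  each ~0.5 s (≈1 beat), substituting intervals drawn uniformly from
  480–650 ms (pause-type subjects: blocked/dropped beats) or 230–330 ms
  (premature-type subjects: extrasystoles), alternating between subjects.
  This makes the pooled arrhythmic interval distribution persistently wide
  and multimodal (pooled SD near 72 ms) across the whole recording. An
  earlier draft used rare multi-second episodes instead; that caps the
  fraction of abnormal segments per subject near 0.3, which contradicts the
  published picture of arrhythmic subject ratios well above the healthy
  band — so the frequent-extrasystole model is the study condition.
- **Waveforms.** QRS complexes are differences of two centred Gaussians
  (biphasic, unit peak, ~40 ms wide fetal / ~80 ms maternal). Abdominal
  channels mix the fetal train (gain 0.7–1.0), a regular 75 bpm maternal
  train at 4× fetal amplitude, three sinusoidal baseline-wander components
  below 0.8 Hz, and white noise (sd 0.055 signal units by default). One
  thoracic channel carries the maternal train nearly clean. SNR-controlled
  runs set the noise from the *power* SNR of the unit-amplitude fetal train
  (`noise_sd_for_snr`).
- **Quantisation.** Outputs are snapped to a 1/2048 amplitude grid and
  clipped at ±15.99, matching the 16-bit WFDB writer's gain of 2048, so
  file round-trips are bit-exact.

## Fixed numerical choices

| Quantity | Value |
| --- | --- |
| Working sampling rate | 500 Hz |
| Segment window / step | 3 s / 1 s (1500 samples) |
| RRI histogram bins | 25 ms over 100–900 ms |
| Range threshold `x` | 0.63 (grid 0.50, 0.60, 0.63, 0.65, 0.70) |
| Decision threshold grid | 0.00–1.00, step 0.05, strict `>` |
| RRI gate / refractory | 100–900 ms / 200 ms |
| CNN | filters (8, 16), kernel 9, pool 4, dense 64, Adam 3·10⁻⁴ |
| Default cohort | 14 healthy + 12 arrhythmic, 120 s each |

## Limitations

- The synthetic cohort is a statistical emulation; absolute performance
  numbers on it do not transfer to clinical recordings, only the relative
  behaviour of the pipeline's components does.
- The maternal train is regular (no maternal HRV) and maternal/fetal QRS
  overlap is the main realistic corruption; P and T waves are not modelled.
- The CNN is deliberately small to train on one CPU in minutes; it is not a
  tuned architecture.
- Per-subject variant calibration assumes enough intervals per subject for a
  stable mean/SD; very short recordings degrade it first.
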