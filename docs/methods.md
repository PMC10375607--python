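# Methods

## Problem and labeling scheme

ECG delineation assigns to every time sample of every lead one of four
classes — isoelectric line (0), P-wave (1), QRS-complex (2), T-wave (3) —
from which wave boundaries (onset/offset) follow as the edges of constant
runs. Annotated corpora in the Lobachevsky layout store, per lead, symbol
streams in which each wave is a run `(`, peak symbol (`p`/`N`/`t`), `)`.
Wave intervals are treated as **closed** `[onset, offset]` in 0-based
sample indices; the symbols sit on samples, so the closed convention makes
the annotated onset and offset samples part of the wave. Runs missing
either boundary are excluded (not repaired) and tallied per lead, so
corpus totals remain diagnosable. Where annotated waves overlap, label
precedence is QRS > T > P: QRS boundaries are the most reliably annotated,
and T/P overlap is the common ambiguous case.

## Denoising

VisuShrink-style wavelet shrinkage. Parameters:

- `wavelet` (default `bior6.8`): biorthogonal 6.8 is the default because
  its symmetric, smooth basis matches ECG morphology; symlet and
  Daubechies candidates are screened alongside it by `rank_wavelets`.
- `level` (default 8): at 500 Hz an 8-level decomposition puts
  baseline wander (< 1 Hz) into the approximation band, which is never
  thresholded, so slow drift is not mistaken for detail noise.
- threshold: soft, universal, σ̂·√(2 ln n) per signal with
  σ̂ = median(|finest detail|)/0.6745. If σ̂ = 0 (noise-free details,
  e.g. a constant signal) the signal is returned unchanged rather than
  divided by zero inside the shrinkage rule.
- boundary extension: symmetric (configurable) — the common choice for
  biosignals, avoiding edge discontinuities.

SNR is `10·log10(Σ ref² / Σ (ref − est)²)` dB. Exact equality returns an
infinite-SNR sentinel (`math.inf`) rather than raising; an identically
zero reference is a parameter error. Two reference conventions exist:
against the known clean signal (synthetic corpora), or against the raw
input (real records, where the "noise" is the removed component — the
only computable convention when no clean reference exists). Infinite
values are excluded from ranking means.

On the synthetic corpus's white-noise + sinusoidal-wander profile the
finer-support wavelets can out-rank `bior6.8` by small margins; the
ranking operation asserts determinism and completeness, not a particular
winner, because the winner is a property of the corpus's noise, not of
the ranking procedure.

## Segmentation and splits

A beat spans one P-wave onset to the next on the same lead. A span is
kept only if it fully contains a complete P and a complete QRS wave; the
trailing partial beat is dropped. Windows are fixed at 512 samples
(~1.02 s at 500 Hz, longer than almost any resting beat): shorter spans
are zero-padded on the right, longer spans are clipped at 512 (clip
events are logged). `valid_length` records the true span so padded
positions can be masked everywhere downstream; labels in the padded
region are 0 by construction.

Beat-based splits shuffle each lead's beats with a documented seed and
partition by fractions (default 0.80 / 0.12 / 0.08, applied as
floor(0.80 n) / floor(0.12 n) / remainder). Patient-based splits assign
whole subjects by record-number range; on a 200-record corpus the
defaults are 1–180 / 181–190 / 191–200, and `auto_patient_ranges`
produces the analogous ~90/5/5 partition for other corpus sizes. On real
corpora, published per-lead beat tallies can differ slightly depending on
the exclusion conventions applied; the segmenter therefore reports raw
counts plus per-lead exclusion tallies instead of forcing agreement with
any particular published total.

## Model family

Thirteen standard configurations: a prefix of the filter ladder
(8, 16, 32, 64, 128, 256, 512, 1024, 2048) of same-padding Conv1D layers
(kernel 3, stride 1, ReLU), then a recurrent head returning outputs at
every timestep, then a per-timestep dense(4) + softmax. Models 1–4 use an
LSTM head with 1–4 conv layers; models 5–13 use a BiLSTM head with 1–9
conv layers. There is no pooling: pooling would destroy the per-sample
output the delineation task requires, and the conv specs are stride-1
only. The recurrent head consumes the conv feature sequence directly (no
flattening).

Head width is 64 units per direction by default — not part of the
13-config definition; chosen as the smallest common width that trains
stably at desk scale, and configurable everywhere. The optimizer is Adam
(the de-facto default for the 10⁻⁵ schedule); weights use Glorot-uniform
input matrices, orthogonal recurrent matrices, zero biases except the
LSTM forget gate at 1.

The layers are implemented on numpy arrays (batch, time, channels) with
hand-derived backward passes; backprop-through-time gradients for all
four heads are verified against central finite differences (relative
tolerance 10⁻³) in the test suite. `predict_labels` takes the per-sample
argmax; numpy's argmax resolves ties toward the lower class index, which
makes the tie rule deterministic (isoelectric wins a perfect tie).

A numerical note on the bidirectionality probe: in an *untrained* LSTM
the influence of sample 511 on the output at sample 0 decays like the
product of ~511 forget-gate activations (≈0.73⁵¹¹ under default
initialization), far below double precision. The probe test therefore
uses a persistent-memory initialization (forget-gate bias +6, input-gate
bias −6) so the architectural property is measurable; the converse check
— a unidirectional head cannot react at t=0 to a change at t=511 — is
structural and holds for any weights.

## Training and metrics

Loss is categorical cross-entropy over non-padded samples only. Including
the padded tail (trailing zeros labeled isoelectric) would inflate every
metric with trivially correct samples, so padding is masked out of the
loss, the confusion matrix, and all metrics.

One model is trained on beats pooled from all 12 leads and evaluated per
lead (a per-lead-model mode exists but is not the default). Metrics are
sample-wise: every one of the 512 positions is a classification event.
Per class c (one-vs-rest): SEN = TP/(TP+FN), SPE = TN/(TN+FP),
PRE = TP/(TP+FP), ACC = (TP+TN)/N, F1 = harmonic mean of PRE and SEN,
all in percent. Zero-denominator ratios are reported as NaN, excluded
from the unweighted macro means, and logged. The full-scale training
schedule (300 epochs, batch 8, lr 10⁻⁵, categorical cross-entropy) is the
`TrainConfig` default; desk-scale experiments override it explicitly.

## Synthetic generator

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) with per-wave
amplitude (mV), center offset (s), and width σ (s); defaults give a
lead-II-like morphology (P 0.15 mV / σ 25 ms, R 1.0 mV / σ 12 ms, T
0.3 mV / σ 50 ms) at 60 bpm with ±5% uniform RR jitter, 500 Hz, 10 s.
Ground truth is analytic: P and T span μ ± 3σ, QRS spans
[μ_Q − 3σ_Q, μ_S + 3σ_S] (3σ covers > 99% of each bump's mass); configs
whose ground-truth intervals would overlap are rejected at construction,
so fixtures are valid by force. The 12 leads are fixed signed scalings of
one source (aVR −0.85, i.e. inverted, as on a real torso); this crude
single-dipole surrogate is adequate because the pipeline treats leads
independently. White noise and sinusoidal baseline wander are added after
annotation, so labels stay exact at any noise level.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: pathological morphologies (atrial fibrillation,
bundle-branch block, ST deviation), biphasic or inverted T-waves on
normally-upright leads, inter-lead timing differences, electrode
artifacts, or annotation disagreement between human readers. Tests
against it validate the pipeline's bookkeeping, learnability, and
numerics, not clinical performance.

## Delineation post-processing

Predicted label runs shorter than `min_run` = 10 samples (20 ms at
500 Hz) are relabeled isoelectric before interval extraction — long
enough to suppress single-sample flicker, short enough to keep every
plausible wave. Predicted and true intervals are matched per beat window
(windows share the 0–511 coordinate space), greedily by descending
overlap, one-to-one, accepting a pair only if it overlaps and both
boundary errors are within `tolerance` = 75 samples (150 ms), the
conventional acceptance window in the delineation literature. Matched
pairs yield signed onset/offset errors in samples and ms.

## Problem sizes

Desk-scale experiments use: 3–10 synthetic records for corpus-level
checks; a reduced classifier (2 conv layers, BiLSTM, 16 units/direction)
trained 20 epochs with Adam at 3·10⁻³ on 200 noise-free beats for the
recovery experiment — the full-scale 10⁻⁵/300-epoch schedule is far too
slow-moving to converge in 20 epochs, so the reduced experiment uses a
learning rate appropriate to its horizon. These sizes are the package's
own choices for a fast, deterministic suite; the full 13-model, 300-epoch
program on a real 200-record corpus runs through the same code paths via
`run_pipeline` or the CLI.

## Known limitations

- The WFDB codec covers the dialect this pipeline needs (format-16
  single-.dat records, per-lead MIT annotation files with SKIP escapes);
  it is not a general WFDB implementation.
- Training is pure numpy on one CPU: correct and verifiable, but not fast
  enough for the 2048-filter configurations at full scale in reasonable
  wall time.
- `snr_db`'s raw-reference convention on real records measures the
  retained-to-removed power ratio, which is only a proxy for true
  denoising quality; the clean-reference convention is exact but requires
  synthetic data.
- Beat-based splitting shares subjects across splits by design; use the
  patient-based mode for leakage-free evaluation.
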