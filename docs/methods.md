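# Methods

## Problem and model

The package treats crop phenology staging as ordinal 8-class image
classification. Two networks share one five-stage convolutional trunk design
with tap points after the stem and after each subsequent stage:

- **Teacher**: the trunk embeds each frame of a temporally ordered series
  (global average pooling to a feature vector); a single-layer LSTM (hidden
  size 128 in the `mini` preset, 512 for `resnet50`) integrates the feature
  sequence; a linear head maps the hidden state at every step to stage
  logits. The LSTM is causal, so the step-*t* logits depend only on frames
  1..*t*: one forward pass simultaneously yields the prediction for every
  truncation of the series. The teacher is trained with per-timestep
  cross-entropy against each frame's stage — every frame supervises the
  network, no future information leaks into any prediction, and the same
  pass later provides causally valid soft labels for mid-series frames.
  (Supervising only the final frame is available via the evaluation policy
  but converges far more slowly at small scale.)
- **Student**: the trunk alone plus dropout and a linear head; one frame in,
  stage logits out.

### Distillation objective

With teacher logits v and student logits z, the temperature softmax is
q_i = exp(z_i/T)/Σ_j exp(z_j/T); the combined objective is

    L = α·L_soft + (1−α)·L_hard + β·L_attention
    L_soft = −Σ_i p_i^T log q_i^T       (p^T, q^T at temperature T)
    L_hard = −Σ_i c_i log q_i^1         (student softmax at T = 1)
    L_attention = Σ_{l∈S} ‖vec(A_S^l) − vec(A_T^l)‖₂

Defaults: T = 3, α = 0.7, β = 0.001, S = {1, 3, 4}. Three deliberate choices:

- **No T² rescaling of L_soft.** The classical gradient-rescaling factor is
  *not* applied by default; the objective is used exactly as written above.
  An opt-in `scale_soft_by_T2` flag restores it.
- **L_attention sums over the configured layer set** (rather than averaging),
  so adding a layer adds its term; per-layer terms are logged separately.
- **Maps are L2-normalised before the distance.** An attention map is the
  channel-wise sum of squared activations A[h,w] = Σ_c a[c,h,w]², normalised
  to unit flattened L2 norm. Without normalisation the β weighting would
  depend on activation magnitude and therefore on layer width and training
  stage; with it, each per-layer term is bounded by 2. The zero activation
  passes through unnormalised and is flagged. This one definition is used by
  the loss and by the visualisation panels alike.
- Logs clamp their argument at 1e-12.

The teacher's supervision for a student sample at frame *t* is the soft label
from the series truncated at *t* and the attention maps *of frame t itself* —
the frame the student sees — so paired maps are spatially comparable.
Analytic gradients of the full objective (including through the map
normalisation) are implemented alongside and verified against central finite
differences at 1e-4 relative tolerance in the test-suite.

## Synthetic data generator

The generator emulates the statistical structure that motivates temporal
modelling, not wheat photographs:

- Each series has a latent growth state g on [0, 1], starting uniform on
  [−0.15, 0.9] (clamped, so early stages occur) and increasing by
  |N(0.010, 0.005)| per frame; 30 frames then span ~2–3 of the 8 equal-width
  stage bins. The stage label is 1 + floor(8·clip(g,0,1)), capped at 8.
- A frame is rendered from a noisy observation g_obs = g + N(0, σ):
  3 + 22·g_obs elongated "shoot" strokes (length also grows with g_obs),
  elliptical "spike" clusters appearing past the heading boundary
  (g_obs > 0.5) at rate 30·(g_obs − 0.5), and a green→gold colour drift past
  g_obs = 0.7, over a soil-coloured background, plus per-frame brightness
  jitter (±10%) and mild pixel noise (sd 0.02). Element counts are logged so
  tests can check the renderer against its own bookkeeping.
- **σ (default 0.08) is the single ambiguity knob**, measured in latent
  growth units: 0.64 of a stage-bin width, enough that single frames of
  adjacent stages overlap while the ~30 frames of a series still pin the
  trajectory down. A nearest-centroid pilot classifier drops from ~0.6
  (σ = 0) to ~0.4 (σ = 0.08) single-frame accuracy; its monotone decrease in
  σ is a tested property.
- Per-series random substreams are spawned from the global seed by counter
  (SeedSequence spawn keys), so increasing `n_series` never perturbs earlier
  series, and identical (config, seed) give bit-identical pixels and
  manifests.

What the generator does **not** emulate: photorealistic canopy texture,
weather and illumination regimes, camera geometry, cross-season domain shift,
within-field spatial heterogeneity. Passing benchmarks here therefore shows
the *machinery* (temporal advantage, distillation transfer, attention
alignment) behaves as designed, not that any accuracy level carries over to
real field imagery.

## Dataset handling

Frames arrive as PNGs plus a `series_id,frame_index,stage,path` manifest.
Series are assembled at a fixed length (default 30; short series are rejected
by default or front-padded by repeating the earliest frame), and a series'
label is its final frame's stage (majority-stage labelling is available).
Splits are **series-level** (default 6:2:2), stratified by label with
deterministic shuffling; global sizes are round(n·ratio) for val/test with
the remainder to train, and no series ever straddles splits. Training
augmentation expands the set by an integer factor (default 3: originals plus
two copies); each copy draws one transform — brightness factor in ±20%,
horizontal flip, rotation in ±15° (ranges are package choices) — applied
identically to every frame so the augmented series stays temporally coherent.

## Training and the benchmark

Optimisation is Adam with the study defaults on `TrainConfig` (batch 16,
learning rate 1e-4, dropout 0.3). The self-contained benchmark
(`phenodistill.benchmark`) uses desk-scale conditions chosen once:

- 60 series × 30 frames at 32 px, `mini` trunk widths (8, 16, 32, 64, 128);
- teacher: 30 epochs at lr 1e-3 — at ~7 optimizer steps per epoch the 1e-4
  default cannot leave the initialisation basin in any reasonable time, and
  1e-3 converges smoothly on pilot runs; student: 10 epochs at lr 5e-4,
  trained and evaluated on **all frames** (`all_frames` policy) rather than
  final frames only, giving ~360 validation points per replicate instead of
  12 — the teacher is correspondingly scored at every causal truncation, so
  both models are measured on identical points;
- three replicates (fresh data, splits, and initialisation per seed), medians
  reported.

Within a replicate, the three ablation modes (baseline: α = β = 0; KD:
β = 0; KD+AT: full objective) share the data, the frozen teacher, and the
initial student weights, so differences are attributable to the loss.
Best-epoch selection is by validation overall accuracy with ties broken by
lower MAE. Teacher parameters are bitwise untouched by student training
(tested). The expected orderings — teacher ≥ KD+AT ≥ KD ≥ baseline, each
within a 0.02 tolerance on the median — plus a decreasing validation
KL(p^T‖q^T) during KD training are the benchmark's acceptance properties.
Which attention-layer subset wins the 31-subset sweep is data-dependent; the
harness reports it without asserting.

## Metrics

Multi-class overall accuracy (confusion-matrix trace over total), per-class
one-vs-rest precision/recall/F1 with **macro** averaging for the headline F1
(classes absent from both truth and prediction are excluded from the macro
mean; micro-F1 is also emitted), multi-class Cohen's kappa with chance
agreement p_e = Σ_k row_k·col_k / n² (both reduce exactly to the familiar
binary TP/TN forms at N = 2), and the ordinal MAE, the mean absolute stage
difference on the 1–8 scale. Zero-denominator classes score 0 with a
warning. The whole suite is tested to 1e-12 against a naive per-definition
oracle and cross-checked against scikit-learn.

## Numerical and engineering choices

- `phenodistill.nn` is a compact numpy NN library (float32, channels-last):
  convolution is computed as a sum of k² offset matmuls on contiguous
  slices; LSTM backward is full BPTT; Adam uses default moments and bias
  correction. All initialisation flows from per-build seeded generators, and
  single-threaded CPU runs are bit-reproducible.
- Teacher supervision (per-truncation logits, per-frame attention maps) is
  computed in one tapped forward per series and memoised in memory and
  optionally on disk, keyed by series id; cache hits are bit-identical.
- Spatial-size mismatch between paired attention maps raises an error rather
  than silently interpolating (it cannot occur with shared presets).
- Visualisation panels are composed as raw arrays with a fixed colormap and
  bilinear, parameter-free upsampling, so repeated renders are byte-identical.
- Checkpoints are versioned `.npz` archives holding the config header and all
  named parameters.

## Limitations

- The `resnet50` preset is structurally faithful (five taps, bottleneck
  3-4-6-3, ~23.5 M parameters at 8 classes) but not intended for CPU
  training; no pretrained weights are shipped or downloaded.
- Benchmark accuracies quantify behaviour on the synthetic regime only, and
  the attention-transfer gain at β = 0.001 is small by construction —
  orderings are asserted with a tolerance, not as strict improvements.
- No learning-rate schedules, weight decay, or multi-device support; the
  training loops are deliberately plain.
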