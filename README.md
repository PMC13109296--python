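# phenodistill

Crop phenology — which development stage (emergence, tillering, jointing,
booting, heading, anthesis, filling, maturity) a field is in — is far easier
to read from a *sequence* of field-camera images than from one photo: single
frames of adjacent stages look alike, while the growth dynamics disambiguate
them. But models that need a whole multi-temporal image series are heavy to
deploy. `phenodistill` implements the standard remedy for this trade-off:
**knowledge distillation with multi-layer attention transfer**, compressing a
temporal teacher into a single-image student.

- The **teacher** applies a convolutional backbone to every frame of an
  ordered series and integrates the features with an LSTM; its logits at step
  *t* estimate the stage at frame *t* given frames 1..*t*.
- The **student** is the backbone alone: one frame in, stage logits out.
- The student is trained against three signals, with temperature *T*,
  weights α and β:

  q_i = exp(z_i/T) / Σ_j exp(z_j/T)

  L = α · L_soft + (1 − α) · L_hard + β · L_attention

  where L_soft = −Σ_i p_i^T log q_i^T is the cross-entropy to the teacher's
  temperature-softened distribution p^T, L_hard the usual cross-entropy to
  the one-hot label, and L_attention = Σ_{l ∈ S} ‖A_S^l − A_T^l‖₂ pulls the
  student's per-layer spatial attention maps A^l (channel-wise sum of squared
  activations, L2-normalised) toward the teacher's on a configurable layer
  subset S. Defaults: T = 3, α = 0.7, β = 0.001, S = {1, 3, 4}.

Everything — the CNN, the LSTM, backpropagation, Adam — is implemented in
numpy (`phenodistill.nn`), so the whole study runs on one CPU in minutes at
the built-in `mini` scale (a `resnet50` preset preserves the full five-tap
topology for structural work). A synthetic generator emulates the data
regime: 8 ordinal stages from a monotone latent growth state, 30-frame
series, series-level 6:2:2 splits, 3× training augmentation, and a tunable
appearance-noise knob that makes single frames of adjacent stages overlap —
the gap the teacher can close and the student must inherit.

## Worked example

`examples/03_train_and_distill.py` generates 40 series, splits them 6:2:2 at
the series level, augments training 3×, trains the teacher, then a
hard-label-only student and a distilled (KD + attention transfer) student:

```
series: 72 train (3x augmented) / 8 val
teacher validation OA 0.754 (best epoch 29)
baseline student validation OA 0.537
kd_at    student validation OA 0.562
```

The teacher, which sees each frame's history, is well above both single-frame
students (the generator's ambiguity at work); the distilled student recovers
part of that gap over the purely supervised one. Overall accuracy here is
frame-level: the teacher is scored at every causal truncation, the student on
every frame, so both are measured on the same validation points.

The other examples are narrative single-capability scripts: dataset
generation and the ambiguity knob (`01`), the loss anatomy on worked numbers
(`02`), the ordinal metric bundle — OA, macro F1, Cohen's kappa, stage MAE —
on a hand-checkable 6-sample case (`04`), and attention panels (`05`).

A thin CLI wires the same stages for shell use:

```bash
phenodistill --seed 1 generate --out data --n-series 60
phenodistill --seed 1 prepare --data data --ratios 6:2:2
phenodistill --seed 0 train-teacher --data data --out run --epochs 30 --lr 1e-3
phenodistill --seed 0 train-student --data data --out run \
    --teacher run/teacher.npz --mode kd_at --policy all_frames
phenodistill evaluate --data data --checkpoint run/student_kd_at.npz
phenodistill visualize --data data --checkpoint run/teacher.npz --out panel.png
```

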