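"""Distillation and attention-transfer objectives.

The student is trained against three signals:

* ``L_soft`` — cross-entropy between the teacher's temperature-softened class
  distribution p^T = softmax(v / T) and the student's softened output
  q^T = softmax(z / T).  Raising T above 1 flattens both distributions and
  exposes inter-class similarity structure ("dark knowledge"), which for an
  ordinal staging task mostly encodes adjacent-stage similarity.
* ``L_hard`` — standard cross-entropy between the student's T=1 softmax and
  the one-hot ground-truth label.
* ``L_attention`` — the sum over a configured set of backbone layers of the
  L2 distance between the student's and teacher's (L2-normalised) spatial
  attention maps.

The combined objective is  L = alpha * L_soft + (1 - alpha) * L_hard
+ beta * L_attention.  The soft term is used as written, without the
classical T^2 gradient-rescaling factor; opt in via ``scale_soft_by_T2`` if
the rescaled variant is wanted.

All functions here are pure numpy on single samples; batching and autodiff
bookkeeping live in :mod:`phenodistill.training`.  Analytic gradients with
respect to the student's logits and tap activations are provided alongside
(:func:`combined_loss_gradients`) and are validated against finite
differences in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attention import AttentionMap

LOG_EPS = 1e-12  # clamp inside logarithms


@dataclass
class LossConfig:
    """Scalar hyperparameters of the combined objective.

    T > 0 is the distillation temperature (default 3), alpha in [0, 1] the
    soft/hard mixing weight (default 0.7), beta >= 0 the attention-transfer
    weight (default 0.001), and ``transfer_layers`` the backbone tap indices
    whose attention maps are matched (default {1, 3, 4}).
    """

    T: float = 3.0
    alpha: float = 0.7
    beta: float = 0.001
    transfer_layers: tuple[int, ...] = (1, 3, 4)
    scale_soft_by_T2: bool = False

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError(f"temperature T must be > 0, got {self.T}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        self.transfer_layers = tuple(sorted(set(int(l) for l in self.transfer_layers)))
        if self.beta > 0 and not self.transfer_layers:
            raise ValueError("transfer_layers must be non-empty when beta > 0")
        if any(l < 1 or l > 5 for l in self.transfer_layers):
            raise ValueError("transfer_layers must be a subset of {1..5}")


@dataclass
class LossBreakdown:
    """Individual terms and the weighted total of the combined objective."""

    soft: float
    hard: float
    attention: float | None
    total: float

    def as_row(self) -> dict:
        return {
            "L_soft": self.soft,
            "L_hard": self.hard,
            "L_attention": 0.0 if self.attention is None else self.attention,
            "L_total": self.total,
        }


def one_hot(stage: int, n: int = 8) -> np.ndarray:
    """One-hot encoding of a 1-based stage label."""
    if not 1 <= stage <= n:
        raise ValueError(f"stage {stage} outside 1..{n}")
    c = np.zeros(n)
    c[stage - 1] = 1.0
    return c


def softened_probabilities(z: np.ndarray, T: float) -> np.ndarray:
    """Temperature softmax q_i = exp(z_i/T) / sum_j exp(z_j/T).

    T = 1 reproduces the standard softmax.  Computed with max-subtraction so
    arbitrarily large logits do not overflow.
    """
    if T <= 0:
        raise ValueError(f"temperature T must be > 0, got {T}")
    z = np.asarray(z, dtype=np.float64)
    if not np.all(np.isfinite(z)):
        raise ValueError("logits contain non-finite values")
    s = z / T
    s = s - s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(p: np.ndarray, q: np.ndarray) -> float:
    """-sum_i p_i log q_i with the log clamped at LOG_EPS."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    return float(-(p * np.log(np.maximum(q, LOG_EPS))).sum())


def distillation_loss(v: np.ndarray, z: np.ndarray, c: np.ndarray,
                      cfg: LossConfig) -> LossBreakdown:
    """Soft + hard cross-entropy mix (attention term zero).

    ``v`` are the teacher logits, ``z`` the student logits and ``c`` the
    one-hot ground truth.  L_soft = -sum p^T log q^T with p^T, q^T the
    teacher/student softmaxes at temperature cfg.T; L_hard uses the student's
    T=1 softmax against c.
    """
    v = np.asarray(v, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    if not (v.shape == z.shape == c.shape):
        raise ValueError(f"logit/label length mismatch: {v.shape}, {z.shape}, {c.shape}")
    p_T = softened_probabilities(v, cfg.T)
    q_T = softened_probabilities(z, cfg.T)
    q_1 = softened_probabilities(z, 1.0)
    l_soft = cross_entropy(p_T, q_T)
    if cfg.scale_soft_by_T2:
        l_soft *= cfg.T**2
    l_hard = cross_entropy(c, q_1)
    total = cfg.alpha * l_soft + (1.0 - cfg.alpha) * l_hard
    return LossBreakdown(soft=l_soft, hard=l_hard, attention=None, total=total)


def _paired_maps(student_maps, teacher_maps, layers):
    by_layer_s = {m.layer_index: m for m in student_maps}
    by_layer_t = {m.layer_index: m for m in teacher_maps}
    for layer in layers:
        if layer not in by_layer_s or layer not in by_layer_t:
            raise ValueError(f"attention maps missing for layer {layer}")
        ms, mt = by_layer_s[layer], by_layer_t[layer]
        if ms.map.shape != mt.map.shape:
            raise ValueError(
                f"layer {layer}: attention map shapes differ "
                f"({ms.map.shape} vs {mt.map.shape})")
        yield layer, ms, mt


def attention_loss(student_maps: list[AttentionMap], teacher_maps: list[AttentionMap],
                   layers: tuple[int, ...]) -> float:
    """Sum over selected layers of ||vec(A_S) - vec(A_T)||_2.

    Maps are expected already L2-normalised (as produced by
    :func:`phenodistill.attention.attention_from_activation`), so each
    per-layer term lies in [0, 2].
    """
    total = 0.0
    for _, ms, mt in _paired_maps(student_maps, teacher_maps, layers):
        total += float(np.linalg.norm((ms.map - mt.map).ravel()))
    return total


def attention_loss_per_layer(student_maps, teacher_maps, layers) -> dict[int, float]:
    """Per-layer L2 terms, for logging and the layer-sweep ablation."""
    return {layer: float(np.linalg.norm((ms.map - mt.map).ravel()))
            for layer, ms, mt in _paired_maps(student_maps, teacher_maps, layers)}


def combined_loss(v, z, c, student_maps, teacher_maps, cfg: LossConfig) -> LossBreakdown:
    """Full objective: alpha*L_soft + (1-alpha)*L_hard + beta*L_attention."""
    base = distillation_loss(v, z, c, cfg)
    if cfg.beta == 0:
        return base
    l_att = attention_loss(student_maps, teacher_maps, cfg.transfer_layers)
    total = base.total + cfg.beta * l_att
    return LossBreakdown(soft=base.soft, hard=base.hard, attention=l_att, total=total)


# ---------------------------------------------------------------------------
# analytic gradients (used by the training loop; checked vs finite differences)
# ---------------------------------------------------------------------------

def distillation_loss_grad_z(v, z, c, cfg: LossConfig) -> np.ndarray:
    """d(alpha*L_soft + (1-alpha)*L_hard)/dz.

    d L_soft / dz = (q^T - p^T) / T  (times T^2 if rescaling is enabled);
    d L_hard / dz = q^1 - c.
    """
    v = np.asarray(v, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    p_T = softened_probabilities(v, cfg.T)
    q_T = softened_probabilities(z, cfg.T)
    q_1 = softened_probabilities(z, 1.0)
    g_soft = (q_T - p_T) / cfg.T
    if cfg.scale_soft_by_T2:
        g_soft *= cfg.T**2
    return cfg.alpha * g_soft + (1.0 - cfg.alpha) * (q_1 - c)


def attention_term_grad_raw(raw_student: np.ndarray, teacher_map: AttentionMap,
                            eps: float = 1e-30) -> tuple[float, np.ndarray]:
    """Value and gradient of ||A_S - A_T||_2 w.r.t. the *raw* student map.

    ``raw_student`` is the un-normalised channel-collapsed map r (sum of
    squared activations); A_S = r / ||r||.  Returns (term, d term / d r).
    Degenerate cases (zero raw map, or A_S == A_T exactly) have zero
    subgradient and return a zero array.
    """
    r = np.asarray(raw_student, dtype=np.float64)
    n = float(np.linalg.norm(r.ravel()))
    if n <= eps:
        a_s = r
        d = a_s - teacher_map.map
        return float(np.linalg.norm(d.ravel())), np.zeros_like(r)
    a_s = r / n
    d = a_s - teacher_map.map
    dn = float(np.linalg.norm(d.ravel()))
    if dn <= eps:
        return dn, np.zeros_like(r)
    g_a = d / dn  # d term / d A_S
    # through A = r / ||r||:  dA/dr = (I - A A^t) / ||r||
    g_r = (g_a - a_s * float((a_s * g_a).sum())) / n
    return dn, g_r


def attention_loss_grad_activations(student_activations: list[np.ndarray],
                                    teacher_maps: list[AttentionMap],
                                    layers: tuple[int, ...]):
    """Value and gradients of L_attention w.r.t. student tap activations.

    ``student_activations`` holds the five raw (C, H, W) tap activations in
    layer order 1..5.  Returns (loss, grads) where ``grads`` has one entry per
    tap (zero array for layers outside the transfer set).
    """
    by_layer_t = {m.layer_index: m for m in teacher_maps}
    grads = [np.zeros_like(np.asarray(a, dtype=np.float64))
             for a in student_activations]
    total = 0.0
    for layer in layers:
        act = np.asarray(student_activations[layer - 1], dtype=np.float64)
        raw = np.sum(act * act, axis=0)
        mt = by_layer_t[layer]
        if raw.shape != mt.map.shape:
            raise ValueError(
                f"layer {layer}: attention map shapes differ "
                f"({raw.shape} vs {mt.map.shape})")
        term, g_r = attention_term_grad_raw(raw, mt)
        total += term
        grads[layer - 1] = 2.0 * act * g_r[None, :, :]
    return total, grads


def combined_loss_gradients(v, z, c, student_activations, teacher_maps,
                            cfg: LossConfig):
    """(LossBreakdown, dL/dz, [dL/d tap activation]) for one sample."""
    g_z = distillation_loss_grad_z(v, z, c, cfg)
    base = distillation_loss(v, z, c, cfg)
    if cfg.beta == 0:
        zero = [np.zeros_like(np.asarray(a, dtype=np.float64))
                for a in student_activations]
        return base, g_z, zero
    l_att, g_acts = attention_loss_grad_activations(
        student_activations, teacher_maps, cfg.transfer_layers)
    bd = LossBreakdown(soft=base.soft, hard=base.hard, attention=l_att,
                       total=base.total + cfg.beta * l_att)
    return bd, g_z, [cfg.beta * g for g in g_acts]
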