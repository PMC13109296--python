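"""Two-phase training: temporal teacher first, distilled student second.

Phase 1 trains the teacher (backbone + LSTM) on augmented frame series with
per-timestep hard-label cross-entropy: because the LSTM is causal, the logits
at step t are the teacher's estimate of the stage at frame t given frames
1..t, so every frame supervises the network and no future information leaks
backwards.

Phase 2 freezes the teacher and trains the single-frame student against the
combined objective: the teacher's temperature-softened distribution at the
matching truncation (soft label), the one-hot stage (hard label) and,
optionally, the teacher's attention maps of the very frame the student sees.
Three modes support the component ablation: ``baseline`` (hard labels only),
``kd`` (soft + hard) and ``kd_at`` (soft + hard + attention transfer).

All loops are seeded and single-threaded-deterministic: identical (config,
seed, data) reproduce bit-identical logged losses.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .attention import AttentionMap
from .data import SeriesCache, SeriesSample
from .losses import (LossConfig, attention_loss_grad_activations,
                     softened_probabilities)
from .metrics import MetricReport, evaluate
from .models import (BackboneConfig, StudentModel, TeacherModel, build_student,
                     build_teacher, get_state, set_state)
from .nn import Adam


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (defaults: Adam, batch 16, lr 1e-4,
    dropout 0.3) plus the loss configuration and sampling policies."""

    batch_size: int = 16
    lr: float = 1e-4
    optimizer: str = "adam"
    dropout: float = 0.3
    epochs: int = 10
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    student_sample_policy: str = "final_frame"  # or "all_frames"
    eval_policy: str = "all_frames"  # frames scored during validation
    hidden_size: int = 128

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.optimizer != "adam":
            raise ValueError(f"only 'adam' is supported, got {self.optimizer!r}")
        if self.student_sample_policy not in ("final_frame", "all_frames"):
            raise ValueError(f"unknown student_sample_policy "
                             f"{self.student_sample_policy!r}")
        if self.eval_policy not in ("final_frame", "all_frames"):
            raise ValueError(f"unknown eval_policy {self.eval_policy!r}")


@dataclass
class TrainLog:
    """Per-epoch loss/metric records and the best-epoch bookkeeping."""

    records: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_oa: float = -1.0
    best_val_mae: float = np.inf
    checkpoint_path: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _check_finite(loss: float, context: str):
    if not np.isfinite(loss):
        raise RuntimeError(f"training diverged: non-finite loss in {context}")


def _maybe_update_best(log: TrainLog, epoch: int, report: MetricReport, model,
                       best_state: list) -> None:
    better = (report.oa > log.best_val_oa
              or (report.oa == log.best_val_oa and report.mae < log.best_val_mae))
    if better:
        log.best_epoch = epoch
        log.best_val_oa = report.oa
        log.best_val_mae = report.mae
        best_state[0] = get_state(model)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_teacher(teacher: TeacherModel, samples: list[SeriesSample],
                     cache: SeriesCache, eval_policy: str = "all_frames",
                     batch_size: int = 16) -> MetricReport:
    """Score the teacher's causal per-frame predictions (or final frame only)."""
    teacher.eval()
    y_true, y_pred = [], []
    for i in range(0, len(samples), batch_size):
        chunk = samples[i:i + batch_size]
        x = np.stack([cache.series_array(s) for s in chunk])
        preds = teacher.forward(x).argmax(axis=2) + 1
        for s, p in zip(chunk, preds):
            if eval_policy == "all_frames":
                y_true.extend(s.stages().tolist())
                y_pred.extend(p.tolist())
            else:
                y_true.append(s.label)
                y_pred.append(int(p[-1]))
    return evaluate(y_true, y_pred)


def student_eval_points(samples: list[SeriesSample], policy: str
                        ) -> list[tuple[SeriesSample, int]]:
    if policy == "final_frame":
        return [(s, s.L - 1) for s in samples]
    return [(s, t) for s in samples for t in range(s.L)]


def evaluate_student(student: StudentModel, samples: list[SeriesSample],
                     cache: SeriesCache, eval_policy: str = "all_frames",
                     batch_size: int = 64) -> MetricReport:
    """Score the student frame-by-frame against per-frame stage labels."""
    student.eval()
    points = student_eval_points(samples, eval_policy)
    y_true = [s.frames[t].stage for s, t in points]
    y_pred = []
    for i in range(0, len(points), batch_size):
        x = np.stack([cache.frame_array(s, t) for s, t in points[i:i + batch_size]])
        y_pred.extend((student.forward(x).argmax(axis=1) + 1).tolist())
    return evaluate(y_true, y_pred)


# ---------------------------------------------------------------------------
# phase 1: teacher
# ---------------------------------------------------------------------------

def train_teacher(train: list[SeriesSample], val: list[SeriesSample],
                  cache: SeriesCache, config: TrainConfig,
                  model_config: BackboneConfig | None = None,
                  checkpoint_dir=None) -> tuple[TeacherModel, TrainLog]:
    """Train the temporal teacher with per-timestep cross-entropy.

    Returns the model restored to its best-validation-OA parameters (ties
    broken by lower MAE) together with the per-epoch log.
    """
    if not train or not val:
        raise ValueError("train and validation splits must be non-empty")
    model_config = model_config or BackboneConfig(dropout=config.dropout)
    teacher = build_teacher(model_config, hidden_size=config.hidden_size,
                            seed=config.seed)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(101,)))
    teacher.set_dropout_rng(rng)
    opt = Adam(teacher.parameters(), lr=config.lr)
    log = TrainLog()
    best_state = [None]

    labels = {s.series_id: s.stages() for s in train}
    for epoch in range(1, config.epochs + 1):
        teacher.train()
        order = rng.permutation(len(train))
        epoch_loss, n_batches = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            chunk = [train[j] for j in order[i:i + config.batch_size]]
            x = np.stack([cache.series_array(s) for s in chunk])
            y = np.stack([labels[s.series_id] for s in chunk])  # (B, L) stages
            logits = teacher.forward(x)
            b, L, n = logits.shape
            p = _softmax(logits.reshape(b * L, n))
            onehot = np.eye(n, dtype=p.dtype)[y.reshape(-1) - 1]
            loss = float(-(onehot * np.log(np.maximum(p, 1e-12))).sum() / (b * L))
            _check_finite(loss, f"teacher epoch {epoch}")
            opt.zero_grad()
            teacher.backward(((p - onehot) / (b * L)).reshape(b, L, n))
            opt.step()
            epoch_loss += loss
            n_batches += 1
        report = evaluate_teacher(teacher, val, cache, config.eval_policy)
        _maybe_update_best(log, epoch, report, teacher, best_state)
        log.records.append({"epoch": epoch, "train_loss": epoch_loss / n_batches,
                            "val_oa": report.oa, "val_mae": report.mae,
                            "val_macro_f1": report.macro_f1,
                            "val_kappa": report.kappa})
    set_state(teacher, best_state[0])
    teacher.eval()
    if checkpoint_dir is not None:
        from .models import save_checkpoint
        os.makedirs(checkpoint_dir, exist_ok=True)
        log.checkpoint_path = os.path.join(os.fspath(checkpoint_dir), "teacher.npz")
        save_checkpoint(teacher, log.checkpoint_path)
    return teacher, log


# ---------------------------------------------------------------------------
# teacher supervision (soft labels + attention maps), cached
# ---------------------------------------------------------------------------

class TeacherSupervision:
    """Frozen-teacher outputs for every causal truncation of each series.

    One tapped eval-mode forward per series yields the logits at every step t
    (prediction from frames 1..t) and the attention maps of every frame; both
    are memoised in memory, and optionally on disk (``cache_dir``) keyed by
    series_id so repeated student epochs and repeated runs reuse them
    bit-identically.
    """

    def __init__(self, teacher: TeacherModel, cache: SeriesCache,
                 loss_config: LossConfig, cache_dir=None):
        self.teacher = teacher
        self.cache = cache
        self.loss_config = loss_config
        self.cache_dir = None if cache_dir is None else os.fspath(cache_dir)
        if self.cache_dir:
            os.makedirs(self.cache_dir, exist_ok=True)
        self._mem: dict[str, tuple[np.ndarray, list[np.ndarray], np.ndarray]] = {}

    def _series_key(self, sample: SeriesSample) -> str:
        return sample.series_id.replace(os.sep, "_")

    def _compute(self, sample: SeriesSample):
        self.teacher.eval()
        x = self.cache.series_array(sample)[None]
        logits = self.teacher.forward(x, want_taps=True)[0]  # (L, n)
        taps = self.teacher.backbone.taps  # list of (L, H, W, C)
        maps, flags = [], []
        for act in taps:
            layer_maps, layer_flags = [], []
            for t in range(act.shape[0]):
                raw = np.sum(act[t].astype(np.float64) ** 2, axis=-1)
                norm = float(np.linalg.norm(raw.ravel()))
                layer_flags.append(norm > 0)
                layer_maps.append(raw / norm if norm > 0 else raw)
            maps.append(np.stack(layer_maps))  # (L, H, W)
            flags.append(layer_flags)
        return logits.astype(np.float64), maps, np.array(flags, dtype=bool)

    def _get_series(self, sample: SeriesSample):
        key = self._series_key(sample)
        if key in self._mem:
            return self._mem[key]
        if self.cache_dir:
            path = os.path.join(self.cache_dir, key + ".npz")
            if os.path.exists(path):
                with np.load(path) as d:
                    entry = (d["logits"],
                             [d[f"maps{i}"] for i in range(5)],
                             d["flags"])
                self._mem[key] = entry
                return entry
        entry = self._compute(sample)
        self._mem[key] = entry
        if self.cache_dir:
            path = os.path.join(self.cache_dir, key + ".npz")
            np.savez(path, logits=entry[0], flags=entry[2],
                     **{f"maps{i}": m for i, m in enumerate(entry[1])})
        return entry

    def logits(self, sample: SeriesSample, t: int) -> np.ndarray:
        """Teacher logits v for the series truncated at frame t (0-based)."""
        logits, _, _ = self._get_series(sample)
        if not 0 <= t < logits.shape[0]:
            raise ValueError(f"frame index {t} out of range 0..{logits.shape[0] - 1}")
        return logits[t]

    def soft_label(self, sample: SeriesSample, t: int) -> np.ndarray:
        """p^T: the teacher's temperature-softened distribution at frame t."""
        return softened_probabilities(self.logits(sample, t), self.loss_config.T)

    def attention_maps(self, sample: SeriesSample, t: int) -> list[AttentionMap]:
        """The five per-layer attention maps of frame t."""
        logits, maps, flags = self._get_series(sample)
        if not 0 <= t < logits.shape[0]:
            raise ValueError(f"frame index {t} out of range 0..{logits.shape[0] - 1}")
        return [AttentionMap(layer_index=i + 1, map=maps[i][t],
                             normalized=bool(flags[i][t]))
                for i in range(len(maps))]


def teacher_supervision(teacher: TeacherModel, sample: SeriesSample, t: int,
                        config: LossConfig, cache: SeriesCache,
                        cache_dir=None):
    """(soft label at temperature T, five attention maps) for frames 1..t.

    Convenience wrapper over :class:`TeacherSupervision` for one query.
    """
    sup = TeacherSupervision(teacher, cache, config, cache_dir=cache_dir)
    return sup.soft_label(sample, t), sup.attention_maps(sample, t)


# ---------------------------------------------------------------------------
# phase 2: student
# ---------------------------------------------------------------------------

STUDENT_MODES = ("baseline", "kd", "kd_at")


def effective_loss_config(loss: LossConfig, mode: str) -> LossConfig:
    """Ablation-mode view of the loss: baseline = hard only, kd = no AT."""
    if mode not in STUDENT_MODES:
        raise ValueError(f"unknown mode {mode!r}; use one of {STUDENT_MODES}")
    if mode == "baseline":
        return replace(loss, alpha=0.0, beta=0.0)
    if mode == "kd":
        return replace(loss, beta=0.0)
    return loss


def train_student(train: list[SeriesSample], val: list[SeriesSample],
                  teacher: TeacherModel | None, config: TrainConfig,
                  mode: str = "kd_at",
                  model_config: BackboneConfig | None = None,
                  supervision: TeacherSupervision | None = None,
                  initial_state: dict | None = None,
                  checkpoint_dir=None, cache: SeriesCache | None = None
                  ) -> tuple[StudentModel, TrainLog]:
    """Train the single-frame student under the chosen ablation mode.

    ``baseline`` needs no teacher; ``kd``/``kd_at`` require a frozen trained
    teacher (its parameters are never touched).  The per-epoch log records the
    loss breakdown, validation metrics and — when a teacher is present — the
    mean validation KL(p^T || q^T), whose decrease over training is the
    distillation-convergence diagnostic.
    """
    if not train or not val:
        raise ValueError("train and validation splits must be non-empty")
    if cache is None:
        raise ValueError("a SeriesCache is required")
    loss_cfg = effective_loss_config(config.loss, mode)
    needs_teacher = mode != "baseline"
    if needs_teacher and teacher is None:
        raise ValueError(f"mode {mode!r} requires a trained teacher")

    model_config = model_config or BackboneConfig(dropout=config.dropout)
    student = build_student(model_config, seed=config.seed)
    if initial_state is not None:
        set_state(student, initial_state)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(202,)))
    student.set_dropout_rng(rng)
    opt = Adam(student.parameters(), lr=config.lr)
    log = TrainLog()
    best_state = [None]

    if needs_teacher and supervision is None:
        supervision = TeacherSupervision(teacher, cache, config.loss)

    points = student_eval_points(train, config.student_sample_policy)
    val_points = student_eval_points(val, config.eval_policy)
    want_taps = loss_cfg.beta > 0

    for epoch in range(1, config.epochs + 1):
        student.train()
        order = rng.permutation(len(points))
        sums = {"L_soft": 0.0, "L_hard": 0.0, "L_attention": 0.0, "L_total": 0.0}
        n_samples = 0
        for i in range(0, len(order), config.batch_size):
            batch = [points[j] for j in order[i:i + config.batch_size]]
            bsz = len(batch)
            x = np.stack([cache.frame_array(s, t) for s, t in batch])
            logits = student.forward(x, want_taps=want_taps)
            n_cls = logits.shape[1]
            z = logits.astype(np.float64)
            onehot = np.zeros((bsz, n_cls))
            for k, (s, t) in enumerate(batch):
                onehot[k, s.frames[t].stage - 1] = 1.0
            q_1 = _softmax(z)
            l_hard = -(onehot * np.log(np.maximum(q_1, 1e-12))).sum(axis=1)
            dlogits = (1.0 - loss_cfg.alpha) * (q_1 - onehot)
            if needs_teacher:
                v = np.stack([supervision.logits(s, t) for s, t in batch])
                p_T = _softmax(v / loss_cfg.T)
                q_T = _softmax(z / loss_cfg.T)
                l_soft = -(p_T * np.log(np.maximum(q_T, 1e-12))).sum(axis=1)
                dlogits += loss_cfg.alpha * (q_T - p_T) / loss_cfg.T
            else:
                l_soft = np.zeros(bsz)
            sums["L_soft"] += float(l_soft.sum())
            sums["L_hard"] += float(l_hard.sum())
            total = (loss_cfg.alpha * l_soft + (1 - loss_cfg.alpha) * l_hard).sum()
            tap_grads = None
            if want_taps:
                taps = student.tap_activations()
                tap_grads = [np.zeros_like(a) for a in taps]
                for k, (s, t) in enumerate(batch):
                    # taps are NHWC; the attention loss works on (C, H, W)
                    s_acts = [a[k].transpose(2, 0, 1) for a in taps]
                    l_att, g_acts = attention_loss_grad_activations(
                        s_acts, supervision.attention_maps(s, t),
                        loss_cfg.transfer_layers)
                    sums["L_attention"] += l_att
                    total += loss_cfg.beta * l_att
                    for li in range(len(tap_grads)):
                        tap_grads[li][k] = (loss_cfg.beta
                                            * g_acts[li].transpose(1, 2, 0))
                tap_grads = [g / bsz for g in tap_grads]
            sums["L_total"] += float(total)
            _check_finite(sums["L_total"], f"student epoch {epoch} ({mode})")
            opt.zero_grad()
            student.backward((dlogits / bsz).astype(logits.dtype),
                             tap_grads=tap_grads)
            opt.step()
            n_samples += bsz
        report = evaluate_student(student, val, cache, config.eval_policy)
        record = {"epoch": epoch, "mode": mode,
                  **{k: v / n_samples for k, v in sums.items()},
                  "val_oa": report.oa, "val_mae": report.mae,
                  "val_macro_f1": report.macro_f1, "val_kappa": report.kappa}
        if needs_teacher:
            record["val_kl"] = validation_kl(student, supervision, val_points,
                                             cache, loss_cfg.T)
        _maybe_update_best(log, epoch, report, student, best_state)
        log.records.append(record)
    set_state(student, best_state[0])
    student.eval()
    if checkpoint_dir is not None:
        from .models import save_checkpoint
        os.makedirs(checkpoint_dir, exist_ok=True)
        log.checkpoint_path = os.path.join(os.fspath(checkpoint_dir),
                                           f"student_{mode}.npz")
        save_checkpoint(student, log.checkpoint_path)
    return student, log


def validation_kl(student: StudentModel, supervision: TeacherSupervision,
                  val_points, cache: SeriesCache, T: float,
                  batch_size: int = 64) -> float:
    """Mean KL(p^T || q^T) between teacher and student softened outputs."""
    student.eval()
    total = 0.0
    for i in range(0, len(val_points), batch_size):
        chunk = val_points[i:i + batch_size]
        x = np.stack([cache.frame_array(s, t) for s, t in chunk])
        z = student.forward(x)
        for k, (s, t) in enumerate(chunk):
            p = softened_probabilities(supervision.logits(s, t), T)
            q = softened_probabilities(z[k], T)
            total += float((p * (np.log(np.maximum(p, 1e-12))
                                 - np.log(np.maximum(q, 1e-12)))).sum())
    return total / len(val_points)
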