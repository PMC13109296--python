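"""Student and teacher networks for phenological stage classification.

Both networks share one backbone design exposing five ordered "tap" points —
the stem output plus the four subsequent stages — from which spatial
attention maps are computed for transfer and for visualisation.

Activations flow in channels-last (NHWC) layout; images are (H, W, 3)
float arrays in [0, 1].

* The **student** maps a single RGB frame to 8-class logits:
  backbone -> global average pool -> dropout -> linear head.
* The **teacher** consumes an ordered frame series: the same backbone design
  (with its own weights) embeds each frame, a single-layer LSTM integrates
  the embedding sequence, and a linear head emits logits at every time step.
  Because the LSTM is causal, the logits at step t depend only on frames
  1..t, so one pass yields the prediction for every truncation of the series.

Two presets are provided: ``mini`` (stage widths 8/16/32/64/128 at 32 px,
trainable on a CPU in minutes) and ``resnet50`` (the standard 3-4-6-3
bottleneck architecture), both preserving the same five-tap topology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .attention import AttentionMap, attention_from_activation

CHECKPOINT_VERSION = 1

MINI_WIDTHS = (8, 16, 32, 64, 128)


@dataclass
class BackboneConfig:
    """Architecture hyperparameters shared by student and teacher builders."""

    preset: str = "mini"
    n_stages_out: int = 8
    dropout: float = 0.3
    input_size: int = 32
    widths: tuple[int, ...] = MINI_WIDTHS

    def __post_init__(self):
        if self.preset not in ("mini", "resnet50"):
            raise ValueError(f"unknown preset {self.preset!r}; use 'mini' or 'resnet50'")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must lie in [0, 1), got {self.dropout}")
        if self.preset == "mini" and len(self.widths) != 5:
            raise ValueError("mini preset needs exactly 5 stage widths")

    def to_dict(self) -> dict:
        return {"preset": self.preset, "n_stages_out": self.n_stages_out,
                "dropout": self.dropout, "input_size": self.input_size,
                "widths": list(self.widths)}


class Bottleneck(nn.Module):
    """ResNet bottleneck (1x1 -> 3x3 -> 1x1 with identity/projection skip)."""

    def __init__(self, c_in, c_mid, c_out, stride, rng):
        super().__init__()
        self.main = nn.Sequential(
            nn.Conv2d(c_in, c_mid, k=1, rng=rng, bias=False), nn.BatchNorm2d(c_mid),
            nn.ReLU(),
            nn.Conv2d(c_mid, c_mid, k=3, stride=stride, rng=rng, bias=False),
            nn.BatchNorm2d(c_mid), nn.ReLU(),
            nn.Conv2d(c_mid, c_out, k=1, rng=rng, bias=False), nn.BatchNorm2d(c_out),
        )
        if stride != 1 or c_in != c_out:
            self.skip = nn.Sequential(
                nn.Conv2d(c_in, c_out, k=1, stride=stride, rng=rng, bias=False),
                nn.BatchNorm2d(c_out))
        else:
            self.skip = None
        self.relu = nn.ReLU()

    def forward(self, x):
        y = self.main.forward(x)
        s = self.skip.forward(x) if self.skip is not None else x
        return self.relu.forward(y + s)

    def backward(self, grad):
        g = self.relu.backward(grad)
        gx = self.main.backward(g)
        gx = gx + (self.skip.backward(g) if self.skip is not None else g)
        return gx

    def parameters(self):
        out = self.main.parameters()
        if self.skip is not None:
            out += self.skip.parameters()
        return out

    def named_parameters(self, prefix=""):
        out = self.main.named_parameters(prefix + "main.")
        if self.skip is not None:
            out += self.skip.named_parameters(prefix + "skip.")
        return out

    def train(self):
        self.training = True
        self.main.train()
        self.relu.train()
        if self.skip is not None:
            self.skip.train()

    def eval(self):
        self.training = False
        self.main.eval()
        self.relu.eval()
        if self.skip is not None:
            self.skip.eval()


class TapBackbone(nn.Module):
    """Five-stage convolutional trunk that records per-stage activations."""

    def __init__(self, stages: list[nn.Module], feature_dim: int):
        super().__init__()
        self.stages = stages
        self.feature_dim = feature_dim
        self.pool = nn.GlobalAvgPool()
        self.taps: list[np.ndarray] | None = None

    def forward(self, x, want_taps: bool = False):
        taps = []
        for stage in self.stages:
            x = stage.forward(x)
            taps.append(x)
        self.taps = taps if want_taps else None
        return self.pool.forward(x)

    def backward(self, grad_feat, tap_grads: list[np.ndarray] | None = None):
        grad = self.pool.backward(grad_feat)
        for i in range(len(self.stages) - 1, -1, -1):
            if tap_grads is not None and tap_grads[i] is not None:
                grad = grad + tap_grads[i].astype(grad.dtype)
            grad = self.stages[i].backward(grad)
        return grad

    def parameters(self):
        out = []
        for s in self.stages:
            out.extend(s.parameters())
        return out

    def named_parameters(self, prefix=""):
        out = []
        for i, s in enumerate(self.stages):
            out.extend(s.named_parameters(f"{prefix}stage{i + 1}."))
        return out

    def train(self):
        self.training = True
        for s in self.stages:
            s.train()

    def eval(self):
        self.training = False
        for s in self.stages:
            s.eval()


def _mini_backbone(cfg: BackboneConfig, rng) -> TapBackbone:
    w = cfg.widths
    stages = [nn.Sequential(nn.Conv2d(3, w[0], k=3, stride=1, rng=rng), nn.ReLU())]
    for c_in, c_out in zip(w[:-1], w[1:]):
        stages.append(nn.Sequential(
            nn.Conv2d(c_in, c_out, k=3, stride=2, rng=rng), nn.ReLU()))
    return TapBackbone(stages, feature_dim=w[-1])


def _resnet50_backbone(cfg: BackboneConfig, rng) -> TapBackbone:
    def stage(c_in, c_mid, c_out, blocks, stride, prepend=()):
        mods = list(prepend)
        mods.append(Bottleneck(c_in, c_mid, c_out, stride, rng))
        for _ in range(blocks - 1):
            mods.append(Bottleneck(c_out, c_mid, c_out, 1, rng))
        return nn.Sequential(*mods)

    stem = nn.Sequential(nn.Conv2d(3, 64, k=7, stride=2, pad=3, rng=rng, bias=False),
                         nn.BatchNorm2d(64), nn.ReLU())
    stages = [
        stem,
        stage(64, 64, 256, 3, 1, prepend=(nn.MaxPool2d(k=3, stride=2, pad=1),)),
        stage(256, 128, 512, 4, 2),
        stage(512, 256, 1024, 6, 2),
        stage(1024, 512, 2048, 3, 2),
    ]
    return TapBackbone(stages, feature_dim=2048)


def _make_backbone(cfg: BackboneConfig, rng) -> TapBackbone:
    return _mini_backbone(cfg, rng) if cfg.preset == "mini" else _resnet50_backbone(cfg, rng)


class StudentModel(nn.Module):
    """Single-frame classifier: backbone + GAP + dropout + linear head."""

    def __init__(self, config: BackboneConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(11,)))
        self.backbone = _make_backbone(config, rng)
        self.dropout = nn.Dropout(config.dropout)
        self.head = nn.Linear(self.backbone.feature_dim, config.n_stages_out, rng=rng)

    # -- plumbing -----------------------------------------------------------
    def parameters(self):
        return self.backbone.parameters() + self.dropout.parameters() + self.head.parameters()

    def named_parameters(self, prefix=""):
        return (self.backbone.named_parameters(prefix + "backbone.")
                + self.head.named_parameters(prefix + "head."))

    def train(self):
        self.training = True
        self.backbone.train()
        self.dropout.train()
        self.head.train()

    def eval(self):
        self.training = False
        self.backbone.eval()
        self.dropout.eval()
        self.head.eval()

    def set_dropout_rng(self, rng: np.random.Generator):
        self.dropout.rng = rng

    # -- compute ------------------------------------------------------------
    def forward(self, images: np.ndarray, want_taps: bool = False) -> np.ndarray:
        """(B, H, W, 3) images -> (B, n_stages) logits."""
        feat = self.backbone.forward(images, want_taps=want_taps)
        return self.head.forward(self.dropout.forward(feat))

    def backward(self, dlogits: np.ndarray, tap_grads=None):
        g = self.dropout.backward(self.head.backward(dlogits))
        return self.backbone.backward(g, tap_grads=tap_grads)

    def tap_activations(self) -> list[np.ndarray]:
        """Per-stage activations (each (B, H, W, C)) from the last forward."""
        if self.backbone.taps is None:
            raise RuntimeError("forward(..., want_taps=True) required first")
        return self.backbone.taps

    def attention_maps(self, sample: int = 0) -> list[AttentionMap]:
        """Five attention maps for one sample of the last tapped forward."""
        return [attention_from_activation(act[sample].transpose(2, 0, 1),
                                          layer_index=i + 1)
                for i, act in enumerate(self.tap_activations())]

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Eval-mode 1-based stage predictions for a batch of frames."""
        was_training = self.training
        self.eval()
        logits = self.forward(images)
        if was_training:
            self.train()
        return logits.argmax(axis=1) + 1


class TeacherModel(nn.Module):
    """Series classifier: per-frame backbone + LSTM + per-step linear head."""

    def __init__(self, config: BackboneConfig, hidden_size: int = 128, seed: int = 0):
        super().__init__()
        if hidden_size < 1:
            raise ValueError(f"hidden size must be >= 1, got {hidden_size}")
        self.config = config
        self.hidden_size = hidden_size
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(22,)))
        self.backbone = _make_backbone(config, rng)
        self.lstm = nn.LSTM(self.backbone.feature_dim, hidden_size, rng=rng)
        self.dropout = nn.Dropout(config.dropout)
        self.head = nn.Linear(hidden_size, config.n_stages_out, rng=rng)
        self._shape = None

    def parameters(self):
        return (self.backbone.parameters() + self.lstm.parameters()
                + self.head.parameters())

    def named_parameters(self, prefix=""):
        return (self.backbone.named_parameters(prefix + "backbone.")
                + self.lstm.named_parameters(prefix + "lstm.")
                + self.head.named_parameters(prefix + "head."))

    def train(self):
        self.training = True
        for m in (self.backbone, self.lstm, self.dropout, self.head):
            m.train()

    def eval(self):
        self.training = False
        for m in (self.backbone, self.lstm, self.dropout, self.head):
            m.eval()

    def set_dropout_rng(self, rng: np.random.Generator):
        self.dropout.rng = rng

    def forward(self, series: np.ndarray, want_taps: bool = False) -> np.ndarray:
        """(B, L, H, W, 3) ordered series -> (B, L, n_stages) causal logits.

        logits[:, t] is the prediction for the state at frame t given frames
        1..t; logits[:, -1] is the whole-series (final-frame) prediction.
        """
        series = np.asarray(series)
        if series.ndim != 5 or series.shape[1] < 1:
            raise ValueError(f"expected (B, L>=1, H, W, 3) series, got {series.shape}")
        b, L = series.shape[:2]
        frames = series.reshape(b * L, *series.shape[2:])
        feat = self.backbone.forward(frames, want_taps=want_taps)
        hs = self.lstm.forward(feat.reshape(b, L, -1))
        out = self.head.forward(self.dropout.forward(hs.reshape(b * L, -1)))
        self._shape = (b, L)
        return out.reshape(b, L, -1)

    def backward(self, dlogits: np.ndarray):
        b, L = self._shape
        g = self.dropout.backward(self.head.backward(dlogits.reshape(b * L, -1)))
        g = self.lstm.backward(g.reshape(b, L, -1))
        return self.backbone.backward(g.reshape(b * L, -1))

    def attention_maps(self, sample: int = 0, frame: int = -1) -> list[AttentionMap]:
        """Attention maps for one frame of one series of the last forward."""
        if self.backbone.taps is None:
            raise RuntimeError("forward(..., want_taps=True) required first")
        b, L = self._shape
        idx = sample * L + (frame % L)
        return [attention_from_activation(act[idx].transpose(2, 0, 1),
                                          layer_index=i + 1)
                for i, act in enumerate(self.backbone.taps)]

    def predict(self, series: np.ndarray, per_frame: bool = False) -> np.ndarray:
        """Eval-mode 1-based stage predictions (final frame, or every t)."""
        was_training = self.training
        self.eval()
        logits = self.forward(series)
        if was_training:
            self.train()
        preds = logits.argmax(axis=2) + 1
        return preds if per_frame else preds[:, -1]


def build_student(config: BackboneConfig | None = None, seed: int = 0) -> StudentModel:
    """Construct a student classifier; identical seeds give identical weights.

    The model is returned in eval mode; training loops switch it to train
    mode and attach a dropout rng.
    """
    model = StudentModel(config or BackboneConfig(), seed=seed)
    model.eval()
    return model


def build_teacher(config: BackboneConfig | None = None, hidden_size: int | None = None,
                  seed: int = 0) -> TeacherModel:
    """Construct a teacher (backbone + recurrent head over frame series)."""
    config = config or BackboneConfig()
    if hidden_size is None:
        hidden_size = 128 if config.preset == "mini" else 512
    model = TeacherModel(config, hidden_size=hidden_size, seed=seed)
    model.eval()
    return model


def complexity_report(model: nn.Module) -> dict:
    """Parameter counts per submodule (architecture plumbing, no timings)."""
    report: dict[str, int] = {}
    for name, p in model.named_parameters():
        top = name.split(".")[0]
        report[top] = report.get(top, 0) + int(p.value.size)
    report["total"] = int(sum(report.values()))
    return report


def save_checkpoint(model: nn.Module, path) -> None:
    """Versioned .npz checkpoint: config header + all named parameters."""
    header = {"version": CHECKPOINT_VERSION,
              "kind": type(model).__name__,
              "config": model.config.to_dict()}
    if isinstance(model, TeacherModel):
        header["hidden_size"] = model.hidden_size
    arrays = {f"param:{name}": p.value for name, p in model.named_parameters()}
    np.savez(path, __header__=json.dumps(header), **arrays)


def load_checkpoint(path):
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["__header__"]))
        if header.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header.get('version')}")
        cfg_d = header["config"]
        cfg = BackboneConfig(preset=cfg_d["preset"], n_stages_out=cfg_d["n_stages_out"],
                             dropout=cfg_d["dropout"], input_size=cfg_d["input_size"],
                             widths=tuple(cfg_d["widths"]))
        if header["kind"] == "TeacherModel":
            model = TeacherModel(cfg, hidden_size=header["hidden_size"])
        elif header["kind"] == "StudentModel":
            model = StudentModel(cfg)
        else:
            raise ValueError(f"unknown checkpoint kind {header['kind']!r}")
        for name, p in model.named_parameters():
            p.value[...] = data[f"param:{name}"]
    model.eval()
    return model


def get_state(model: nn.Module) -> dict[str, np.ndarray]:
    """Copy of all parameter arrays, keyed by name."""
    return {name: p.value.copy() for name, p in model.named_parameters()}


def set_state(model: nn.Module, state: dict[str, np.ndarray]) -> None:
    for name, p in model.named_parameters():
        p.value[...] = state[name]
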