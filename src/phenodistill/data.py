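"""Dataset handling: manifests, series assembly, splits and augmentation.

A dataset is a directory of RGB frames plus a CSV manifest with header
``series_id,frame_index,stage,path`` assigning every frame to a temporally
ordered series and an ordinal stage label in 1..8.  Frames are grouped into
:class:`SeriesSample` units of a fixed length (default 30), and all dataset
splitting happens **at the series level** — no series ever contributes frames
to two splits, which would leak near-duplicate images across them.

Training augmentation (brightness scaling, horizontal flip, small rotation)
expands the training set by an integer factor, default 3 (originals plus two
augmented copies).  An augmentation is drawn once per copied series and
applied identically to every frame, so the augmented series remains a
temporally coherent sequence.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .metrics import N_STAGES
from .synthetic import MANIFEST_COLUMNS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrameRecord:
    """One manifest row: a single labelled frame of one series."""

    series_id: str
    frame_index: int
    stage: int
    path: str


@dataclass
class Transform:
    """A per-series augmentation, applied identically to every frame."""

    brightness: float = 1.0  # multiplicative factor
    flip: bool = False       # horizontal mirror
    rotation: float = 0.0    # degrees, counter-clockwise


@dataclass
class SeriesSample:
    """One temporally ordered frame sequence; the split and teacher unit.

    ``label`` is the stage of the final frame (the state the series has
    reached), or the majority stage if assembled with ``label_policy=
    'majority'``.  Augmented copies keep ``source_id`` pointing at the
    original series and carry a non-trivial :class:`Transform`.
    """

    series_id: str
    frames: list[FrameRecord]
    label: int
    transform: Transform | None = None
    source_id: str | None = None

    @property
    def L(self) -> int:
        return len(self.frames)

    @property
    def is_augmented(self) -> bool:
        return self.source_id is not None and self.source_id != self.series_id

    def stages(self) -> np.ndarray:
        return np.array([f.stage for f in self.frames], dtype=int)


@dataclass
class SplitSpec:
    """Series-level split ratios (train, val, test) plus the shuffle seed."""

    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self):
        r = tuple(float(x) for x in self.ratios)
        if len(r) != 3 or any(x < 0 for x in r):
            raise ValueError(f"ratios must be three non-negative reals, got {self.ratios}")
        if abs(sum(r) - 1.0) > 1e-9:
            raise ValueError(f"ratios must sum to 1, got {sum(r)}")
        self.ratios = r


KNOWN_AUG_OPS = ("brightness", "flip", "rotation")


@dataclass
class AugmentationPolicy:
    """Which augmentations to draw and how far to expand the training set."""

    ops: tuple[str, ...] = KNOWN_AUG_OPS
    expansion_factor: int = 3
    brightness_range: float = 0.2   # factor drawn from [1-r, 1+r]
    rotation_range: float = 15.0    # degrees, drawn from [-r, r]
    seed: int = 0

    def __post_init__(self):
        unknown = [op for op in self.ops if op not in KNOWN_AUG_OPS]
        if unknown:
            raise ValueError(f"unknown augmentation op(s) {unknown}; "
                             f"known: {list(KNOWN_AUG_OPS)}")
        if self.expansion_factor < 1:
            raise ValueError(f"expansion_factor must be >= 1, got {self.expansion_factor}")


# ---------------------------------------------------------------------------
# manifest I/O
# ---------------------------------------------------------------------------

def read_manifest(path, n_stages: int = N_STAGES) -> list[FrameRecord]:
    """Parse and validate a manifest CSV into FrameRecords.

    Errors name the offending data row (1-based, excluding the header):
    missing columns, non-integer or out-of-range stages, negative frame
    indices and duplicate (series_id, frame_index) keys are all rejected.
    """
    df = pd.read_csv(path, dtype={"series_id": str, "path": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path!r} is missing column(s) {missing}")
    records: list[FrameRecord] = []
    seen: set[tuple[str, int]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            stage = int(row.stage)
            frame_index = int(row.frame_index)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"manifest row {i}: non-integer stage/frame_index") from exc
        if not 1 <= stage <= n_stages:
            raise ValueError(f"manifest row {i}: stage {stage} outside 1..{n_stages}")
        if frame_index < 0:
            raise ValueError(f"manifest row {i}: negative frame_index {frame_index}")
        key = (row.series_id, frame_index)
        if key in seen:
            raise ValueError(f"manifest row {i}: duplicate (series_id, frame_index) {key}")
        seen.add(key)
        records.append(FrameRecord(series_id=str(row.series_id),
                                   frame_index=frame_index, stage=stage,
                                   path=str(row.path)))
    return records


def assemble_series(records: list[FrameRecord], L: int,
                    length_policy: str = "reject",
                    label_policy: str = "final") -> list[SeriesSample]:
    """Group frames by series_id into length-L ordered SeriesSamples.

    ``length_policy='reject'`` drops series whose frame count differs from L
    (with a logged warning); ``'pad'`` front-pads short series by repeating
    their earliest frame (over-long series are still rejected).  ``label_
    policy`` selects the series label: the final frame's stage (default) or
    the majority stage.
    """
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    if length_policy not in ("reject", "pad"):
        raise ValueError(f"unknown length_policy {length_policy!r}")
    if label_policy not in ("final", "majority"):
        raise ValueError(f"unknown label_policy {label_policy!r}")

    by_series: dict[str, list[FrameRecord]] = {}
    for rec in records:
        by_series.setdefault(rec.series_id, []).append(rec)

    samples: list[SeriesSample] = []
    for sid in sorted(by_series):
        frames = sorted(by_series[sid], key=lambda r: r.frame_index)
        if len(frames) > L or (len(frames) < L and length_policy == "reject"):
            logger.warning("series %s has %d frames (expected %d); excluded",
                           sid, len(frames), L)
            continue
        if len(frames) < L:  # pad policy: repeat the earliest frame in front
            frames = [frames[0]] * (L - len(frames)) + frames
        stages = np.array([f.stage for f in frames])
        if label_policy == "final":
            label = int(stages[-1])
        else:
            label = int(np.bincount(stages).argmax())
        samples.append(SeriesSample(series_id=sid, frames=frames, label=label,
                                    source_id=sid))
    return samples


# ---------------------------------------------------------------------------
# series-level split
# ---------------------------------------------------------------------------

def split_series(samples: list[SeriesSample], spec: SplitSpec
                 ) -> tuple[list[SeriesSample], list[SeriesSample], list[SeriesSample]]:
    """Partition whole series into train/val/test, stratified by label.

    Global sizes are round(n * ratio) for val and test with the remainder to
    train.  Within each label group, series are shuffled deterministically
    (spec.seed) and allocated proportionally (largest-remainder), so every
    stage appears in every split whenever its count permits.  No series_id
    ever straddles two splits.
    """
    n = len(samples)
    r_train, r_val, r_test = spec.ratios
    if n < 3 and min(spec.ratios) > 0:
        raise ValueError(f"need at least 3 series to fill three splits, got {n}")

    n_val = int(round(n * r_val))
    n_test = int(round(n * r_test))

    rng = np.random.default_rng(spec.seed)
    groups: dict[int, list[SeriesSample]] = {}
    for s in sorted(samples, key=lambda s: s.series_id):
        groups.setdefault(s.label, []).append(s)
    labels = sorted(groups)
    for lab in labels:
        idx = rng.permutation(len(groups[lab]))
        groups[lab] = [groups[lab][i] for i in idx]

    def allocate(target: int, ratio: float, taken: dict[int, int]) -> dict[int, int]:
        base = {lab: int(np.floor(len(groups[lab]) * ratio)) for lab in labels}
        rem = {lab: len(groups[lab]) * ratio - base[lab] for lab in labels}
        short = target - sum(base.values())
        order = sorted(labels, key=lambda lab: (-rem[lab], lab))
        k = 0
        while short > 0 and k < 10 * len(labels):
            lab = order[k % len(labels)]
            if base[lab] + taken.get(lab, 0) + 1 <= len(groups[lab]):
                base[lab] += 1
                short -= 1
            k += 1
        while short < 0:  # floor overshoot cannot happen, but keep totals exact
            lab = order[-1]
            if base[lab] > 0:
                base[lab] -= 1
                short += 1
        return base

    val_alloc = allocate(n_val, r_val, {})
    test_alloc = allocate(n_test, r_test, val_alloc)

    train, val, test = [], [], []
    for lab in labels:
        g = groups[lab]
        nv, nt = val_alloc[lab], test_alloc[lab]
        val.extend(g[:nv])
        test.extend(g[nv:nv + nt])
        train.extend(g[nv + nt:])
    return train, val, test


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _draw_transform(policy: AugmentationPolicy, rng: np.random.Generator) -> Transform:
    t = Transform()
    if "brightness" in policy.ops:
        t.brightness = float(1.0 + rng.uniform(-policy.brightness_range,
                                               policy.brightness_range))
    if "flip" in policy.ops:
        t.flip = bool(rng.random() < 0.5)
    if "rotation" in policy.ops:
        t.rotation = float(rng.uniform(-policy.rotation_range, policy.rotation_range))
    return t


def augment_training_set(train: list[SeriesSample],
                         policy: AugmentationPolicy) -> list[SeriesSample]:
    """Expand the training set to expansion_factor x its size.

    Returns the originals plus (factor - 1) augmented copies per original.
    Each copy carries one Transform applied to all its frames, preserves its
    source's label and frame count, and gets a derived series_id
    (``<id>~aug<k>``) so split purity checks still see one family per split.
    """
    out = list(train)
    rng = np.random.default_rng(policy.seed)
    for k in range(1, policy.expansion_factor):
        for s in train:
            out.append(SeriesSample(
                series_id=f"{s.series_id}~aug{k}",
                frames=s.frames,
                label=s.label,
                transform=_draw_transform(policy, rng),
                source_id=s.series_id,
            ))
    return out


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

def dataset_summary(train: list[SeriesSample], val: list[SeriesSample],
                    test: list[SeriesSample], n_stages: int = N_STAGES) -> pd.DataFrame:
    """Per-stage sample accounting in the style of a dataset table.

    ``train`` may be the augmented training set; originals and augmented
    copies are told apart via ``is_augmented``, giving both the before- and
    after-augmentation columns.  The overall column counts the after-
    augmentation train plus val plus test, and an ALL row sums each column.
    """
    from .metrics import STAGE_NAMES

    def counts(samples):
        c = np.zeros(n_stages, dtype=int)
        for s in samples:
            c[s.label - 1] += 1
        return c

    before = counts([s for s in train if not s.is_augmented])
    after = counts(train)
    v = counts(val)
    t = counts(test)
    overall = after + v + t
    names = list(STAGE_NAMES[:n_stages]) + ["ALL"]
    data = {
        "train_before_aug": np.append(before, before.sum()),
        "train_after_aug": np.append(after, after.sum()),
        "val": np.append(v, v.sum()),
        "test": np.append(t, t.sum()),
        "overall": np.append(overall, overall.sum()),
    }
    return pd.DataFrame(data, index=pd.Index(names, name="stage"))


# ---------------------------------------------------------------------------
# frame loading
# ---------------------------------------------------------------------------

def apply_transform(img: np.ndarray, t: Transform | None) -> np.ndarray:
    """Apply a series transform to one (H, W, 3) float image in [0, 1].

    Order: rotation (bilinear, edges extended), then horizontal flip, then
    brightness scaling; output re-clipped to [0, 1].
    """
    if t is None:
        return img
    out = img
    if t.rotation != 0.0:
        out = ndimage.rotate(out, t.rotation, axes=(1, 0), reshape=False,
                             order=1, mode="nearest")
    if t.flip:
        out = out[:, ::-1, :]
    if t.brightness != 1.0:
        out = out * t.brightness
    return np.clip(out, 0.0, 1.0)


def load_frame(record: FrameRecord, root, transform: Transform | None = None
               ) -> np.ndarray:
    """Load one frame as a (H, W, 3) float32 array in [0, 1]."""
    path = os.path.join(os.fspath(root), record.path)
    img = np.asarray(iio.imread(path), dtype=np.float32) / 255.0
    return np.ascontiguousarray(apply_transform(img, transform), dtype=np.float32)


class SeriesCache:
    """Loads and memoises series arrays (augmentations included).

    Keeps every decoded series as one (L, 3, H, W) float32 array keyed by
    series_id; at desk scale (tens of 30-frame series at 32 px) this is a few
    tens of MB.
    """

    def __init__(self, root):
        self.root = os.fspath(root)
        self._cache: dict[str, np.ndarray] = {}

    def series_array(self, sample: SeriesSample) -> np.ndarray:
        hit = self._cache.get(sample.series_id)
        if hit is None:
            hit = np.stack([load_frame(f, self.root, sample.transform)
                            for f in sample.frames])
            self._cache[sample.series_id] = hit
        return hit

    def frame_array(self, sample: SeriesSample, t: int) -> np.ndarray:
        return self.series_array(sample)[t]
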