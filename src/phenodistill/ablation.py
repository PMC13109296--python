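"""Ablation harnesses: loss-component ablation and the layer-subset sweep.

Two experiments quantify where the student's accuracy comes from:

* the **component ablation** trains students with hard labels only, with
  knowledge distillation, and with distillation plus attention transfer,
  under identical data, teacher and initial weights;
* the **layer sweep** trains one KD+AT student per subset of the five
  backbone tap layers (all 31 non-empty subsets by default, groupable by
  subset size), to map how much each depth's attention contributes.

Within a seed, every run shares the dataset, splits, frozen teacher and
initial student parameters; only the loss configuration differs, so result
differences are attributable to the ablated component.  Which layer subset
wins is data-dependent; the harness reports, it does not assert.
"""

from __future__ import annotations

import itertools
import os
import tempfile
from dataclasses import dataclass, field, replace

import pandas as pd

from .benchmark import BenchmarkConfig, prepare_benchmark_data
from .training import (TeacherSupervision, TrainConfig, evaluate_student,
                       evaluate_teacher, train_student, train_teacher)

ALL_LAYERS = (1, 2, 3, 4, 5)


def all_nonempty_subsets(layers: tuple[int, ...] = ALL_LAYERS) -> list[tuple[int, ...]]:
    """The 2^n - 1 non-empty layer subsets, ordered by size then lexically."""
    subsets = []
    for r in range(1, len(layers) + 1):
        subsets.extend(itertools.combinations(layers, r))
    return subsets


QUICK_SUBSETS: tuple[tuple[int, ...], ...] = (
    (1,), (2,), (3,), (4,), (5,), (1, 3, 4), (2, 5))


@dataclass
class AblationGrid:
    """Which configurations to run: layer subsets, modes and seeds."""

    layer_subsets: list[tuple[int, ...]] = field(default_factory=all_nonempty_subsets)
    modes: tuple[str, ...] = ("baseline", "kd", "kd_at")
    seeds: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self):
        cleaned = []
        seen = set()
        for s in self.layer_subsets:
            t = tuple(sorted(set(int(x) for x in s)))
            if not t:
                raise ValueError("empty layer subset in grid")
            if t in seen:
                raise ValueError(f"duplicate layer subset {t} in grid")
            seen.add(t)
            cleaned.append(t)
        self.layer_subsets = cleaned


RESULT_COLUMNS = ("mode", "layers", "OA", "MAE", "F1", "Kappa", "seed")


def _layers_str(layers: tuple[int, ...] | None) -> str:
    return "" if not layers else "+".join(str(l) for l in layers)


def _result_row(mode: str, layers, report: dict, seed: int) -> dict:
    return {"mode": mode, "layers": _layers_str(layers), "OA": report["oa"],
            "MAE": report["mae"], "F1": report["macro_f1"],
            "Kappa": report["kappa"], "seed": seed}


def _seed_context(config: BenchmarkConfig, seed: int, workdir):
    """Shared per-seed context: data, frozen teacher, supervision cache."""
    train, val, test, cache = prepare_benchmark_data(config, workdir, seed)
    t_cfg = TrainConfig(batch_size=config.batch_size, lr=config.teacher_lr,
                        epochs=config.teacher_epochs, seed=seed, loss=config.loss,
                        student_sample_policy=config.student_sample_policy)
    teacher, _ = train_teacher(train, val, cache, t_cfg, model_config=config.model)
    supervision = TeacherSupervision(teacher, cache, config.loss)
    s_cfg = replace(t_cfg, epochs=config.student_epochs, lr=config.student_lr)
    return dict(train=train, val=val, test=test, cache=cache, teacher=teacher,
                supervision=supervision, s_cfg=s_cfg,
                teacher_val=evaluate_teacher(teacher, val, cache).to_dict())


def _run_student(ctx, config: BenchmarkConfig, mode: str,
                 layers: tuple[int, ...] | None, seed: int) -> dict:
    loss = config.loss if layers is None else replace(config.loss,
                                                      transfer_layers=layers)
    cfg = replace(ctx["s_cfg"], loss=loss)
    needs_teacher = mode != "baseline"
    student, _ = train_student(
        ctx["train"], ctx["val"], ctx["teacher"] if needs_teacher else None, cfg,
        mode=mode, model_config=config.model,
        supervision=ctx["supervision"] if needs_teacher else None,
        cache=ctx["cache"])
    return evaluate_student(student, ctx["val"], ctx["cache"]).to_dict()


def run_component_ablation(config: BenchmarkConfig | None = None,
                           grid: AblationGrid | None = None,
                           workdir=None) -> pd.DataFrame:
    """Baseline / KD / KD+AT students under shared conditions, per seed.

    Returns one row per (mode, seed) with validation OA, MAE, macro F1 and
    kappa, in the shape of a component-ablation summary table.
    """
    config = config or BenchmarkConfig()
    grid = grid or AblationGrid()
    if workdir is None:
        with tempfile.TemporaryDirectory() as tmp:
            return run_component_ablation(config, grid, workdir=tmp)
    rows = []
    for seed in grid.seeds:
        wd = os.path.join(os.fspath(workdir), f"seed{seed}")
        os.makedirs(wd, exist_ok=True)
        ctx = _seed_context(config, seed, wd)
        for mode in grid.modes:
            layers = config.loss.transfer_layers if mode == "kd_at" else None
            report = _run_student(ctx, config, mode, layers, seed)
            rows.append(_result_row(mode, layers, report, seed))
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def run_layer_sweep(config: BenchmarkConfig | None = None,
                    grid: AblationGrid | None = None,
                    workdir=None) -> pd.DataFrame:
    """One KD+AT student per layer subset per seed.

    The returned frame carries a ``panel`` column grouping subsets by
    cardinality (1; 2; 3; 4–5) and a ``best`` flag on the subset with the
    highest median validation OA.
    """
    config = config or BenchmarkConfig()
    grid = grid or AblationGrid()
    if workdir is None:
        with tempfile.TemporaryDirectory() as tmp:
            return run_layer_sweep(config, grid, workdir=tmp)
    rows = []
    for seed in grid.seeds:
        wd = os.path.join(os.fspath(workdir), f"seed{seed}")
        os.makedirs(wd, exist_ok=True)
        ctx = _seed_context(config, seed, wd)
        for subset in grid.layer_subsets:
            report = _run_student(ctx, config, "kd_at", subset, seed)
            rows.append(_result_row("kd_at", subset, report, seed))
    df = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    df["panel"] = [subset_panel(s) for s in df["layers"]]
    med = df.groupby("layers")["OA"].median()
    df["best"] = df["layers"] == med.idxmax()
    return df


def subset_panel(layers_str: str) -> str:
    """Panel grouping by subset size: '1', '2', '3' or '4-5'."""
    size = len(layers_str.split("+"))
    return "4-5" if size >= 4 else str(size)


def summarize_component_ablation(results: pd.DataFrame) -> pd.DataFrame:
    """Median-over-seeds table, one row per mode (component-ablation layout)."""
    agg = results.groupby("mode")[["OA", "MAE", "F1", "Kappa"]].median()
    order = [m for m in ("baseline", "kd", "kd_at") if m in agg.index]
    table = agg.loc[order].reset_index()
    table.insert(1, "knowledge_distillation",
                 ["" if m == "baseline" else "yes" for m in table["mode"]])
    table.insert(2, "attention_transfer",
                 ["yes" if m == "kd_at" else "" for m in table["mode"]])
    return table
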