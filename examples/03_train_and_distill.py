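"""Train a temporal teacher, distill it into a single-frame student.

A small end-to-end run (smaller than the package's benchmark defaults, a
couple of minutes on one CPU): generate data, split at the series level,
augment the training series 3x, train the teacher, then train one student
with hard labels only and one with knowledge distillation + attention
transfer, and compare their validation accuracy.
"""

import tempfile
from dataclasses import replace

from phenodistill.benchmark import BenchmarkConfig, prepare_benchmark_data
from phenodistill.models import BackboneConfig
from phenodistill.synthetic import SynthConfig
from phenodistill.training import (TeacherSupervision, TrainConfig,
                                   evaluate_teacher, evaluate_student,
                                   train_student, train_teacher)

config = BenchmarkConfig(synth=SynthConfig(n_series=40), teacher_epochs=30,
                         student_epochs=8)

with tempfile.TemporaryDirectory() as workdir:
    train, val, test, cache = prepare_benchmark_data(config, workdir, seed=1)
    print(f"series: {len(train)} train (3x augmented) / {len(val)} val")

    t_cfg = TrainConfig(lr=config.teacher_lr, epochs=config.teacher_epochs,
                        seed=1, student_sample_policy="all_frames")
    teacher, t_log = train_teacher(train, val, cache, t_cfg)
    print(f"teacher validation OA {t_log.best_val_oa:.3f} "
          f"(best epoch {t_log.best_epoch})")

    supervision = TeacherSupervision(teacher, cache, config.loss)
    s_cfg = replace(t_cfg, lr=config.student_lr, epochs=config.student_epochs)
    for mode in ("baseline", "kd_at"):
        student, s_log = train_student(
            train, val, teacher if mode != "baseline" else None, s_cfg,
            mode=mode, supervision=supervision if mode != "baseline" else None,
            cache=cache)
        print(f"{mode:8s} student validation OA {s_log.best_val_oa:.3f}")
# The teacher, which integrates the whole frame history, sits above both
# single-frame students; the distilled student should recover part of the gap.
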