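"""phenodistill: distill a multi-temporal crop-phenology classifier into a
single-image one.

A temporal teacher (convolutional backbone + LSTM over an ordered image
series) is trained to stage crop development; a lightweight student that sees
only one frame is then trained against the teacher's temperature-softened
class distributions (knowledge distillation) and its per-layer spatial
attention maps (multi-layer attention transfer), alongside the ground-truth
labels.  The package ships a synthetic ordinal-stage image generator, the
networks and losses, training/ablation harnesses, the ordinal metric suite
and attention visualisation — all pure numpy/scipy, CPU-sized.
"""

from .attention import AttentionMap, attention_from_activation
from .losses import (LossBreakdown, LossConfig, attention_loss, combined_loss,
                     distillation_loss, softened_probabilities)
from .metrics import (MetricReport, confusion, evaluate, f1_scores, kappa,
                      ordinal_mae, overall_accuracy)
from .models import (BackboneConfig, StudentModel, TeacherModel, build_student,
                     build_teacher, complexity_report, load_checkpoint,
                     save_checkpoint)
from .synthetic import (GrowthTrajectory, SynthConfig, generate_dataset,
                        generate_trajectory, render_frame, stage_of)
from .training import (TrainConfig, TrainLog, TeacherSupervision,
                       teacher_supervision, train_student, train_teacher)

__version__ = "0.1.0"

__all__ = [
    "AttentionMap", "attention_from_activation",
    "LossBreakdown", "LossConfig", "attention_loss", "combined_loss",
    "distillation_loss", "softened_probabilities",
    "MetricReport", "confusion", "evaluate", "f1_scores", "kappa",
    "ordinal_mae", "overall_accuracy",
    "BackboneConfig", "StudentModel", "TeacherModel", "build_student",
    "build_teacher", "complexity_report", "load_checkpoint", "save_checkpoint",
    "GrowthTrajectory", "SynthConfig", "generate_dataset",
    "generate_trajectory", "render_frame", "stage_of",
    "TrainConfig", "TrainLog", "TeacherSupervision", "teacher_supervision",
    "train_student", "train_teacher",
]
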