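"""The distillation objective on a worked numeric example.

Shows how the temperature flattens the softmax, how the combined loss mixes
its three terms (soft cross-entropy to the teacher, hard cross-entropy to the
label, attention-map distance), and what each term contributes.
"""

import numpy as np

from phenodistill.attention import attention_from_activation
from phenodistill.losses import (LossConfig, combined_loss, one_hot,
                                 softened_probabilities)

teacher_logits = np.array([0.2, 1.5, 4.0, 2.5, 0.0, -1.0, -1.0, -2.0])
student_logits = np.array([0.0, 1.0, 3.0, 3.0, 0.5, -1.0, -0.5, -2.0])
label = one_hot(3)  # true stage: jointing

print("teacher probabilities at T=1:",
      np.round(softened_probabilities(teacher_logits, 1.0), 3))
print("teacher probabilities at T=3:",
      np.round(softened_probabilities(teacher_logits, 3.0), 3))
# T=3 keeps the argmax but reveals that stage 4 (booting) is the runner-up —
# the adjacent-stage similarity the student is meant to inherit.

rng = np.random.default_rng(0)
student_maps = [attention_from_activation(rng.random((8, 4, 4)), i + 1)
                for i in range(5)]
teacher_maps = [attention_from_activation(rng.random((8, 4, 4)), i + 1)
                for i in range(5)]

cfg = LossConfig()  # T=3, alpha=0.7, beta=0.001, transfer layers {1,3,4}
bd = combined_loss(teacher_logits, student_logits, label,
                   student_maps, teacher_maps, cfg)
print(f"L_soft={bd.soft:.4f}  L_hard={bd.hard:.4f}  "
      f"L_attention={bd.attention:.4f}  total={bd.total:.4f}")
print("total == 0.7*soft + 0.3*hard + 0.001*attention:",
      np.isclose(bd.total, 0.7 * bd.soft + 0.3 * bd.hard + 0.001 * bd.attention))
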