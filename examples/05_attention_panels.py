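"""Visualise where the networks look: per-layer attention panels.

Renders the five channel-collapsed attention maps of a (here untrained, for
speed) student beside its input frame; after training, shallow layers pick
out stroke edges and deeper layers the spike clusters.  Run the distillation
example first and pass a trained checkpoint for meaningful maps.
"""

import tempfile

import numpy as np

from phenodistill.models import BackboneConfig, build_student
from phenodistill.synthetic import SynthConfig, render_frame, series_rng
from phenodistill.visualization import attention_panel, render_attention_panel

config = SynthConfig(seed=3)
frame = render_frame(0.8, config, series_rng(3, 0)).astype(np.float32)

student = build_student(BackboneConfig(), seed=0)
panel, maps = attention_panel(student, frame)
print(f"panel array: {panel.shape} (input + 5 layer heatmaps)")
for i, m in enumerate(maps, start=1):
    print(f"layer {i}: map min {m.min():.2f} max {m.max():.2f}")

with tempfile.TemporaryDirectory() as tmp:
    path = render_attention_panel(student, frame, f"{tmp}/panel.png")
    print("wrote", path)
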