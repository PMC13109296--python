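"""Activation-based spatial attention maps.

A convolutional activation ``a`` of shape (C, H, W) is collapsed across the
channel dimension into a single 2-D saliency map

    A[h, w] = sum_c a[c, h, w]^2

and then L2-normalised over the flattened map, so that maps from networks of
different widths and activation scales are directly comparable.  This single
definition is used everywhere: as the quantity matched by the attention
transfer loss and as the heatmap that is visualised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class AttentionMap:
    """Per-layer 2-D saliency derived from a backbone activation."""

    layer_index: int  # 1..5, ordered from shallow to deep
    map: np.ndarray  # 2-D, non-negative
    normalized: bool  # True unless the source activation was all-zero

    def __post_init__(self):
        self.map = np.asarray(self.map, dtype=np.float64)
        if self.map.ndim != 2:
            raise ValueError("attention map must be 2-D")
        if np.any(self.map < 0):
            raise ValueError("attention map must be non-negative")


def attention_from_activation(activation: np.ndarray, layer_index: int = 0) -> AttentionMap:
    """Collapse a (C, H, W) activation to an L2-normalised attention map.

    An all-zero activation passes through unchanged with ``normalized=False``
    (there is no direction to normalise onto).
    """
    act = np.asarray(activation, dtype=np.float64)
    if act.ndim != 3:
        raise ValueError(f"expected a 3-D (C, H, W) activation, got shape {act.shape}")
    if not np.all(np.isfinite(act)):
        raise ValueError("activation contains non-finite values")
    raw = np.sum(act * act, axis=0)
    norm = float(np.linalg.norm(raw.ravel()))
    if norm == 0.0:
        return AttentionMap(layer_index=layer_index, map=raw, normalized=False)
    return AttentionMap(layer_index=layer_index, map=raw / norm, normalized=True)
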