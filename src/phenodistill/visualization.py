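"""Attention interpretability panels.

For a trained model and one input (a frame for the student, a series for the
teacher) the five per-layer attention maps — the same channel-collapsed,
L2-normalised maps used by the transfer loss — are upsampled to the input
resolution, min-max scaled per map, colour-mapped and laid out beside the
original frame, shallow layers first.  Panels are composed as raw pixel
arrays and written with a fixed colormap, so repeated calls produce
byte-identical files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from matplotlib import colormaps
from scipy import ndimage

from .models import StudentModel, TeacherModel

COLORMAP = "viridis"  # fixed for byte-stable output
SEPARATOR_PX = 2


def upsample_map(m: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear, parameter-free upsampling of a 2-D map to ``shape``."""
    if m.shape == tuple(shape):
        return m.astype(np.float64)
    zoom = (shape[0] / m.shape[0], shape[1] / m.shape[1])
    out = ndimage.zoom(m.astype(np.float64), zoom, order=1, mode="nearest",
                       grid_mode=True)
    return out[: shape[0], : shape[1]]


def minmax_scale(m: np.ndarray) -> np.ndarray:
    """Scale a map to [0, 1]; a constant map becomes all zeros."""
    lo, hi = float(m.min()), float(m.max())
    if hi - lo <= 0:
        return np.zeros_like(m, dtype=np.float64)
    return (m - lo) / (hi - lo)


def model_attention_maps(model, inputs: np.ndarray, frame: int = -1):
    """(input frame, five AttentionMaps) for a student frame or teacher series."""
    was_training = model.training
    model.eval()
    if isinstance(model, TeacherModel):
        series = np.asarray(inputs, dtype=np.float32)
        if series.ndim != 4:
            raise ValueError(f"teacher input must be (L, H, W, 3), got {series.shape}")
        model.forward(series[None], want_taps=True)
        maps = model.attention_maps(0, frame=frame)
        image = series[frame % series.shape[0]]
    elif isinstance(model, StudentModel):
        image = np.asarray(inputs, dtype=np.float32)
        if image.ndim != 3:
            raise ValueError(f"student input must be (H, W, 3), got {image.shape}")
        model.forward(image[None], want_taps=True)
        maps = model.attention_maps(0)
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    if was_training:
        model.train()
    return image, maps


def attention_panel(model, inputs: np.ndarray, frame: int = -1):
    """(panel RGB array in [0,1], list of upsampled min-max-scaled maps).

    The panel holds the input frame followed by the five per-layer heatmaps
    (layer order 1..5), separated by thin white gutters.
    """
    image, maps = model_attention_maps(model, inputs, frame=frame)
    h, w = image.shape[:2]
    cmap = colormaps[COLORMAP]
    scaled = [minmax_scale(upsample_map(m.map, (h, w))) for m in maps]
    tiles = [np.asarray(image, dtype=np.float64)]
    tiles.extend(np.asarray(cmap(s))[..., :3] for s in scaled)
    sep = np.ones((h, SEPARATOR_PX, 3))
    row = []
    for i, tile in enumerate(tiles):
        if i:
            row.append(sep)
        row.append(tile)
    return np.concatenate(row, axis=1), scaled


def render_attention_panel(model, inputs: np.ndarray, out_path,
                           frame: int = -1) -> str:
    """Write the 6-tile attention panel as a PNG; returns the path."""
    import imageio.v3 as iio

    panel, _ = attention_panel(model, inputs, frame=frame)
    iio.imwrite(out_path, (np.clip(panel, 0, 1) * 255.0 + 0.5).astype(np.uint8))
    return str(out_path)


def dump_attention_csv(model, inputs: np.ndarray, out_path, frame: int = -1) -> str:
    """Raw (pre-scaling) per-layer maps as long-format CSV for analysis."""
    _, maps = model_attention_maps(model, inputs, frame=frame)
    rows = []
    for m in maps:
        hh, ww = m.map.shape
        ys, xs = np.mgrid[0:hh, 0:ww]
        rows.append(pd.DataFrame({"layer": m.layer_index, "y": ys.ravel(),
                                  "x": xs.ravel(), "value": m.map.ravel()}))
    pd.concat(rows, ignore_index=True).to_csv(out_path, index=False)
    return str(out_path)
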