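"""Pixel-wise concentration maps: apply a fitted pretreatment chain, band
selection and calibration model to every foreground pixel of a reflectance
cube and render the result as a pseudo-color image.

The pixel pipeline order is fixed: trim edge bands -> pretreat (with the
parameters fitted on the calibration rows, so pixels receive the exact
same transformation as tabular spectra) -> subset to the selected bands ->
model predict. Background pixels are identified by thresholding the mean
reflectance over a near-infrared window and left undefined (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw
from matplotlib import colormaps

from .hsi_io import SpectralCube, trim_bands
from .preprocessing import Pretreatment

__all__ = ["PredictionMap", "mask_background", "predict_map", "render_pseudocolor"]

#: default foreground window/threshold: leaf material reflects strongly
#: in the 750-950 nm plateau while the background filler does not
DEFAULT_MASK_WINDOW = (750.0, 950.0)
DEFAULT_MASK_THRESHOLD = 0.15


@dataclass
class PredictionMap:
    """Per-pixel TFAA (% dry mass); NaN outside the foreground mask."""

    values: np.ndarray  # (h, w) float, NaN on background
    mask: np.ndarray  # (h, w) bool
    model_label: str
    scale_limits: tuple

    def __post_init__(self):
        if self.values.shape != self.mask.shape:
            raise ValueError("values/mask shape mismatch")
        lo, hi = self.scale_limits
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ValueError("scale limits must be finite and ordered")

    @property
    def foreground_values(self) -> np.ndarray:
        return self.values[self.mask]


def mask_background(
    cube: SpectralCube,
    window_nm: tuple = DEFAULT_MASK_WINDOW,
    threshold: float = DEFAULT_MASK_THRESHOLD,
) -> np.ndarray:
    """Foreground = pixels whose mean reflectance over ``window_nm``
    exceeds ``threshold``."""
    lo, hi = window_nm
    sel = (cube.wavelengths_nm >= lo) & (cube.wavelengths_nm <= hi)
    if not sel.any():
        raise ValueError(f"window {window_nm} contains no channels of the cube's grid")
    return cube.data[:, :, sel].mean(axis=2) > threshold


def predict_map(
    cube: SpectralCube,
    pretreatment: Pretreatment,
    selected_bands,
    model,
    mask: np.ndarray | None = None,
    trim: tuple = (0, 0),
    model_label: str = "",
    scale_percentiles: tuple = (2.0, 98.0),
) -> PredictionMap:
    """Predict TFAA for every foreground pixel.

    ``selected_bands`` indexes the trimmed grid; ``model`` is any object
    with a ``predict`` method over that band subset. ``trim`` drops edge
    channels first so cubes on the raw acquisition grid can be fed
    directly. Color-scale limits default to robust percentiles of the
    foreground values.
    """
    if cube.kind != "reflectance":
        raise ValueError("predict_map requires a reflectance cube")
    if pretreatment.fitted_ is None:
        raise RuntimeError("pretreatment must be fitted on calibration rows first")
    work = trim_bands(cube, *trim) if any(trim) else cube
    if mask is None:
        mask = mask_background(work)
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    values = np.full((h, w), np.nan)
    if mask.any():
        pixels = work.data[mask]  # (n_fg, p_trimmed)
        treated = pretreatment.apply(pixels)
        sel = np.asarray(selected_bands, dtype=int)
        if sel.size and sel.max() >= treated.shape[1]:
            raise ValueError("selected band index exceeds the cube's trimmed band axis")
        preds = model.predict(treated[:, sel])
        values[mask] = preds
        finite = preds[np.isfinite(preds)]
        if finite.size:
            lo, hi = np.percentile(finite, scale_percentiles)
        else:
            lo = hi = 0.0
    else:
        lo = hi = 0.0
    return PredictionMap(values, mask, model_label, (float(lo), float(hi)))


def render_pseudocolor(
    pmap: PredictionMap,
    path,
    palette: str = "viridis",
    limits: tuple | None = None,
    scale: int = 8,
) -> None:
    """Write an 8-bit PNG: pseudo-colored foreground, neutral gray
    background, and a labelled color-bar strip annotated in % dry mass.
    Output bytes are deterministic for fixed inputs."""
    lo, hi = limits if limits is not None else pmap.scale_limits
    if hi < lo:
        raise ValueError("reversed color limits")
    cmap = colormaps[palette]
    span = hi - lo if hi > lo else 1.0
    norm = np.clip((pmap.values - lo) / span, 0.0, 1.0)
    rgba = (cmap(np.nan_to_num(norm)) * 255).astype(np.uint8)
    rgba[~pmap.mask] = (200, 200, 200, 255)  # neutral background

    h, w = pmap.mask.shape
    img = Image.fromarray(rgba, "RGBA").resize((w * scale, h * scale), Image.NEAREST)

    # color-bar strip on the right, annotated with the limits
    bar_w, pad, text_h = 20, 8, 14
    canvas = Image.new("RGBA", (img.width + bar_w + 3 * pad + 60, img.height + 2 * pad),
                       (255, 255, 255, 255))
    canvas.paste(img, (pad, pad))
    grad = cmap(np.linspace(1.0, 0.0, img.height))[:, None, :]
    bar = (np.repeat(grad, bar_w, axis=1) * 255).astype(np.uint8)
    canvas.paste(Image.fromarray(bar, "RGBA"), (img.width + 2 * pad, pad))
    draw = ImageDraw.Draw(canvas)
    x_text = img.width + 2 * pad + bar_w + 4
    draw.text((x_text, pad), f"{hi:.2f}", fill=(0, 0, 0, 255))
    draw.text((x_text, pad + img.height - text_h), f"{lo:.2f}", fill=(0, 0, 0, 255))
    draw.text((x_text, pad + img.height // 2 - text_h // 2), "% dm", fill=(0, 0, 0, 255))
    canvas.save(path, format="PNG")
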