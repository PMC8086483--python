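"""Whole-image staining: tiled prediction, stitching and seam correction.

Prediction runs patch-by-patch (the networks were trained on fixed-size
patches), and the stitched result shows a "patch effect" — a visible seam
at every patch-size-th row and column.  Seam pixels are repaired by linear
interpolation from their perpendicular neighbours: a least-squares line
through the three nearest pixels on each side, evaluated at the seam
position (configurable to a simple two-neighbour average).
"""

from __future__ import annotations

import warnings
from typing import Callable, List, Optional

import numpy as np

from .preprocessing import extract_patches, scale_to_model_range, stitch_patches, unscale_from_model_range
from .types import MultimodalImage, StitchedPrediction, validate_uint8_rgb

__all__ = ["stain_image", "correct_patch_effect", "adjust_contrast"]


def stain_image(
    generator,
    nlm: MultimodalImage,
    patch_size: int = 256,
    correct_seams: bool = False,
) -> StitchedPrediction:
    """Translate a pre-processed, contrast-inverted multimodal image into a
    generated H&E image.

    ``generator`` is any object with ``forward(x, train=False)`` mapping a
    (3, P, P) array in [-1, 1] to the same shape (a trained network, or a
    pass-through for pipeline tests).  Patches are predicted independently,
    unscaled to 8-bit and reassembled at their recorded origins; padding is
    trimmed.
    """
    grid = extract_patches(nlm.pixels, size=patch_size)
    out_patches: List[np.ndarray] = []
    for patch in grid.patches:
        x = scale_to_model_range(patch).transpose(2, 0, 1)
        y = generator.forward(x, train=False) if hasattr(generator, "forward") else generator(x)
        y = np.asarray(y)
        if y.shape != x.shape:
            raise ValueError(f"generator produced shape {y.shape}, expected {x.shape}")
        out_patches.append(unscale_from_model_range(np.clip(y, -1.0, 1.0)).transpose(1, 2, 0))
    grid.patches = out_patches
    pixels = stitch_patches(grid)
    pred = StitchedPrediction(pixels=pixels, seam_rows=grid.seam_rows, seam_cols=grid.seam_cols)
    return correct_patch_effect(pred) if correct_seams else pred


def _interp_line(stack: np.ndarray) -> np.ndarray:
    """Value at offset 0 of a least-squares line through offsets ±1..±3.

    With symmetric offsets the fitted line's value at the seam equals the
    mean of the six neighbours.
    """
    return stack.mean(axis=0)


def correct_patch_effect(pred: StitchedPrediction, neighbors: int = 3) -> StitchedPrediction:
    """Replace each seam pixel using its perpendicular neighbours.

    ``neighbors`` is per side: 3 (default, least-squares line) or 1
    (two-neighbour average).  Non-seam pixels are untouched; the output is
    clipped to [0, 255] with round-half-even.  Seams closer than
    ``neighbors`` pixels to the border are skipped with a warning.
    """
    if neighbors not in (1, 3):
        raise ValueError("neighbors must be 1 or 3 per side")
    px = pred.pixels.astype(np.float64)
    h, w = px.shape[:2]
    offs = [o for o in range(-neighbors, neighbors + 1) if o != 0]

    for r in pred.seam_rows:
        if r - neighbors < 0 or r + neighbors >= h:
            warnings.warn(f"seam row {r} too close to the border; skipped", stacklevel=2)
            continue
        px[r, :, :] = _interp_line(np.stack([px[r + o, :, :] for o in offs]))
    for c in pred.seam_cols:
        if c - neighbors < 0 or c + neighbors >= w:
            warnings.warn(f"seam column {c} too close to the border; skipped", stacklevel=2)
            continue
        px[:, c, :] = _interp_line(np.stack([px[:, c + o, :] for o in offs]))

    out = np.clip(np.rint(px), 0, 255).astype(np.uint8)
    return StitchedPrediction(
        pixels=out, seam_rows=list(pred.seam_rows), seam_cols=list(pred.seam_cols), corrected=True
    )


def adjust_contrast(image: np.ndarray, factor: float = 0.7) -> np.ndarray:
    """Scale contrast about each channel's mean: ``v -> mean + f * (v - mean)``."""
    if factor <= 0:
        raise ValueError("contrast factor must be positive")
    arr = validate_uint8_rgb(image, "image").astype(np.float64)
    mean = arr.mean(axis=(0, 1), keepdims=True)
    out = mean + factor * (arr - mean)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
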