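"""Image pre-processing: contrast handling, filtering, tiling and scaling.

The two modalities follow distinct routes which this module keeps separate:

* the H&E image is grayscaled and contrast-inverted **only** to drive the
  mutual-information registration (see :mod:`nlmstain.registration`); the
  model is trained on the non-inverted H&E pixels;
* the multimodal (NLM) image is median-filtered, downsampled ×4,
  illumination-corrected and contrast-stretched, then contrast-inverted
  **only** for model training — the inverted image is what the generator
  sees as input.

Patches are 256×256 by default (64×64 in the reduced CPU profile), cut on a
regular grid with bottom/right reflection padding, and scaled to [-1, 1]
before entering a network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .types import MultimodalImage, PatchGrid, validate_uint8_rgb

__all__ = [
    "PreprocessConfig",
    "invert_contrast",
    "to_grayscale",
    "preprocess_nlm",
    "extract_patches",
    "stitch_patches",
    "padding_fractions",
    "homogeneity_factor",
    "filter_background",
    "filter_registration_artifacts",
    "scale_to_model_range",
    "unscale_from_model_range",
]

#: ITU-R BT.601 luma weights used for grayscale conversion
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class PreprocessConfig:
    """Parameters of the multimodal pre-processing chain and patch filters."""

    median_size: int = 3
    downsample: int = 4
    illumination_sigma: float = 50.0
    stretch_percentiles: Optional[Tuple[float, float]] = (1.0, 99.0)  # None disables the stretch
    patch_size: int = 256
    homogeneity_threshold: float = 0.60
    homogeneity_tolerance: int = 10
    max_padding_fraction: float = 0.5


def invert_contrast(image: np.ndarray) -> np.ndarray:
    """Per-pixel, per-channel 8-bit inversion ``v -> 255 - v`` (an involution)."""
    arr = np.asarray(image)
    if not np.issubdtype(arr.dtype, np.integer):
        raise TypeError("invert_contrast requires an 8-bit integer image")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("invert_contrast requires values in [0, 255]")
    return (255 - arr.astype(np.int16)).astype(np.uint8)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Weighted-luma grayscale (BT.601), rounded to uint8."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("to_grayscale expects an H×W×3 image")
    gray = arr[..., 0] * LUMA_WEIGHTS[0] + arr[..., 1] * LUMA_WEIGHTS[1] + arr[..., 2] * LUMA_WEIGHTS[2]
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def _stretch_channel(ch: np.ndarray, plo: float, phi: float) -> np.ndarray:
    lo, hi = np.percentile(ch, [plo, phi])
    if hi <= lo:
        return ch  # flat channel: stretching is a no-op by convention
    out = (ch - lo) / (hi - lo) * 255.0
    return np.clip(out, 0.0, 255.0)


def preprocess_nlm(raw: MultimodalImage, config: Optional[PreprocessConfig] = None) -> MultimodalImage:
    """Median filter → ×4 downsampling → illumination flattening → contrast stretch.

    Illumination is flattened per channel by division with a Gaussian-blurred
    (``illumination_sigma``) copy, renormalized to preserve the channel mean;
    contrast is stretched between the 1st and 99th percentile.  Output stays
    8-bit RGB at 1/4 the input size.
    """
    cfg = config or PreprocessConfig()
    px = raw.pixels.astype(np.float64)
    h, w = px.shape[:2]

    # per-channel median filter
    if cfg.median_size > 1:
        px = np.stack(
            [ndimage.median_filter(px[..., c], size=cfg.median_size) for c in range(3)], axis=-1
        )

    # block-mean downsampling
    d = cfg.downsample
    if d > 1:
        hc, wc = (h // d) * d, (w // d) * d
        px = px[:hc, :wc].reshape(hc // d, d, wc // d, d, 3).mean(axis=(1, 3))

    if min(px.shape[:2]) < cfg.patch_size:
        warnings.warn(
            f"pre-processed image {px.shape[:2]} is smaller than the patch size {cfg.patch_size}",
            stacklevel=2,
        )

    out = np.empty_like(px)
    for c in range(3):
        ch = px[..., c]
        if cfg.illumination_sigma > 0:
            bg = ndimage.gaussian_filter(ch, sigma=cfg.illumination_sigma)
            flat = ch / np.maximum(bg, 1e-6) * max(bg.mean(), 1e-6)
        else:
            flat = ch
        out[..., c] = _stretch_channel(flat, *cfg.stretch_percentiles) if cfg.stretch_percentiles else flat

    return MultimodalImage(np.clip(np.rint(out), 0, 255).astype(np.uint8), pixel_size_um=raw.pixel_size_um * d)


def _padded_extent(n: int, size: int, stride: int) -> int:
    steps = max(1, -(-(n - size) // stride) + 1) if n > size else 1
    return (steps - 1) * stride + size


def extract_patches(image: np.ndarray, size: int = 256, stride: Optional[int] = None) -> PatchGrid:
    """Tile an image into ``size``×``size`` patches with recorded origins.

    Non-multiple images are reflection-padded on the bottom/right so that
    ``stitch_patches`` is an exact inverse on the original support.
    """
    stride = stride or size
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = arr[..., None]
    h, w = arr.shape[:2]
    if h < 1 or w < 1:
        raise ValueError("empty image")
    ph, pw = _padded_extent(h, size, stride), _padded_extent(w, size, stride)

    def _pad(a: np.ndarray, axis: int, amount: int) -> np.ndarray:
        while amount > 0:
            step = min(amount, a.shape[axis] - 1) if a.shape[axis] > 1 else amount
            spec = [(0, 0)] * a.ndim
            spec[axis] = (0, step)
            a = np.pad(a, spec, mode="reflect" if a.shape[axis] > 1 else "edge")
            amount -= step
        return a

    padded = _pad(_pad(arr, 0, ph - h), 1, pw - w)
    patches, origins = [], []
    for r in range(0, ph - size + 1, stride):
        for c in range(0, pw - size + 1, stride):
            patches.append(padded[r : r + size, c : c + size].copy())
            origins.append((r, c))
    return PatchGrid(
        patches=patches,
        origins=origins,
        parent_shape=(h, w),
        padded_shape=(ph, pw),
        patch_size=size,
    )


def stitch_patches(grid: PatchGrid, trim: bool = True) -> np.ndarray:
    """Reassemble a PatchGrid; with ``trim`` the padding is cut away."""
    ph, pw = grid.padded_shape
    ch = grid.patches[0].shape[2] if grid.patches[0].ndim == 3 else 1
    canvas = np.zeros((ph, pw, ch), dtype=grid.patches[0].dtype)
    s = grid.patch_size
    for patch, (r, c) in zip(grid.patches, grid.origins):
        canvas[r : r + s, c : c + s] = patch.reshape(s, s, ch)
    if trim:
        h, w = grid.parent_shape
        canvas = canvas[:h, :w]
    return canvas if ch > 1 else canvas[..., 0]


def padding_fractions(grid: PatchGrid) -> np.ndarray:
    """Fraction of each patch's area lying outside the original support."""
    h, w = grid.parent_shape
    s = grid.patch_size
    fr = np.empty(len(grid), dtype=np.float64)
    for i, (r, c) in enumerate(grid.origins):
        vr = max(0, min(r + s, h) - r)
        vc = max(0, min(c + s, w) - c)
        fr[i] = 1.0 - (vr * vc) / (s * s)
    return fr


def homogeneity_factor(patch: np.ndarray, tolerance: int = 10) -> float:
    """Fraction of pixels whose grayscale value lies within ±tolerance of
    the patch median — 1.0 for a perfectly homogeneous (background) patch."""
    arr = np.asarray(patch)
    gray = to_grayscale(arr) if arr.ndim == 3 else arr
    gray = gray.astype(np.int16)
    med = np.median(gray)
    return float(np.mean(np.abs(gray - med) <= tolerance))


def filter_background(
    patches: Sequence[np.ndarray],
    homogeneity_threshold: float = 0.60,
    tolerance: int = 10,
) -> Tuple[List[np.ndarray], List[int]]:
    """Drop background patches: keep those with homogeneity factor ≤ threshold."""
    kept, idx = [], []
    for i, p in enumerate(patches):
        if homogeneity_factor(p, tolerance) <= homogeneity_threshold:
            kept.append(p)
            idx.append(i)
    return kept, idx


def filter_registration_artifacts(
    pairs: Sequence[Tuple[np.ndarray, np.ndarray]],
    masks: Optional[Sequence[np.ndarray]],
) -> Tuple[List[Tuple[np.ndarray, np.ndarray]], List[int]]:
    """Remove every (NLM, H&E) patch pair whose H&E patch touches the
    zero-filled registration border (any masked pixel disqualifies)."""
    if masks is None:
        raise ValueError("registration-artifact filtering requires zero-fill masks")
    if len(masks) != len(pairs):
        raise ValueError("one mask per pair required")
    kept, idx = [], []
    for i, (pair, m) in enumerate(zip(pairs, masks)):
        if not np.asarray(m).any():
            kept.append(pair)
            idx.append(i)
    if pairs and not kept:
        warnings.warn("all patch pairs showed registration artifacts; empty training set", stacklevel=2)
    return kept, idx


def scale_to_model_range(patch: np.ndarray) -> np.ndarray:
    """Map 8-bit values to the generator range: ``v -> v/127.5 - 1``."""
    arr = np.asarray(patch)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("scale_to_model_range expects values in [0, 255]")
    return (arr.astype(np.float32) / 127.5) - 1.0


def unscale_from_model_range(patch: np.ndarray) -> np.ndarray:
    """Inverse of :func:`scale_to_model_range`, rounded back to uint8."""
    arr = np.asarray(patch, dtype=np.float64)
    return np.clip(np.rint((arr + 1.0) * 127.5), 0, 255).astype(np.uint8)
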