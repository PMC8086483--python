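"""Core image containers shared across the pipeline.

All pixel grids are 8-bit RGB ``(H, W, 3)`` uint8 arrays with a 0-based,
row-major, top-left-origin coordinate convention.  The red/green/blue
channels of a multimodal image carry the CARS, TPEF and SHG signals,
respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "MultimodalImage",
    "HEImage",
    "PatchGrid",
    "StitchedPrediction",
    "validate_uint8_rgb",
]

#: physical pixel sizes of the two modalities, micrometres per pixel
NLM_PIXEL_SIZE_UM = 0.227
HE_PIXEL_SIZE_UM = 0.219


def validate_uint8_rgb(pixels: np.ndarray, what: str = "image") -> np.ndarray:
    arr = np.asarray(pixels)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{what} must be an H×W×3 array, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if not np.issubdtype(arr.dtype, np.integer):
            raise TypeError(f"{what} must be 8-bit integer, got dtype {arr.dtype}")
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError(f"{what} values must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


@dataclass
class MultimodalImage:
    """Three-channel non-linear multimodal image (R=CARS, G=TPEF, B=SHG)."""

    pixels: np.ndarray
    pixel_size_um: float = NLM_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.pixels = validate_uint8_rgb(self.pixels, "MultimodalImage")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class HEImage:
    """A real or generated H&E-stained RGB section.

    ``zero_fill_mask`` marks pixels outside the warped support after
    registration (filled with zeros); it is present iff ``registered``.
    """

    pixels: np.ndarray
    pixel_size_um: float = HE_PIXEL_SIZE_UM
    registered: bool = False
    zero_fill_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pixels = validate_uint8_rgb(self.pixels, "HEImage")
        if self.registered and self.zero_fill_mask is None:
            raise ValueError("registered HEImage requires a zero_fill_mask")
        if not self.registered and self.zero_fill_mask is not None:
            raise ValueError("zero_fill_mask only valid on a registered HEImage")
        if self.zero_fill_mask is not None:
            self.zero_fill_mask = np.asarray(self.zero_fill_mask, dtype=bool)
            if self.zero_fill_mask.shape != self.pixels.shape[:2]:
                raise ValueError("zero_fill_mask shape must match the image")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class PatchGrid:
    """Ordered tiling of an image into fixed-size square patches.

    ``origins`` are (row, col) top-left coordinates in the (padded) parent
    frame; with the default stride every origin is a multiple of the patch
    size.  ``scaled`` flags patches living in the model range [-1, 1].
    """

    patches: List[np.ndarray]
    origins: List[Tuple[int, int]]
    parent_shape: Tuple[int, int]
    padded_shape: Tuple[int, int]
    patch_size: int = 256
    scaled: bool = False

    def __post_init__(self) -> None:
        if len(self.patches) != len(self.origins):
            raise ValueError("patches and origins must have the same length")
        for p in self.patches:
            if p.shape[:2] != (self.patch_size, self.patch_size):
                raise ValueError("patch shape does not match patch_size")
        if self.scaled:
            for p in self.patches:
                if p.min() < -1.0 - 1e-6 or p.max() > 1.0 + 1e-6:
                    raise ValueError("scaled patches must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def seam_rows(self) -> List[int]:
        """Interior horizontal seam indices in the parent frame."""
        return [r for r in range(self.patch_size, self.parent_shape[0], self.patch_size)]

    @property
    def seam_cols(self) -> List[int]:
        return [c for c in range(self.patch_size, self.parent_shape[1], self.patch_size)]


@dataclass
class StitchedPrediction:
    """A whole generated H&E image reassembled from patch predictions."""

    pixels: np.ndarray
    seam_rows: List[int] = field(default_factory=list)
    seam_cols: List[int] = field(default_factory=list)
    corrected: bool = False

    def __post_init__(self) -> None:
        self.pixels = validate_uint8_rgb(self.pixels, "StitchedPrediction")
        h, w = self.pixels.shape[:2]
        if any(not 0 < r < h for r in self.seam_rows) or any(not 0 < c < w for c in self.seam_cols):
            raise ValueError("seam indices must lie strictly inside the image")
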