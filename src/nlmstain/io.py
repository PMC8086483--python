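"""Reading and writing images, transforms and configuration sidecars."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import tifffile
import yaml
from PIL import Image

__all__ = ["read_image", "write_image", "save_transform", "load_transform"]


def read_image(path: Union[str, Path]) -> np.ndarray:
    """Load an 8-bit image (TIFF via tifffile, PNG & friends via Pillow)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected an 8-bit image, got {arr.dtype}")
    return arr


def write_image(path: Union[str, Path], image: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        raise ValueError("only 8-bit images are written")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def save_transform(path: Union[str, Path], matrix: np.ndarray, meta: dict | None = None) -> None:
    """Serialize a 3×3 homogeneous (row, col) transform to a YAML sidecar."""
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3):
        raise ValueError("transform must be a 3×3 matrix")
    payload = {"matrix": m.tolist(), **(meta or {})}
    Path(path).write_text(yaml.safe_dump(payload))


def load_transform(path: Union[str, Path]) -> np.ndarray:
    payload = yaml.safe_load(Path(path).read_text())
    return np.asarray(payload["matrix"], dtype=float)
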