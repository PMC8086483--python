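"""Similarity metrics between generated and reference H&E images.

Three metrics, all computed on 8-bit RGB images with an optional background
exclusion mask:

* **MSE** on the 0–255 intensity scale, averaged over evaluated pixels and
  all three channels;
* **SSIM**, computed per channel and averaged.  The default ``local`` mode
  is the standard windowed index (11×11 Gaussian window, sigma 1.5,
  c1=(0.01·255)², c2=(0.03·255)²); a ``global`` mode evaluates the closed
  formula

      SSIM = (2 μx μy + c1)(2 σxy + c2) / ((μx² + μy² + c1)(σx² + σy² + c2))

  once with whole-image statistics;
* **CSS** (color shading similarity): both images are converted to CIELAB
  (sRGB companding, D65), and for each of the A*/B* chroma channels a
  per-pixel similarity ``Sim = 1 - |ΔC| / max|ΔC|`` is thresholded by an
  indicator (``Sim > 0.5`` by default) and averaged; the two channel scores
  are averaged.  A channel with no difference anywhere scores 1.

Background is excluded by the same homogeneity criterion used for patch
filtering, applied tile-wise.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage.color import rgb2lab
from skimage.metrics import structural_similarity

from .preprocessing import homogeneity_factor

__all__ = [
    "EvalConfig",
    "EvalReport",
    "mse",
    "ssim",
    "css",
    "css_from_lab",
    "background_mask",
    "evaluate_dataset",
]


@dataclass
class EvalConfig:
    ssim_mode: str = "local"  # "local" (windowed) or "global" (whole-image formula)
    css_threshold: float = 0.5
    css_max_dist: str = "per_pair"  # or "fixed" (theoretical CIELAB chroma range)
    exclude_background: bool = True
    background_tile: int = 256
    homogeneity_threshold: float = 0.60
    homogeneity_tolerance: int = 10


@dataclass
class EvalReport:
    per_image: List[Dict[str, float]]
    mean_mse: float
    mean_ssim: float
    mean_css: float
    config: EvalConfig

    def to_csv(self, path: Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=["image", "mse", "ssim", "css", "excluded_background_fraction"])
            w.writeheader()
            for row in self.per_image:
                w.writerow(row)
            w.writerow(
                {
                    "image": "mean",
                    "mse": self.mean_mse,
                    "ssim": self.mean_ssim,
                    "css": self.mean_css,
                    "excluded_background_fraction": "",
                }
            )


def _as_float_rgb(x: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{name} must be H×W×3")
    return arr.astype(np.float64)


def mse(x: np.ndarray, y: np.ndarray, mask: Optional[np.ndarray] = None) -> float:
    """Mean squared error on the 8-bit scale over evaluated pixels."""
    xf, yf = _as_float_rgb(x, "x"), _as_float_rgb(y, "y")
    if xf.shape != yf.shape:
        raise ValueError("images must share a shape")
    sq = (xf - yf) ** 2
    if mask is None:
        return float(sq.mean())
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty evaluation mask")
    return float(sq[m].mean())


def _global_ssim_channel(x: np.ndarray, y: np.ndarray, c1: float, c2: float) -> float:
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    return float(((2 * mx * my + c1) * (2 * cov + c2)) / ((mx**2 + my**2 + c1) * (vx + vy + c2)))


def ssim(
    x: np.ndarray,
    y: np.ndarray,
    mode: str = "local",
    mask: Optional[np.ndarray] = None,
    data_range: float = 255.0,
) -> float:
    """Channel-averaged structural similarity (see module docstring)."""
    xf, yf = _as_float_rgb(x, "x"), _as_float_rgb(y, "y")
    if xf.shape != yf.shape:
        raise ValueError("images must share a shape")
    c1, c2 = (0.01 * data_range) ** 2, (0.03 * data_range) ** 2
    vals = []
    for ch in range(3):
        a, b = xf[..., ch], yf[..., ch]
        if mode == "global":
            if mask is not None:
                a, b = a[np.asarray(mask, bool)], b[np.asarray(mask, bool)]
            vals.append(_global_ssim_channel(a, b, c1, c2))
        elif mode == "local":
            if min(a.shape) < 11:
                raise ValueError("image smaller than the 11×11 SSIM window; use global mode")
            s, smap = structural_similarity(
                a,
                b,
                data_range=data_range,
                gaussian_weights=True,
                sigma=1.5,
                win_size=11,
                use_sample_covariance=False,
                full=True,
            )
            if mask is None:
                vals.append(float(s))
            else:
                m = np.asarray(mask, dtype=bool)
                if not m.any():
                    raise ValueError("empty evaluation mask")
                vals.append(float(smap[m].mean()))
        else:
            raise ValueError("mode must be 'local' or 'global'")
    return float(np.mean(vals))


#: theoretical width of the CIELAB a*/b* ranges reachable from sRGB
_LAB_FIXED_RANGE = 255.0


def css_from_lab(
    lab_x: np.ndarray,
    lab_y: np.ndarray,
    threshold: float = 0.5,
    mask: Optional[np.ndarray] = None,
    max_dist: str = "per_pair",
) -> float:
    """CSS on precomputed CIELAB arrays (channels L*, A*, B*)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    m = np.ones(lab_x.shape[:2], dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty evaluation mask")
    scores = []
    for ch in (1, 2):  # A*, B*
        d = np.abs(lab_x[..., ch] - lab_y[..., ch])[m]
        md = d.max() if max_dist == "per_pair" else _LAB_FIXED_RANGE
        if md == 0:
            scores.append(1.0)
            continue
        sim = 1.0 - d / md
        ind = sim > threshold
        scores.append(float((sim * ind).mean()))
    return float(np.mean(scores))


def css(
    x: np.ndarray,
    y: np.ndarray,
    threshold: float = 0.5,
    mask: Optional[np.ndarray] = None,
    max_dist: str = "per_pair",
) -> float:
    """Color shading similarity over the CIELAB A*/B* channels."""
    xf, yf = _as_float_rgb(x, "x"), _as_float_rgb(y, "y")
    if xf.shape != yf.shape:
        raise ValueError("images must share a shape")
    if xf.size == 0:
        raise ValueError("empty image")
    return css_from_lab(rgb2lab(xf / 255.0), rgb2lab(yf / 255.0), threshold, mask, max_dist)


def background_mask(image: np.ndarray, config: Optional[EvalConfig] = None) -> np.ndarray:
    """True where the image is evaluated (tissue), False on background tiles.

    The image is scanned in ``background_tile``-sized tiles; a tile whose
    homogeneity factor exceeds the threshold counts as background.
    """
    cfg = config or EvalConfig()
    arr = np.asarray(image)
    h, w = arr.shape[:2]
    if not cfg.exclude_background:
        return np.ones((h, w), dtype=bool)
    t = cfg.background_tile
    mask = np.ones((h, w), dtype=bool)
    for r in range(0, h, t):
        for c in range(0, w, t):
            tile = arr[r : r + t, c : c + t]
            if homogeneity_factor(tile, cfg.homogeneity_tolerance) > cfg.homogeneity_threshold:
                mask[r : r + t, c : c + t] = False
    return mask


def evaluate_dataset(
    pairs: Sequence[Tuple[np.ndarray, np.ndarray]],
    config: Optional[EvalConfig] = None,
    names: Optional[Sequence[str]] = None,
    csv_path: Optional[Path] = None,
) -> EvalReport:
    """Per-image MSE/SSIM/CSS (+ means) for (generated, reference) pairs.

    The background mask is derived from the reference image and shared by
    all three metrics so the means cover the same pixel set.
    """
    cfg = config or EvalConfig()
    if not pairs:
        raise ValueError("need at least one image pair")
    rows: List[Dict[str, float]] = []
    for i, (pred, ref) in enumerate(pairs):
        name = names[i] if names else f"image{i:03d}"
        if np.asarray(pred).shape != np.asarray(ref).shape:
            warnings.warn(f"{name}: shape mismatch, pair skipped", stacklevel=2)
            continue
        m = background_mask(ref, cfg)
        rows.append(
            {
                "image": name,
                "mse": mse(pred, ref, m),
                "ssim": ssim(pred, ref, cfg.ssim_mode, m),
                "css": css(pred, ref, cfg.css_threshold, m, cfg.css_max_dist),
                "excluded_background_fraction": float(1.0 - m.mean()),
            }
        )
    if not rows:
        raise ValueError("no evaluable pairs")
    report = EvalReport(
        per_image=rows,
        mean_mse=float(np.mean([r["mse"] for r in rows])),
        mean_ssim=float(np.mean([r["ssim"] for r in rows])),
        mean_css=float(np.mean([r["css"] for r in rows])),
        config=cfg,
    )
    if csv_path is not None:
        report.to_csv(csv_path)
    return report
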