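"""Procedural tissue phantoms: paired multimodal / H&E renderings.

The generator draws a colon-mucosa-like label map — elliptical crypts with a
pale lumen and a dark epithelial ring, a textured stroma, sparse nuclei and
an optional blank background region — and renders it twice from the same
labels: once with H&E stain colors and once with class-specific CARS / TPEF /
SHG channel intensities.  The two renderings are deliberately in *inverse*
contrast (tissue that stains dark in H&E is signal-bright in the multimodal
channels), which is the relationship the staining models must learn and the
reason the pipeline contrast-inverts the multimodal image before training.

Because both renderings are deterministic functions of one label map, a
"perfect generator" oracle exists for every phantom, and known misalignments
can be injected with an exactly recorded ground-truth transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .types import HEImage, MultimodalImage

__all__ = [
    "LABELS",
    "PhantomParams",
    "generate_phantom_pair",
    "generate_patch_dataset",
]

LABELS = {"background": 0, "lumen": 1, "epithelium": 2, "stroma": 3, "nuclei": 4}

# H&E palette: lumen pale pink, epithelium dark purple, stroma pink,
# nuclei dark blue-purple, background near-white.
_HE_PALETTE = np.array(
    [
        [245, 245, 245],  # background
        [235, 205, 215],  # lumen
        [90, 50, 120],  # epithelium
        [225, 150, 180],  # stroma
        [60, 40, 95],  # nuclei
    ],
    dtype=np.float64,
)

# Multimodal channel intensities (CARS, TPEF, SHG) per class — bright where
# H&E is dark and vice versa (inverse-contrast relationship); stroma carries
# the collagen SHG signal in the blue channel.
_NLM_PALETTE = np.array(
    [
        [4, 4, 4],  # background: no signal
        [35, 28, 18],  # lumen: weak signal
        [210, 185, 70],  # epithelium: strong CARS/TPEF
        [110, 85, 190],  # stroma: moderate CARS, SHG-rich
        [18, 18, 18],  # nuclei: negative contrast
    ],
    dtype=np.float64,
)


@dataclass
class PhantomParams:
    """Knobs of the phantom generator; deterministic per ``seed``."""

    image_size: Tuple[int, int] = (512, 512)
    crypt_count: int = 10
    crypt_radius_range: Tuple[float, float] = (24.0, 48.0)
    ring_fraction: float = 0.35  # epithelial ring thickness as a fraction of the radius
    stroma_texture_scale: float = 8.0  # px, smoothing length of the texture field
    texture_amplitude: float = 0.18
    nuclei_density: float = 2.5e-4  # nuclei per stroma pixel
    nuclei_radius_range: Tuple[float, float] = (2.0, 4.0)
    noise_sigma: float = 4.0  # additive Gaussian noise, 8-bit counts
    background_quadrant: Optional[int] = None  # 0..3 = TL, TR, BL, BR blank region
    he_palette: np.ndarray = field(default_factory=lambda: _HE_PALETTE.copy())
    nlm_palette: np.ndarray = field(default_factory=lambda: _NLM_PALETTE.copy())
    misalignment: Optional[Dict[str, float]] = None  # shift_rows, shift_cols, rotation_deg, scale
    crypt_retry_budget: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for pal in (self.he_palette, self.nlm_palette):
            if np.asarray(pal).min() < 0 or np.asarray(pal).max() > 255:
                raise ValueError("palette entries must lie in [0, 255]")


def _ellipse_mask(shape, center, axes, angle_rad) -> np.ndarray:
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(angle_rad), np.sin(angle_rad)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _draw_label_map(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    h, w = params.image_size
    labels = np.full((h, w), LABELS["stroma"], dtype=np.uint8)

    tissue = np.ones((h, w), dtype=bool)
    if params.background_quadrant is not None:
        q = params.background_quadrant
        rs = slice(0, h // 2) if q in (0, 1) else slice(h // 2, h)
        cs = slice(0, w // 2) if q in (0, 2) else slice(w // 2, w)
        labels[rs, cs] = LABELS["background"]
        tissue[rs, cs] = False

    # crypts: epithelial ring around a lumen, rejection-sampled to keep
    # them inside the tissue with limited mutual overlap
    centers: List[Tuple[float, float]] = []
    placed = 0
    tries = 0
    lo, hi = params.crypt_radius_range
    while placed < params.crypt_count:
        tries += 1
        if tries > params.crypt_retry_budget + params.crypt_count:
            raise RuntimeError(
                f"could not place {params.crypt_count} crypts within the retry budget "
                f"(placed {placed})"
            )
        r = rng.uniform(lo, hi)
        cy = rng.uniform(r, h - r)
        cx = rng.uniform(r, w - r)
        if not tissue[int(cy), int(cx)]:
            continue
        if any((cy - oy) ** 2 + (cx - ox) ** 2 < (1.2 * r) ** 2 for oy, ox in centers):
            continue
        ratio = rng.uniform(0.7, 1.0)
        angle = rng.uniform(0, np.pi)
        outer = _ellipse_mask((h, w), (cy, cx), (r, r * ratio), angle)
        inner = _ellipse_mask((h, w), (cy, cx), (r * (1 - params.ring_fraction), r * ratio * (1 - params.ring_fraction)), angle)
        outer &= tissue
        inner &= tissue
        labels[outer] = LABELS["epithelium"]
        labels[inner] = LABELS["lumen"]
        centers.append((cy, cx))
        placed += 1

    # sparse nuclei scattered in the stroma
    stroma = labels == LABELS["stroma"]
    n_nuclei = rng.poisson(params.nuclei_density * stroma.sum())
    rows, cols = np.nonzero(stroma)
    if len(rows) and n_nuclei:
        idx = rng.choice(len(rows), size=min(n_nuclei, len(rows)), replace=False)
        for i in idx:
            nr = rng.uniform(*params.nuclei_radius_range)
            m = _ellipse_mask((h, w), (rows[i], cols[i]), (nr, nr * rng.uniform(0.7, 1.0)), rng.uniform(0, np.pi))
            labels[m & stroma] = LABELS["nuclei"]
    return labels


def _texture_field(shape, scale, amplitude, rng) -> np.ndarray:
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=scale)
    s = smooth.std()
    if s > 0:
        smooth = smooth / s
    # unit-std smooth field; amplitude is the std of the multiplicative
    # modulation (clipped at 2.5 sigma), strong enough that tissue tiles
    # read as textured under the homogeneity criterion
    return 1.0 + amplitude * np.clip(smooth, -2.5, 2.5)


def _render(labels: np.ndarray, palette: np.ndarray, texture: np.ndarray, noise_sigma: float, rng) -> np.ndarray:
    # texture modulates tissue only; background stays a blank region
    tex = np.where(labels == LABELS["background"], 1.0, texture)
    img = palette[labels] * tex[..., None]
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def misalignment_matrix(shift_rows: float, shift_cols: float, rotation_deg: float = 0.0, scale: float = 1.0, center: Tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """3×3 homogeneous matrix in (row, col) coordinates.

    Maps an original content point to its misaligned location: rotate/scale
    about ``center`` then translate by the shift.
    """
    th = np.deg2rad(rotation_deg)
    r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]) * scale
    t = np.asarray([shift_rows, shift_cols]) + np.asarray(center) - r @ np.asarray(center)
    m = np.eye(3)
    m[:2, :2] = r
    m[:2, 2] = t
    return m


def _warp(img: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Apply the homogeneous (row, col) content transform; zero fill."""
    inv = np.linalg.inv(matrix)
    out = np.empty_like(img)
    for ch in range(img.shape[2]):
        out[..., ch] = ndimage.affine_transform(
            img[..., ch].astype(np.float64), inv[:2, :2], offset=inv[:2, 2], order=1, cval=0.0
        ).round().clip(0, 255).astype(np.uint8)
    return out


def generate_phantom_pair(params: PhantomParams):
    """Return ``(MultimodalImage, HEImage, label_map, transform)``.

    ``transform`` is the 3×3 ground-truth misalignment applied to the H&E
    rendering (identity if ``params.misalignment`` is None).  Output is
    bit-identical for identical ``params``.
    """
    rng = np.random.default_rng(params.seed)
    labels = _draw_label_map(params, rng)
    texture = _texture_field(params.image_size, params.stroma_texture_scale, params.texture_amplitude, rng)
    nlm_px = _render(labels, params.nlm_palette, texture, params.noise_sigma, rng)
    he_px = _render(labels, params.he_palette, texture, params.noise_sigma, rng)

    h, w = params.image_size
    matrix = np.eye(3)
    if params.misalignment:
        mis = dict(params.misalignment)
        matrix = misalignment_matrix(
            mis.get("shift_rows", 0.0),
            mis.get("shift_cols", 0.0),
            mis.get("rotation_deg", 0.0),
            mis.get("scale", 1.0),
            center=((h - 1) / 2.0, (w - 1) / 2.0),
        )
        he_px = _warp(he_px, matrix)

    return (
        MultimodalImage(nlm_px),
        HEImage(he_px),
        labels,
        matrix,
    )


def generate_patch_dataset(
    params: PhantomParams,
    n_pairs: int,
    patch_size: int = 64,
    paired: bool = True,
    phantoms: int = 4,
):
    """Sample a pool of patches from seeded phantoms.

    paired=True  -> list of ``(nlm_patch, he_patch)`` uint8 tuples cut at a
                    shared origin of the same phantom (co-registered).
    paired=False -> ``(nlm_patches, he_patches)`` drawn from *disjoint*
                    phantom seeds, emulating unregistered material.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    if patch_size > min(h, w):
        raise ValueError("patch_size larger than the phantom image")

    def sample_origin() -> Tuple[int, int]:
        return (int(rng.integers(0, h - patch_size + 1)), int(rng.integers(0, w - patch_size + 1)))

    if paired:
        pairs = []
        per_phantom = -(-n_pairs // phantoms)
        for k in range(phantoms):
            nlm, he, _, _ = generate_phantom_pair(replace(params, seed=params.seed + 1000 + k, misalignment=None))
            for _ in range(per_phantom):
                if len(pairs) == n_pairs:
                    break
                r, c = sample_origin()
                pairs.append(
                    (
                        nlm.pixels[r : r + patch_size, c : c + patch_size].copy(),
                        he.pixels[r : r + patch_size, c : c + patch_size].copy(),
                    )
                )
        return pairs

    nlm_pool, he_pool = [], []
    per_phantom = -(-n_pairs // phantoms)
    for k in range(phantoms):
        nlm, _, _, _ = generate_phantom_pair(replace(params, seed=params.seed + 2000 + k, misalignment=None))
        _, he, _, _ = generate_phantom_pair(replace(params, seed=params.seed + 3000 + k, misalignment=None))
        for _ in range(per_phantom):
            if len(nlm_pool) < n_pairs:
                r, c = sample_origin()
                nlm_pool.append(nlm.pixels[r : r + patch_size, c : c + patch_size].copy())
            if len(he_pool) < n_pairs:
                r, c = sample_origin()
                he_pool.append(he.pixels[r : r + patch_size, c : c + patch_size].copy())
    return nlm_pool, he_pool
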