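"""Mutual-information registration of the H&E image onto the multimodal image.

The H&E section is grayscaled and contrast-inverted (inversion happens here
and only here — it is a registration aid, not a training transform) and used
as the moving image; the grayscale multimodal image is the fixed image.  A
similarity transform (translation + rotation + isotropic scale) is estimated
by maximizing Mattes mutual information over a multi-resolution (3-level)
pyramid via SimpleITK.  The default optimizer is regular-step gradient
descent, which recovers rotation far more reliably here than the classic
gradient-free one-plus-one evolutionary scheme (still available through the
config).  A precomputed transform can be applied instead, which keeps the
registration step pluggable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import SimpleITK as sitk

from .preprocessing import invert_contrast, to_grayscale
from .types import HEImage, MultimodalImage

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "estimate_transform",
    "apply_transform",
    "register_he_to_nlm",
]


@dataclass
class RegistrationConfig:
    mi_bins: int = 32
    shrink_factors: Tuple[int, ...] = (4, 2, 1)
    smoothing_sigmas: Tuple[float, ...] = (2.0, 1.0, 0.0)
    optimizer: str = "gradient_descent"  # or "evolutionary" (1+1, gradient-free)
    iterations: int = 200
    learning_rate: float = 1.0
    min_step: float = 1e-4
    relaxation_factor: float = 0.6
    initial_radius: float = 6.25e-3
    growth_factor: float = 1.05
    epsilon: float = 1.5e-6
    convergence_warning: bool = True


@dataclass
class RegistrationResult:
    """Estimated correction, expressed in (row, col) pixel coordinates.

    ``matrix`` maps a point of the *moving* (H&E) content to its registered
    location; for a phantom whose H&E was shifted by ``(dr, dc)`` the
    recovered ``translation`` is approximately ``(-dr, -dc)``.
    """

    matrix: np.ndarray
    translation: Tuple[float, float]
    rotation_deg: float
    scale: float
    final_metric: float
    converged: bool


def _to_sitk(img: np.ndarray) -> sitk.Image:
    return sitk.GetImageFromArray(np.asarray(img, dtype=np.float32))


def _similarity_to_result(tx: sitk.Similarity2DTransform, metric: float, converged: bool) -> RegistrationResult:
    # sitk works in (x=col, y=row); transform maps fixed points to moving
    # points, so the content correction is its inverse.
    m = np.array(tx.GetMatrix()).reshape(2, 2)
    c = np.array(tx.GetCenter())
    t = np.array(tx.GetTranslation())
    fwd = np.eye(3)
    fwd[:2, :2] = m
    fwd[:2, 2] = c + t - m @ c
    corr_xy = np.linalg.inv(fwd)
    perm = np.array([[0.0, 1.0], [1.0, 0.0]])
    corr = np.eye(3)
    corr[:2, :2] = perm @ corr_xy[:2, :2] @ perm
    corr[:2, 2] = perm @ corr_xy[:2, 2]
    scale = float(np.sqrt(max(np.linalg.det(corr_xy[:2, :2]), 0.0)))
    rot = float(np.rad2deg(np.arctan2(corr[1, 0], corr[0, 0])))
    return RegistrationResult(
        matrix=corr,
        translation=(float(corr[0, 2]), float(corr[1, 2])),
        rotation_deg=rot,
        scale=scale,
        final_metric=metric,
        converged=converged,
    )


def estimate_transform(
    moving: np.ndarray,
    fixed: np.ndarray,
    config: Optional[RegistrationConfig] = None,
) -> Tuple[RegistrationResult, sitk.Transform]:
    """Estimate the similarity transform aligning ``moving`` to ``fixed``.

    Both inputs are single-channel grayscale arrays (the contrast-inverted
    H&E and the multimodal image).  Degenerate (constant) images are
    rejected — mutual information is undefined for them.
    """
    cfg = config or RegistrationConfig()
    mov, fix = np.asarray(moving, dtype=np.float32), np.asarray(fixed, dtype=np.float32)
    if mov.std() == 0 or fix.std() == 0:
        raise ValueError("cannot register constant images (no mutual information)")

    f_img, m_img = _to_sitk(fix), _to_sitk(mov)
    initial = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.Similarity2DTransform(), sitk.CenteredTransformInitializerFilter.GEOMETRY
    )

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=cfg.mi_bins)
    reg.SetMetricSamplingStrategy(reg.NONE)  # full sampling: deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    if cfg.optimizer == "gradient_descent":
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=cfg.learning_rate,
            minStep=cfg.min_step,
            numberOfIterations=cfg.iterations,
            relaxationFactor=cfg.relaxation_factor,
        )
    elif cfg.optimizer == "evolutionary":
        reg.SetOptimizerAsOnePlusOneEvolutionary(
            numberOfIterations=cfg.iterations,
            epsilon=cfg.epsilon,
            initialRadius=cfg.initial_radius,
            growthFactor=cfg.growth_factor,
            seed=12345,
        )
    else:
        raise ValueError("optimizer must be 'gradient_descent' or 'evolutionary'")
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(initial, inPlace=False)
    reg.SetShrinkFactorsPerLevel(list(cfg.shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(cfg.smoothing_sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()

    out = reg.Execute(f_img, m_img)
    metric = float(reg.GetMetricValue())
    converged = reg.GetOptimizerIteration() < cfg.iterations
    if not converged and cfg.convergence_warning:
        warnings.warn(
            f"registration optimizer reached the iteration cap; final metric {metric:.4f}",
            stacklevel=2,
        )
    tx = sitk.Similarity2DTransform(out if isinstance(out, sitk.Similarity2DTransform) else sitk.CompositeTransform(out).GetNthTransform(0))
    return _similarity_to_result(tx, metric, converged), tx


def apply_transform(he: HEImage, tx: sitk.Transform, reference_shape: Tuple[int, int]) -> HEImage:
    """Warp the color H&E image with an estimated transform; out-of-support
    pixels are filled with zeros and recorded in the zero-fill mask."""
    h, w = reference_shape
    ref = sitk.Image(int(w), int(h), sitk.sitkFloat32)
    channels = []
    for c in range(3):
        img = _to_sitk(he.pixels[..., c])
        res = sitk.Resample(img, ref, tx, sitk.sitkLinear, 0.0)
        channels.append(sitk.GetArrayFromImage(res))
    support = sitk.Resample(_to_sitk(np.ones(he.pixels.shape[:2])), ref, tx, sitk.sitkNearestNeighbor, 0.0)
    mask = sitk.GetArrayFromImage(support) < 0.5
    px = np.clip(np.rint(np.stack(channels, axis=-1)), 0, 255).astype(np.uint8)
    px[mask] = 0
    return HEImage(px, pixel_size_um=he.pixel_size_um, registered=True, zero_fill_mask=mask)


def register_he_to_nlm(
    he: HEImage,
    nlm: MultimodalImage,
    config: Optional[RegistrationConfig] = None,
    precomputed: Optional[sitk.Transform] = None,
):
    """Full supervised-route registration step.

    Grayscales both modalities, contrast-inverts the H&E grayscale (used as
    the moving image), estimates — or takes as given — the similarity
    transform, and returns ``(RegistrationResult | None, registered HEImage)``
    with the zero-fill mask of the warped support.
    """
    if precomputed is not None:
        return None, apply_transform(he, precomputed, nlm.shape)
    moving = invert_contrast(to_grayscale(he.pixels))
    fixed = to_grayscale(nlm.pixels)
    result, tx = estimate_transform(moving, fixed, config)
    return result, apply_transform(he, tx, nlm.shape)
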