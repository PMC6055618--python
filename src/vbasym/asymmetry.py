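"""Per-voxel asymmetry-index (AI) images on a right-hemisphere mask.

At each right-hemisphere voxel of the symmetric template grid, the warped
original segment carries the subject's RIGHT-hemisphere value and the warped
flipped segment carries the LEFT homologue; the asymmetry index is

    AI = (left - right) / (0.5 * (left + right)),

bounded in [-2, 2], positive for leftward asymmetry.  All asymmetry
information is contained in one hemisphere, so analysis is restricted to the
right hemisphere with a binary mask.  AI images are smoothed with a
mask-normalized Gaussian kernel so that a constant field is a fixed point and
magnitudes are not diluted at the hemisphere boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_core import GreyMatterVolume, world_x_coords
from .registration import SymmetricTemplate
from .synthetic import fwhm_to_sigma

__all__ = ["HemisphereMask", "AIImage", "make_right_hemisphere_mask", "compute_ai", "smooth_ai"]


@dataclass
class HemisphereMask:
    """Binary right-hemisphere mask in template space (world x > 0 only)."""

    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.mask.any():
            raise ValueError("empty mask")
        flipped = self.mask[::-1, :, :]
        if (self.mask & flipped).any():
            raise ValueError("mask overlaps its own mirror (includes midline or left-hemisphere voxels)")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]


@dataclass
class AIImage:
    """Per-voxel AI on the mask, zero outside; values in [-2, 2]."""

    data: np.ndarray
    mask: HemisphereMask
    subject_id: str = ""
    smoothed_fwhm_mm: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != self.mask.shape:
            raise ValueError("AI grid does not match mask grid")
        vals = self.data[self.mask.mask]
        if (np.abs(vals) > 2.0 + 1e-9).any():
            raise ValueError("AI values outside [-2, 2]")
        if np.abs(self.data[~self.mask.mask]).max(initial=0.0) > 0:
            raise ValueError("AI must be exactly 0 outside the mask")

    def masked_values(self) -> np.ndarray:
        return self.data[self.mask.mask]


def make_right_hemisphere_mask(
    template: SymmetricTemplate | GreyMatterVolume, gm_threshold: float
) -> HemisphereMask:
    """Voxels with world x > 0 and template grey matter above threshold;
    the midline column x = 0 is excluded."""
    vol = template.template if isinstance(template, SymmetricTemplate) else template
    x = world_x_coords(vol.shape, vol.affine)
    dx = abs(vol.affine[0, 0])
    mask = (x > 1e-9 * dx) & (vol.data > gm_threshold)
    if not mask.any():
        raise ValueError("empty mask: grey-matter threshold too high")
    return HemisphereMask(mask, vol.affine.copy())


def compute_ai(
    warped: GreyMatterVolume,
    warped_flipped: GreyMatterVolume,
    mask: HemisphereMask,
    eps: float = 1e-6,
    subject_id: str = "",
) -> AIImage:
    """AI = (left - right) / (0.5 (left + right)) per masked voxel.

    ``warped`` supplies the right-hemisphere value, ``warped_flipped`` the
    left homologue.  Voxels whose mean tissue 0.5 (left + right) falls below
    ``eps`` carry no asymmetry evidence and are set to 0.
    """
    if warped.shape != mask.shape or warped_flipped.shape != mask.shape:
        raise ValueError("volumes and mask must share one grid")
    if (warped.data < 0).any() or (warped_flipped.data < 0).any():
        raise ValueError("inputs must be non-negative")
    left = warped_flipped.data
    right = warped.data
    denom = 0.5 * (left + right)
    with np.errstate(divide="ignore", invalid="ignore"):
        ai = np.where(denom >= eps, (left - right) / np.where(denom > 0, denom, 1.0), 0.0)
    ai = np.clip(ai, -2.0, 2.0)
    ai[~mask.mask] = 0.0
    return AIImage(ai, mask, subject_id=subject_id, smoothed_fwhm_mm=0.0)


def smooth_ai(ai: AIImage, mask: HemisphereMask, fwhm_mm: float) -> AIImage:
    """Mask-normalized isotropic Gaussian smoothing.

    Smooths ai*mask and the mask separately and divides, then re-zeros outside
    the mask; a constant AI field is unchanged and the [-2, 2] bound is
    preserved (the result is a convex combination of masked values).
    fwhm = 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be >= 0")
    if fwhm_mm == 0:
        return AIImage(ai.data.copy(), mask, ai.subject_id, 0.0)
    vs = np.sqrt((mask.affine[:3, :3] ** 2).sum(axis=0))
    sigma_vox = [fwhm_to_sigma(fwhm_mm) / v for v in vs]
    m = mask.mask.astype(np.float64)
    num = ndimage.gaussian_filter(ai.data * m, sigma_vox, mode="constant")
    den = ndimage.gaussian_filter(m, sigma_vox, mode="constant")
    out = np.zeros_like(ai.data)
    inside = mask.mask & (den > 1e-12)
    out[inside] = num[inside] / den[inside]
    out = np.clip(out, -2.0, 2.0)
    return AIImage(out, mask, ai.subject_id, fwhm_mm)
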