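"""Applicator removal from the brachytherapy planning CT.

The applicator is present only in the reference (brachytherapy) frame, so it
cannot be matched by any registration of the applicator-free external-beam CT.
Before registration the applicator voxels are therefore in-painted: each is
replaced by a random HU value drawn uniformly within ±200 HU of the mean HU of
the surrounding tissue, and the replaced area is then blurred with a Gaussian
filter so the patch blends into its neighbourhood. Voxels outside a one-voxel
dilation of the applicator mask are left bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

from .core import ImageVolume, StructureMask


@dataclass(frozen=True)
class InpaintParams:
    """In-painting knobs.

    hu_halfwidth: half-width of the uniform HU band around the ring mean (HU).
    ring_width_voxels: width of the dilation ring defining "surrounding tissue".
    blur_sigma_mm: Gaussian blur width applied to the replaced area (mm).
    seed: RNG seed; fixed seed gives a bit-reproducible volume.
    """

    hu_halfwidth: float = 200.0
    ring_width_voxels: int = 2
    blur_sigma_mm: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.hu_halfwidth < 0:
            raise ValueError("hu_halfwidth must be >= 0")
        if self.ring_width_voxels < 1:
            raise ValueError("ring_width_voxels must be >= 1")
        if self.blur_sigma_mm < 0:
            raise ValueError("blur_sigma_mm must be >= 0")


def _ball(r: int) -> np.ndarray:
    """Voxel-unit Euclidean ball structuring element of radius r."""
    ax = np.arange(-r, r + 1)
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    return z * z + y * y + x * x <= r * r + 1e-9


def dilate_mask(mask: StructureMask, r_voxels: int) -> StructureMask:
    """Binary dilation with an axis-aligned ball of radius ``r_voxels``."""
    if r_voxels < 1:
        raise ValueError("dilation radius must be >= 1")
    dilated = binary_dilation(mask.mask, structure=_ball(int(r_voxels)))
    return StructureMask(mask.name, dilated, mask.spacing, mask.origin)


def replace_applicator(
    ct: ImageVolume, applicator_mask: StructureMask, params: InpaintParams = InpaintParams()
) -> ImageVolume:
    """In-paint the applicator region of a CT.

    Steps: (1) the mean HU ``m`` over the ring of surrounding tissue (a
    ``ring_width_voxels`` dilation of the mask, minus the mask) is computed;
    (2) every masked voxel is replaced by an independent uniform draw from
    ``[m - hu_halfwidth, m + hu_halfwidth]``; (3) the volume is Gaussian-blurred
    with ``blur_sigma_mm`` and the blurred values are written back only inside a
    one-voxel dilation of the mask. Everything outside that dilation is returned
    bit-identical to the input.
    """
    if not ct.geometry.close_to(applicator_mask.geometry) or ct.shape != applicator_mask.mask.shape:
        raise ValueError("applicator mask must live on the CT geometry")
    if applicator_mask.is_empty:
        raise ValueError("applicator mask is empty; nothing to in-paint")
    ring = dilate_mask(applicator_mask, params.ring_width_voxels).mask & ~applicator_mask.mask
    if not ring.any():
        raise ValueError("surrounding-tissue ring is empty (mask covers the whole volume)")

    m = float(ct.data[ring].mean())
    rng = np.random.default_rng(params.seed)
    out = ct.data.copy()
    out[applicator_mask.mask] = rng.uniform(
        m - params.hu_halfwidth, m + params.hu_halfwidth, size=applicator_mask.voxel_count()
    )

    if params.blur_sigma_mm > 0:
        sigma_vox = [params.blur_sigma_mm / s for s in ct.spacing]
        blurred = gaussian_filter(out, sigma=sigma_vox)
        region = dilate_mask(applicator_mask, 1).mask
        out[region] = blurred[region]
    return ImageVolume(out, ct.spacing, ct.origin)
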