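"""Threshold segmentation: 40%-of-maximum region growing for hot targets and
the below-threshold background mask that isolates cold rods."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import ImageVolume, Mask

DEFAULT_FRACTION = 0.40
DEFAULT_VOLUME_CAP = 5.0

_STRUCT_6 = ndimage.generate_binary_structure(3, 1)   # faces only
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)   # in-plane edges


@dataclass
class SegmentationResult:
    mask: Mask
    threshold_value: float
    max_value: float
    failed: bool = False
    failure_reason: str = "none"  # none | leak_to_boundary | volume_cap_exceeded | empty

    @property
    def volume_ml(self) -> float:
        return self.mask.volume_ml


def region_grow(
    volume: ImageVolume,
    seed: tuple[int, int, int],
    search_region: Mask,
    fraction: float = DEFAULT_FRACTION,
    volume_cap: float = DEFAULT_VOLUME_CAP,
    reference_volume_ml: float | None = None,
) -> SegmentationResult:
    """Grow a 6-connected region from ``seed`` including voxels whose
    intensity is >= ``fraction`` x (maximum inside ``search_region``).

    The regional (not global) maximum defines the threshold, which keeps the
    segmentation of one target independent of hotter neighbours.  Failure
    modes: ``empty`` if the seed itself is below threshold,
    ``leak_to_boundary`` if the grown region reaches the search-region
    boundary, ``volume_cap_exceeded`` if it exceeds ``volume_cap`` times the
    reference ROI volume (checked only when that volume is supplied).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    region = search_region.voxels
    seed = tuple(int(c) for c in seed)
    if not region[seed]:
        raise ValueError(f"seed {seed} lies outside the search region")
    max_value = float(volume.voxels[region].max())
    threshold = fraction * max_value
    empty = Mask(np.zeros(volume.shape, dtype=bool), volume.spacing, volume.origin)

    above = region & (volume.voxels >= threshold)
    if not above[seed]:
        return SegmentationResult(empty, threshold, max_value, True, "empty")

    labels, _ = ndimage.label(above, structure=_STRUCT_6)
    comp = labels == labels[seed]

    # boundary = search-region voxels adjacent to its outside (grid edge counts)
    eroded = ndimage.binary_erosion(region, structure=_STRUCT_6, border_value=0)
    if (comp & region & ~eroded).any():
        return SegmentationResult(empty, threshold, max_value, True, "leak_to_boundary")

    vol_ml = comp.sum() * volume.voxel_volume_ml
    if reference_volume_ml is not None and vol_ml > volume_cap * reference_volume_ml:
        return SegmentationResult(empty, threshold, max_value, True, "volume_cap_exceeded")

    mask = Mask(comp, volume.spacing, volume.origin)
    return SegmentationResult(mask, threshold, max_value, False, "none")


def rod_background_mask(
    volume: ImageVolume, triangle: Mask, fraction: float = DEFAULT_FRACTION
) -> Mask:
    """Voxels of ``triangle`` strictly below ``fraction`` x the slice maximum.

    In the rod phantom the radioactive background is hot and the solid rods
    are cold, so the below-threshold voxels are the rods.  The maximum is
    evaluated per slice: slices at different axial positions may differ in
    intensity and must not share a threshold.
    """
    tri = triangle.voxels
    if not tri.any():
        raise ValueError("triangle mask is empty")
    out = np.zeros_like(tri)
    for iz in np.flatnonzero(tri.any(axis=(0, 1))):
        sl = tri[:, :, iz]
        m = volume.voxels[:, :, iz][sl].max()
        out[:, :, iz] = sl & (volume.voxels[:, :, iz] < fraction * m)
    return Mask(out, triangle.spacing, triangle.origin)


def slice_rod_components(
    volume: ImageVolume,
    triangle: Mask,
    iz: int,
    fraction: float = DEFAULT_FRACTION,
    min_component_voxels: int = 1,
) -> int:
    """Number of 4-connected cold components on one slice of a triangle."""
    sl = triangle.voxels[:, :, iz]
    if not sl.any():
        raise ValueError(f"triangle empty on slice {iz}")
    m = volume.voxels[:, :, iz][sl].max()
    cold = sl & (volume.voxels[:, :, iz] < fraction * m)
    labels, n = ndimage.label(cold, structure=_STRUCT_4)
    if min_component_voxels <= 1:
        return int(n)
    sizes = np.bincount(labels.ravel())[1:]
    return int((sizes >= min_component_voxels).sum())
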