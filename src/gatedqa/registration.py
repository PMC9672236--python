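"""Propagation of reference segmentations onto motion-compensated images.

The motion platform translates the phantom strictly along the
superior-inferior (z) axis, so registration reduces to a 1D z-translation
estimated by cross-correlating the axial intensity profiles of the two
images.  Reference ROIs drawn on the static image are translated by that
shift, dilated into a search region, and seeded at the local intensity
maximum (hot targets) or used directly (cold-rod triangles).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import ImageVolume, Mask, RoiSpec, voxelize_roi

DEFAULT_MARGIN_MM = 15.0  # > half the largest peak-to-peak motion (28 mm)
PROFILE_STEP_MM = 0.5


@dataclass
class PropagatedRoi:
    source_label: str
    target_image_id: str
    roi: RoiSpec            # reference ROI translated onto the moving image
    search_region: Mask
    seed: tuple[int, int, int] | None
    shift_mm: float


def _axial_profile(volume: ImageVolume, z_grid: np.ndarray) -> np.ndarray:
    prof = volume.voxels.mean(axis=(0, 1))
    z = volume.axis_coords(2)
    return np.interp(z_grid, z, prof, left=0.0, right=0.0)


def estimate_axial_shift(
    reference: ImageVolume,
    moving: ImageVolume,
    max_shift_mm: float = 40.0,
    step_mm: float = PROFILE_STEP_MM,
) -> float:
    """z-translation (mm) aligning ``moving`` onto ``reference``.

    If ``moving`` equals ``reference`` shifted by +s mm, the returned value
    is -s.  The estimate scans shifts at ``step_mm`` resolution maximizing
    the cross-correlation of the mean-subtracted axial profiles.
    """
    z_lo = min(reference.axis_coords(2)[0], moving.axis_coords(2)[0]) - max_shift_mm
    z_hi = max(reference.axis_coords(2)[-1], moving.axis_coords(2)[-1]) + max_shift_mm
    # flatness is judged on the raw in-volume profile, before zero padding
    for name, vol in (("reference", reference), ("moving", moving)):
        raw = vol.voxels.mean(axis=(0, 1))
        if raw.std() <= 1e-12 * max(abs(raw).max(), 1.0):
            raise ValueError(f"no structure to register: {name} profile is flat")
    z_grid = np.arange(z_lo, z_hi + step_mm, step_mm)
    p_ref = _axial_profile(reference, z_grid)
    p_mov = _axial_profile(moving, z_grid)
    p_ref = p_ref - p_ref.mean()
    p_mov = p_mov - p_mov.mean()
    n_lag = int(round(max_shift_mm / step_mm))
    lags = np.arange(-n_lag, n_lag + 1)
    scores = np.array(
        [np.dot(p_ref, np.roll(p_mov, -lag)) for lag in lags]
    )
    best = lags[int(np.argmax(scores))]
    # moving(z) = reference(z - s) correlates best at lag s; the translation
    # aligning moving onto reference is -s
    return float(-best * step_mm)


def propagate_roi(
    roi: RoiSpec,
    reference: ImageVolume,
    moving: ImageVolume,
    margin: float = DEFAULT_MARGIN_MM,
    target_image_id: str = "",
    shift_mm: float | None = None,
) -> PropagatedRoi:
    """Generate the search region and seed for ``roi`` on ``moving``.

    The ROI center is translated by the estimated axial shift (negated,
    since the shift aligns moving onto reference); spheres and cylinders
    are inflated by ``margin`` mm into a search region whose intensity
    maximum seeds the region growing.  Triangle prisms (cold rods in a hot
    background) propagate geometrically with no dilation and no seed.
    """
    if shift_mm is None:
        shift_mm = estimate_axial_shift(reference, moving)
    dz = -shift_mm  # ROI follows the feature, opposite to the aligning shift
    moved = roi.translated_z(dz)
    if roi.kind == "triangle_prism":
        region = voxelize_roi(moved, moving)
        return PropagatedRoi(
            source_label=roi.label,
            target_image_id=target_image_id,
            roi=moved,
            search_region=region,
            seed=None,
            shift_mm=shift_mm,
        )
    search = moved.inflated(margin) if margin > 0 else moved
    region = voxelize_roi(search, moving)  # raises if entirely outside grid
    inside = np.argwhere(region.voxels)
    vals = moving.voxels[region.voxels]
    seed = tuple(int(c) for c in inside[int(np.argmax(vals))])
    return PropagatedRoi(
        source_label=roi.label,
        target_image_id=target_image_id,
        roi=moved,
        search_region=region,
        seed=seed,
        shift_mm=shift_mm,
    )
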