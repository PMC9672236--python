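"""Recovery-coefficient metrics: volume, activity concentration, spatial
resolution (cold-rod counting), plus the background-noise figure.

Every measurement is an ``RcRecord``: the ratio of a quantity on a
motion-compensated image to the same quantity on the static reference
(ideal value 1).  A failed volume segmentation is reported with the
sentinel RC = 5, the conventional marker of gross volume overestimation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .imaging import ImageVolume, Mask, RoiSpec, decay_factor, voxelize_roi, F18_HALF_LIFE_S
from .segmentation import SegmentationResult, slice_rod_components, rod_background_mask

VOLUME_FAILURE_RC = 5.0
DISTINGUISHED_FRACTION = 0.75
NOISE_VOI_ML = 30.0


@dataclass
class RcRecord:
    analysis: str          # volume | concentration | resolution
    protocol_id: str
    pattern_id: str
    target_id: str
    static_value: float
    moving_value: float
    rc: float
    failed: bool = False
    phase: int | None = None

    def as_row(self) -> dict:
        return {
            "analysis": self.analysis,
            "protocol": self.protocol_id,
            "pattern": self.pattern_id,
            "target": self.target_id,
            "phase": -1 if self.phase is None else self.phase,
            "static_value": self.static_value,
            "moving_value": self.moving_value,
            "rc": self.rc,
            "failed": int(self.failed),
        }


@dataclass
class SectorResult:
    rod_diameter: float
    rods_total: int
    rods_detected: int
    distinguished: bool
    contrast: float
    segmentation_failed: bool = False


def mask_volume(mask: Mask) -> float:
    """Segmented volume in ml (voxel count x voxel volume)."""
    return mask.volume_ml


def volume_rc(
    moving: SegmentationResult,
    static: SegmentationResult,
    protocol_id: str = "",
    pattern_id: str = "",
    target_id: str = "",
    phase: int | None = None,
) -> RcRecord:
    """RC = V_mov / V_static; a failed moving segmentation yields RC = 5."""
    if static.failed:
        raise ValueError(
            f"static reference segmentation failed ({static.failure_reason})"
        )
    v_static = static.volume_ml
    if moving.failed:
        return RcRecord(
            "volume", protocol_id, pattern_id, target_id,
            v_static, moving.volume_ml, VOLUME_FAILURE_RC, failed=True, phase=phase,
        )
    return RcRecord(
        "volume", protocol_id, pattern_id, target_id,
        v_static, moving.volume_ml, moving.volume_ml / v_static, phase=phase,
    )


def mean_concentration(volume: ImageVolume, mask: Mask) -> float:
    """Mean activity concentration (Bq/ml) under a mask."""
    if not mask.voxels.any():
        raise ValueError("mask is empty")
    return float(volume.voxels[mask.voxels].mean())


def concentration_rc(
    c_moving: float,
    c_static: float,
    delta_t: float = 0.0,
    half_life: float = F18_HALF_LIFE_S,
    protocol_id: str = "",
    pattern_id: str = "",
    target_id: str = "",
    phase: int | None = None,
) -> RcRecord:
    """Decay-compensated RC = C_mov * 2^(dt/T1/2) / C_static, with dt the
    moving-minus-static acquisition time."""
    if c_static <= 0:
        raise ValueError("static concentration must be > 0")
    rc = c_moving * decay_factor(delta_t, half_life) / c_static
    return RcRecord(
        "concentration", protocol_id, pattern_id, target_id,
        c_static, c_moving, rc, phase=phase,
    )


def count_rods(
    volume: ImageVolume,
    triangle: Mask,
    fraction: float = 0.40,
    min_component_voxels: int = 1,
) -> int:
    """Rods detected in a sector: per analysed slice, cold (< fraction x slice
    max) 4-connected components are counted; the sector count is the median
    over slices, rounded half up."""
    slices = np.flatnonzero(triangle.voxels.any(axis=(0, 1)))
    if len(slices) == 0:
        raise ValueError("triangle mask is empty")
    counts = [
        slice_rod_components(volume, triangle, int(iz), fraction, min_component_voxels)
        for iz in slices
    ]
    return int(math.floor(float(np.median(counts)) + 0.5))


def classify_sector(rods_detected: int, rods_total: int) -> bool:
    """A sector is distinguished when at least 75% of its rods are found."""
    if rods_total <= 0:
        raise ValueError("rods_total must be > 0")
    return rods_detected / rods_total >= DISTINGUISHED_FRACTION


def sector_contrast(
    volume: ImageVolume, triangle: Mask, fraction: float = 0.40
) -> float:
    """Contrast = C_FDG / C_Bg: mean of above-threshold (hot background)
    voxels over mean of below-threshold (rod) voxels, thresholds per slice."""
    cold = rod_background_mask(volume, triangle, fraction)
    hot = triangle.voxels & ~cold.voxels
    if not cold.voxels.any() or not hot.any():
        raise ValueError("contrast undefined: sector has no cold/hot partition")
    c_bg = volume.voxels[cold.voxels].mean()
    c_fdg = volume.voxels[hot].mean()
    if c_bg == 0:
        return float("inf")
    return float(c_fdg / c_bg)


def background_noise(
    volume: ImageVolume, background_voi: RoiSpec | Mask, voi_ml: float = NOISE_VOI_ML
) -> float:
    """Noise figure: standard deviation (Bq/ml) of the voxels in a ~30 ml
    VOI placed in the uniform phantom background."""
    mask = (
        background_voi
        if isinstance(background_voi, Mask)
        else voxelize_roi(background_voi, volume)
    )
    vol = mask.volume_ml
    if abs(vol - voi_ml) > 0.10 * voi_ml:
        raise ValueError(
            f"background VOI volume {vol:.1f} ml deviates more than 10% from {voi_ml} ml"
        )
    return float(volume.voxels[mask.voxels].std(ddof=1))


def collapse_phases(records: list[RcRecord]) -> list[RcRecord]:
    """Summarize retrospective protocols: the protocol's RC per target is the
    mean RC over its breathing phases (failed-phase sentinels included)."""
    from collections import defaultdict

    groups: dict[tuple, list[RcRecord]] = defaultdict(list)
    for r in records:
        groups[(r.analysis, r.protocol_id, r.pattern_id, r.target_id)].append(r)
    out = []
    for (analysis, proto, pattern, target), recs in groups.items():
        if len(recs) == 1 and recs[0].phase is None:
            out.append(recs[0])
            continue
        rc = float(np.mean([r.rc for r in recs]))
        out.append(
            RcRecord(
                analysis, proto, pattern, target,
                recs[0].static_value,
                float(np.mean([r.moving_value for r in recs])),
                rc,
                failed=all(r.failed for r in recs),
            )
        )
    return out
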