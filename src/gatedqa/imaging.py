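"""Image containers, NIfTI/DICOM I/O, ROI voxelization, grid resampling and decay.

Conventions
-----------
Volumes are indexed ``voxels[ix, iy, iz]`` with ``x`` = left-right,
``y`` = anterior-posterior and ``z`` = superior-inferior; ``z`` is the
respiratory-motion axis.  All geometry is expressed in physical millimetres.
``origin`` is the physical position of the *center* of voxel ``(0, 0, 0)``;
the value of voxel ``i`` lives at ``origin + i * spacing``.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import nibabel as nib

#: F-18 half-life in seconds (default isotope; override via config/half_life).
F18_HALF_LIFE_S = 6586.2

AXIS_LABELS = ("x:left-right", "y:anterior-posterior", "z:superior-inferior")


@dataclass
class ImageVolume:
    """A 3D activity-concentration image (Bq/ml) on a regular grid."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    acquisition_time: float = 0.0
    axis_labels: tuple[str, str, str] = AXIS_LABELS

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.voxels.ndim}")
        if min(self.voxels.shape) < 1:
            raise ValueError("grid must have at least one voxel per axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.isfinite(self.voxels).all():
            raise ValueError("voxel values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_ml(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        n = self.voxels.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def same_grid(self, other: "ImageVolume | Mask", tol: float = 1e-6) -> bool:
        return (
            self.voxels.shape == other.voxels.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def with_voxels(self, voxels: np.ndarray) -> "ImageVolume":
        return replace(self, voxels=voxels)


@dataclass
class Mask:
    """Binary mask aligned to an :class:`ImageVolume` grid."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be a 3D grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @classmethod
    def like(cls, grid: ImageVolume, voxels: np.ndarray) -> "Mask":
        return cls(voxels=voxels, spacing=grid.spacing, origin=grid.origin)

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    @property
    def voxel_volume_ml(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    @property
    def volume_ml(self) -> float:
        return self.count * self.voxel_volume_ml


@dataclass
class RoiSpec:
    """Geometric reference segmentation.

    kinds and parameters (all mm):
      - ``sphere``: ``center`` (x, y, z), ``radius``
      - ``cylinder``: ``center``, ``radius``, ``height``, optional ``axis``
        ('x' | 'y' | 'z', default 'z')
      - ``triangle_prism``: ``vertices`` (three in-plane (x, y) points) plus
        either ``slices`` (z grid indices) or ``z_mm`` (physical z positions,
        mapped to the nearest slice of the target grid)
    """

    kind: str
    params: dict = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "cylinder", "triangle_prism"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        p = self.params
        if self.kind == "sphere":
            if p["radius"] <= 0:
                raise ValueError("sphere radius must be > 0")
        elif self.kind == "cylinder":
            if p["radius"] <= 0 or p["height"] <= 0:
                raise ValueError("cylinder radius/height must be > 0")
        else:
            v = np.asarray(p["vertices"], dtype=float)
            if v.shape != (3, 2):
                raise ValueError("triangle_prism needs three (x, y) vertices")
            area2 = abs(
                (v[1, 0] - v[0, 0]) * (v[2, 1] - v[0, 1])
                - (v[2, 0] - v[0, 0]) * (v[1, 1] - v[0, 1])
            )
            if area2 <= 1e-9:
                raise ValueError("triangle vertices are collinear")
            if "slices" not in p and "z_mm" not in p:
                raise ValueError("triangle_prism needs 'slices' or 'z_mm'")

    def translated_z(self, dz: float) -> "RoiSpec":
        """Return a copy shifted by ``dz`` mm along the motion (z) axis."""
        p = dict(self.params)
        if self.kind in ("sphere", "cylinder"):
            cx, cy, cz = p["center"]
            p["center"] = (cx, cy, cz + dz)
        else:
            if "z_mm" in p:
                p["z_mm"] = [z + dz for z in p["z_mm"]]
            elif abs(dz) > 1e-12:
                raise ValueError(
                    "cannot translate an index-based triangle_prism; "
                    "define it with 'z_mm' for propagation"
                )
        return RoiSpec(kind=self.kind, params=p, label=self.label)

    def inflated(self, margin: float) -> "RoiSpec":
        """Grow the ROI isotropically by ``margin`` mm (search regions)."""
        if margin < 0:
            raise ValueError("margin must be >= 0")
        p = dict(self.params)
        if self.kind == "sphere":
            p["radius"] = p["radius"] + margin
        elif self.kind == "cylinder":
            p["radius"] = p["radius"] + margin
            p["height"] = p["height"] + 2 * margin
        else:
            raise ValueError("triangle_prism ROIs are used without inflation")
        return RoiSpec(kind=self.kind, params=p, label=self.label)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": _jsonable(self.params), "label": self.label}

    @classmethod
    def from_dict(cls, d: dict) -> "RoiSpec":
        return cls(kind=d["kind"], params=dict(d["params"]), label=d.get("label", ""))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in np.asarray(obj).tolist()] if isinstance(obj, np.ndarray) else [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TIME_TAG = "tacq="


def write_volume(volume: ImageVolume, path: str) -> None:
    """Write a volume (or mask) as NIfTI-1 with a diagonal affine."""
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    data = volume.voxels
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, affine)
    img.header["descrip"] = f"{_TIME_TAG}{volume.acquisition_time:.3f}".encode()
    nib.save(img, path)


def write_mask(mask: Mask, path: str) -> None:
    affine = np.diag(list(mask.spacing) + [1.0])
    affine[:3, 3] = mask.origin
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), affine), path)


def read_volume(path: str, format: str | None = None) -> ImageVolume:
    """Read a 3D volume from NIfTI (.nii/.nii.gz) or a DICOM series directory.

    Spacing and origin come from the header; the acquisition timestamp is
    taken from the header when present and defaults to 0 s.
    """
    if format is None:
        format = "dicom_dir" if os.path.isdir(path) else "nifti"
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom_dir":
        return _read_dicom_dir(path)
    raise ValueError(f"unknown format {format!r}")


def _read_nifti(path: str) -> ImageVolume:
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got shape {data.shape}; "
            "4D (dynamic) NIfTI is not supported"
        )
    affine = img.affine
    rot = affine[:3, :3]
    spacing = tuple(np.sqrt((rot ** 2).sum(axis=0)))
    off = rot - np.diag(np.diag(rot))
    if np.abs(off).max() > 1e-3 * max(spacing):
        raise ValueError(f"{path}: oblique/rotated affines are not supported")
    origin = tuple(affine[:3, 3])
    t = 0.0
    descrip = img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="ignore")
    if descrip.startswith(_TIME_TAG):
        try:
            t = float(descrip[len(_TIME_TAG):])
        except ValueError:
            pass
    return ImageVolume(voxels=data, spacing=spacing, origin=origin, acquisition_time=t)


def _read_dicom_dir(path: str) -> ImageVolume:
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    series_ids = reader.GetGDCMSeriesIDs(path)
    if not series_ids:
        raise ValueError(f"{path}: no DICOM series found")
    if len(series_ids) > 1:
        raise ValueError(
            f"{path}: directory contains {len(series_ids)} DICOM series "
            f"({', '.join(series_ids)}); split them or pass a single series"
        )
    files = reader.GetGDCMSeriesFileNames(path, series_ids[0])
    reader.SetFileNames(files)
    img = reader.Execute()
    # sitk arrays come back [z, y, x]; transpose to our [x, y, z]
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(float)
    spacing = tuple(img.GetSpacing())
    origin = tuple(img.GetOrigin())
    t = _dicom_acquisition_time(files[0])
    return ImageVolume(voxels=data, spacing=spacing, origin=origin, acquisition_time=t)


def _dicom_acquisition_time(first_file: str) -> float:
    import pydicom

    try:
        ds = pydicom.dcmread(first_file, stop_before_pixels=True)
        raw = getattr(ds, "AcquisitionTime", None)
        if raw:
            raw = str(raw)
            h, m = int(raw[0:2]), int(raw[2:4])
            s = float(raw[4:]) if len(raw) > 4 else 0.0
            return h * 3600 + m * 60 + s
    except Exception:  # pragma: no cover - defensive; header quirks abound
        pass
    return 0.0


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------

def voxelize_roi(roi: RoiSpec, grid: ImageVolume) -> Mask:
    """Rasterize a geometric ROI: a voxel is included iff its center lies
    inside the shape (no partial-volume weighting)."""
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    zs = grid.axis_coords(2)
    p = roi.params
    if roi.kind == "sphere":
        cx, cy, cz = p["center"]
        r2 = p["radius"] ** 2
        d2 = (
            (xs - cx)[:, None, None] ** 2
            + (ys - cy)[None, :, None] ** 2
            + (zs - cz)[None, None, :] ** 2
        )
        m = d2 <= r2
    elif roi.kind == "cylinder":
        cx, cy, cz = p["center"]
        r2 = p["radius"] ** 2
        h2 = p["height"] / 2.0
        axis = p.get("axis", "z")
        if axis == "z":
            inplane = (xs - cx)[:, None, None] ** 2 + (ys - cy)[None, :, None] ** 2
            along = np.abs(zs - cz)[None, None, :]
        elif axis == "y":
            inplane = (xs - cx)[:, None, None] ** 2 + (zs - cz)[None, None, :] ** 2
            along = np.abs(ys - cy)[None, :, None]
        elif axis == "x":
            inplane = (ys - cy)[None, :, None] ** 2 + (zs - cz)[None, None, :] ** 2
            along = np.abs(xs - cx)[:, None, None]
        else:
            raise ValueError(f"unknown cylinder axis {axis!r}")
        m = (inplane <= r2) & (along <= h2)
    else:  # triangle_prism
        from matplotlib.path import Path

        verts = np.asarray(p["vertices"], dtype=float)
        path = Path(verts)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        inplane = path.contains_points(pts, radius=1e-9).reshape(len(xs), len(ys))
        if "slices" in p:
            idx = [int(i) for i in p["slices"]]
        else:
            idx = [int(np.argmin(np.abs(zs - z))) for z in p["z_mm"]]
            # drop physical slices that fall outside the grid extent
            half = grid.spacing[2] / 2.0
            idx = [
                i
                for i, z in zip(idx, p["z_mm"])
                if zs[0] - half <= z <= zs[-1] + half
            ]
        idx = sorted(set(idx))
        if any(i < 0 or i >= len(zs) for i in idx):
            raise ValueError("triangle_prism slice index outside grid")
        m = np.zeros(grid.shape, dtype=bool)
        for i in idx:
            m[:, :, i] = inplane
    if not m.any():
        raise ValueError(f"ROI {roi.label!r} lies entirely outside the grid")
    return Mask.like(grid, m)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to_grid(
    volume: ImageVolume, target_grid: ImageVolume, mode: str = "linear"
) -> ImageVolume:
    """Resample ``volume`` onto the grid of ``target_grid``.

    ``linear`` (intensity images) applies a gaussian anti-alias prefilter
    when downsampling so total activity is conserved; ``nearest`` is for
    label masks.  Voxels outside the source field of view are set to 0.
    """
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown mode {mode!r}")
    from scipy import ndimage

    lo_s = np.array(volume.origin) - np.array(volume.spacing) / 2
    hi_s = lo_s + np.array(volume.spacing) * np.array(volume.shape)
    lo_t = np.array(target_grid.origin) - np.array(target_grid.spacing) / 2
    hi_t = lo_t + np.array(target_grid.spacing) * np.array(target_grid.shape)
    if (np.minimum(hi_s, hi_t) <= np.maximum(lo_s, lo_t)).any():
        raise ValueError("no physical overlap between volume and target grid")

    data = volume.voxels
    if mode == "linear":
        ratio = np.array(target_grid.spacing) / np.array(volume.spacing)
        sigma = 0.5 * np.sqrt(np.maximum(ratio ** 2 - 1.0, 0.0))
        if sigma.max() > 0:
            data = ndimage.gaussian_filter(data, sigma=sigma, mode="nearest")

    coords = [
        (target_grid.axis_coords(ax) - volume.origin[ax]) / volume.spacing[ax]
        for ax in range(3)
    ]
    mesh = np.meshgrid(*coords, indexing="ij")
    out = ndimage.map_coordinates(
        data,
        np.stack([m.ravel() for m in mesh]),
        order=1 if mode == "linear" else 0,
        mode="constant",
        cval=0.0,
    ).reshape(target_grid.shape)
    return ImageVolume(
        voxels=out,
        spacing=target_grid.spacing,
        origin=target_grid.origin,
        acquisition_time=volume.acquisition_time,
    )


# ---------------------------------------------------------------------------
# Decay
# ---------------------------------------------------------------------------

def decay_factor(delta_t: float, half_life: float = F18_HALF_LIFE_S) -> float:
    """Factor multiplying a concentration acquired ``delta_t`` s after the
    reference so it is back-corrected to the reference time: 2^(dt/T1/2)."""
    if half_life <= 0:
        raise ValueError("half_life must be > 0")
    return float(2.0 ** (delta_t / half_life))
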