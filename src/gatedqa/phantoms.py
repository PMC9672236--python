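"""Digital phantoms and the gated-acquisition forward model.

Three classic nuclear-medicine phantoms are modelled digitally:

* a body phantom with six hot spheres (0.52-26.2 ml, 80 kBq/ml in a
  15 kBq/ml background) for volume accuracy,
* an electron-density phantom carrying six refillable cylindrical inserts
  (3 x 33 ml and 3 x 11 ml at 900 kBq/ml) for concentration accuracy,
* a cold-rod phantom (rod diameters 4.8-12.7 mm in a 7 kBq/ml background,
  pitch twice the diameter, six 60-degree sectors) for spatial resolution.

The forward model turns a high-resolution activity map and a displacement
kernel into a gated PET image: weighted z-shifts, isotropic gaussian PSF
(default FWHM 4.7 mm), resampling to the acquisition voxel size (2 mm
static, 4 mm gated) and optional Poisson count noise scaled by the duty
cycle.  It deliberately skips sinogram formation and iterative
reconstruction: kernel convolution is sufficient to exercise every QA
metric at desk scale.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .gating import BreathingWaveform, DisplacementKernel, GatingProtocol, gate
from .imaging import ImageVolume, RoiSpec, resample_to_grid, write_volume

FWHM_TO_SIGMA = 1.0 / 2.3548200450309493

NEMA_SPHERE_VOLUMES_ML = (0.52, 1.15, 2.57, 5.57, 11.49, 26.2)
NEMA_SPHERE_KBQ_ML = 80.0
NEMA_BACKGROUND_KBQ_ML = 15.0
CIRS_INSERT_KBQ_ML = 900.0
CIRS_LARGE_ML = 33.0
CIRS_SMALL_ML = 11.0
JASZCZAK_ROD_DIAMETERS_MM = (4.8, 6.4, 7.9, 9.5, 11.1, 12.7)
JASZCZAK_BACKGROUND_KBQ_ML = 7.0


@dataclass
class Primitive:
    kind: str            # sphere | cylinder | rod_sector
    params: dict
    activity_bq_ml: float
    label: str = ""


@dataclass
class PhantomSpec:
    name: str
    geometry: list[Primitive]
    grid_shape: tuple[int, int, int]
    grid_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    grid_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    reference_rois: list[RoiSpec] = field(default_factory=list)
    noise_voi: RoiSpec | None = None
    truth: dict = field(default_factory=dict)


@dataclass
class AcquisitionSettings:
    psf_fwhm: float = 4.7          # mm, scanner transverse resolution
    voxel_out: float = 4.0         # mm (2 static, 4 gated)
    counts_per_kbq: float = 0.5    # effective sensitivity, counts/(kBq*s) per ml
    acquisition_time: float = 840.0  # s (14 min gated; 660 s static)
    noise: bool = False
    seed: int | None = None
    time_offset_s: float = 0.0     # acquisition start relative to reference
    half_life_s: float = 6586.2


# ---------------------------------------------------------------------------
# Rod-sector layout
# ---------------------------------------------------------------------------

def rod_sector_centers(
    rod_diameter: float,
    angle_start_deg: float,
    angle_end_deg: float,
    inner_radius: float = 12.0,
    outer_radius: float = 80.0,
    pitch: float | None = None,
) -> np.ndarray:
    """Triangular-lattice rod centers filling a 60-degree wedge.

    Pitch defaults to twice the rod diameter (standard cold-rod phantom
    convention).  A rod is kept only when it fits entirely inside the wedge
    (radial and angular clearance of one rod radius)."""
    p = 2.0 * rod_diameter if pitch is None else pitch
    r_rod = rod_diameter / 2.0
    a1 = np.array([p, 0.0])
    a2 = np.array([p / 2.0, p * np.sqrt(3) / 2.0])
    nmax = int(np.ceil(2 * outer_radius / p)) + 2
    centers = []
    mid = np.deg2rad((angle_start_deg + angle_end_deg) / 2.0)
    rot = np.array([[np.cos(mid), -np.sin(mid)], [np.sin(mid), np.cos(mid)]])
    for i in range(-nmax, nmax + 1):
        for j in range(-nmax, nmax + 1):
            c = rot @ (i * a1 + j * a2)
            r = np.hypot(*c)
            if r < inner_radius + r_rod or r > outer_radius - r_rod:
                continue
            ang = np.rad2deg(np.arctan2(c[1], c[0])) % 360.0
            clearance = np.rad2deg(np.arcsin(min(1.0, r_rod / r)))
            lo = (angle_start_deg + clearance) % 360.0
            hi = (angle_end_deg - clearance) % 360.0
            inside = lo <= ang <= hi if lo <= hi else (ang >= lo or ang <= hi)
            if inside:
                centers.append(c)
    return np.array(centers) if centers else np.empty((0, 2))


# ---------------------------------------------------------------------------
# Phantom factories
# ---------------------------------------------------------------------------

def _sphere_radius_mm(volume_ml: float) -> float:
    return (3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


def nema_phantom(spacing: float = 1.0) -> PhantomSpec:
    """Body phantom: six hot spheres on a 114.4 mm circle in a warm
    cylindrical background, plus a 30 ml central background VOI."""
    shape = tuple(int(round(e / spacing)) for e in (180.0, 180.0, 160.0))
    origin = tuple(-(n - 1) * spacing / 2.0 for n in shape)
    geometry = [
        Primitive(
            "cylinder",
            {"center": (0.0, 0.0, 0.0), "radius": 82.0, "height": 104.0, "axis": "z"},
            NEMA_BACKGROUND_KBQ_ML * 1000.0,
            label="background",
        )
    ]
    rois = []
    ring = 114.4 / 2.0
    for k, vol in enumerate(NEMA_SPHERE_VOLUMES_ML):
        ang = np.deg2rad(60.0 * k)
        center = (ring * np.cos(ang), ring * np.sin(ang), 0.0)
        radius = _sphere_radius_mm(vol)
        label = f"sphere_{vol:g}ml"
        geometry.append(
            Primitive("sphere", {"center": center, "radius": radius},
                      NEMA_SPHERE_KBQ_ML * 1000.0, label=label)
        )
        rois.append(RoiSpec("sphere", {"center": center, "radius": radius}, label=label))
    noise_voi = RoiSpec(
        "sphere",
        {"center": (0.0, 0.0, 0.0), "radius": (3.0 * 30.0 * 1000.0 / (4 * np.pi)) ** (1 / 3)},
        label="noise_voi_30ml",
    )
    truth = {
        "sphere_volumes_ml": dict(zip([r.label for r in rois], NEMA_SPHERE_VOLUMES_ML)),
        "sphere_kbq_ml": NEMA_SPHERE_KBQ_ML,
        "background_kbq_ml": NEMA_BACKGROUND_KBQ_ML,
    }
    return PhantomSpec(
        name="nema", geometry=geometry, grid_shape=shape,
        grid_spacing=(spacing,) * 3, grid_origin=origin,
        reference_rois=rois, noise_voi=noise_voi, truth=truth,
    )


def cirs_phantom(spacing: float = 1.0) -> PhantomSpec:
    """Electron-density phantom: six refillable 30 mm-diameter cylindrical
    inserts (three 33 ml "TL", three 11 ml "TS") at 900 kBq/ml in a cold
    body.  Reference ROIs are equal-diameter cylinders inside each insert."""
    shape = tuple(int(round(e / spacing)) for e in (170.0, 170.0, 120.0))
    origin = tuple(-(n - 1) * spacing / 2.0 for n in shape)
    geometry = []
    rois = []
    ring = 55.0
    r_insert = 15.0
    for k in range(6):
        large = k % 2 == 0
        vol = CIRS_LARGE_ML if large else CIRS_SMALL_ML
        height = vol * 1000.0 / (np.pi * r_insert ** 2)
        ang = np.deg2rad(60.0 * k)
        center = (ring * np.cos(ang), ring * np.sin(ang), 0.0)
        label = f"{'TL' if large else 'TS'}{k // 2 + 1}"
        geometry.append(
            Primitive("cylinder",
                      {"center": center, "radius": r_insert, "height": height, "axis": "z"},
                      CIRS_INSERT_KBQ_ML * 1000.0, label=label)
        )
        # measurement ROI: same diameter for all inserts, shorter than the insert
        rois.append(
            RoiSpec("cylinder",
                    {"center": center, "radius": 9.0, "height": min(8.0, height * 0.5),
                     "axis": "z"},
                    label=label)
        )
    truth = {
        "insert_kbq_ml": CIRS_INSERT_KBQ_ML,
        "insert_volumes_ml": {r.label: (CIRS_LARGE_ML if r.label.startswith("TL") else CIRS_SMALL_ML) for r in rois},
    }
    return PhantomSpec(
        name="cirs", geometry=geometry, grid_shape=shape,
        grid_spacing=(spacing,) * 3, grid_origin=origin,
        reference_rois=rois, truth=truth,
    )


def jaszczak_phantom(
    spacing: float = 1.0,
    inner_radius: float = 12.0,
    outer_radius: float = 80.0,
    n_analysis_slices: int = 3,
) -> PhantomSpec:
    """Cold-rod phantom: six 60-degree sectors of solid (cold) rods in a
    7 kBq/ml cylindrical background.  Reference ROIs are triangles covering
    each sector on three central slices."""
    shape = tuple(int(round(e / spacing)) for e in (200.0, 200.0, 100.0))
    origin = tuple(-(n - 1) * spacing / 2.0 for n in shape)
    geometry = [
        Primitive("cylinder",
                  {"center": (0.0, 0.0, 0.0), "radius": 95.0, "height": 56.0, "axis": "z"},
                  JASZCZAK_BACKGROUND_KBQ_ML * 1000.0, label="background")
    ]
    rois = []
    rod_counts = {}
    half = (n_analysis_slices - 1) / 2.0
    z_slices = [(-half + i) * 6.0 for i in range(n_analysis_slices)]
    for k, d in enumerate(JASZCZAK_ROD_DIAMETERS_MM):
        a0, a1 = 60.0 * k, 60.0 * (k + 1)
        centers = rod_sector_centers(d, a0, a1, inner_radius, outer_radius)
        label = f"sector_{d:g}mm"
        geometry.append(
            Primitive("rod_sector",
                      {"rod_diameter": d, "centers": centers.tolist(),
                       "height": 56.0, "center_z": 0.0},
                      0.0, label=label)
        )
        rod_counts[label] = len(centers)
        # triangle covering the wedge: apex near the center, corners past the rim
        rim = outer_radius + 6.0
        v0 = (0.0, 0.0)
        v1 = (rim * np.cos(np.deg2rad(a0)), rim * np.sin(np.deg2rad(a0)))
        v2 = (rim * np.cos(np.deg2rad(a1)), rim * np.sin(np.deg2rad(a1)))
        rois.append(
            RoiSpec("triangle_prism",
                    {"vertices": [v0, v1, v2], "z_mm": list(z_slices)},
                    label=label)
        )
    truth = {
        "rod_counts": rod_counts,
        "rod_diameters_mm": {f"sector_{d:g}mm": d for d in JASZCZAK_ROD_DIAMETERS_MM},
        "background_kbq_ml": JASZCZAK_BACKGROUND_KBQ_ML,
    }
    return PhantomSpec(
        name="jaszczak", geometry=geometry, grid_shape=shape,
        grid_spacing=(spacing,) * 3, grid_origin=origin,
        reference_rois=rois, truth=truth,
    )


# ---------------------------------------------------------------------------
# Rasterization and forward model
# ---------------------------------------------------------------------------

def build_phantom(spec: PhantomSpec) -> ImageVolume:
    """Rasterize a phantom spec into a noise-free activity map (Bq/ml).

    Primitives paint in order; cold rod sectors carve their (zero) activity
    out of the previously painted background."""
    vol = ImageVolume(
        voxels=np.zeros(spec.grid_shape),
        spacing=spec.grid_spacing,
        origin=spec.grid_origin,
    )
    xs, ys, zs = (vol.axis_coords(i) for i in range(3))
    for prim in spec.geometry:
        p = prim.params
        if prim.kind == "sphere":
            cx, cy, cz = p["center"]
            m = (
                (xs - cx)[:, None, None] ** 2
                + (ys - cy)[None, :, None] ** 2
                + (zs - cz)[None, None, :] ** 2
            ) <= p["radius"] ** 2
        elif prim.kind == "cylinder":
            cx, cy, cz = p["center"]
            m = (
                ((xs - cx)[:, None, None] ** 2 + (ys - cy)[None, :, None] ** 2)
                <= p["radius"] ** 2
            ) & (np.abs(zs - cz)[None, None, :] <= p["height"] / 2.0)
        elif prim.kind == "rod_sector":
            centers = np.asarray(p["centers"], dtype=float)
            r2 = (p["rod_diameter"] / 2.0) ** 2
            inplane = np.zeros((len(xs), len(ys)), dtype=bool)
            for cx, cy in centers:
                inplane |= (
                    (xs - cx)[:, None] ** 2 + (ys - cy)[None, :] ** 2
                ) <= r2
            m = inplane[:, :, None] & (
                np.abs(zs - p.get("center_z", 0.0))[None, None, :]
                <= p["height"] / 2.0
            )
        else:
            raise ValueError(f"unknown primitive kind {prim.kind!r}")
        vol.voxels[m] = prim.activity_bq_ml
    return vol


def _output_grid(activity: ImageVolume, voxel_out: float) -> ImageVolume:
    extent = np.array(activity.shape) * np.array(activity.spacing)
    n_out = np.maximum(1, np.floor(extent / voxel_out).astype(int))
    center = np.array(activity.origin) + (np.array(activity.shape) - 1) * np.array(activity.spacing) / 2.0
    origin = center - (n_out - 1) * voxel_out / 2.0
    return ImageVolume(
        voxels=np.zeros(tuple(n_out)),
        spacing=(voxel_out,) * 3,
        origin=tuple(origin),
    )


def simulate_gated_image(
    activity: ImageVolume,
    kernel: DisplacementKernel,
    settings: AcquisitionSettings,
) -> ImageVolume:
    """Forward-model one gated acquisition.

    blurred = sum_k w_k shift_z(activity, o_k) * PSF, resampled to the
    output voxel size.  With noise on, the expected counts per voxel are
    value(kBq/ml) x voxel volume(ml) x sensitivity x duty cycle x
    acquisition time, Poisson-sampled and converted back to Bq/ml.
    Physical decay over ``time_offset_s`` is applied before sampling and
    the image is stamped with that acquisition time.
    """
    if abs(kernel.weights.sum() - 1.0) > 1e-9:
        raise ValueError("kernel weights must be normalized")
    sz = activity.spacing[2]
    acc = np.zeros_like(activity.voxels)
    n = activity.shape[2]
    for off, wgt in zip(kernel.offsets, kernel.weights):
        if wgt == 0:
            continue
        v = off / sz
        if abs(v - round(v)) < 1e-9:  # whole-voxel shifts: exact slice moves
            v = int(round(v))
            if v == 0:
                acc += wgt * activity.voxels
            elif 0 < v < n:
                acc[:, :, v:] += wgt * activity.voxels[:, :, : n - v]
            elif -n < v < 0:
                acc[:, :, :v] += wgt * activity.voxels[:, :, -v:]
        else:
            acc += wgt * ndimage.shift(
                activity.voxels, (0.0, 0.0, v), order=1, mode="constant", cval=0.0
            )
    if settings.psf_fwhm > 0:
        sigma = settings.psf_fwhm * FWHM_TO_SIGMA
        acc = ndimage.gaussian_filter(
            acc, sigma=[sigma / s for s in activity.spacing], mode="constant"
        )
    moved = activity.with_voxels(acc)
    target = _output_grid(activity, settings.voxel_out)
    out = resample_to_grid(moved, target, mode="linear")
    if settings.time_offset_s:
        out.voxels *= 2.0 ** (-settings.time_offset_s / settings.half_life_s)
    if settings.noise:
        rng = np.random.default_rng(settings.seed)
        scale = (
            out.voxel_volume_ml
            * settings.counts_per_kbq
            * kernel.duty_cycle
            * settings.acquisition_time
            / 1000.0
        )  # Bq/ml -> expected counts
        lam = np.clip(out.voxels, 0.0, None) * scale
        out = out.with_voxels(rng.poisson(lam).astype(float) / scale)
    out.acquisition_time = settings.time_offset_s
    return out


# ---------------------------------------------------------------------------
# Study bundles
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    phantom: PhantomSpec
    static: ImageVolume
    images: dict          # protocol_id -> list[(phase, ImageVolume, duty_cycle)]
    kernels: dict         # protocol_id -> list[DisplacementKernel]
    pattern_id: str
    manifest: dict


def make_study(
    phantom: PhantomSpec,
    waveform: BreathingWaveform,
    protocols: list[GatingProtocol],
    settings: AcquisitionSettings | None = None,
    static_settings: AcquisitionSettings | None = None,
    out_dir: str | None = None,
    seed: int | None = None,
) -> StudyBundle:
    """Simulate one static reference plus one image per protocol (per phase
    for retrospective protocols) and record the ground truth.

    When ``out_dir`` is given, NIfTI images and a ``manifest.json`` holding
    the truth (volumes, concentrations, rod counts, duty cycles, seeds) are
    written there.
    """
    settings = settings or AcquisitionSettings(voxel_out=4.0, acquisition_time=840.0)
    static_settings = static_settings or AcquisitionSettings(
        psf_fwhm=settings.psf_fwhm, voxel_out=2.0, noise=settings.noise,
        counts_per_kbq=settings.counts_per_kbq, acquisition_time=660.0,
        time_offset_s=0.0, half_life_s=settings.half_life_s,
    )
    rng = np.random.default_rng(seed)
    activity = build_phantom(phantom)

    def next_seed() -> int:
        return int(rng.integers(0, 2 ** 31 - 1))

    st_settings = AcquisitionSettings(**{**static_settings.__dict__, "seed": next_seed()})
    static = simulate_gated_image(activity, DisplacementKernel.delta(0.0, 1.0), st_settings)

    images: dict = {}
    kernels: dict = {}
    manifest = {
        "phantom": phantom.name,
        "pattern": waveform.pattern_id,
        "seed": seed,
        "truth": phantom.truth,
        "rois": [r.to_dict() for r in phantom.reference_rois],
        "noise_voi": phantom.noise_voi.to_dict() if phantom.noise_voi else None,
        "protocols": {},
        "files": {"static": "static.nii.gz"},
    }
    for proto in protocols:
        ks = gate(waveform, proto)
        kernels[proto.protocol_id] = ks
        entries = []
        for phase, k in enumerate(ks):
            s = AcquisitionSettings(**{**settings.__dict__, "seed": next_seed()})
            img = simulate_gated_image(activity, k, s)
            entries.append((phase if len(ks) > 1 else None, img, k.duty_cycle))
        images[proto.protocol_id] = entries
        manifest["protocols"][proto.protocol_id] = {
            "kind": proto.kind,
            "duty_cycles": [k.duty_cycle for k in ks],
            "kernel_spread_mm": [k.spread for k in ks],
        }
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        write_volume(static, os.path.join(out_dir, "static.nii.gz"))
        for proto_id, entries in images.items():
            names = []
            for phase, img, _ in entries:
                name = (
                    f"{proto_id}.nii.gz" if phase is None else f"{proto_id}_phase{phase}.nii.gz"
                )
                write_volume(img, os.path.join(out_dir, name))
                names.append(name)
            manifest["files"][proto_id] = names
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)
    return StudyBundle(
        phantom=phantom, static=static, images=images, kernels=kernels,
        pattern_id=waveform.pattern_id, manifest=manifest,
    )
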