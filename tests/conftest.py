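"""Shared fixtures: small synthetic volumes and identity study bundles.

Expensive phantom builds are session-scoped; everything is generated
programmatically at test time.
"""
from __future__ import annotations

import numpy as np
import pytest

import gatedqa as g


def make_volume(shape=(40, 40, 40), spacing=1.0, value=0.0):
    n = np.array(shape)
    origin = tuple(-(n - 1) * spacing / 2.0)
    return g.ImageVolume(
        voxels=np.full(shape, float(value)),
        spacing=(spacing,) * 3,
        origin=origin,
    )


def sphere_image(radius=10.0, value=1.0, background=0.0, shape=(48, 48, 48), spacing=1.0):
    vol = make_volume(shape, spacing, background)
    xs, ys, zs = (vol.axis_coords(i) for i in range(3))
    m = (
        xs[:, None, None] ** 2 + ys[None, :, None] ** 2 + zs[None, None, :] ** 2
    ) <= radius ** 2
    vol.voxels[m] = value
    return vol


@pytest.fixture(scope="session")
def nema_bundle():
    """Static NEMA-type study analysed against itself (identity)."""
    ph = g.nema_phantom()
    act = g.build_phantom(ph)
    st = g.simulate_gated_image(
        act, g.DisplacementKernel.delta(0.0, 1.0), g.AcquisitionSettings(voxel_out=2.0)
    )
    return g.StudyBundle(
        phantom=ph, static=st, images={"self": [(None, st, 1.0)]},
        kernels={}, pattern_id="static", manifest={},
    )


@pytest.fixture(scope="session")
def cirs_activity():
    ph = g.cirs_phantom()
    return ph, g.build_phantom(ph)


@pytest.fixture(scope="session")
def jaszczak_bundle():
    ph = g.jaszczak_phantom()
    act = g.build_phantom(ph)
    st = g.simulate_gated_image(
        act, g.DisplacementKernel.delta(0.0, 1.0), g.AcquisitionSettings(voxel_out=2.0)
    )
    return g.StudyBundle(
        phantom=ph, static=st, images={"self": [(None, st, 1.0)]},
        kernels={}, pattern_id="static", manifest={},
    )


def write_dicom_series(dirname, series_uid, prefix, nslices=3, acq_time="120000.00"):
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import (
        ExplicitVRLittleEndian,
        SecondaryCaptureImageStorage,
        generate_uid,
    )

    study_uid = generate_uid()
    for i in range(nslices):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.SOPClassUID = SecondaryCaptureImageStorage
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "OT"
        ds.AcquisitionTime = acq_time
        ds.Rows = ds.Columns = 8
        ds.BitsAllocated = ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, 2.0 * i]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [2.0, 2.0]
        ds.SliceThickness = 2.0
        arr = (np.arange(64).reshape(8, 8) + i).astype(np.uint16)
        ds.PixelData = arr.tobytes()
        ds.save_as(str(dirname / f"{prefix}_{i}.dcm"), enforce_file_format=True)
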