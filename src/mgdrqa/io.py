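"""Readers and writers for dose grids, planar doses, and profiles.

Two dose-grid dialects are supported:

``portable``
    A self-describing NumPy ``.npz`` container holding origin/spacing/values
    plus a units tag.  Exact round-trip (bitwise-equal values), no DICOM
    dependency; the format used by the synthetic pipeline and the tests.

``dicom_rt_dose``
    DICOM RT Dose via pydicom.  Reading applies DoseGridScaling and maps the
    frame/row/column layout onto the (x, y, z) voxel order used here; writing
    emits a minimal but standards-shaped RTDOSE dataset with 32-bit stored
    values.

All distances are mm and all doses Gy on both sides of every call.
"""

from __future__ import annotations

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import FormatError
from .grids import DoseGrid, PlanarDose

__all__ = [
    "read_dose_grid",
    "write_dose_grid",
    "read_planar_dose",
    "write_planar_dose",
    "read_profile_table",
    "write_profile_table",
]

_RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"


def read_dose_grid(path, dialect: str = "portable") -> DoseGrid:
    """Read a 3D dose grid in Gy from ``path`` under the named dialect."""
    if dialect == "portable":
        return _read_portable(path)
    if dialect == "dicom_rt_dose":
        return _read_dicom(path)
    raise ValueError(f"unknown dialect '{dialect}'")


def write_dose_grid(grid: DoseGrid, path, dialect: str = "portable") -> None:
    """Write ``grid`` so that :func:`read_dose_grid` recovers an equal grid."""
    if not isinstance(grid, DoseGrid):
        raise TypeError("grid must be a DoseGrid")
    if dialect == "portable":
        _write_portable(grid, path)
    elif dialect == "dicom_rt_dose":
        _write_dicom(grid, path)
    else:
        raise ValueError(f"unknown dialect '{dialect}'")


# -- portable ---------------------------------------------------------------

def _read_portable(path) -> DoseGrid:
    try:
        with np.load(path, allow_pickle=False) as z:
            if "values" not in z or "origin" not in z or "spacing" not in z:
                raise FormatError(
                    f"{path}: portable container missing origin/spacing/values"
                )
            units = str(z["units"]) if "units" in z else "Gy"
            if units != "Gy":
                raise FormatError(f"{path}: unsupported dose units '{units}'")
            frame_id = str(z["frame_id"]) if "frame_id" in z else "frame-0"
            return DoseGrid(z["origin"], z["spacing"], z["values"],
                            frame_id=frame_id)
    except (OSError, ValueError) as exc:
        raise FormatError(f"{path}: not a portable dose container: {exc}") from exc


def _write_portable(grid: DoseGrid, path) -> None:
    np.savez(
        path,
        origin=grid.origin,
        spacing=grid.spacing,
        values=grid.values,
        units=np.array("Gy"),
        frame_id=np.array(grid.frame_id),
    )


# -- DICOM RT Dose ----------------------------------------------------------

def _read_dicom(path) -> DoseGrid:
    ds = pydicom.dcmread(path)
    for attr in ("DoseGridScaling", "ImagePositionPatient", "PixelSpacing",
                 "GridFrameOffsetVector"):
        if not hasattr(ds, attr):
            raise FormatError(f"{path}: RT Dose missing {attr}")
    if str(getattr(ds, "DoseUnits", "GY")).upper() != "GY":
        raise FormatError(f"{path}: DoseUnits must be GY, got {ds.DoseUnits}")
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = np.diff(offsets)
    if len(dz) == 0 or not np.allclose(dz, dz[0], atol=1e-6) or dz[0] <= 0:
        raise FormatError(
            f"{path}: GridFrameOffsetVector is not uniformly increasing"
        )
    scaling = float(ds.DoseGridScaling)
    if not np.isfinite(scaling) or scaling <= 0:
        raise FormatError(f"{path}: invalid DoseGridScaling {ds.DoseGridScaling}")
    # pixel_array: (frames=z, rows=y, cols=x) -> values[x, y, z]
    stored = ds.pixel_array.astype(float)
    values = np.transpose(stored * scaling, (2, 1, 0))
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)  # row=y, col=x
    spacing = np.array([col_sp, row_sp, float(dz[0])])
    origin = np.asarray(ds.ImagePositionPatient, dtype=float) + np.array(
        [0.0, 0.0, offsets[0]]
    )
    frame_id = str(getattr(ds, "FrameOfReferenceUID", "frame-0"))
    return DoseGrid(origin, spacing, values, frame_id=frame_id)


def _write_dicom(grid: DoseGrid, path) -> None:
    nx, ny, nz = grid.shape
    vmax = float(grid.values.max())
    scaling = vmax / (2**32 - 1) if vmax > 0 else 1e-9
    stored = np.round(grid.values / scaling).astype(np.uint32)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTDOSE_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = _RTDOSE_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.FrameOfReferenceUID = grid.frame_id if grid.frame_id.count(".") > 3 \
        else generate_uid()
    ds.PatientName = "phantom"
    ds.PatientID = "phantom"
    # private tag is avoided; stash the portable frame token in a comment
    ds.add_new(0x30040006, "LO", grid.frame_id)  # DoseComment
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.PixelSpacing = [float(grid.spacing[1]), float(grid.spacing[0])]
    ds.ImagePositionPatient = [float(v) for v in grid.origin]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.GridFrameOffsetVector = [float(grid.spacing[2] * k) for k in range(nz)]
    ds.DoseGridScaling = scaling
    ds.PixelData = np.ascontiguousarray(
        np.transpose(stored, (2, 1, 0))
    ).tobytes()
    ds.save_as(path, enforce_file_format=True)


# -- planar dose ------------------------------------------------------------

def write_planar_dose(planar: PlanarDose, path) -> None:
    np.savez(
        path,
        values=planar.values,
        spacing=planar.spacing,
        source_distance=np.array(planar.source_distance),
        origin_uv=planar.origin_uv,
        axis_u=planar.axis_u,
        axis_v=planar.axis_v,
        plane_origin=planar.plane_origin,
        units=np.array("Gy"),
    )


def read_planar_dose(path) -> PlanarDose:
    try:
        with np.load(path, allow_pickle=False) as z:
            return PlanarDose(
                values=z["values"],
                spacing=z["spacing"],
                source_distance=float(z["source_distance"]),
                origin_uv=z["origin_uv"],
                axis_u=z["axis_u"],
                axis_v=z["axis_v"],
                plane_origin=z["plane_origin"],
            )
    except (OSError, KeyError, ValueError) as exc:
        raise FormatError(f"{path}: not a planar dose container: {exc}") from exc


# -- profiles ---------------------------------------------------------------

def read_profile_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column text profile: position (mm), relative dose."""
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (position, dose)")
    return data[:, 0], data[:, 1]


def write_profile_table(positions, values, path) -> None:
    np.savetxt(
        path,
        np.column_stack([positions, values]),
        header="position_mm relative_dose",
        fmt="%.6g",
    )
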