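"""DICOM CT series I/O: read, validate, order and round-trip head CT volumes.

A classic CT series stores one axial slice per file.  Reading converts stored
pixel values to Hounsfield units via each file's rescale slope/intercept and
sorts slices by their physical position along the scanner axis (image
position z, instance number as tie-break) — position is the ground truth for
slice adjacency, which the vertex-artifact suppression rule depends on.
Files lacking rescale tags are refused rather than guessed at: a silent HU
offset would corrupt every downstream threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .errors import GeometryError, ICHScreenError, MetadataError, MultiSeriesError

__all__ = [
    "CTVolume",
    "SeriesValidationReport",
    "read_dicom_series",
    "validate_series",
    "write_dicom_series",
    "DEFAULT_MIN_SLICES",
]

DEFAULT_MIN_SLICES = 20


@dataclass
class CTVolume:
    """An ordered stack of axial CT slices in Hounsfield units.

    ``slices`` is (n_slices, rows, cols); slice index 0 is the lowest
    position.  ``pixel_spacing`` is (row_mm, col_mm).  ``slice_positions``
    are mm along the scanner axis, strictly increasing.
    """

    slices: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_thickness: float
    slice_positions: np.ndarray
    series_id: str = ""

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=np.float64)
        self.slice_positions = np.asarray(self.slice_positions, dtype=np.float64)
        if self.slices.ndim != 3:
            raise GeometryError(f"slices must be 3-D, got shape {self.slices.shape}")
        if len(self.slice_positions) != self.slices.shape[0]:
            raise GeometryError("one position per slice required")
        if not np.all(np.isfinite(self.slices)):
            raise GeometryError("HU values must be finite")

    @property
    def n_slices(self) -> int:
        return int(self.slices.shape[0])

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.pixel_spacing[0] * self.pixel_spacing[1])

    def positions_strictly_increasing(self) -> bool:
        return bool(np.all(np.diff(self.slice_positions) > 0))


@dataclass
class SeriesValidationReport:
    """Outcome of protocol validation; never raises, only reports."""

    n_slices: int
    min_required: int
    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.reasons


def validate_series(volume: CTVolume, min_slices: int = DEFAULT_MIN_SLICES) -> SeriesValidationReport:
    """Check a series against the acquisition protocol.

    A series with fewer slices than the protocol minimum is rejected with
    code ``"too_few_slices"`` (the requirement is strictly "fewer than":
    exactly ``min_slices`` passes).
    """
    reasons: list[str] = []
    if volume.n_slices < min_slices:
        reasons.append("too_few_slices")
    return SeriesValidationReport(
        n_slices=volume.n_slices, min_required=min_slices, reasons=reasons
    )


def _dicom_files(directory: Path) -> list[Path]:
    files = sorted(p for p in directory.iterdir() if p.is_file())
    dcm = [p for p in files if p.suffix.lower() in (".dcm", ".dicom")]
    return dcm if dcm else files


def read_dicom_series(directory) -> CTVolume:
    """Read a single-series directory of classic CT slices into a CTVolume.

    Pixel data are converted to HU with each file's RescaleSlope/Intercept;
    slices are sorted by image-position z (instance number tie-break), so any
    on-disk file ordering yields the same volume.
    """
    directory = Path(directory)
    paths = _dicom_files(directory)
    if not paths:
        raise ICHScreenError(f"no DICOM files found in {directory}")

    datasets = [pydicom.dcmread(p) for p in paths]

    series_uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(series_uids) != 1:
        raise MultiSeriesError(
            f"directory mixes {len(series_uids)} series: {sorted(series_uids)}"
        )
    series_id = series_uids.pop()

    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) != 1:
        raise GeometryError(f"inconsistent matrix sizes across slices: {sorted(shapes)}")

    def sort_key(ds: Dataset) -> tuple[float, int]:
        try:
            z = float(ds.ImagePositionPatient[2])
        except Exception as exc:
            raise MetadataError("ImagePositionPatient missing or malformed") from exc
        return (z, int(getattr(ds, "InstanceNumber", 0)))

    datasets.sort(key=sort_key)

    slices = []
    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise MetadataError(
                "RescaleSlope/RescaleIntercept missing; refusing to guess HU scaling"
            )
        slope = float(ds.RescaleSlope)
        intercept = float(ds.RescaleIntercept)
        slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)

    positions = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    first = datasets[0]
    spacing = tuple(float(v) for v in first.PixelSpacing)
    thickness = float(getattr(first, "SliceThickness", 0.0))

    return CTVolume(
        slices=np.stack(slices),
        pixel_spacing=(spacing[0], spacing[1]),
        slice_thickness=thickness,
        slice_positions=positions,
        series_id=series_id,
    )


def write_dicom_series(volume: CTVolume, directory) -> Path:
    """Write a CTVolume as a minimal valid classic CT series, one file per slice.

    Stored values are int16 with slope 1 / intercept 0, so the read-back HU
    differ from the source by at most 0.5 (rounding quantization).
    """
    if volume.n_slices == 0:
        raise ICHScreenError("cannot write an empty volume")
    if not volume.positions_strictly_increasing():
        raise GeometryError("slice positions must be strictly increasing")

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    series_uid = volume.series_id or generate_uid()
    study_uid = generate_uid()
    n = volume.n_slices

    for i in range(n):
        ds = Dataset()
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = generate_uid()
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.PatientName = "PHANTOM"
        ds.PatientID = "PHANTOM"
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(volume.slice_positions[i])]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [volume.pixel_spacing[0], volume.pixel_spacing[1]]
        ds.SliceThickness = volume.slice_thickness
        ds.Rows, ds.Columns = volume.slices.shape[1:3]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        stored = np.clip(np.round(volume.slices[i]), -32768, 32767).astype(np.int16)
        ds.PixelData = stored.tobytes()

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta

        ds.save_as(directory / f"slice_{i:04d}.dcm", enforce_file_format=True)

    return directory
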