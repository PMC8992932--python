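"""Phantom image containers and DICOM series I/O.

Internally an image is a plain float array plus the spatial metadata the
analyzers need (pixel spacing, slice position, in-plane orientation class).
On disk a series is one single-frame MR DICOM file per slice; pixel data is
stored as 16-bit unsigned integers, so a round trip through
:func:`write_series` / :func:`read_series` reproduces integer-valued pixel
arrays exactly and spacing to well below 1e-6 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

MR_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.4"

__all__ = ["QAImage", "QASeries", "read_series", "write_series", "SeriesFormatError"]


class SeriesFormatError(ValueError):
    """Raised for empty, mixed, or spatially inconsistent DICOM directories."""


@dataclass
class QAImage:
    """A single phantom slice: pixel intensities plus spatial metadata.

    pixels
        2-D array, arbitrary non-negative units, shape (rows, cols).
    pixel_spacing
        (row spacing, column spacing) in mm.
    slice_position
        Position along the slice-normal axis in mm.
    orientation
        ``"axial"`` or ``"sagittal"`` (dominant slice-normal axis).
    """

    pixels: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_position: float = 0.0
    orientation: str = "axial"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("QAImage pixels must be 2-D")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("QAImage pixels must be finite and non-negative")
        if min(self.pixel_spacing) <= 0:
            raise ValueError("pixel spacing must be positive")
        if self.orientation not in ("axial", "sagittal"):
            raise ValueError(f"unsupported orientation {self.orientation!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def center_pixel(self) -> tuple[float, float]:
        """(row, col) of the geometric image center, pixel-center convention."""
        return ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)


@dataclass
class QASeries:
    """An ordered multi-slice acquisition of one phantom."""

    images: list[QAImage]
    slice_thickness: float
    slice_gap: float = 0.0
    field_strength: str = ""
    weighting: str = ""
    coil: str = ""
    series_uid: str = field(default_factory=generate_uid)

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError("QASeries needs at least one image")
        spacings = {im.pixel_spacing for im in self.images}
        if len(spacings) != 1:
            raise SeriesFormatError("pixel spacing differs between slices")
        orients = {im.orientation for im in self.images}
        if len(orients) != 1:
            raise SeriesFormatError("orientation differs between slices")
        self.images.sort(key=lambda im: im.slice_position)

    def __len__(self) -> int:
        return len(self.images)

    def __getitem__(self, i: int) -> QAImage:
        return self.images[i]

    @property
    def pixel_spacing(self) -> tuple[float, float]:
        return self.images[0].pixel_spacing

    @property
    def orientation(self) -> str:
        return self.images[0].orientation


def _classify_orientation(iop: list[float]) -> str:
    row = np.asarray(iop[:3], dtype=float)
    col = np.asarray(iop[3:], dtype=float)
    normal = np.cross(row, col)
    axis = int(np.argmax(np.abs(normal)))
    if np.abs(normal[axis]) < 0.999:
        raise SeriesFormatError("oblique acquisitions are not supported")
    return {0: "sagittal", 2: "axial"}.get(axis) or _raise_coronal()


def _raise_coronal() -> str:
    raise SeriesFormatError("coronal acquisitions are not supported")


def read_series(path: str | Path) -> QASeries:
    """Read one single-frame MR DICOM series from a directory.

    Slices are ordered by position along the slice normal regardless of file
    naming.  Directories containing files from more than one series, or with
    inconsistent pixel spacing / orientation, are rejected.
    """
    path = Path(path)
    datasets = []
    for f in sorted(path.iterdir()) if path.is_dir() else []:
        if not f.is_file():
            continue
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue  # non-DICOM clutter is ignored
    if not datasets:
        raise SeriesFormatError(f"no readable DICOM files in {path}")
    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) != 1:
        raise SeriesFormatError(f"directory mixes {len(uids)} series")

    images = []
    for ds in datasets:
        orientation = _classify_orientation([float(v) for v in ds.ImageOrientationPatient])
        axis = {"axial": 2, "sagittal": 0}[orientation]
        pos = float(ds.ImagePositionPatient[axis])
        spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
        images.append(
            QAImage(
                pixels=ds.pixel_array.astype(float),
                pixel_spacing=spacing,
                slice_position=pos,
                orientation=orientation,
            )
        )
    ds0 = datasets[0]
    thickness = float(getattr(ds0, "SliceThickness", 0.0) or 0.0)
    between = float(getattr(ds0, "SpacingBetweenSlices", thickness) or thickness)
    return QASeries(
        images=images,
        slice_thickness=thickness,
        slice_gap=max(between - thickness, 0.0),
        field_strength=str(getattr(ds0, "MagneticFieldStrength", "") or ""),
        weighting=str(getattr(ds0, "SeriesDescription", "") or ""),
        coil=str(getattr(ds0, "ReceiveCoilName", "") or ""),
        series_uid=str(ds0.SeriesInstanceUID),
    )


def write_series(series: QASeries, path: str | Path) -> list[Path]:
    """Write one DICOM file per slice; returns the written file paths.

    Pixels are clipped to [0, 65535] and rounded to integers; series produced
    by the simulator are already integer-valued so the round trip is exact.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    iop = {
        "axial": [1.0, 0.0, 0.0, 0.0, 1.0, 0.0],
        "sagittal": [0.0, 1.0, 0.0, 0.0, 0.0, 1.0],
    }[series.orientation]
    axis = {"axial": 2, "sagittal": 0}[series.orientation]
    written = []
    for i, im in enumerate(series.images):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = MR_IMAGE_STORAGE
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = MR_IMAGE_STORAGE
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "MR"
        ds.SeriesInstanceUID = series.series_uid
        ds.StudyInstanceUID = series.series_uid  # one study per series here
        ds.InstanceNumber = i + 1
        ds.SeriesDescription = series.weighting
        ds.ReceiveCoilName = series.coil
        if series.field_strength:
            ds.MagneticFieldStrength = series.field_strength
        ds.PixelSpacing = [f"{series.pixel_spacing[0]:.6f}", f"{series.pixel_spacing[1]:.6f}"]
        ds.SliceThickness = series.slice_thickness
        ds.SpacingBetweenSlices = series.slice_thickness + series.slice_gap
        ds.ImageOrientationPatient = iop
        ipp = [0.0, 0.0, 0.0]
        ipp[axis] = im.slice_position
        ds.ImagePositionPatient = ipp
        ds.SliceLocation = im.slice_position

        arr = np.clip(np.round(im.pixels), 0, 65535).astype(np.uint16)
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows, ds.Columns = arr.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = arr.tobytes()

        out = path / f"slice_{i:03d}.dcm"
        ds.save_as(str(out), enforce_file_format=True)
        written.append(out)
    return written


def quantize(series: QASeries) -> QASeries:
    """Round pixel values to the integer grid used on disk (in place-free)."""
    imgs = [replace(im, pixels=np.clip(np.round(im.pixels), 0, 65535)) for im in series.images]
    return replace(series, images=imgs)
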