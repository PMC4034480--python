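"""Core raster types and image I/O.

An :class:`ImageFrame` is the universal carrier between pipeline stages: a
2-D array of detector digital units (DU) together with the pixel pitch in
mm and the acquisition context (entrance air kerma, kVp, mAs).  Pixels are
stored as float64 regardless of the source bit depth so that filtered
images never need clipping until export; export clamps to the stored
dynamic range of the output format.

Coordinate convention: 0-based indices, row-major, origin at the top-left,
and half-open regions of interest.

Supported formats: single-frame monochrome DICOM, 8/16-bit grayscale PNG,
and a raw ``.npy`` array dump with a plain-text ``key: value`` sidecar
(``<stem>.meta``) carrying pitch, kerma and label.  DICOM rescale
slope/intercept are NOT applied unless asked for — the analysis works in
raw digital units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import BoundsError, DataError, UnsupportedFormatError

__all__ = [
    "AcquisitionContext",
    "ImageFrame",
    "RegionOfInterest",
    "read_image",
    "write_image",
    "extract_roi",
    "tile_rois",
]


@dataclass(frozen=True)
class AcquisitionContext:
    """Exposure conditions of one image.

    air_kerma_uGy is the entrance air kerma at the detector plane; it is
    the X of the NNPS normalisation NPS/(G·X)².
    """

    air_kerma_uGy: float | None = None
    kVp: float | None = None
    mAs: float | None = None

    def __post_init__(self) -> None:
        if self.air_kerma_uGy is not None and self.air_kerma_uGy < 0:
            raise ValueError(f"air_kerma_uGy must be >= 0, got {self.air_kerma_uGy}")


@dataclass(frozen=True)
class RegionOfInterest:
    """Half-open rectangular region: rows [row0, row0+n_rows), cols
    [col0, col0+n_cols)."""

    row0: int
    col0: int
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError(f"ROI extents must be positive, got {self.n_rows}x{self.n_cols}")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError(f"ROI origin must be non-negative, got ({self.row0},{self.col0})")

    @property
    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.n_rows),
            slice(self.col0, self.col0 + self.n_cols),
        )

    def check_inside(self, shape: tuple[int, int]) -> None:
        if self.row0 + self.n_rows > shape[0] or self.col0 + self.n_cols > shape[1]:
            raise BoundsError(
                f"ROI rows [{self.row0},{self.row0 + self.n_rows}) x "
                f"cols [{self.col0},{self.col0 + self.n_cols}) exceeds frame {shape}"
            )


@dataclass
class ImageFrame:
    """A 2-D raster of digital units plus pixel pitch and metadata."""

    pixels: np.ndarray
    pixel_pitch_mm: float
    acquisition: AcquisitionContext = field(default_factory=AcquisitionContext)
    label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError(f"pixels must be a non-empty 2-D array, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if not (self.pixel_pitch_mm > 0):
            raise ValueError(f"pixel_pitch_mm must be > 0, got {self.pixel_pitch_mm}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def nyquist_per_mm(self) -> float:
        """Maximum faithfully sampled spatial frequency, 1/(2·pitch)."""
        return 1.0 / (2.0 * self.pixel_pitch_mm)

    def with_pixels(self, pixels: np.ndarray, label: str | None = None) -> "ImageFrame":
        return ImageFrame(
            pixels=pixels,
            pixel_pitch_mm=self.pixel_pitch_mm,
            acquisition=self.acquisition,
            label=self.label if label is None else label,
        )


def extract_roi(frame: ImageFrame, roi: RegionOfInterest) -> ImageFrame:
    """Return the sub-raster of ``roi``; pitch and acquisition are copied."""
    roi.check_inside(frame.shape)
    return replace(frame, pixels=frame.pixels[roi.slices].copy())


def tile_rois(
    frame: ImageFrame | tuple[int, int],
    size: int,
    overlap_fraction: float = 0.0,
) -> list[RegionOfInterest]:
    """Maximal regular grid of size×size ROIs fully inside the frame.

    The stride is ``size·(1−overlap_fraction)`` rounded down, at least 1.
    Ordering is deterministic: row-major by origin.
    """
    shape = frame.shape if isinstance(frame, ImageFrame) else tuple(frame)
    if not (0.0 <= overlap_fraction < 1.0):
        raise ValueError(f"overlap_fraction must be in [0,1), got {overlap_fraction}")
    if size <= 0:
        raise ValueError(f"size must be positive, got {size}")
    if size > shape[0] or size > shape[1]:
        raise ValueError(f"ROI size {size} exceeds frame shape {shape}")
    stride = max(1, int(math.floor(size * (1.0 - overlap_fraction))))
    rows = range(0, shape[0] - size + 1, stride)
    cols = range(0, shape[1] - size + 1, stride)
    return [RegionOfInterest(r, c, size, size) for r in rows for c in cols]


# ---------------------------------------------------------------------------
# File I/O

_FORMATS = ("dicom", "png", "npy-raw")

_SUFFIX_TO_FORMAT = {
    ".dcm": "dicom",
    ".dicom": "dicom",
    ".png": "png",
    ".npy": "npy-raw",
}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise UnsupportedFormatError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
        return fmt
    try:
        return _SUFFIX_TO_FORMAT[path.suffix.lower()]
    except KeyError:
        raise UnsupportedFormatError(
            f"cannot infer format from suffix {path.suffix!r} of {path}"
        ) from None


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta")


def _read_sidecar(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    if not path.exists():
        return meta
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise DataError(f"malformed sidecar line {line!r} in {path}")
        key, value = line.split(":", 1)
        meta[key.strip()] = value.strip()
    return meta


def _write_sidecar(path: Path, frame: ImageFrame) -> None:
    acq = frame.acquisition
    lines = ["# mamiq raw-frame sidecar", f"pixel_pitch_mm: {frame.pixel_pitch_mm!r}"]
    if frame.label:
        lines.append(f"label: {frame.label}")
    if acq.air_kerma_uGy is not None:
        lines.append(f"air_kerma_uGy: {acq.air_kerma_uGy!r}")
    if acq.kVp is not None:
        lines.append(f"kVp: {acq.kVp!r}")
    if acq.mAs is not None:
        lines.append(f"mAs: {acq.mAs!r}")
    path.write_text("\n".join(lines) + "\n")


def read_image(
    path: str | Path,
    format: str | None = None,
    pixel_pitch_mm: float | None = None,
    acquisition: AcquisitionContext | None = None,
    apply_rescale: bool = False,
    pitch_override: bool = False,
) -> ImageFrame:
    """Read an image file into an :class:`ImageFrame`.

    Pixel values are the stored digital units, unrescaled, unless
    ``apply_rescale`` asks for DICOM slope/intercept.  The pitch is taken
    from DICOM tags or the sidecar when present, else from the argument;
    on conflict the file wins unless ``pitch_override`` is set.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    fmt = _infer_format(path, format)

    file_pitch: float | None = None
    file_acq: AcquisitionContext | None = None
    label = ""

    if fmt == "dicom":
        import pydicom

        try:
            ds = pydicom.dcmread(path)
            arr = ds.pixel_array
        except Exception as exc:  # pragma: no cover - pydicom error paths
            raise DataError(f"cannot read DICOM file {path}: {exc}") from exc
        if int(getattr(ds, "NumberOfFrames", 1)) > 1:
            raise UnsupportedFormatError(f"multi-frame DICOM not supported: {path}")
        if int(getattr(ds, "SamplesPerPixel", 1)) != 1 or arr.ndim != 2:
            raise UnsupportedFormatError(f"colour / non-2D DICOM not supported: {path}")
        pixels = arr.astype(np.float64)
        if apply_rescale:
            slope = float(getattr(ds, "RescaleSlope", 1.0))
            intercept = float(getattr(ds, "RescaleIntercept", 0.0))
            pixels = pixels * slope + intercept
        spacing = getattr(ds, "ImagerPixelSpacing", None) or getattr(ds, "PixelSpacing", None)
        if spacing is not None:
            file_pitch = float(spacing[0])
        kvp = getattr(ds, "KVP", None)
        if kvp is not None:
            file_acq = AcquisitionContext(kVp=float(kvp))
    elif fmt == "png":
        import imageio.v3 as iio

        try:
            arr = iio.imread(path)
        except Exception as exc:
            raise DataError(f"cannot read PNG file {path}: {exc}") from exc
        if arr.ndim != 2:
            raise UnsupportedFormatError(f"colour PNG not supported: {path}")
        pixels = arr.astype(np.float64)
    else:  # npy-raw
        try:
            pixels = np.load(path, allow_pickle=False)
        except Exception as exc:
            raise DataError(f"cannot read npy file {path}: {exc}") from exc
        if pixels.ndim != 2:
            raise UnsupportedFormatError(f"array in {path} is not 2-D")
        meta = _read_sidecar(_sidecar_path(path))
        if "pixel_pitch_mm" in meta:
            file_pitch = float(meta["pixel_pitch_mm"])
        label = meta.get("label", "")
        kw = {}
        for name in ("air_kerma_uGy", "kVp", "mAs"):
            if name in meta:
                kw[name] = float(meta[name])
        if kw:
            file_acq = AcquisitionContext(**kw)

    if file_pitch is not None and not pitch_override:
        pitch = file_pitch
    elif pixel_pitch_mm is not None:
        pitch = pixel_pitch_mm
    elif file_pitch is not None:
        pitch = file_pitch
    else:
        raise DataError(f"pixel pitch not stored in {path} and not given as argument")

    acq = acquisition if acquisition is not None else (file_acq or AcquisitionContext())
    return ImageFrame(pixels=pixels, pixel_pitch_mm=pitch, acquisition=acq, label=label)


def write_image(frame: ImageFrame, path: str | Path, format: str | None = None) -> Path:
    """Write a frame to disk; round-trips bit-exactly for integer DU data.

    PNG export rounds and clamps to uint16; the DICOM writer emits a
    minimal single-frame monochrome dataset (sufficient for round-trip
    testing, not a conformant clinical object).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "png":
        import imageio.v3 as iio

        data = np.clip(np.rint(frame.pixels), 0, 65535).astype(np.uint16)
        iio.imwrite(path, data)
    elif fmt == "npy-raw":
        np.save(path, frame.pixels)
        # np.save may append .npy; normalise
        if not path.exists() and path.with_suffix(path.suffix + ".npy").exists():
            path = path.with_suffix(path.suffix + ".npy")
        _write_sidecar(_sidecar_path(path), frame)
    else:  # dicom
        _write_minimal_dicom(frame, path)
    return path


def _write_minimal_dicom(frame: ImageFrame, path: Path) -> None:
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    data = np.clip(np.rint(frame.pixels), 0, 65535).astype("<u2")

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "MG"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = data.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.ImagerPixelSpacing = [frame.pixel_pitch_mm, frame.pixel_pitch_mm]
    if frame.acquisition.kVp is not None:
        ds.KVP = str(frame.acquisition.kVp)
    ds.PixelData = data.tobytes()
    pydicom.dcmwrite(path, ds, enforce_file_format=True)
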