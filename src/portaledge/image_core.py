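"""Image containers, projection geometry, and file I/O.

The package works on pairs of 2D grayscale projections: a digitally
reconstructed radiograph (DRR, the kilovoltage-quality reference) and an
electronic portal image (EPID, the megavoltage acquisition).  Both live in
:class:`IntensityGrid`, a plain 2D array of intensities tagged with the
physical detector pixel pitch.

Geometry follows the standard isocentric treatment setup: a point source,
the isocenter at ``sid_mm`` from the source, and a flat detector at
``sdd_mm``.  Shifts measured on the detector (in pixels) are divided by the
magnification ``sdd/sid`` to express them as couch shifts at the isocenter
plane, which is how portal-image translations are reported clinically.

Index convention: arrays are indexed ``(row, col)``, 0-based; ``i`` indexes
rows (image vertical) and ``j`` columns.  All physical distances are in mm
and angles in degrees.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "DEFAULT_SPACING_MM",
    "IntensityGrid",
    "ProjectionGeometry",
    "ViewLabel",
    "ImageFormatError",
    "GeometryError",
    "detector_px_to_isocenter_mm",
    "isocenter_mm_to_detector_px",
    "read_image",
    "write_image",
    "read_geometry_config",
]

#: Effective pixel pitch of a typical amorphous-silicon portal panel (mm).
DEFAULT_SPACING_MM = 0.39
#: Source-to-detector distance of the reference setup (mm).
DEFAULT_SDD_MM = 1400.0
#: Source-to-isocenter distance of the reference setup (mm).
DEFAULT_SID_MM = 1000.0


class ImageFormatError(ValueError):
    """Raised when a file cannot be decoded into a single-channel 2D frame."""


class GeometryError(ValueError):
    """Raised for physically impossible projection geometry."""


@dataclass(frozen=True)
class IntensityGrid:
    """A 2D grid of scalar intensities with a physical pixel pitch.

    Holds both raw projections and derived gradient images (gradients may be
    signed).  Values are kept in whatever dtype they arrive in so that file
    round-trips are bit-exact; processing code converts to float on demand.

    Parameters
    ----------
    values
        2D array, at least 2x2, all entries finite.
    spacing_px_mm
        Physical detector pixel pitch in mm (> 0).
    """

    values: np.ndarray
    spacing_px_mm: float = DEFAULT_SPACING_MM

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise ValueError(f"values must be 2D, got ndim={arr.ndim}")
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError(f"grid must be at least 2x2, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("grid contains non-finite values")
        if not self.spacing_px_mm > 0:
            raise ValueError(f"spacing_px_mm must be > 0, got {self.spacing_px_mm}")
        object.__setattr__(self, "values", arr)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def as_float(self) -> np.ndarray:
        """Return the intensities as a float64 array (copy only if needed)."""
        return np.asarray(self.values, dtype=np.float64)


@dataclass(frozen=True)
class ProjectionGeometry:
    """Isocentric point-source projection geometry for one view.

    ``magnification = sdd_mm / sid_mm`` scales objects at the isocenter
    plane onto the detector plane; it must exceed 1 (the detector sits
    beyond the isocenter).
    """

    sdd_mm: float = DEFAULT_SDD_MM
    sid_mm: float = DEFAULT_SID_MM
    gantry_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sdd_mm > self.sid_mm > 0):
            raise GeometryError(
                f"require sdd_mm > sid_mm > 0, got sdd={self.sdd_mm}, sid={self.sid_mm}"
            )

    @property
    def magnification(self) -> float:
        return self.sdd_mm / self.sid_mm


class ViewLabel(str, Enum):
    """Orthogonal portal views and their fixed patient-axis mapping.

    AP (gantry 0°): image columns run along patient X (medio-lateral),
    rows along patient Z (cranio-caudal).  LAT (gantry 90°): columns run
    along patient Y (anterior-posterior), rows along patient Z.  The two
    views share the Z (row) axis.
    """

    AP = "AP"
    LAT = "LAT"

    @property
    def column_axis(self) -> str:
        return {"AP": "X", "LAT": "Y"}[self.value]

    @property
    def row_axis(self) -> str:
        return "Z"


def detector_px_to_isocenter_mm(
    delta_px: float,
    geometry: ProjectionGeometry,
    spacing_px_mm: float = DEFAULT_SPACING_MM,
) -> float:
    """Convert a detector-plane pixel shift to mm at the isocenter plane.

    A shift of ``delta_px`` pixels on the detector spans
    ``delta_px * spacing_px_mm`` mm there; dividing by the magnification
    projects it back to the isocenter plane, where couch shifts are defined.
    """
    return float(delta_px) * spacing_px_mm / geometry.magnification


def isocenter_mm_to_detector_px(
    delta_mm: float,
    geometry: ProjectionGeometry,
    spacing_px_mm: float = DEFAULT_SPACING_MM,
) -> float:
    """Inverse of :func:`detector_px_to_isocenter_mm`."""
    return float(delta_mm) * geometry.magnification / spacing_px_mm


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_SUFFIX_FORMAT = {
    ".png": "png",
    ".tif": "tiff",
    ".tiff": "tiff",
    ".dcm": "dicom",
    ".dicom": "dicom",
}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    try:
        return _SUFFIX_FORMAT[path.suffix.lower()]
    except KeyError:
        raise ImageFormatError(f"cannot infer image format from suffix {path.suffix!r}")


def read_image(
    path: str | Path,
    format: str | None = None,
    to_gray: bool = False,
    spacing_px_mm: float | None = None,
) -> IntensityGrid:
    """Read a grayscale image file into an :class:`IntensityGrid`.

    Supported formats: 8/16-bit PNG, 16-bit TIFF, single-frame DICOM.
    Intensities are returned as stored (no rescale).  Pixel spacing is taken
    from the DICOM PixelSpacing / ImagerPixelSpacing tag when present,
    otherwise from ``spacing_px_mm`` (falling back to the default panel
    pitch).  A multi-channel image is rejected unless ``to_gray`` is set,
    in which case channels are averaged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)

    tag_spacing = None
    if fmt == "png":
        from PIL import Image

        with Image.open(path) as im:
            arr = np.asarray(im)
    elif fmt == "tiff":
        import tifffile

        arr = tifffile.imread(path)
    elif fmt == "dicom":
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
        for tag in ("PixelSpacing", "ImagerPixelSpacing"):
            if tag in ds:
                tag_spacing = float(ds.data_element(tag).value[0])
                break
    else:
        raise ImageFormatError(f"unsupported format {fmt!r}")

    if arr.ndim == 3:
        if not to_gray:
            raise ImageFormatError(
                f"{path.name} has {arr.shape[-1]} channels; pass to_gray=True "
                "to average them into one"
            )
        arr = arr.astype(np.float64).mean(axis=-1)
    if arr.ndim != 2:
        raise ImageFormatError(f"{path.name} does not decode to a single 2D frame")

    spacing = tag_spacing if tag_spacing is not None else spacing_px_mm
    if spacing is None:
        spacing = DEFAULT_SPACING_MM
    return IntensityGrid(arr, spacing_px_mm=spacing)


def write_image(grid: IntensityGrid, path: str | Path) -> Path:
    """Write a grid to PNG (8/16-bit) or TIFF (16-bit).

    TIFF round-trips the stored values bit-exactly.  Float-valued grids are
    cast to uint16 (values are expected to already lie in 16-bit range).
    """
    path = Path(path)
    fmt = _infer_format(path, None)
    arr = grid.values
    if fmt == "tiff":
        import tifffile

        if arr.dtype.kind == "f":
            arr = np.clip(np.rint(arr), 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, arr)
    elif fmt == "png":
        from PIL import Image

        if arr.dtype == np.uint8:
            im = Image.fromarray(arr, mode="L")
        else:
            arr16 = np.clip(np.rint(np.asarray(arr, dtype=np.float64)), 0, 65535)
            im = Image.fromarray(arr16.astype(np.uint16))
        im.save(path)
    else:
        raise ImageFormatError(f"cannot write format {fmt!r}")
    return path


def read_geometry_config(path: str | Path) -> tuple[ProjectionGeometry, float]:
    """Read a TOML config with a ``[geometry]`` table.

    Recognised keys: ``sdd_mm``, ``sid_mm``, ``pixel_mm`` and optionally
    ``gantry_deg``.  Returns the geometry and the pixel pitch in mm.
    """
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    geo = cfg.get("geometry", {})
    geometry = ProjectionGeometry(
        sdd_mm=float(geo.get("sdd_mm", DEFAULT_SDD_MM)),
        sid_mm=float(geo.get("sid_mm", DEFAULT_SID_MM)),
        gantry_deg=float(geo.get("gantry_deg", 0.0)),
    )
    spacing = float(geo.get("pixel_mm", DEFAULT_SPACING_MM))
    if spacing <= 0:
        raise GeometryError(f"pixel_mm must be > 0, got {spacing}")
    return geometry, spacing
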