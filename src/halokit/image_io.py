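"""Reading micrographs into intensity fields and writing analysis outputs.

The DNA-halo assay is quantified from 8-bit fluorescence micrographs
(grayscale or RGB, typically 1388 x 1040 px TIFF).  All thresholds used
downstream are defined on the 0-255 intensity scale, so images with a
higher bit depth are rejected outright rather than silently rescaled.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional, Sequence

import imageio.v3 as iio
import numpy as np
from skimage.segmentation import find_boundaries

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for type hints
    from .halo_core import FieldResult

CHANNEL_POLICIES = ("max", "red", "green", "blue", "luminance")

#: column order of the measurement table, fixed so downstream parsers can
#: rely on it
CSV_COLUMNS = (
    "source_id",
    "object_index",
    "frame_time_s",
    "local_max",
    "rn_area_px",
    "outer_area_px",
    "rn_radius_px",
    "outer_radius_px",
    "halo_radius_px",
    "status",
    "class",
)


class UnsupportedBitDepthError(ValueError):
    """Raised for images deeper than 8 bits per channel."""


@dataclass
class IntensityField:
    """One 8-bit grayscale micrograph, or one frame of a timed series.

    Parameters
    ----------
    pixels
        2-D ``uint8`` array of intensities.
    source_id
        Identifier of the originating file or synthetic render.
    frame_time_s
        Acquisition time within a timed series, seconds; ``None`` for
        single-shot size analysis.
    """

    pixels: np.ndarray
    source_id: str = ""
    frame_time_s: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.pixels.dtype != np.uint8:
            if np.issubdtype(self.pixels.dtype, np.integer) and (
                self.pixels.min() >= 0 and self.pixels.max() <= 255
            ):
                self.pixels = self.pixels.astype(np.uint8)
            else:
                raise ValueError("pixel values must be integers in [0, 255]")
        if self.frame_time_s is not None and self.frame_time_s < 0:
            raise ValueError("frame_time_s must be non-negative")

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]


def _collapse_rgb(arr: np.ndarray, channel_policy: str) -> np.ndarray:
    if channel_policy == "max":
        return arr[..., :3].max(axis=-1)
    if channel_policy == "red":
        return arr[..., 0]
    if channel_policy == "green":
        return arr[..., 1]
    if channel_policy == "blue":
        return arr[..., 2]
    if channel_policy == "luminance":
        # ITU-R BT.601 luma weights, rounded back to 8 bit
        rgb = arr[..., :3].astype(np.float64)
        y = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
        return np.rint(y).astype(np.uint8)
    raise ValueError(
        f"unknown channel_policy {channel_policy!r}; expected one of {CHANNEL_POLICIES}"
    )


def load_field(
    path: str | Path,
    channel_policy: str = "max",
    frame_time_s: Optional[float] = None,
) -> IntensityField:
    """Read an 8-bit grayscale or RGB image into an :class:`IntensityField`.

    RGB input is collapsed to one value per pixel according to
    ``channel_policy`` (default ``max`` across channels, robust to which
    channel the red-fluorescence signal landed in).  Grayscale input passes
    through unchanged.

    Raises
    ------
    IOError
        If the file cannot be read or decoded.
    UnsupportedBitDepthError
        For bit depths above 8; thresholds are defined on the 0-255 scale
        and rescaling would silently change them.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by plugin
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    if arr.dtype != np.uint8:
        raise UnsupportedBitDepthError(
            f"{path}: bit depth of dtype {arr.dtype} exceeds 8 bits; "
            "only 8-bit images are supported (no rescaling is applied)"
        )
    if arr.ndim == 2:
        gray = arr
    elif arr.ndim == 3 and arr.shape[-1] in (3, 4):
        gray = _collapse_rgb(arr, channel_policy)
    else:
        raise IOError(f"{path}: unsupported image layout with shape {arr.shape}")
    return IntensityField(
        pixels=np.ascontiguousarray(gray, dtype=np.uint8),
        source_id=path.name,
        frame_time_s=frame_time_s,
    )


def write_field(field: IntensityField, path: str | Path) -> None:
    """Write a field as an 8-bit grayscale TIFF or PNG (by extension)."""
    iio.imwrite(Path(path), field.pixels)


def _overlay_paths(path: Path) -> tuple[Path, Path]:
    suffix = path.suffix if path.suffix.lower() in (".png", ".tif", ".tiff") else ".png"
    stem = path.with_suffix("")
    return (
        stem.parent / f"{stem.name}_rn{suffix}",
        stem.parent / f"{stem.name}_outer{suffix}",
    )


def _draw_boundaries(
    base: np.ndarray, pixel_sets: Iterable[Optional[np.ndarray]], color: tuple[int, int, int]
) -> np.ndarray:
    out = base.copy()
    for coords in pixel_sets:
        if coords is None or len(coords) == 0:
            continue
        mask = np.zeros(base.shape[:2], dtype=bool)
        mask[coords[:, 0], coords[:, 1]] = True
        edge = find_boundaries(mask, mode="inner", connectivity=2)
        out[edge] = color
    return out


def write_overlay(field: IntensityField, result: "FieldResult", path: str | Path) -> tuple[Path, Path]:
    """Write the pair of threshold-analysis pictures for one field.

    Two raster images are produced next to ``path``: ``<stem>_rn`` with the
    residual-nucleus boundaries drawn in red, and ``<stem>_outer`` with the
    outer halo boundaries drawn in green.  Fields with no measured objects
    yield overlays identical to the input image.

    Returns the two paths written.
    """
    rn_path, outer_path = _overlay_paths(Path(path))
    base = np.stack([field.pixels] * 3, axis=-1)
    rn_img = _draw_boundaries(
        base, (m.rn_pixels for m in result.measurements), (255, 0, 0)
    )
    outer_img = _draw_boundaries(
        base, (m.outer_pixels for m in result.measurements), (0, 255, 0)
    )
    try:
        iio.imwrite(rn_path, rn_img.astype(np.uint8))
        iio.imwrite(outer_path, outer_img.astype(np.uint8))
    except Exception as exc:
        raise IOError(f"cannot write overlay near {path}: {exc}") from exc
    return rn_path, outer_path


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return f"{value:.4f}"
    return str(value)


def write_measurements_csv(results: Sequence["FieldResult"], path: str | Path) -> None:
    """Write one CSV row per detected object across all field results.

    Numeric cells of failed measurements are left empty; the ``status``
    column records why (``rn_fail`` / ``outer_fail``).  The header is always
    present, comma-separated, UTF-8, ``.`` decimal.
    """
    path = Path(path)
    try:
        handle = open(path, "w", newline="", encoding="utf-8")
    except OSError as exc:
        raise IOError(f"cannot write measurement table {path}: {exc}") from exc
    with handle:
        writer = csv.writer(handle)
        writer.writerow(CSV_COLUMNS)
        for result in results:
            for m in result.measurements:
                writer.writerow(
                    [
                        result.source_id,
                        m.object_index,
                        _fmt(result.frame_time_s),
                        m.local_max,
                        _fmt(m.rn_area_px),
                        _fmt(m.outer_area_px),
                        _fmt(m.rn_radius_px),
                        _fmt(m.outer_radius_px),
                        _fmt(m.halo_radius_px),
                        m.status,
                        m.class_label or "",
                    ]
                )
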