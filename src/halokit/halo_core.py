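"""The measurement heart of the halo pipeline.

A salt-extracted nucleus images as a bright, near-circular residual nucleus
(RN) surrounded by a diffuse halo of expanded chromatin loops.  Both
structures are delimited by pure intensity thresholding:

* the RN edge sits at ``local_max - x`` for a per-object local maximum and
  a configured offset ``x`` (e.g. ``x = 55``);
* the outer halo edge sits at either an absolute intensity (e.g. 15) or at
  an offset from the local maximum (e.g. ``local_max - 180``).

The shorthand ``"x55/15"`` names the first configuration and ``"x75/x180"``
the second.  Under a relative outer threshold, a dim object whose maximum
cannot be ``outer_value`` above the clip floor *fails* to return a value —
the failure event that drives the stability analysis.

Areas are converted to radii by the equal-area-circle convention
``r = sqrt(A / pi)``, and the halo radius is the outer radius minus the RN
radius.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field as dc_field
from typing import List, Optional, Tuple

import numpy as np
from skimage.measure import label as cc_label

from .image_io import IntensityField

OUTER_MODES = ("absolute", "relative")
BORDER_POLICIES = ("exclude_touching", "keep")
MAXIMA_SCOPES = ("object", "image")

_SHORTHAND_RE = re.compile(r"^x(\d+)/(x?)(\d+)$")


@dataclass(frozen=True)
class ThresholdConfig:
    """Threshold parameterization of one measurement run.

    Attributes
    ----------
    rn_offset_x
        The ``x`` in ``x55``: RN threshold = local maximum - x.
    outer_mode
        ``absolute`` (fixed intensity, e.g. 15) or ``relative``
        (local maximum - outer_value, e.g. 180).
    outer_value
        Absolute intensity, or offset from the local maximum, depending on
        ``outer_mode``.
    seed_threshold
        Coarse detection level for candidate objects; default 15, the most
        permissive outer threshold in use, so detection never misses an
        object the outer threshold could measure.
    min_object_area_px
        Detected components (and segmented RNs) smaller than this are
        discarded as debris.  Default 500 px, sized for full 1388 x 1040
        micrographs; small synthetic frames typically lower it.
    border_policy
        ``exclude_touching`` drops objects touching the frame border whose
        areas would be truncated; ``keep`` retains them.
    maxima_scope
        ``object`` anchors thresholds to each object's own maximum (the
        default — required when cells in one field differ in brightness);
        ``image`` uses the brightest detected object's maximum for every
        object in the field.
    """

    rn_offset_x: int
    outer_mode: str = "absolute"
    outer_value: int = 15
    seed_threshold: int = 15
    min_object_area_px: int = 500
    border_policy: str = "exclude_touching"
    maxima_scope: str = "object"

    def __post_init__(self) -> None:
        for name in ("rn_offset_x", "outer_value", "seed_threshold"):
            v = getattr(self, name)
            if not (1 <= int(v) <= 254):
                raise ValueError(f"{name} must lie in [1, 254], got {v}")
        if self.outer_mode not in OUTER_MODES:
            raise ValueError(f"outer_mode must be one of {OUTER_MODES}")
        if self.border_policy not in BORDER_POLICIES:
            raise ValueError(f"border_policy must be one of {BORDER_POLICIES}")
        if self.maxima_scope not in MAXIMA_SCOPES:
            raise ValueError(f"maxima_scope must be one of {MAXIMA_SCOPES}")
        if self.min_object_area_px < 0:
            raise ValueError("min_object_area_px must be non-negative")
        if self.outer_mode == "relative" and self.rn_offset_x >= self.outer_value:
            # RN threshold must sit above the outer threshold or the RN
            # region would not nest inside the halo.
            raise ValueError(
                "relative outer_value must exceed rn_offset_x "
                f"(got x{self.rn_offset_x}/x{self.outer_value})"
            )

    def shorthand(self) -> str:
        """Render the ``xA/B`` / ``xA/xB`` shorthand for this config."""
        outer = f"x{self.outer_value}" if self.outer_mode == "relative" else str(self.outer_value)
        return f"x{self.rn_offset_x}/{outer}"

    @classmethod
    def from_shorthand(cls, text: str, **overrides) -> "ThresholdConfig":
        """Parse ``"x55/15"`` or ``"x75/x180"`` into a config.

        Keyword overrides set the detection nuisance parameters
        (``seed_threshold``, ``min_object_area_px``, ...).
        """
        m = _SHORTHAND_RE.match(text.strip())
        if not m:
            raise ValueError(
                f"unparseable threshold shorthand {text!r}; expected 'xA/B' or 'xA/xB'"
            )
        rn_offset = int(m.group(1))
        outer_mode = "relative" if m.group(2) == "x" else "absolute"
        outer_value = int(m.group(3))
        return cls(
            rn_offset_x=rn_offset,
            outer_mode=outer_mode,
            outer_value=outer_value,
            **overrides,
        )


@dataclass
class CandidateObject:
    """One connected above-seed-threshold component, before measurement."""

    pixel_coords: np.ndarray  # (N, 2) array of (row, col)
    centroid: Tuple[float, float]
    local_max: int
    max_pixel: Tuple[int, int]  # topmost-then-leftmost maximum-intensity pixel

    @property
    def area_px(self) -> int:
        return len(self.pixel_coords)


@dataclass
class HaloMeasurement:
    """Linked RN/outer measurements and derived radii for one object.

    ``status`` is one of ``measured``, ``rn_fail`` (RN threshold absent, or
    RN region degenerate) and ``outer_fail`` (outer threshold unreachable —
    the decay "fail" event).  Numeric fields of a failed region are ``None``.
    """

    object_index: int
    local_max: int
    centroid: Tuple[float, float]
    rn_threshold: Optional[int] = None
    outer_threshold: Optional[int] = None
    rn_area_px: Optional[int] = None
    outer_area_px: Optional[int] = None
    rn_radius_px: Optional[float] = None
    outer_radius_px: Optional[float] = None
    halo_radius_px: Optional[float] = None
    status: str = "measured"
    class_label: Optional[str] = None
    rn_pixels: Optional[np.ndarray] = dc_field(default=None, repr=False)
    outer_pixels: Optional[np.ndarray] = dc_field(default=None, repr=False)


@dataclass
class FieldResult:
    """All measurements from one field under one configuration."""

    source_id: str
    frame_time_s: Optional[float]
    config: ThresholdConfig
    measurements: List[HaloMeasurement]


def compute_thresholds(
    local_max: int, config: ThresholdConfig
) -> Tuple[Optional[int], Optional[int]]:
    """Derive (rn_threshold, outer_threshold) from an object's maximum.

    A threshold that would fall below 1 is reported absent: the region is
    unmeasurable (a threshold of 0 would select the whole frame).  In
    relative mode the outer threshold is absent exactly when
    ``local_max - outer_value < 1`` — the condition under which a decaying
    halo "fails" to return a value.
    """
    if not (0 <= local_max <= 255):
        raise ValueError(f"local_max must lie in [0, 255], got {local_max}")
    rn = local_max - config.rn_offset_x
    rn_threshold = rn if rn >= 1 else None
    if config.outer_mode == "absolute":
        outer_threshold: Optional[int] = config.outer_value
    else:
        outer = local_max - config.outer_value
        outer_threshold = outer if outer >= 1 else None
    return rn_threshold, outer_threshold


def area_to_radius(area_px: float) -> float:
    """Equal-area-circle radius ``sqrt(A / pi)`` of a pixel region."""
    if area_px < 0:
        raise ValueError("area_px must be non-negative")
    return math.sqrt(area_px / math.pi)


def _touches_border(coords: np.ndarray, shape: Tuple[int, int]) -> bool:
    rows, cols = coords[:, 0], coords[:, 1]
    return bool(
        (rows == 0).any()
        or (cols == 0).any()
        or (rows == shape[0] - 1).any()
        or (cols == shape[1] - 1).any()
    )


def _max_pixel(pixels: np.ndarray, coords: np.ndarray) -> Tuple[int, int, int]:
    """Return (value, row, col) of the topmost-then-leftmost maximum pixel."""
    values = pixels[coords[:, 0], coords[:, 1]]
    vmax = int(values.max())
    at_max = coords[values == vmax]
    # coords from row-major labelling are already sorted (row, col)
    order = np.lexsort((at_max[:, 1], at_max[:, 0]))
    r, c = at_max[order[0]]
    return vmax, int(r), int(c)


def detect_objects(field: IntensityField, config: ThresholdConfig) -> List[CandidateObject]:
    """Find candidate halo objects: 8-connected components above the seed
    threshold, filtered by minimum area and (optionally) border contact.

    Objects are returned in labelling order (top-to-bottom, left-to-right of
    first pixel), each carrying its centroid and per-object local maximum.
    """
    mask = field.pixels >= config.seed_threshold
    labels, n = cc_label(mask, connectivity=2, return_num=True)
    objects: List[CandidateObject] = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        if len(coords) < config.min_object_area_px:
            continue
        if config.border_policy == "exclude_touching" and _touches_border(
            coords, field.pixels.shape
        ):
            continue
        vmax, r, c = _max_pixel(field.pixels, coords)
        centroid = (float(coords[:, 0].mean()), float(coords[:, 1].mean()))
        objects.append(
            CandidateObject(
                pixel_coords=coords, centroid=centroid, local_max=vmax, max_pixel=(r, c)
            )
        )
    return objects


def segment_region(
    field: IntensityField, obj: CandidateObject, threshold: int
) -> Tuple[np.ndarray, int]:
    """Segment one region: the 8-connected component of pixels at or above
    ``threshold`` that contains the object's maximum-intensity pixel.

    Returns ``(coords, area_px)``; an empty coords array and area 0 when no
    pixel of the object reaches the threshold.
    """
    if not (1 <= threshold <= 255):
        raise ValueError(f"threshold must lie in [1, 255], got {threshold}")
    r, c = obj.max_pixel
    if field.pixels[r, c] < threshold:
        return np.empty((0, 2), dtype=np.intp), 0
    mask = field.pixels >= threshold
    labels = cc_label(mask, connectivity=2)
    lab = labels[r, c]
    coords = np.argwhere(labels == lab)
    return coords, len(coords)


def measure_object(
    field: IntensityField,
    obj: CandidateObject,
    config: ThresholdConfig,
    object_index: int = 0,
    local_max: Optional[int] = None,
) -> HaloMeasurement:
    """Measure one candidate object: thresholds, linked RN/outer regions,
    areas and radii.

    The RN and outer regions are linked positionally: both are grown from
    the object's maximum-intensity pixel, so the outer component is by
    construction the one containing the RN seed.  ``local_max`` overrides the
    object's own maximum when thresholds are anchored per image.
    """
    lm = obj.local_max if local_max is None else local_max
    rn_t, outer_t = compute_thresholds(lm, config)
    m = HaloMeasurement(
        object_index=object_index,
        local_max=lm,
        centroid=obj.centroid,
        rn_threshold=rn_t,
        outer_threshold=outer_t,
    )

    rn_ok = False
    if rn_t is not None and (outer_t is None or rn_t > outer_t):
        rn_coords, rn_area = segment_region(field, obj, rn_t)
        if rn_area >= max(config.min_object_area_px, 1):
            m.rn_pixels = rn_coords
            m.rn_area_px = rn_area
            m.rn_radius_px = area_to_radius(rn_area)
            rn_ok = True

    outer_ok = False
    if outer_t is not None:
        outer_coords, outer_area = segment_region(field, obj, outer_t)
        if outer_area > 0:
            m.outer_pixels = outer_coords
            m.outer_area_px = outer_area
            m.outer_radius_px = area_to_radius(outer_area)
            outer_ok = True

    if not rn_ok:
        m.status = "rn_fail"
    elif not outer_ok:
        m.status = "outer_fail"
    else:
        m.status = "measured"
        m.halo_radius_px = m.outer_radius_px - m.rn_radius_px
    return m


def measure_field(field: IntensityField, config: ThresholdConfig) -> FieldResult:
    """Detect and measure every halo in one field.

    Per-object failures are encoded in each measurement's ``status``; the
    call itself never raises for an unmeasurable object, and an empty field
    yields a result with zero measurements.
    """
    objects = detect_objects(field, config)
    image_max = max((o.local_max for o in objects), default=0)
    measurements = []
    for idx, obj in enumerate(objects):
        lm = image_max if config.maxima_scope == "image" else None
        measurements.append(measure_object(field, obj, config, object_index=idx, local_max=lm))
    return FieldResult(
        source_id=field.source_id,
        frame_time_s=field.frame_time_s,
        config=config,
        measurements=measurements,
    )
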