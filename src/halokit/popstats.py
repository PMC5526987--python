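"""Population summaries and threshold-calibration procedures.

Two calibrations anchor the pipeline to independent references:

* exposure calibration — residual-nucleus radii are expressed as a percent
  of a nuclear-matrix marker radius measured in the same cells, so the
  capture exposure can be tuned until the mean percent sits at parity;
* RN-threshold calibration — RN radii measured with a range of offsets are
  compared against visual estimates on a training set, and the offset whose
  mean percent-of-visual is closest to 100 is selected.

Group comparisons use the two-sample equal-variance Student's t-test with
significance stars at p < 0.05 / 0.005 / 0.0005; error bars are SEM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Polygon

from .halo_core import ThresholdConfig, area_to_radius, measure_field
from .image_io import IntensityField

STAR_CUTS = ((0.0005, "***"), (0.005, "**"), (0.05, "*"))


@dataclass(frozen=True)
class CalibrationPair:
    """A reference radius (marker or visual estimate) and the pipeline's."""

    reference_radius_px: float
    derived_radius_px: float

    def __post_init__(self) -> None:
        if self.reference_radius_px <= 0 or self.derived_radius_px <= 0:
            raise ValueError("calibration radii must be strictly positive")


def mean_sem(values: Sequence[float]) -> Tuple[float, Optional[float]]:
    """Arithmetic mean and standard error; SEM is absent for n = 1."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("mean of an empty sample is undefined")
    mean = float(arr.mean())
    if arr.size < 2:
        return mean, None
    return mean, float(arr.std(ddof=1) / math.sqrt(arr.size))


def p_to_stars(p_value: float) -> str:
    """Significance stars at the cuts 0.05 (*), 0.005 (**), 0.0005 (***)."""
    for cut, stars in STAR_CUTS:
        if p_value < cut:
            return stars
    return ""


def two_sample_t(
    values_a: Sequence[float], values_b: Sequence[float]
) -> Tuple[float, float, str]:
    """Two-sided equal-variance Student's t-test with significance stars."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    t = float(t)
    p = float(p)
    if math.isnan(t):  # zero variance in both groups with equal means
        t, p = 0.0, 1.0
    return t, p, p_to_stars(p)


def percent_of_reference(
    pairs: Sequence[CalibrationPair],
) -> Tuple[float, Optional[float]]:
    """Mean and SEM of per-pair percents ``100 * derived / reference``."""
    if len(pairs) == 0:
        raise ValueError("percent_of_reference of an empty pair list is undefined")
    percents = [100.0 * p.derived_radius_px / p.reference_radius_px for p in pairs]
    return mean_sem(percents)


def _field_rn_radius(field: IntensityField, config: ThresholdConfig) -> Optional[float]:
    """Mean RN radius over the measurable objects of one field, or None."""
    result = measure_field(field, config)
    radii = [m.rn_radius_px for m in result.measurements if m.rn_radius_px is not None]
    if not radii:
        return None
    return float(np.mean(radii))


def calibrate_rn_offset(
    training: Sequence[Tuple[IntensityField, float]],
    candidate_offsets: Sequence[int],
    config_base: ThresholdConfig,
) -> Tuple[Optional[int], pd.DataFrame]:
    """Select the RN offset whose measurements best match visual estimates.

    For each candidate offset ``x`` every training field is measured with
    ``rn_offset_x = x`` and the per-field percent of the recorded visual
    radius is averaged.  The selected offset minimizes the distance of that
    mean percent from 100 (parity with the visual training set); ties go to
    the smaller offset.  Candidates for which no training image yields a
    measurable RN are reported with an absent percent and excluded from
    selection.

    Returns ``(best_offset, table)`` where the table has one row per
    candidate: ``candidate_x, n_measured, mean_percent, sem_percent,
    selected``.
    """
    if len(training) == 0:
        raise ValueError("calibration needs a non-empty training set")
    if len(candidate_offsets) == 0:
        raise ValueError("calibration needs at least one candidate offset")
    rows = []
    for x in candidate_offsets:
        cfg = replace(config_base, rn_offset_x=x)
        percents = []
        for field, visual_radius in training:
            if visual_radius <= 0:
                raise ValueError("visual radii must be strictly positive")
            r = _field_rn_radius(field, cfg)
            if r is not None:
                percents.append(100.0 * r / visual_radius)
        if percents:
            mean, sem = mean_sem(percents)
        else:
            mean, sem = None, None
        rows.append(
            {
                "candidate_x": int(x),
                "n_measured": len(percents),
                "mean_percent": mean,
                "sem_percent": sem,
                "selected": False,
            }
        )
    table = pd.DataFrame(rows)
    usable = table[table["mean_percent"].notna()]
    if usable.empty:
        return None, table
    deviation = (usable["mean_percent"] - 100.0).abs()
    # ties resolved toward the smaller offset: stable sort on (|dev|, x)
    order = usable.assign(_dev=deviation).sort_values(["_dev", "candidate_x"])
    best = int(order.iloc[0]["candidate_x"])
    table.loc[table["candidate_x"] == best, "selected"] = True
    return best, table


def polygon_radius(vertices: Sequence[Tuple[float, float]]) -> float:
    """Equal-area-circle radius of a hand-drawn polygon outline.

    Mirrors the visual sizing procedure: trace the structure with a polygon,
    take its (shoelace) area, convert to the radius of the equal-area
    circle.
    """
    if len(vertices) < 3:
        raise ValueError("a polygon needs at least three vertices")
    poly = Polygon(vertices)
    if not poly.is_valid:
        raise ValueError("polygon is self-intersecting or otherwise invalid")
    if poly.area == 0:
        raise ValueError("polygon is degenerate (zero area)")
    return area_to_radius(poly.area)
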