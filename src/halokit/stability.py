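"""Halo decay over timed image series.

The imaging wavelength damages the extracted DNA, so halos decay during
capture: intensity drops until the relative outer threshold becomes
unreachable and the cell "fails" to return a value.  A series of frames
(typically 7, at 0-60 s in 10 s steps) per cell yields a per-cell fail
time; cells still measurable at the last frame are censored at a sentinel
time (70 s by default).  Populations are summarized as the percentage of
surviving halos per time point and as mean time to decay, the censored
cells contributing the sentinel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .halo_core import ThresholdConfig, detect_objects, measure_object
from .image_io import IntensityField

DEFAULT_CENSOR_TIME_S = 70.0
DEFAULT_TRACKING_GATE_PX = 50.0


@dataclass
class CellTimeSeries:
    """Ordered frames of one cell followed through time."""

    cell_id: str
    frames: List[IntensityField]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a time series needs at least one frame")
        times = [f.frame_time_s for f in self.frames]
        if any(t is None for t in times):
            raise ValueError("every frame needs a frame_time_s")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        shape = self.frames[0].pixels.shape
        if any(f.pixels.shape != shape for f in self.frames):
            raise ValueError("all frames must share dimensions")

    @property
    def times(self) -> List[float]:
        return [f.frame_time_s for f in self.frames]


@dataclass
class DecayRecord:
    """Fail time of one cell, censored at the sentinel when it never fails."""

    cell_id: str
    fail_time_s: float
    censored: bool
    note: str = ""


def _select_tracked(
    objects, prev_centroid: Optional[Tuple[float, float]], gate_px: float
):
    """Pick the tracked object: largest at the first frame, thereafter the
    object nearest the previous centroid within the displacement gate."""
    if not objects:
        return None
    if prev_centroid is None:
        return max(objects, key=lambda o: o.area_px)
    best, best_d = None, gate_px
    for o in objects:
        d = math.hypot(
            o.centroid[0] - prev_centroid[0], o.centroid[1] - prev_centroid[1]
        )
        if d <= best_d:
            best, best_d = o, d
    return best


def decay_record(
    series: CellTimeSeries,
    config: ThresholdConfig,
    censor_time_s: float = DEFAULT_CENSOR_TIME_S,
    tracking_gate_px: float = DEFAULT_TRACKING_GATE_PX,
) -> DecayRecord:
    """Measure one cell across its frames and record its first failure.

    Each frame is measured for the tracked cell only.  The fail time is the
    time of the first frame whose measurement status is not ``measured``
    (including frames where the tracked object vanishes below the seed
    threshold or leaves the tracking gate).  A cell measurable at every
    frame is censored at ``censor_time_s``.  A frame that becomes measurable
    again *after* a failure does not rescind it; such transients are noted
    in the record for audit.
    """
    if config.outer_mode != "relative":
        raise ValueError(
            "decay is defined by a relative outer threshold becoming "
            "unreachable; config.outer_mode must be 'relative'"
        )
    prev_centroid: Optional[Tuple[float, float]] = None
    fail_time: Optional[float] = None
    notes: List[str] = []
    for frame in series.frames:
        objects = detect_objects(frame, config)
        tracked = _select_tracked(objects, prev_centroid, tracking_gate_px)
        if tracked is None:
            measured = False
            reason = "object lost (below seed threshold or outside gate)"
        else:
            m = measure_object(frame, tracked, config)
            measured = m.status == "measured"
            reason = m.status
            prev_centroid = tracked.centroid
        if fail_time is None and not measured:
            fail_time = float(frame.frame_time_s)
            if tracked is None:
                notes.append(f"tracking lost at {frame.frame_time_s:g} s")
        elif fail_time is not None and measured:
            notes.append(
                f"transiently measurable again at {frame.frame_time_s:g} s (ignored)"
            )
    if fail_time is None:
        return DecayRecord(
            cell_id=series.cell_id,
            fail_time_s=float(censor_time_s),
            censored=True,
            note="; ".join(notes),
        )
    return DecayRecord(
        cell_id=series.cell_id,
        fail_time_s=fail_time,
        censored=False,
        note="; ".join(notes),
    )


def surviving_fraction(
    records: Sequence[DecayRecord], times: Sequence[float]
) -> List[Tuple[float, float]]:
    """Percent of halos still measurable at each time point.

    A cell survives time ``t`` when its fail time is strictly greater than
    ``t``; censored cells carry the sentinel and hence survive every
    observed time.
    """
    if len(records) == 0:
        raise ValueError("surviving_fraction of an empty record set is undefined")
    n = len(records)
    fails = np.array([r.fail_time_s for r in records], dtype=float)
    return [(float(t), 100.0 * float((fails > t).sum()) / n) for t in times]


def mean_time_to_decay(records: Sequence[DecayRecord]) -> Tuple[float, Optional[float]]:
    """Mean and SEM of per-cell fail times, censored cells contributing the
    sentinel value (70 s by default)."""
    if len(records) == 0:
        raise ValueError("mean time to decay of an empty record set is undefined")
    values = np.array([r.fail_time_s for r in records], dtype=float)
    mean = float(values.mean())
    if len(values) < 2:
        return mean, None
    sem = float(values.std(ddof=1) / math.sqrt(len(values)))
    return mean, sem
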