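"""Synthetic halo phantoms with closed-form ground truth.

No public image sets exist for the salt-extraction halo assay, so tests and
benchmarks run on rendered phantoms: a bright near-circular residual
nucleus (RN) of radius ``a`` sitting on a uniform background ``b``, with a
Gaussian-tailed halo of decay length ``s``:

    I(r) = b + (P - b)                              for r <= a   (plateau)
    I(r) = b + (P - b) * exp(-((r - a) / s)^2)      for r >  a

where ``P`` is the peak intensity.  The Gaussian tail makes every
intensity-threshold crossing available in closed form,

    r(t) = a + s * sqrt(ln((P - b) / (t - b))),

which is what turns the generator into an oracle: the pipeline's measured
radii can be compared against analytic truth to sub-pixel accuracy.  Timed
series decay the peak multiplicatively, ``P(t) = b + (P0 - b) *
exp(-k t)``, so the frame at which a relative outer threshold becomes
unreachable is also known exactly.

Rendering is deterministic given a seed; noise is additive Gaussian,
clipped to [0, 255] and rounded, a simple stand-in for camera noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .image_io import IntensityField, write_field
from .stability import CellTimeSeries

DEFAULT_FRAME_TIMES_S = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)

#: intensity contribution below which a rendered pixel rounds to background
_RENDER_FLOOR = 0.5


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic halo.

    ``peak_intensity`` may be fractional during decay rendering; rendered
    pixels are always rounded to 8-bit.  ``class_intent`` records which
    stability class the phantom was built to exercise (metadata only; the
    classifier never sees it).
    """

    center: Tuple[float, float]
    rn_radius_px: float
    peak_intensity: float
    halo_scale_px: float
    background: int = 0
    plateau: bool = True
    noise_sd: float = 0.0
    class_intent: Optional[str] = None

    def __post_init__(self) -> None:
        if self.rn_radius_px <= 0:
            raise ValueError("rn_radius_px must be positive")
        if self.halo_scale_px <= 0:
            raise ValueError("halo_scale_px must be positive")
        if not (0 <= self.background <= 255):
            raise ValueError("background must lie in [0, 255]")
        if not (1 <= self.peak_intensity <= 255):
            raise ValueError("peak_intensity must lie in [1, 255]")
        if self.peak_intensity <= self.background:
            raise ValueError("peak_intensity must exceed background")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def crossing_radius(spec: PhantomSpec, threshold: float) -> Optional[float]:
    """Analytic radius at which the phantom's profile crosses ``threshold``.

    Returns ``None`` when the threshold exceeds the peak (no pixel reaches
    it) and ``math.inf`` when the threshold does not exceed the background
    (the crossing is unbounded; callers must use thresholds above
    background).
    """
    if threshold > spec.peak_intensity:
        return None
    if threshold <= spec.background:
        return math.inf
    amplitude = spec.peak_intensity - spec.background
    arg = math.sqrt(math.log(amplitude / (threshold - spec.background)))
    if spec.plateau:
        return spec.rn_radius_px + spec.halo_scale_px * arg
    return spec.halo_scale_px * arg


def support_radius(spec: PhantomSpec) -> float:
    """Radius beyond which rendered pixels round to the background."""
    r = crossing_radius(spec, spec.background + _RENDER_FLOOR)
    assert r is not None and math.isfinite(r)
    return r


def _profile(spec: PhantomSpec, r: np.ndarray) -> np.ndarray:
    amplitude = spec.peak_intensity - spec.background
    if spec.plateau:
        tail_arg = np.maximum(r - spec.rn_radius_px, 0.0) / spec.halo_scale_px
    else:
        tail_arg = r / spec.halo_scale_px
    return spec.background + amplitude * np.exp(-(tail_arg**2))


def _validate_layout(
    specs: Sequence[PhantomSpec], width_px: int, height_px: int
) -> None:
    sup = [support_radius(s) for s in specs]
    for s, r in zip(specs, sup):
        row, col = s.center
        if not (r <= row <= height_px - 1 - r and r <= col <= width_px - 1 - r):
            raise ValueError(
                f"phantom at {s.center} with support radius {r:.1f} px does "
                f"not fit within a {width_px} x {height_px} frame"
            )
    for i in range(len(specs)):
        for j in range(i + 1, len(specs)):
            d = math.dist(specs[i].center, specs[j].center)
            if d < sup[i] + sup[j]:
                raise ValueError(
                    f"phantoms {i} and {j} overlap above background "
                    f"(centers {d:.1f} px apart, supports {sup[i]:.1f} + {sup[j]:.1f})"
                )
    backgrounds = {s.background for s in specs}
    if len(backgrounds) > 1:
        raise ValueError("all phantoms in one field must share a background level")
    noise_levels = {s.noise_sd for s in specs}
    if len(noise_levels) > 1:
        raise ValueError("all phantoms in one field must share a noise level")


def render_field(
    specs: Sequence[PhantomSpec],
    width_px: int,
    height_px: int,
    seed: int,
    source_id: Optional[str] = None,
    frame_time_s: Optional[float] = None,
) -> Tuple[IntensityField, List[PhantomSpec]]:
    """Render a multi-phantom field; same specs + seed give bit-identical
    pixels.

    Pixels take the maximum over phantom profiles, then additive Gaussian
    noise (the specs' common ``noise_sd``), clipping to [0, 255] and
    rounding.  Returns the field together with the spec list, which *is*
    the ground truth: per-phantom analytic threshold crossings come from
    :func:`crossing_radius`.
    """
    if len(specs) == 0:
        raise ValueError("render_field needs at least one phantom spec")
    _validate_layout(specs, width_px, height_px)
    background = specs[0].background
    noise_sd = specs[0].noise_sd
    canvas = np.full((height_px, width_px), float(background))
    rows = np.arange(height_px, dtype=float)[:, None]
    cols = np.arange(width_px, dtype=float)[None, :]
    for spec in specs:
        # render only within the support bounding box
        sup = support_radius(spec) + 2.0
        r0, c0 = spec.center
        rlo, rhi = max(0, int(r0 - sup)), min(height_px, int(r0 + sup) + 1)
        clo, chi = max(0, int(c0 - sup)), min(width_px, int(c0 + sup) + 1)
        rr = rows[rlo:rhi] - r0
        cc = cols[:, clo:chi] - c0
        dist = np.sqrt(rr**2 + cc**2)
        patch = _profile(spec, dist)
        np.maximum(canvas[rlo:rhi, clo:chi], patch, out=canvas[rlo:rhi, clo:chi])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        canvas = canvas + rng.normal(0.0, noise_sd, size=canvas.shape)
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    field = IntensityField(
        pixels=pixels,
        source_id=source_id or f"synthetic_seed{seed}",
        frame_time_s=frame_time_s,
    )
    return field, list(specs)


def single_phantom_field(
    spec: PhantomSpec, seed: int, margin_px: float = 8.0
) -> Tuple[IntensityField, PhantomSpec]:
    """Render one phantom centred in the smallest frame that contains its
    support plus a margin; the spec's own center is replaced accordingly."""
    half = int(math.ceil(support_radius(spec) + margin_px))
    size = 2 * half + 1
    centred = replace(spec, center=(float(half), float(half)))
    field, truth = render_field([centred], size, size, seed)
    return field, truth[0]


@dataclass(frozen=True)
class DecaySpec:
    """A phantom plus a multiplicative intensity-decay law for timed series."""

    phantom: PhantomSpec
    decay_rate_per_s: float
    frame_times_s: Tuple[float, ...] = DEFAULT_FRAME_TIMES_S
    seed: int = 0
    width_px: int = 128
    height_px: int = 128

    def __post_init__(self) -> None:
        if self.decay_rate_per_s < 0:
            raise ValueError("decay_rate_per_s must be non-negative")
        times = self.frame_times_s
        if len(times) == 0 or any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be non-empty and strictly increasing")

    def peak_at(self, t: float) -> float:
        """Continuous decayed peak ``b + (P0 - b) * exp(-k t)``."""
        p = self.phantom
        return p.background + (p.peak_intensity - p.background) * math.exp(
            -self.decay_rate_per_s * t
        )


def analytic_fail_time(spec: DecaySpec, outer_value: int) -> Optional[float]:
    """First frame time at which the relative outer threshold is
    unreachable, i.e. the rendered (rounded) peak minus ``outer_value``
    drops below 1; ``None`` when the halo survives every frame."""
    for t in spec.frame_times_s:
        rendered_peak = float(np.rint(spec.peak_at(t)))
        if rendered_peak - outer_value < 1:
            return float(t)
    return None


def render_timeseries(
    spec: DecaySpec, cell_id: str = "cell", outer_value: int = 180
) -> Tuple[CellTimeSeries, Optional[float]]:
    """Render a decaying per-cell series and its analytic fail time.

    Each frame re-renders the phantom with the decayed peak; noise (if any)
    is drawn independently per frame from the series seed.  The returned
    fail time is ``None`` for a series that stays measurable at every frame
    (the censored case).
    """
    frames = []
    for k, t in enumerate(spec.frame_times_s):
        peak_t = spec.peak_at(t)
        frame_phantom = replace(spec.phantom, peak_intensity=max(1.0, peak_t))
        field, _ = render_field(
            [frame_phantom],
            spec.width_px,
            spec.height_px,
            seed=int(np.random.SeedSequence([spec.seed, k]).generate_state(1)[0] % (2**31)),
            source_id=f"{cell_id}_t{t:g}",
            frame_time_s=t,
        )
        frames.append(field)
    series = CellTimeSeries(cell_id=cell_id, frames=frames)
    return series, analytic_fail_time(spec, outer_value)


def write_phantom_field(
    field: IntensityField,
    truth: Sequence[PhantomSpec],
    tiff_path: str | Path,
    sidecar_thresholds: Sequence[int] = (15, 180, 200, 220),
) -> Path:
    """Write a rendered field as 8-bit grayscale TIFF plus a JSON ground
    truth sidecar (per phantom: center, radii, peak, class intent, and
    analytic crossing radii at the named thresholds)."""
    tiff_path = Path(tiff_path)
    write_field(field, tiff_path)
    records = []
    for spec in truth:
        crossings = {}
        for t in sidecar_thresholds:
            r = crossing_radius(spec, t)
            crossings[str(t)] = (
                None if r is None else ("unbounded" if math.isinf(r) else round(r, 3))
            )
        records.append(
            {
                "center": list(spec.center),
                "rn_radius_px": spec.rn_radius_px,
                "peak_intensity": spec.peak_intensity,
                "halo_scale_px": spec.halo_scale_px,
                "background": spec.background,
                "noise_sd": spec.noise_sd,
                "class_intent": spec.class_intent,
                "crossing_radius_px": crossings,
            }
        )
    sidecar = tiff_path.with_suffix(".json")
    sidecar.write_text(json.dumps({"source_id": field.source_id, "phantoms": records}, indent=2))
    return sidecar


# ---------------------------------------------------------------------------
# Study populations: samplers used by the benchmark suites.  Parameter
# ranges are chosen so every phantom is unambiguous by design (thresholds
# cross well inside the frame; class intents sit >= 10 intensity units from
# the classifier cuts).


def sample_recovery_phantom(rng: np.random.Generator, noise_sd: float = 0.0) -> PhantomSpec:
    """One random size-recovery phantom: peak 255 on background 0, RN core
    2-20 px, halo decay length 17-40 px (RN crossings land near 10-40 px and
    halo widths near 20-50 px under the x55/15 thresholds)."""
    return PhantomSpec(
        center=(0.0, 0.0),  # placed by single_phantom_field
        rn_radius_px=float(rng.uniform(2.0, 20.0)),
        peak_intensity=255,
        halo_scale_px=float(rng.uniform(17.0, 40.0)),
        background=0,
        noise_sd=noise_sd,
    )


def phantom_for_class(intent: str, rng: np.random.Generator) -> PhantomSpec:
    """A phantom built to land in class ``intent`` under an ``RNxA/RN220``
    classifier with A in {55, 75}.

    Ia: saturated plateau (peak 255) — most RN pixels exceed the 220 cut.
    Ib: pale plateau (peak 190-210) — no RN pixel exceeds the cut.
    II: dim object (peak 30-45) — the RN threshold falls below 1 and RN
    measurement fails outright.
    """
    if intent == "Ia":
        peak = 255.0
    elif intent == "Ib":
        peak = float(rng.integers(190, 211))
    elif intent == "II":
        peak = float(rng.integers(30, 46))
    else:
        raise ValueError(f"unknown class intent {intent!r}")
    return PhantomSpec(
        center=(0.0, 0.0),
        rn_radius_px=float(rng.uniform(14.0, 22.0)),
        peak_intensity=peak,
        halo_scale_px=float(rng.uniform(8.0, 14.0)),
        background=0,
        class_intent=intent,
    )


def sample_decay_spec(
    rng: np.random.Generator,
    outer_value: int = 180,
    frame_times_s: Tuple[float, ...] = DEFAULT_FRAME_TIMES_S,
    guard_margin: float = 0.3,
) -> DecaySpec:
    """A random decay series whose analytic fail frame is unambiguous.

    Rates are drawn log-uniformly over [0.002, 0.05] /s so the population
    mixes fast failures, mid-series failures and censored survivors; draws
    whose decayed peak lands within ``guard_margin`` intensity units of the
    rounding boundary at any frame are rejected and redrawn (rounding would
    otherwise make the crossing frame ill-defined).
    """
    phantom = PhantomSpec(
        center=(64.0, 64.0),
        rn_radius_px=float(rng.uniform(12.0, 18.0)),
        peak_intensity=255,
        halo_scale_px=float(rng.uniform(7.0, 10.0)),
        background=0,
    )
    boundary = outer_value + 0.5  # rounded peak <= outer_value iff peak < boundary
    while True:
        rate = float(np.exp(rng.uniform(np.log(0.002), np.log(0.05))))
        spec = DecaySpec(
            phantom=phantom,
            decay_rate_per_s=rate,
            frame_times_s=frame_times_s,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        if all(
            abs(spec.peak_at(t) - boundary) >= guard_margin for t in frame_times_s
        ):
            return spec
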