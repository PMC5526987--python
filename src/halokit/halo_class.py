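"""Stability classes of halo products.

Populations of salt-extracted nuclei fall into three phenotypes reflecting
decreasing DNA:nuclear-matrix attachment stability:

* **Ia** — bright, well defined residual nucleus (RN): more than half of the
  RN pixels exceed the brightness cut (default 220);
* **Ib** — pale but defined RN: half or fewer RN pixels exceed the cut;
* **II** — ill-defined RN that fails RN measurement altogether.

The classifier re-segments the RN with its own offset (shorthand
``"RNx75/RN220"``: RN threshold = local maximum - 75, brightness cut 220),
so classification is independent of whichever thresholds sized the halo.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .halo_core import (
    FieldResult,
    HaloMeasurement,
    ThresholdConfig,
    measure_field,
)
from .image_io import IntensityField

CLASS_LABELS = ("Ia", "Ib", "II")

_CLASS_SHORTHAND_RE = re.compile(r"^RNx(\d+)/RN(\d+)$")


class EmptyPopulationError(ValueError):
    """Raised when a distribution is requested over zero cells."""


@dataclass(frozen=True)
class HaloClass:
    """Class designation for one cell.

    ``bright_fraction`` is the fraction of RN pixels strictly above the
    brightness cut; it is absent exactly for class II (no measurable RN).
    """

    label: str
    bright_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ValueError(f"label must be one of {CLASS_LABELS}")
        if (self.label == "II") != (self.bright_fraction is None):
            raise ValueError("bright_fraction is absent exactly for class II")


@dataclass(frozen=True)
class ClassConfig:
    """Parameters of the classification variant of the measurement macro.

    Defaults reproduce ``RNx75/RN220``; ``RNx55/RN220`` is the variant used
    for cell lines measured with the ``x55`` size offset.
    """

    rn_offset_x: int = 75
    bright_intensity_cut: int = 220
    bright_fraction_cut: float = 0.5

    def __post_init__(self) -> None:
        if not (1 <= self.rn_offset_x <= 254):
            raise ValueError("rn_offset_x must lie in [1, 254]")
        if not (0 <= self.bright_intensity_cut <= 255):
            raise ValueError("bright_intensity_cut must lie in [0, 255]")
        if not (0 < self.bright_fraction_cut < 1):
            raise ValueError("bright_fraction_cut must lie in (0, 1)")

    def shorthand(self) -> str:
        return f"RNx{self.rn_offset_x}/RN{self.bright_intensity_cut}"

    @classmethod
    def from_shorthand(cls, text: str, **overrides) -> "ClassConfig":
        m = _CLASS_SHORTHAND_RE.match(text.strip())
        if not m:
            raise ValueError(
                f"unparseable class shorthand {text!r}; expected 'RNxA/RNB'"
            )
        return cls(
            rn_offset_x=int(m.group(1)),
            bright_intensity_cut=int(m.group(2)),
            **overrides,
        )


def classify_halo(
    field: IntensityField,
    measurement: HaloMeasurement,
    rn_pixels: Optional[np.ndarray],
    config: ClassConfig,
) -> HaloClass:
    """Classify one measured halo as Ia, Ib or II.

    Class II is RN-measurement failure.  Otherwise the bright fraction
    ``f = #(RN pixels > cut) / RN area`` decides: strictly above the
    fraction cut (default 0.5) is Ia, at or below is Ib — an exact 50/50 tie
    is pale (Ib) so the boundary is deterministic.
    """
    if measurement.status == "rn_fail":
        return HaloClass(label="II")
    if rn_pixels is None or len(rn_pixels) == 0:
        raise ValueError(
            "measurement reports a segmented RN but no RN pixels were supplied"
        )
    values = field.pixels[rn_pixels[:, 0], rn_pixels[:, 1]]
    f = float(np.count_nonzero(values > config.bright_intensity_cut)) / len(values)
    label = "Ia" if f > config.bright_fraction_cut else "Ib"
    return HaloClass(label=label, bright_fraction=f)


def classify_field(
    field: IntensityField,
    config: ClassConfig,
    detection: Optional[ThresholdConfig] = None,
) -> Tuple[FieldResult, List[HaloClass]]:
    """Measure a field with the classifier's own RN offset and classify
    every detected object.

    ``detection`` supplies the nuisance parameters (seed threshold, minimum
    area, border policy); its RN offset is replaced by the classifier's.
    Each measurement's ``class_label`` is filled in, so the class column
    appears in measurement CSVs.
    """
    base = detection if detection is not None else ThresholdConfig(rn_offset_x=config.rn_offset_x)
    cfg = replace(base, rn_offset_x=config.rn_offset_x)
    result = measure_field(field, cfg)
    classes: List[HaloClass] = []
    for m in result.measurements:
        c = classify_halo(field, m, m.rn_pixels, config)
        m.class_label = c.label
        classes.append(c)
    return result, classes


def class_distribution(classes: Sequence[HaloClass]) -> Tuple[float, float, float]:
    """Fractions (Ia, Ib, II) of a classified population; they sum to 1."""
    if len(classes) == 0:
        raise EmptyPopulationError("cannot compute a class distribution of zero cells")
    n = len(classes)
    counts = {lab: 0 for lab in CLASS_LABELS}
    for c in classes:
        counts[c.label] += 1
    return counts["Ia"] / n, counts["Ib"] / n, counts["II"] / n
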