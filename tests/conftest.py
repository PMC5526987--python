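import pytest

from halokit import ThresholdConfig
from halokit import synthgen as sg


@pytest.fixture
def recovery_config() -> ThresholdConfig:
    """x55/15 thresholds with a debris floor sized for small test frames."""
    return ThresholdConfig.from_shorthand("x55/15", min_object_area_px=200)


@pytest.fixture
def relative_config() -> ThresholdConfig:
    """x75/x180 thresholds (relative outer edge, the decay configuration)."""
    return ThresholdConfig.from_shorthand("x75/x180", min_object_area_px=200)


def render_single(spec: sg.PhantomSpec, seed: int):
    """Render one phantom in a fitted frame; returns (field, placed spec)."""
    return sg.single_phantom_field(spec, seed=seed)


@pytest.fixture
def simple_phantom() -> sg.PhantomSpec:
    return sg.PhantomSpec(
        center=(0.0, 0.0),
        rn_radius_px=12.0,
        peak_intensity=255,
        halo_scale_px=20.0,
        background=0,
    )
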