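import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from curvimetry import PhantomSpec, generate_phantom

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_phantom():
    """Factory for noise-free, untilted phantoms, cached per angle."""
    cache: dict[float, object] = {}

    def _make(angle_deg: float, **kwargs):
        key = (angle_deg, tuple(sorted(kwargs.items())))
        if key not in cache:
            cache[key] = generate_phantom(
                PhantomSpec(curvature_angle_deg=angle_deg, **kwargs)
            )
        return cache[key]

    return _make


@pytest.fixture(scope="session")
def rect_mask():
    """Axis-aligned 40x100 solid rectangle inside a 200x260 frame."""
    mask = np.zeros((200, 260), dtype=bool)
    mask[80:120, 80:180] = True
    return mask
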