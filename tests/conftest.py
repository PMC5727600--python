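import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy import ndimage

from disector import SamplingDesign

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Worked-example per-pair count series (13 pairs, cutting order).
TABLE2_Q = [9, 30, 23, 12, 14, 6, 11, 15, 15, 14, 7, 2, 0]


@pytest.fixture(scope="session")
def paper_design() -> SamplingDesign:
    """The study's sampling constants: every 50th section, 60,000 µm² frame,
    387.29 µm steps, 5 µm sections."""
    return SamplingDesign()


@pytest.fixture
def table2_q() -> list[int]:
    return list(TABLE2_Q)


def make_texture(rng: np.random.Generator, size: int = 256) -> np.ndarray:
    """Smooth blob texture emulating a stained tissue section image."""
    img = ndimage.gaussian_filter(rng.normal(size=(size, size)), 6)
    return (img - img.min()) / (img.max() - img.min())
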