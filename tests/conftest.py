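import numpy as np
import pytest

from lipogate.events import ImageEvent
from lipogate.synthetic import DEFAULT_OPTICS, PhenotypeSpec, render_event


@pytest.fixture(scope="session")
def optics():
    return DEFAULT_OPTICS


@pytest.fixture(scope="session")
def sphere_event(optics):
    """Noisy in-focus 8 um sphere with no reporter."""
    return render_event(PhenotypeSpec(diameter=8.0), optics, rng_seed=7)


@pytest.fixture(scope="session")
def clean_sphere_event(optics):
    """Noise-free in-focus 8 um sphere (expected image + background)."""
    return render_event(PhenotypeSpec(diameter=8.0), optics, rng_seed=7,
                        noise=False)


def make_event(arrays: dict, pixel_size: float = 1.0, event_id: str = "t"):
    return ImageEvent(
        event_id=event_id,
        channels={k: np.asarray(v, dtype=float) for k, v in arrays.items()},
        pixel_size=pixel_size,
    )
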