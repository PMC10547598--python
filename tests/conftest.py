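import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from rootsense.synthgen import SyntheticSpec, render_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def scene_factory():
    """Render a small synthetic scene with overridable parameters."""

    def factory(**kwargs):
        defaults = dict(
            image_size=(96, 128), n_roots=1, colour_score=8.0,
            mealiness_score=0.0, pixel_noise_sd=0.0, seed=7,
        )
        defaults.update(kwargs)
        return render_scene(SyntheticSpec(**defaults))

    return factory
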