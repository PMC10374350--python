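import numpy as np
import pytest

from polypcadx import bovw
from polypcadx.synth import SyntheticSpec, generate_polyp_image

CLASSES = ("adenoma", "ssl", "hyperplastic")


def make_samples(n, seed0, radius_rng_seed=0, radii=(55.0, 95.0)):
    """n clean captures cycling through the classes, with ground-truth boxes."""
    rng = np.random.default_rng(radius_rng_seed)
    out = []
    for i in range(n):
        cls = CLASSES[i % 3]
        img, truth = generate_polyp_image(SyntheticSpec(
            polyp_class=cls, polyp_radius=float(rng.uniform(*radii)), seed=seed0 + i))
        out.append((img, truth.box, cls))
    return out


@pytest.fixture(scope="session")
def clean_capture():
    """One undegraded adenoma capture with its ground truth."""
    return generate_polyp_image(SyntheticSpec(polyp_class="adenoma", seed=11))


@pytest.fixture(scope="session")
def small_model():
    """A small but functional BoVW model (48 training captures, k=48)."""
    samples = make_samples(48, seed0=1000)
    return bovw.fit_bovw(samples, params=bovw.BovwParams(vocabulary_size=48), seed=7)
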