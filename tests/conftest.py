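import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stasa.model import Fixation, Scanpath, ScanpathSample, StimulusFrame

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def stimulus() -> StimulusFrame:
    return StimulusFrame(800, 600, 3000)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_scanpath(observer, xs, ys, times):
    """Scanpath from parallel coordinate and (b, e) lists."""
    return Scanpath(
        observer,
        tuple(Fixation(x, y, b, e) for x, y, (b, e) in zip(xs, ys, times)),
    )


@pytest.fixture
def simple_scanpath() -> Scanpath:
    return make_scanpath(
        "obs0",
        [100, 400, 650],
        [150, 300, 500],
        [(0, 500), (600, 1400), (1500, 2800)],
    )


@pytest.fixture
def simple_sample(simple_scanpath, stimulus) -> ScanpathSample:
    shifted = Scanpath(
        "obs1",
        tuple(
            Fixation(f.x + 10, f.y - 10, f.b, f.e) for f in simple_scanpath
        ),
    )
    return ScanpathSample((simple_scanpath, shifted), stimulus)
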