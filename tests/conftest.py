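import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import muscleox as mx

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def timing():
    """The standard 15-min protocol: 5 min each of baseline/occlusion/hyperemia, TR 3 s."""
    return mx.ProtocolTiming()


@pytest.fixture
def short_timing():
    """A compressed paradigm for hand-checkable examples: TR 3 s, 10 frames."""
    return mx.ProtocolTiming(
        baseline_start=0.0,
        occlusion_start=9.0,
        deflation_time=18.0,
        end_time=30.0,
        tr=3.0,
        baseline_discard=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_phantom():
    """Noise-free 32x16x2 phantom over the full 15-min protocol."""
    spec = mx.PhantomSpec(shape=(32, 16, 2), seed=7)
    series, mask, truth = mx.simulate_phantom(spec)
    return spec, series, mask, truth


def make_ntc(pct, tr=3.0, t0=None, muscle="test", baseline_si=100.0):
    """NormalizedTimeCourse from a plain list, frame centers at (i+0.5)*tr."""
    pct = np.asarray(pct, dtype=float)
    start = 0.5 * tr if t0 is None else t0
    times = start + np.arange(pct.size) * tr
    return mx.NormalizedTimeCourse(
        muscle=muscle, times=times, pct=pct, baseline_si=baseline_si, baseline_sd=0.0
    )
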