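import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gaitfloor as gf

# fully reproducible property tests
settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def unit_module() -> gf.ModuleGeometry:
    return gf.ModuleGeometry("m0", (0.0, 0.0), 0.38)


@pytest.fixture
def small_layout() -> gf.FloorLayout:
    """2 x 3 modules of gait-resolution edge length, origin at (0, 0)."""
    return gf.FloorLayout.grid(2, 3, edge=0.38)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sim_recording():
    """One deterministic out-and-back recording on the corridor floor."""
    layout = gf.corridor_layout()
    messages = gf.simulate_recording(
        layout, gf.GaitParams(), gf.SimConfig(), np.random.default_rng(7)
    )
    return layout, messages


def random_messages(layout, n, rng, sorted_times=True):
    """Random valid message stream for a layout (helper, not a fixture)."""
    mods = [m.module_id for m in layout.modules]
    times = np.sort(rng.uniform(0, 10, n)) if sorted_times else rng.uniform(0, 10, n)
    return [
        gf.SensorMessage(float(t), mods[int(rng.integers(len(mods)))], rng.uniform(0, 1, 8))
        for t in times
    ]
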