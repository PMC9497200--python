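import numpy as np
import pytest

from ctcscope import (
    CartridgeConfig,
    detect_cartridge,
    enumerate_events,
    generate_cartridge,
    measure_events,
)


@pytest.fixture(scope="session")
def small_cartridge():
    """One default noise-free cartridge with planted ground truth."""
    return generate_cartridge(CartridgeConfig(), seed=1)


@pytest.fixture(scope="session")
def detected(small_cartridge):
    """Detection + measurement + gating results for the session cartridge."""
    stack, truth = small_cartridge
    events = detect_cartridge(stack)
    features = measure_events(events, stack)
    gated, counts = enumerate_events(features)
    return {
        "stack": stack,
        "truth": truth,
        "events": events,
        "features": features,
        "gated": gated,
        "counts": counts,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
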