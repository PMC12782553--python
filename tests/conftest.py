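import numpy as np
import pytest

from barcodenet import BarcodeMemory, ModelConfig


def reduced_config(N: int = 1000, **kw) -> ModelConfig:
    return ModelConfig(N_p=N, N_x=N, N_y=N, **kw)


@pytest.fixture(scope="session")
def cfg_tiny():
    """Structural-test scale: fast, not meant to show memory behavior."""
    return reduced_config(200)


@pytest.fixture(scope="session")
def cfg_small():
    """Behavioral-test scale: the memory mechanism is fully functional."""
    return reduced_config(1000)


@pytest.fixture(scope="session")
def stored_model(cfg_small):
    """One model with two well-separated caches, shared across read-only tests."""
    model = BarcodeMemory(cfg_small, seed=3)
    model.store_cache(20)
    model.store_cache(70)
    return model


@pytest.fixture(scope="session")
def three_cache_model(cfg_small):
    """Standard three-cache protocol (20%, 35%, 70% of the track)."""
    model = BarcodeMemory(cfg_small, seed=2)
    for c in (20, 35, 70):
        model.store_cache(c)
    return model
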