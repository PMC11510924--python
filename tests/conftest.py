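import numpy as np
import pytest

from mwchamber.em_forward import ChamberModel, generate_mesh, ring_ports, wavelength
from mwchamber.scenarios import ForwardCache


@pytest.fixture(scope="session")
def lam() -> float:
    return wavelength(54.8, 1e9)


@pytest.fixture(scope="session")
def small_model() -> ChamberModel:
    """Shared 8-port chamber at the default mesh rule (fast)."""
    return ChamberModel(n_ports=8)


@pytest.fixture(scope="session")
def small_cache(small_model) -> ForwardCache:
    return ForwardCache(small_model)


@pytest.fixture(scope="session")
def model16() -> ChamberModel:
    return ChamberModel(n_ports=16)


@pytest.fixture(scope="session")
def cache16(model16) -> ForwardCache:
    return ForwardCache(model16)
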