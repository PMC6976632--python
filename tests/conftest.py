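import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from biotinpaint.io import ProteinRecord, StudyRegistry, StudyRegistryEntry

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_proteome():
    return {
        "P1": ProteinRecord("P1", "MKKY", "P1 test protein"),
        "P2": ProteinRecord("P2", "KAKYK", "P2 synthetic ribosomal protein"),
        "P3": ProteinRecord("P3", "STYSTYKK", "P3 test protein"),
    }


@pytest.fixture
def sim_registry():
    return StudyRegistry([StudyRegistryEntry("SIM", "K", "NHS-Biotin", 1000.0)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
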