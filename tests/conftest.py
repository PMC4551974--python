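import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from octsox.motifs import default_motifs
from octsox.simulate import GeneratorConfig, generate_dataset

settings.register_profile(
    "default", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("default")

# EMSA probe sequences used as in-package worked examples: each contains
# exactly one composite element of its namesake class.
PROBES = {
    "HOXB1": "GGAGGAAGTGTCTTTGTCATGCTAATGATTGGGGCTCC",
    "UTF1": "GGAGAAGATGAGAGCCCTCATTGTTATGCTAGTGAAGTGCCAAGCTCC",
    "FGF4": "GGAGAAGAAAACTCTTTGTTTGGATGCTAATGGGATACTAAGCTCC",
}


@pytest.fixture(scope="session")
def motifs():
    return {m.name: m for m in default_motifs()}


@pytest.fixture(scope="session")
def small_config():
    """A fast strict dataset: 60 windows with 10/3/2 plantings."""
    return GeneratorConfig(
        n_peaks=60,
        plant_counts={"Hoxb1-like": 10, "Utf1-like": 3, "Fgf4-like": 2},
        tail=60_000,
        n_genes=40,
        link_fraction=0.5,
        noise_sd=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
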