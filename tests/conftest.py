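import numpy as np
import pytest

from mitooxtox import (
    EndpointTruth,
    GenerativeChemical,
    NoiseModel,
    PlateDesign,
    simulate_plate,
)


@pytest.fixture
def design():
    return PlateDesign()


@pytest.fixture
def noise_free():
    return NoiseModel(signal_cv=0.0, count_dispersion=None, seed=0)


@pytest.fixture
def design_noise():
    """The study design's noise level: ~5% CV on signals and counts."""
    return NoiseModel(signal_cv=0.05, count_dispersion=400.0, seed=0)


@pytest.fixture
def simple_chem():
    """One chemical active on all three endpoints with round-number truth."""
    return GenerativeChemical(
        "chemA",
        mmp=EndpointTruth(top=95.0, ec50=1e-6, hill=1.5),
        cytotoxicity=EndpointTruth(top=90.0, ec50=1e-5, hill=1.5),
        ox_slope=1e5,
        log_dlipw=3.0,
        mie_class="complexI",
    )


@pytest.fixture
def clean_plate(simple_chem, design, noise_free):
    return simulate_plate([simple_chem], design, noise_free)
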