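import json
from pathlib import Path

import pytest

from tissuemech.synthetic import MaterialGroundTruth

FIXTURES = Path(__file__).parent / "fixtures"


@pytest.fixture(scope="session")
def mc_tolerances() -> dict:
    """Recovery tolerances frozen from the independent pilot oracle run."""
    with open(FIXTURES / "mc_tolerances.json") as fh:
        return json.load(fh)["tolerances"]


@pytest.fixture
def clean_truth() -> MaterialGroundTruth:
    """Ground truth with every noise channel switched off."""
    return MaterialGroundTruth(
        E_true=5e3,
        surface_tension_true=0.02,
        pressure_noise_fraction=0.0,
        force_noise_fraction=0.0,
        modulus_noise_fraction=0.0,
        stress_noise_fraction=0.0,
    )
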