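import numpy as np
import pytest

from solvtune import MockEngine, Molecule, SolventSpec, solvent_lookup


@pytest.fixture
def engine():
    return MockEngine()


@pytest.fixture
def water():
    """Small closed-shell solute fixture."""
    return Molecule((
        ("O", (0.000, 0.000, 0.117)),
        ("H", (0.000, 0.757, -0.467)),
        ("H", (0.000, -0.757, -0.467)),
    ))


@pytest.fixture
def dcm():
    return solvent_lookup("DCM")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
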