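import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose oracles.py

from doseshift import DVH
from doseshift.simulate import make_sigmoid_dvh


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def two_level_dvh():
    """Half the structure at 10 Gy, half at 20 Gy (differential form)."""
    return DVH("two-level", "differential", [10.0, 20.0], [0.5, 0.5])


@pytest.fixture
def linear_dvh():
    """Cumulative DVH falling linearly from (0 Gy, 1.0) to (60 Gy, 0.0)."""
    dose = np.linspace(0.0, 60.0, 61)
    return DVH("linear", "cumulative", dose, 1.0 - dose / 60.0)


@pytest.fixture
def uniform_dvh():
    """Whole structure uniformly at 10 Gy (steep cumulative step)."""
    return DVH("uniform", "cumulative", [0.0, 10.0, 10.0 + 1e-9], [1.0, 1.0, 0.0])


def random_clinical_dvh(rng) -> DVH:
    """Random sigmoid DVH with clinically plausible midpoint and spread."""
    d50 = rng.uniform(20.0, 70.0)
    steepness = rng.uniform(0.5, 3.0)
    return make_sigmoid_dvh("random", d50, steepness)
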