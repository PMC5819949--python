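import numpy as np
import pytest

from chexflux import (
    CestSchedule,
    ExchangeNetwork,
    SpinProbe,
    ZzSchedule,
)


@pytest.fixture
def two_state_binding():
    """U <-> B binding step: k_UB = 0.8/s (pseudo-first-order at 500 uM
    ligand), k_BU = 2.7/s."""
    return ExchangeNetwork(
        ("U", "B"), {("U", "B"): 0.8, ("B", "U"): 2.7}, ligand_conc=500e-6
    )


@pytest.fixture
def met_probe():
    return SpinProbe.shared("Met26", {"U": 1.85, "B": 1.95}, r1=2.0, r2=20.0)


@pytest.fixture
def cest_schedule():
    return CestSchedule(tuple(np.linspace(1.0, -0.2, 40)))


@pytest.fixture
def zz_schedule():
    return ZzSchedule(tuple(np.linspace(0.025, 0.8, 13)))
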