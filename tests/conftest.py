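import numpy as np
import pytest

from cpftk.pbk import Scenario, dose_to_cmax_curve


@pytest.fixture(scope="session")
def supersome_scenario():
    return Scenario()


@pytest.fixture(scope="session")
def hlm_scenario():
    return Scenario(mode="hlm_biphasic")


@pytest.fixture(scope="session")
def assembled(supersome_scenario):
    return supersome_scenario.assemble()


@pytest.fixture(scope="session")
def cmax_map(supersome_scenario):
    """Tabulated dose -> free CPO Cmax map for reverse dosimetry tests."""
    doses = np.logspace(-4, 2.5, 25)
    return dose_to_cmax_curve(doses, supersome_scenario, duration=24.0,
                              rtol=1e-6, atol=1e-10)
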