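import numpy as np
import pytest

from copulatrial import CopulaSpec, DesignCriteria, DoseGrid, MarginalPair
from copulatrial.inference import MCMCConfig, PriorSpec, TrialData
from copulatrial.simulation import generate_outcomes, get_scenario


@pytest.fixture(scope="session")
def grid():
    return DoseGrid()


@pytest.fixture(scope="session")
def criteria():
    return DesignCriteria()


@pytest.fixture(scope="session")
def ps1():
    return PriorSpec.preset("PS1")


@pytest.fixture(scope="session")
def fast_mcmc():
    # reduced chain for unit tests; fidelity defaults are 5000/1000
    return MCMCConfig(burn_in=1000, retained=500)


@pytest.fixture(scope="session")
def scenario1():
    return get_scenario(1)


@pytest.fixture(scope="session")
def scenario5():
    return get_scenario(5)


@pytest.fixture(scope="session")
def fixed_design_data():
    """44-subject fixed-design dataset: 11 per dose, Braun psi=0.7, Scenario 1."""
    sc = get_scenario(1)
    rng = np.random.Generator(np.random.PCG64(2024))
    data = TrialData.empty()
    for z in sc.grid.levels:
        y_t, y_e = generate_outcomes(sc, z, CopulaSpec("braun", 0.7), 11, rng)
        data = data.extend([z] * 11, y_t, y_e)
    return data


@pytest.fixture(scope="session")
def pair_grid():
    """Marginal pairs spanning the unit square for property checks."""
    vals = (0.05, 0.27, 0.5, 0.71, 0.95)
    return [MarginalPair(t, e) for t in vals for e in vals]
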