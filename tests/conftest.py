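import numpy as np
import pytest

import deepcompartment as dc


@pytest.fixture(scope="session")
def pk_default() -> dc.PKParameters:
    """Typical adult FVIII parameters used throughout the tests."""
    return dc.PKParameters(CL=0.15, V1=3.0, Q=0.15, V2=0.6)


@pytest.fixture(scope="session")
def small_study() -> dc.SimulatedStudy:
    """A 40-subject virtual study with the generator's defaults."""
    return dc.simulate_population(dc.PopulationConfig(n=40, seed=123))


@pytest.fixture(scope="session")
def random_pk_draws():
    """Random positive parameter/dose draws spanning a wide but sane range."""
    rng = np.random.default_rng(2024)
    draws = []
    for _ in range(100):
        draws.append(
            (
                dc.PKParameters(
                    CL=rng.uniform(0.02, 0.6),
                    V1=rng.uniform(0.4, 7.0),
                    Q=rng.uniform(0.02, 0.6),
                    V2=rng.uniform(0.1, 2.5),
                ),
                rng.uniform(250.0, 5000.0),
            )
        )
    return draws
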