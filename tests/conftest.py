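import numpy as np
import pytest

from tmepre import (SimulationConfig, StabilityParams, build_tmepre,
                    simulate_cohort)

# Reduced derivation settings used throughout the suite: 50 selection rounds
# instead of 200 keeps each derivation under a second while leaving the
# frequency filter meaningful (0.8 * 50 = 40 rounds required).
REDUCED_ROUNDS = 50


@pytest.fixture(scope="session")
def cohort():
    """One paper-scale cohort (131 MSI / 284 MSS, 1000 genes, effect 3)."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def model(cohort):
    """Model derived from the session cohort with reduced selection rounds."""
    expr, ann, _truth = cohort
    return build_tmepre(
        expr, ann,
        StabilityParams(n_rounds=REDUCED_ROUNDS, seed=21),
        StabilityParams(n_rounds=REDUCED_ROUNDS, seed=22),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
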