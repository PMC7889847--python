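import numpy as np
import pytest

from lymphosig.synthetic_data import (
    SubtypeSpec,
    SyntheticCohortSpec,
    demo_signatures,
    generate_reference,
    synthesize_cohort,
)


@pytest.fixture(scope="session")
def signatures():
    return demo_signatures()


@pytest.fixture(scope="session")
def genome():
    return generate_reference(100_000, seed=1)


@pytest.fixture(scope="session")
def small_cohort(genome, signatures):
    """Ten MF-like samples drawn from a 40/60 aging/UV mixture."""
    spec = SyntheticCohortSpec(
        subtypes=[
            SubtypeSpec("MF", 10, {"Signature 1": 0.4, "Signature 7": 0.6})
        ],
        seed=11,
    )
    return synthesize_cohort(spec, genome, signatures)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
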