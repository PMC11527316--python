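import warnings

import pytest

import curiolearn as cl

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_cohort() -> cl.CohortData:
    """A small default-link cohort shared across read-only tests."""
    return cl.simulate_cohort(12, rng_seed=7)


@pytest.fixture(scope="session")
def small_trace(small_cohort):
    """Preprocessed trace merged with participant traits."""
    trials, participants, _ = cl.apply_exclusions(
        small_cohort.trials, small_cohort.participants
    )
    trace = cl.build_trace(trials).merge(participants, on="participant", how="left")
    return trace, participants
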