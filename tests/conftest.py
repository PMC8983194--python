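import numpy as np
import pytest

from gphcs_ge import (
    CensoringPlan,
    GEParams,
    load_ball_bearings,
    scheme_removals,
    simulate_gphc,
)

# printed ball-bearing failure times (millions of revolutions) and plan
BB_TIMES = (17.88, 28.92, 33.00, 42.12, 45.60, 48.80, 51.84, 51.96, 54.12,
            55.56, 67.80, 68.88, 98.64, 105.12, 105.84)
BB_R = (2, 0, 0, 0, 0, 0, 0, 0, 3, 0, 0, 0, 0, 0, 3)


@pytest.fixture(scope="session")
def bb_samples():
    """The three bundled ball-bearing censored datasets, keyed by scheme."""
    return {s: load_ball_bearings(s) for s in (1, 2, 3)}


@pytest.fixture(scope="session")
def study_truth():
    return GEParams(alpha=2.0, lam=1.2)


@pytest.fixture(scope="session")
def benchmark_plan(study_truth):
    """Plan (k=25, m=50, n=60), scheme 1, T=1.5 used by several checks."""
    return CensoringPlan(60, 50, 25, scheme_removals(60, 50, 25, 1), 1.5)


@pytest.fixture(scope="session")
def simulated_samples(study_truth, benchmark_plan):
    """Twenty simulated GPHC samples for randomized derivative checks."""
    return [
        simulate_gphc(study_truth, benchmark_plan,
                      np.random.SeedSequence(entropy=2024, spawn_key=(i,)))
        for i in range(20)
    ]
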