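import warnings

import numpy as np
import pytest

from loombias import lba, synthetic


# BCa bootstrap on tiny samples emits harmless divide warnings from the
# jackknife; keep test output readable.
warnings.filterwarnings(
    "ignore", message=".*divide by zero.*", category=RuntimeWarning
)
warnings.filterwarnings(
    "ignore", message=".*invalid value encountered.*", category=RuntimeWarning
)


@pytest.fixture(scope="session")
def reference_params() -> lba.LBAParams:
    """One plausible participant: correct drifts 2.5, error drifts 1."""
    return lba.LBAParams(
        A=0.5, b=1.2, t0=0.2,
        v={
            n: (2.5 if n.endswith("_correct") else 1.0)
            for n in lba.DRIFT_NAMES
        },
    )


@pytest.fixture(scope="session")
def small_behavior():
    """12 participants x 50 trials/condition from the default truth."""
    truth = synthetic.BehaviorTruth(
        n_participants=12, trials_per_condition=50, seed=5
    )
    data, params = synthetic.gen_behavior(truth)
    return truth, data, params


@pytest.fixture(scope="session")
def tiny_fit():
    """A quick hierarchical fit shared by diagnostic/PPC/ratio tests."""
    truth = synthetic.BehaviorTruth(
        n_participants=4, trials_per_condition=30, seed=42
    )
    data, params = synthetic.gen_behavior(truth)
    chains = lba.de_mcmc_fit(
        data, n_chains=8, n_iter=3000, n_burn=1500, thin=5, seed=7
    )
    return truth, data, chains
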