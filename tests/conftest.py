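import numpy as np
import pytest

import multinoise as mn


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def birth_death():
    """0 -> M at rate 10, M -> 0 at rate 1 (stationary law Poi(10))."""
    return [
        mn.ReactionSpec({}, {"M": 1}, 10.0, name="birth"),
        mn.ReactionSpec({"M": 1}, {}, 1.0, name="death"),
    ]


def se_of_mean(x, n_batches=20):
    from multinoise.summary_stats import batch_stat_se

    return batch_stat_se(x, np.mean, n_batches)
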