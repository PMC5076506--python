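import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160808)


@pytest.fixture(scope="session")
def small_planted_msa():
    """300 x 40 alignment with one strongly planted pair at (3, 20)."""
    from allokin.simulate import MSASimSpec, simulate_msa

    return simulate_msa(
        MSASimSpec(
            n_sequences=300, n_columns=40, planted_pairs=[(3, 20, 0.9)], seed=11
        )
    )


@pytest.fixture(scope="session")
def default_planted_msa():
    """The generator's default study-scale alignment (800 x 120, 4 pairs)."""
    from allokin.simulate import MSASimSpec, simulate_msa

    return simulate_msa(MSASimSpec(seed=101))
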