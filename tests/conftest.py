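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


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_trio():
    """Tiny deterministic trio with all three genotype classes."""
    from cistrio import TrioData

    return TrioData(
        S=np.array([0, 0, 1, 1, 2, 2, 1, 0]),
        R=np.array([-0.5, 0.1, 0.6, 0.4, 1.2, 1.5, 0.3, -0.2]),
        N=np.array([0.2, -0.1, 0.5, 0.8, 1.1, 0.9, 0.4, 0.0]),
    )


@pytest.fixture
def trio_factory(rng):
    """Factory producing random-pattern trios from the shared rng."""
    return lambda n=62: random_trio(rng, n)


def random_trio(rng, n=62):
    """A trio drawn from a random pattern with random moderate effects."""
    from cistrio import SimParams, simulate_trio

    pattern = int(rng.integers(1, 7))
    params = SimParams.for_pattern(
        pattern,
        effect=float(rng.uniform(-1.5, 1.5)),
        n_individuals=n,
        maf=float(rng.uniform(0.1, 0.5)),
        sigma_R=float(rng.uniform(0.3, 1.2)),
        sigma_N=float(rng.uniform(0.3, 1.2)),
    )
    trio, _ = simulate_trio(params, rng=rng)
    return trio
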