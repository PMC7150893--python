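import pytest
from hypothesis import HealthCheck, settings

from icemeta import synthetic as syn

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_run():
    """Default study community, moderate depth, study-level no-hit rate."""
    return syn.simulate_run(
        spec=syn.default_community(seed=11, n_reads_per_sample=400)
    )


@pytest.fixture(scope="session")
def exhaustive_run():
    """Every read gets a hit: exact truth-map comparisons possible."""
    return syn.simulate_run(
        spec=syn.default_community(seed=13, n_reads_per_sample=300), no_hit_rate=0.0
    )
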