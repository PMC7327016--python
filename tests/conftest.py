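import pytest
from hypothesis import HealthCheck, settings

import gradis

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_data():
    """20 genes x 30 samples planted network for fast unit tests."""
    return gradis.make_benchmark_fixture("tiny", seed=0)


@pytest.fixture(scope="session")
def dream4_data():
    """100 genes x 210 samples, 40 TFs, 150 planted edges."""
    return gradis.make_benchmark_fixture("dream4_like", seed=1)


@pytest.fixture(scope="session")
def dream4_fit(dream4_data):
    """Full pipeline fitted at k=30 on the benchmark-shaped fixture."""
    model = gradis.GRADIS(dream4_data.expr, dream4_data.gold, k=30)
    return model.fit(seed=1)


@pytest.fixture(scope="session")
def heldout_scoring():
    """PU scoring run with half the planted edges hidden from the gold
    standard, so the uncharacterized pool contains known-true pairs.

    Returns (dataset, observed_gold, hidden_edges, fitted_results).
    """
    data = gradis.make_benchmark_fixture("dream4_like", seed=2)
    observed_gold, hidden = gradis.hold_out_edges(data.gold, 0.5, seed=2)
    res = gradis.GRADIS(data.expr, observed_gold, k=30).fit(seed=2)
    return data, observed_gold, hidden, res


@pytest.fixture(scope="session")
def tiny_fit(tiny_data):
    return gradis.GRADIS(tiny_data.expr, tiny_data.gold, k=10).fit(seed=0)
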