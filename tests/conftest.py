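import pytest
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
def small_planted():
    """A quick planted dataset: strong signal, 120 windows per class, L=21."""
    from nitrosite import SyntheticSpec, generate_dataset

    spec = SyntheticSpec(
        L=21,
        n_pos=120,
        n_neg=120,
        enrichments=((-1, "K", 0.9), (2, "R", 0.9)),
        terminal_gap_prob=0.1,
        seed=42,
    )
    return generate_dataset(spec)


@pytest.fixture
def tiny_net_params():
    """Network parameters small enough for fast unit tests."""
    return dict(
        hidden_sizes=(16, 8, 8, 8, 8, 8),
        dropout_rates=(0.0, 0.0, 0.0),
        epochs=30,
        batch_size=30,
        l1=0.0,
        l2=1e-4,
    )
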