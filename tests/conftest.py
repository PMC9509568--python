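import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_run(tmp_path_factory):
    """Shared desk-scale end-to-end run: synth → AMSR → train → evaluate.

    One training of the width-0.25 reduced model on 120 synthetic images
    (seeded) serves the end-to-end, loss-decrease, noise-robustness and
    enhancement-benefit checks.
    """
    from leafclar.desk import desk_pipeline

    workdir = tmp_path_factory.mktemp("desk")
    return desk_pipeline(seed=1, workdir=workdir, n_per_class=20,
                         width_multiplier=0.25, max_epochs=30, batch_size=16,
                         use_amsr=True, target_train_acc=0.95)


@pytest.fixture(scope="session")
def tiny_run(tmp_path_factory):
    """Very small trained model for unit-level evaluation plumbing tests."""
    from leafclar.desk import desk_pipeline

    workdir = tmp_path_factory.mktemp("tiny")
    return desk_pipeline(seed=7, workdir=workdir, n_per_class=4,
                         width_multiplier=0.0625, max_epochs=2, batch_size=8,
                         use_amsr=False, target_train_acc=None)
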