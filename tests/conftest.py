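"""Shared fixtures.

The expensive session fixtures (trained desk-scale model suites, the
transfer bundle) back the acceptance tests and a few integration tests;
they are trained once per session at the scaled-down study conditions
documented in docs/methods.md.
"""

import pytest

from tumevol.netmodel import (ModelSpec, TrainConfig, build_network,
                              make_training_set, train, train_desk_models,
                              train_robust_classifier)
from tumevol.sim_neutral import DESK_NARROW, DatasetPriors

DESK_PRIORS = DatasetPriors(**DESK_NARROW)


@pytest.fixture(scope="session")
def toy_data():
    """Small paired dataset for fast integration tests."""
    return make_training_set(300, DESK_PRIORS, seed=4242)


@pytest.fixture(scope="session")
def toy_models(toy_data):
    """Minimally trained model trio (smoke-level quality only)."""
    cfg = dict(max_epochs=8, sims_per_batch=1000, patience=5)
    mms = build_network(ModelSpec(task="ms"), seed=11)
    train(mms, toy_data, TrainConfig(seed=12, **cfg))
    m1 = build_network(ModelSpec(task="1s"), seed=13)
    train(m1, toy_data, TrainConfig(seed=14, **cfg))
    m2 = build_network(ModelSpec(task="2s"), seed=15)
    train(m2, toy_data, TrainConfig(seed=16, **cfg))
    return {"ms": mms, "1s": m1, "2s": m2}


@pytest.fixture(scope="session")
def desk_models():
    """The scaled-down clean-sequencing model suite (25,000 paired
    simulations for the classifier at 100-150x, rho <= 0.003)."""
    return train_desk_models(seed=1001)


@pytest.fixture(scope="session")
def robust_model():
    """Broad-conditions classifier (20-250x, rho up to 0.3) used for
    impure or overdispersed samples after purity correction."""
    return train_robust_classifier(seed=2002)


@pytest.fixture(scope="session")
def transfer_bundle(desk_models):
    """Renovated transfer model fine-tuned on 25,000 deterministic-subclone
    simulations, with held-out data and mutation-rate calibration."""
    from tumevol.transfer import transfer_desk_bundle
    return transfer_desk_bundle(desk_models["ms"], desk_models["1s"],
                                seed=3003)
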