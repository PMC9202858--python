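"""Shared fixtures.

The expensive fixture is ``scaled_training``: a scaled-down staging model
(stage widths 8/16/32/64, BiGRU hidden 16, 5-epoch sequences) trained for 20
passes on a 2000-epoch synthetic night, reused by the end-to-end behaviour
tests so the training cost is paid once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

import somnostage as ss
from somnostage.pipeline import _split_epochsets, predict_epochset
from somnostage.training import TrainConfig, train

# scaled-down profile used by the end-to-end tests
SCALED_WIDTHS = (8, 16, 32, 64)
SCALED_HIDDEN = 16
SCALED_SEQ = 5


def scaled_model_config(**overrides) -> ss.ModelConfig:
    kw = dict(stage_widths=SCALED_WIDTHS, bigru_hidden=SCALED_HIDDEN,
              sequence_length=SCALED_SEQ, epoch_samples=3000, fs=100.0)
    kw.update(overrides)
    return ss.ModelConfig(**kw)


def scaled_train_config(**overrides) -> TrainConfig:
    kw = dict(learning_rate=1e-3, weight_decay=1e-4, decoupled_weight_decay=True,
              batch_size=16, n_epochs=20, label_smoothing=0.1, seed=7)
    kw.update(overrides)
    return TrainConfig(**kw)


@pytest.fixture(scope="session")
def tiny_night() -> ss.EpochSet:
    """A short default-template night for cheap structural tests."""
    return ss.generate_night(ss.SimulationConfig(n_epochs=60, seed=42))


@pytest.fixture(scope="session")
def scaled_training():
    """Train the scaled-down model on a 2000-epoch synthetic night.

    Returns the trained model, its history, the held-out test split of the
    training night, a completely separate held-out night, and a
    balanced-prevalence night for chance-level comparisons.
    """
    night = ss.zscore_epochs(ss.generate_night(ss.SimulationConfig(n_epochs=2000, seed=101)))
    train_set, val_set, test_set = _split_epochsets(night, SCALED_SEQ, 0.7, 0.15)
    model = ss.build_model(scaled_model_config(), seed=7)
    result = train(model, train_set, val_set, scaled_train_config())

    heldout = ss.zscore_epochs(ss.generate_night(ss.SimulationConfig(n_epochs=400, seed=202)))
    balanced = ss.zscore_epochs(ss.generate_night(
        ss.SimulationConfig(n_epochs=400, seed=303,
                            stage_prevalence=np.full(5, 0.2))))
    untrained = ss.build_model(scaled_model_config(), seed=99)
    return {
        "model": model,
        "history": result["history"],
        "test_set": test_set,
        "heldout": heldout,
        "balanced": balanced,
        "untrained": untrained,
        "train_night": night,
    }


def evaluate_on(model, es):
    preds, _, _ = predict_epochset(model, es)
    return ss.report(ss.confusion(es.labels, preds))
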