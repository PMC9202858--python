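"""Confusion matrix, kappa, report and cross-validation behaviour."""

from __future__ import annotations

import numpy as np
import pytest

import somnostage as ss
from somnostage.data_io import SleepStage
from somnostage.evaluation import (
    ConfusionMatrix,
    ConstantEstimator,
    confusion,
    cross_validate,
    format_mean_std,
    kappa,
    report,
)
from somnostage.synthetic import stationary_distribution

W, S1, S2, S3, REM = range(5)


def _embed(counts_2x2):
    counts = np.zeros((5, 5), dtype=np.int64)
    counts[:2, :2] = counts_2x2
    return ConfusionMatrix(counts)


# ---------------------------------------------------------------------------
# confusion
# ---------------------------------------------------------------------------

def test_confusion_enumeration_example():
    cm = confusion([W, W, S2, REM], [W, S2, S2, W])
    expected = np.zeros((5, 5), dtype=np.int64)
    expected[W, W] = 1
    expected[W, S2] = 1
    expected[S2, S2] = 1
    expected[REM, W] = 1
    np.testing.assert_array_equal(cm.counts, expected)


def test_confusion_perfect_agreement_is_diagonal():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 5, size=100)
    cm = confusion(y, y)
    assert np.trace(cm.counts) == 100
    assert cm.counts.sum() - np.trace(cm.counts) == 0


def test_confusion_row_sums_are_true_class_counts():
    rng = np.random.default_rng(1)
    t, p = rng.integers(0, 5, 200), rng.integers(0, 5, 200)
    cm = confusion(t, p)
    np.testing.assert_array_equal(cm.counts.sum(axis=1), np.bincount(t, minlength=5))


def test_confusion_input_validation():
    with pytest.raises(ValueError):
        confusion([0, 1], [0])
    with pytest.raises(ValueError):
        confusion([0, int(SleepStage.EXCLUDED)], [0, 0])


# ---------------------------------------------------------------------------
# kappa
# ---------------------------------------------------------------------------

def test_kappa_two_rater_hand_case():
    """[[20,5],[10,15]]: p0=0.7, pe=0.5, kappa=0.4."""
    k, p0, pe = kappa(_embed([[20, 5], [10, 15]]))
    assert (p0, pe) == (0.7, 0.5)
    assert k == pytest.approx(0.4, abs=1e-12)


def test_kappa_perfect_agreement_is_one():
    counts = np.diag([10, 3, 25, 7, 9])
    k, p0, _ = kappa(ConfusionMatrix(counts))
    assert p0 == 1.0 and k == pytest.approx(1.0)


def test_kappa_outer_product_independence_is_zero():
    r = np.array([2, 3, 4, 1, 5])
    c = np.array([1, 6, 2, 3, 4])
    k, p0, pe = kappa(ConfusionMatrix(np.outer(r, c)))
    assert p0 == pytest.approx(pe)
    assert k == pytest.approx(0.0, abs=1e-12)


def test_kappa_degenerate_single_cell_undefined():
    counts = np.zeros((5, 5), dtype=np.int64)
    counts[2, 2] = 50
    with pytest.raises(ZeroDivisionError):
        kappa(ConfusionMatrix(counts))


def test_kappa_matches_pairwise_oracle_on_random_labels():
    """Brute-force agreement statistic from raw label pairs (independent of
    the matrix intermediate), cross-checked against scikit-learn."""
    from sklearn.metrics import cohen_kappa_score

    rng = np.random.default_rng(7)
    for _ in range(50):
        n = int(rng.integers(20, 200))
        t = rng.integers(0, 5, n)
        p = rng.integers(0, 5, n)
        k, p0, pe = kappa(confusion(t, p))
        # oracle: observed agreement and marginal-chance agreement from pairs
        p0_direct = float((t == p).mean())
        pe_direct = sum(float((t == i).mean()) * float((p == i).mean())
                        for i in range(5))
        k_direct = (p0_direct - pe_direct) / (1 - pe_direct)
        assert k == pytest.approx(k_direct, abs=1e-12)
        assert k == pytest.approx(cohen_kappa_score(t, p, labels=range(5)), abs=1e-10)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def test_report_diagonal_matrix_all_recalls_one():
    rep = report(ConfusionMatrix(np.diag([5, 5, 5, 5, 5])))
    assert rep.overall_accuracy == 1.0
    assert all(v == 1.0 for v in rep.per_stage_recall.values())


def test_report_four_label_example():
    rep = report(confusion([W, W, S2, REM], [W, S2, S2, W]))
    assert rep.per_stage_recall["W"] == 0.5
    assert rep.per_stage_recall["S2"] == 1.0
    assert rep.per_stage_recall["REM"] == 0.0
    assert rep.overall_accuracy == 0.5
    assert np.isnan(rep.per_stage_recall["S1"])   # class absent from truth


def test_accuracy_is_prevalence_weighted_mean_recall():
    rng = np.random.default_rng(3)
    for _ in range(20):
        counts = rng.integers(0, 30, (5, 5))
        counts[np.arange(5), np.arange(5)] += 1   # no empty rows
        rep = report(ConfusionMatrix(counts))
        rows = counts.sum(axis=1)
        weighted = sum((rows[i] / rows.sum()) * rep.per_stage_recall[name]
                       for i, name in enumerate(rep.per_stage_recall))
        assert rep.overall_accuracy == pytest.approx(weighted, abs=1e-12)


def test_format_mean_std():
    assert format_mean_std([0.76, 0.79, 0.82]) == "0.79±0.03"
    assert format_mean_std([0.5]) == "0.50±0.00"


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _recordings(n_rec=6, n_epochs=150, base_seed=31):
    return [ss.generate_night(ss.SimulationConfig(n_epochs=n_epochs, seed=base_seed + i))
            for i in range(n_rec)]


def test_cv_folds_partition_recordings():
    recs = _recordings(n_rec=6, n_epochs=20)
    out = cross_validate(recs, ConstantEstimator, k_folds=3)
    folds = out["fold_indices"]
    flat = sorted(i for f in folds for i in f)
    assert flat == list(range(6))
    assert len(out["folds"]) == 3


def test_cv_two_recordings_two_folds_each_tested_once():
    recs = _recordings(n_rec=2, n_epochs=20)
    out = cross_validate(recs, ConstantEstimator, k_folds=2)
    assert sorted(len(f) for f in out["fold_indices"]) == [1, 1]


def test_cv_more_folds_than_groups_rejected():
    recs = _recordings(n_rec=2, n_epochs=10)
    with pytest.raises(ValueError):
        cross_validate(recs, ConstantEstimator, k_folds=5)


def test_constant_s2_predictor_scores_prevalence_with_zero_kappa():
    """Under the default class imbalance a constant-S2 classifier's accuracy
    is the S2 prevalence and its kappa is exactly zero."""
    recs = _recordings(n_rec=4, n_epochs=400)
    out = cross_validate(recs, lambda: ConstantEstimator(SleepStage.S2), k_folds=4)
    pi_s2 = stationary_distribution(ss.default_transition_matrix())[int(SleepStage.S2)]
    assert out["accuracy_mean"] == pytest.approx(pi_s2, abs=0.08)
    assert out["kappa_mean"] == pytest.approx(0.0, abs=1e-12)


def test_cv_with_network_estimator_runs_each_recording_once():
    """The trained-network CV adapter: tiny model, one pass per fold."""
    from somnostage.network import ModelConfig
    from somnostage.pipeline import NetworkEstimator
    from somnostage.training import TrainConfig

    recs = [ss.zscore_epochs(r) for r in _recordings(n_rec=2, n_epochs=40)]
    mcfg = ModelConfig(stage_widths=(4, 8, 8, 16), bigru_hidden=8,
                       sequence_length=5, dropout_p=0.0)
    tcfg = TrainConfig(learning_rate=1e-3, weight_decay=0.0, n_epochs=1, seed=0)
    out = cross_validate(recs, lambda: NetworkEstimator(mcfg, tcfg), k_folds=2)
    assert sum(r.n_epochs for r in out["folds"]) == 80
    assert all(0.0 <= r.overall_accuracy <= 1.0 for r in out["folds"])


def test_cv_epoch_level_mode_partitions_epochs():
    recs = _recordings(n_rec=2, n_epochs=30)
    out = cross_validate(recs, ConstantEstimator, k_folds=3,
                         group_by_recording=False)
    flat = sorted(i for f in out["fold_indices"] for i in f)
    assert flat == list(range(60))
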