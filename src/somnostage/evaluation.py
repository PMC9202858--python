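"""Staging evaluation: confusion matrix, recall, accuracy, Cohen's kappa, CV.

The confusion matrix is 5x5 with rows the expert (true) stage and columns
the predicted stage, in the fixed order W, S1, S2, S3, REM.  From it we
report per-stage recall (diagonal over row sum; empty rows are reported as
NaN, never silently zero), the overall recognition rate (trace over total),
and chance-corrected agreement

    kappa = (p0 - pe) / (1 - pe),

with p0 the observed accuracy and pe = sum_i row_i * col_i / total^2 the
agreement expected from the marginals alone.

Cross-validation folds group windows by recording (subject) by default so no
recording contributes to both train and test; an epoch-level mode mimicking
the weaker protocol is available.  Summaries are mean +/- sample (n-1)
standard deviation, formatted to 2 decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import STAGE_NAMES, EpochSet, SleepStage

logger = logging.getLogger(__name__)

N_STAGES = len(STAGE_NAMES)

__all__ = [
    "ConfusionMatrix",
    "StagingReport",
    "confusion",
    "kappa",
    "report",
    "cross_validate",
    "ConstantEstimator",
    "format_mean_std",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_STAGES, N_STAGES):
            raise ValueError(f"confusion matrix must be {N_STAGES}x{N_STAGES}")
        if (self.counts < 0).any():
            raise ValueError("negative count in confusion matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class StagingReport:
    per_stage_recall: dict
    overall_accuracy: float
    kappa: float
    p0: float
    pe: float
    n_epochs: int
    confusion: np.ndarray


def confusion(true, pred) -> ConfusionMatrix:
    """Count matrix counts[i, j] = #{t : true_t = i and pred_t = j}."""
    t = np.asarray([int(x) for x in true], dtype=np.int64)
    p = np.asarray([int(x) for x in pred], dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError(f"label lengths differ: {t.shape} vs {p.shape}")
    if (t == int(SleepStage.EXCLUDED)).any() or (p == int(SleepStage.EXCLUDED)).any():
        raise ValueError("EXCLUDED labels must be filtered before evaluation")
    if ((t < 0) | (t >= N_STAGES) | (p < 0) | (p >= N_STAGES)).any():
        raise ValueError("labels outside the 5-class space")
    counts = np.zeros((N_STAGES, N_STAGES), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def kappa(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """Cohen's kappa with its components: returns (kappa, p0, pe)."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    p0 = float(np.trace(cm.counts)) / total
    rows = cm.counts.sum(axis=1).astype(np.float64)
    cols = cm.counts.sum(axis=0).astype(np.float64)
    pe = float((rows * cols).sum()) / (total * total)
    if pe >= 1.0 - 1e-15:
        raise ZeroDivisionError(
            "kappa undefined: expected agreement pe = 1 (single-cell matrix)")
    return (p0 - pe) / (1.0 - pe), p0, pe


def report(cm: ConfusionMatrix) -> StagingReport:
    """Per-stage recall, overall recognition rate and kappa for a matrix."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    rows = cm.counts.sum(axis=1)
    recalls = {}
    for i, name in enumerate(STAGE_NAMES):
        recalls[name] = float(cm.counts[i, i] / rows[i]) if rows[i] > 0 else float("nan")
    acc = float(np.trace(cm.counts)) / total
    k, p0, pe = kappa(cm)
    return StagingReport(per_stage_recall=recalls, overall_accuracy=acc,
                         kappa=k, p0=p0, pe=pe, n_epochs=total,
                         confusion=cm.counts.copy())


def format_mean_std(values, decimals: int = 2) -> str:
    """``mean±sd`` with the sample (n-1) standard deviation, e.g. '0.79±0.03'."""
    arr = np.asarray(values, dtype=np.float64)
    sd = arr.std(ddof=1) if arr.size > 1 else 0.0
    return f"{arr.mean():.{decimals}f}±{sd:.{decimals}f}"


class ConstantEstimator:
    """Predicts one fixed stage for every epoch (imbalance baseline)."""

    def __init__(self, stage: SleepStage = SleepStage.S2):
        self.stage = SleepStage(stage)

    def fit(self, recordings):
        return self

    def predict(self, es: EpochSet) -> np.ndarray:
        return np.full(len(es), int(self.stage), dtype=np.int64)


def cross_validate(recordings, estimator_factory, k_folds: int = 10,
                   group_by_recording: bool = True, seed: int = 0) -> dict:
    """K-fold cross-validation over a list of recordings (EpochSets).

    ``estimator_factory()`` must return an object with ``fit(list[EpochSet])``
    and ``predict(EpochSet) -> labels``.  Folds partition recordings (or,
    with ``group_by_recording=False``, individual epochs pooled across
    recordings); every unit is tested exactly once.

    Returns per-fold reports plus formatted mean±sd summaries of accuracy
    and kappa.
    """
    recordings = list(recordings)
    rng = np.random.default_rng(seed)
    if group_by_recording:
        if k_folds > len(recordings):
            raise ValueError(
                f"k_folds={k_folds} exceeds the {len(recordings)} recording group(s)")
        order = rng.permutation(len(recordings))
        folds = [sorted(order[i::k_folds].tolist()) for i in range(k_folds)]
        units = recordings
    else:
        # epoch-level folding: pool all epochs, split indices
        pooled = recordings[0]
        if len(recordings) > 1:
            pooled = EpochSet(
                data=np.concatenate([r.data for r in recordings]),
                labels=np.concatenate([r.labels for r in recordings]),
                fs=recordings[0].fs, epoch_seconds=recordings[0].epoch_seconds,
                source_id="pooled", channels=list(recordings[0].channels))
        if k_folds > len(pooled):
            raise ValueError("more folds than epochs")
        order = rng.permutation(len(pooled))
        folds = [sorted(order[i::k_folds].tolist()) for i in range(k_folds)]
        units = [EpochSet(data=pooled.data[i:i + 1], labels=pooled.labels[i:i + 1],
                          fs=pooled.fs, epoch_seconds=pooled.epoch_seconds,
                          source_id=f"epoch{i}", channels=list(pooled.channels))
                 for i in range(len(pooled))]

    fold_reports = []
    for f, test_idx in enumerate(folds):
        test_set = set(test_idx)
        train_units = [units[i] for i in range(len(units)) if i not in test_set]
        est = estimator_factory()
        est.fit(train_units)
        trues, preds = [], []
        for i in test_idx:
            trues.append(units[i].labels)
            preds.append(np.asarray(est.predict(units[i]), dtype=np.int64))
        cm = confusion(np.concatenate(trues), np.concatenate(preds))
        fold_reports.append(report(cm))
        logger.info("fold %d/%d: acc %.4f kappa %.4f", f + 1, k_folds,
                    fold_reports[-1].overall_accuracy, fold_reports[-1].kappa)
    accs = [r.overall_accuracy for r in fold_reports]
    kappas = [r.kappa for r in fold_reports]
    return {
        "folds": fold_reports,
        "fold_indices": folds,
        "accuracy_mean": float(np.mean(accs)),
        "accuracy_sd": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        "kappa_mean": float(np.mean(kappas)),
        "kappa_sd": float(np.std(kappas, ddof=1)) if len(kappas) > 1 else 0.0,
        "accuracy_summary": format_mean_std(accs),
        "kappa_summary": format_mean_std(kappas),
    }
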