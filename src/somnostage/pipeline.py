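"""End-to-end runs: simulate (or load) -> train -> evaluate -> artifacts.

A single nested config drives everything; every artifact written embeds the
resolved config's hash and the global seed, so a run is reproducible from
its outputs.  Inference disables dropout and uses non-overlapping windows; a
trailing window that cannot be filled is padded by repeating the last epoch
and the padded epochs are flagged in the prediction table.
"""

from __future__ import annotations

import copy
import hashlib
import json
import csv
import logging
from pathlib import Path

import numpy as np

from .data_io import (
    STAGE_NAMES,
    EpochSet,
    InvalidConfigError,
    drop_excluded,
    load_epoch_store,
    read_edf,
    make_epochset,
    save_epoch_store,
    zscore_epochs,
)
from .evaluation import confusion, report
from .network import (
    ModelConfig,
    SleepStager,
    build_model,
    classify_sequence,
    load_checkpoint,
    save_checkpoint,
)
from .synthetic import SimulationConfig, generate_night
from .training import TrainConfig, make_windows, train

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_CONFIG",
    "resolve_config",
    "config_hash",
    "run_end_to_end",
    "predict_epochset",
    "stage_recording",
    "NetworkEstimator",
]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "somnostage_run",
    "log_level": "INFO",
    "data": {
        "store": None,            # path to an epoch store; None -> simulate
        "zscore": True,
        "train_frac": 0.7,
        "val_frac": 0.15,
    },
    "simulate": {
        "n_epochs": 1000,
        "fs": 100.0,
        "epoch_seconds": 30.0,
        "n_channels": 1,
        "pink_noise": False,
    },
    "model": {
        "branch_kernel_sizes": [3, 5, 7],
        "stem_kernel": 7,
        "stem_pool": 3,
        "stage_widths": [64, 128, 256, 512],
        "blocks_per_stage": 1,
        "attention_reduction": 16,
        "bigru_hidden": 128,
        "dropout_p": 0.5,
        "sequence_length": 10,
        "activation": "relu",
    },
    "train": {
        "learning_rate": 0.005,
        "weight_decay": 0.1,
        "decoupled_weight_decay": True,
        "batch_size": 16,
        "n_epochs": 200,
        "label_smoothing": 0.1,
        "early_stopping_patience": None,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        full = f"{path}{key}"
        if key not in base:
            raise InvalidConfigError(f"unknown config key: {full!r}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _merge(base[key], value, full + ".")
        else:
            out[key] = value
    return out


def resolve_config(overrides: dict | None = None) -> dict:
    """Defaults merged with overrides; unknown keys raise, naming the key."""
    return _merge(DEFAULT_CONFIG, overrides or {})


def config_hash(cfg: dict) -> str:
    """Hash of the scientific configuration (where outputs land and how
    verbosely we log do not change the result)."""
    hashed = {k: v for k, v in cfg.items() if k not in ("out_dir", "log_level")}
    return hashlib.sha256(
        json.dumps(hashed, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _split_epochsets(es: EpochSet, seq_len: int, train_frac: float,
                     val_frac: float) -> tuple[EpochSet, EpochSet, EpochSet]:
    """Contiguous train/val/test split aligned to whole windows."""
    n_windows = len(es) // seq_len
    n_tr = int(round(n_windows * train_frac))
    n_va = int(round(n_windows * val_frac))
    n_tr = max(1, min(n_tr, n_windows - 2))
    n_va = max(1, min(n_va, n_windows - n_tr - 1))
    cuts = [0, n_tr * seq_len, (n_tr + n_va) * seq_len, n_windows * seq_len]

    def piece(lo, hi, tag):
        return EpochSet(data=es.data[lo:hi], labels=es.labels[lo:hi], fs=es.fs,
                        epoch_seconds=es.epoch_seconds,
                        source_id=f"{es.source_id}:{tag}", channels=list(es.channels))

    return (piece(cuts[0], cuts[1], "train"),
            piece(cuts[1], cuts[2], "val"),
            piece(cuts[2], cuts[3], "test"))


def predict_epochset(model: SleepStager, es: EpochSet
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-epoch predictions over non-overlapping windows.

    The tail is padded by repeating the last epoch to fill a window; returns
    (pred labels, probabilities, padded flag) each of length len(es).
    """
    L = model.cfg.sequence_length
    n = len(es)
    if n == 0:
        return (np.empty(0, dtype=np.int64), np.empty((0, model.cfg.n_classes)),
                np.empty(0, dtype=bool))
    n_full = n // L
    windows = []
    if n_full:
        X, _ = make_windows(es, L)
        windows.append(X)
    pad_flag = np.zeros(n, dtype=bool)
    tail = n - n_full * L
    if tail:
        last = es.data[n_full * L:]
        padded = np.concatenate([last, np.repeat(last[-1:], L - tail, axis=0)])
        windows.append(padded[None, ...])
        pad_flag[n_full * L:] = True                 # staged from a padded window
    X_all = np.concatenate(windows)
    probs = classify_sequence(model, X_all)          # (N, L, k)
    probs = probs.reshape(-1, model.cfg.n_classes)[:n]
    preds = probs.argmax(axis=1).astype(np.int64)
    return preds, probs, pad_flag


class NetworkEstimator:
    """Cross-validation adapter: train a fresh stager per fold, predict
    per-epoch labels on held-out recordings."""

    def __init__(self, model_cfg: ModelConfig, train_cfg: TrainConfig,
                 seed: int = 0, val_frac: float = 0.15):
        self.model_cfg = model_cfg
        self.train_cfg = train_cfg
        self.seed = seed
        self.val_frac = val_frac
        self.model: SleepStager | None = None

    def fit(self, recordings):
        pooled = EpochSet(
            data=np.concatenate([r.data for r in recordings]),
            labels=np.concatenate([r.labels for r in recordings]),
            fs=recordings[0].fs, epoch_seconds=recordings[0].epoch_seconds,
            source_id="cv-train", channels=list(recordings[0].channels))
        L = self.model_cfg.sequence_length
        n_val = max(L, int(round(len(pooled) * self.val_frac)) // L * L)
        cut = len(pooled) - n_val
        tr = EpochSet(data=pooled.data[:cut], labels=pooled.labels[:cut],
                      fs=pooled.fs, epoch_seconds=pooled.epoch_seconds)
        va = EpochSet(data=pooled.data[cut:], labels=pooled.labels[cut:],
                      fs=pooled.fs, epoch_seconds=pooled.epoch_seconds)
        self.model = build_model(self.model_cfg, seed=self.seed)
        train(self.model, tr, va, self.train_cfg)
        return self

    def predict(self, es: EpochSet) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("estimator is not fitted")
        preds, _, _ = predict_epochset(self.model, es)
        return preds


def run_end_to_end(overrides: dict | None = None) -> dict:
    """Simulate (or load) -> train -> evaluate; write all artifacts.

    Returns a summary dict with the report and artifact paths.  Idempotent
    under a fixed seed: re-running writes byte-identical report JSON.
    """
    cfg = resolve_config(overrides)
    logging.basicConfig(level=getattr(logging, str(cfg["log_level"]).upper(), logging.INFO))
    seed = int(cfg["seed"])
    chash = config_hash(cfg)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("run %s: seed=%d out=%s", chash, seed, out_dir)

    # --- data ------------------------------------------------------------
    if cfg["data"]["store"]:
        es = load_epoch_store(cfg["data"]["store"])
    else:
        sim = SimulationConfig(seed=seed, **cfg["simulate"])
        es = generate_night(sim)
    es = drop_excluded(es)
    es = zscore_epochs(es, enabled=cfg["data"]["zscore"])
    save_epoch_store(es, out_dir / "epochs.h5")

    # --- model + training -------------------------------------------------
    mc = cfg["model"]
    model_cfg = ModelConfig(in_channels=es.data.shape[1], fs=es.fs,
                            epoch_samples=es.data.shape[2], **mc)
    model = build_model(model_cfg, seed=seed)
    train_set, val_set, test_set = _split_epochsets(
        es, model_cfg.sequence_length, cfg["data"]["train_frac"], cfg["data"]["val_frac"])
    tcfg = TrainConfig(seed=seed, **cfg["train"])
    result = train(model, train_set, val_set, tcfg)
    save_checkpoint(model, out_dir / "checkpoint.zip")

    history_path = out_dir / "history.csv"
    with open(history_path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["pass", "train_loss", "train_acc",
                                           "val_loss", "val_acc"])
        w.writeheader()
        w.writerows(result["history"])

    # --- evaluation -------------------------------------------------------
    preds, probs, padded = predict_epochset(model, test_set)
    rep = report(confusion(test_set.labels, preds))
    pred_path = out_dir / "predictions.csv"
    with open(pred_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch_index", "true", "pred", "padded_window"]
                   + [f"p_{s}" for s in STAGE_NAMES])
        for i in range(len(preds)):
            w.writerow([i, STAGE_NAMES[test_set.labels[i]], STAGE_NAMES[preds[i]],
                        int(padded[i])] + [f"{p:.6f}" for p in probs[i]])

    report_doc = {
        "config_hash": chash,
        "seed": seed,
        "n_test_epochs": rep.n_epochs,
        "overall_accuracy": round(rep.overall_accuracy, 6),
        "kappa": round(rep.kappa, 6),
        "p0": round(rep.p0, 6),
        "pe": round(rep.pe, 6),
        "per_stage_recall": {k: (None if np.isnan(v) else round(v, 6))
                             for k, v in rep.per_stage_recall.items()},
        "confusion": rep.confusion.tolist(),
    }
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report_doc, indent=2, sort_keys=True) + "\n")
    np.savetxt(out_dir / "confusion.csv", rep.confusion, fmt="%d", delimiter=",",
               header=",".join(STAGE_NAMES))
    logger.info("test accuracy %.4f kappa %.4f", rep.overall_accuracy, rep.kappa)
    return {"report": report_doc, "report_path": report_path,
            "checkpoint_path": out_dir / "checkpoint.zip",
            "history_path": history_path, "predictions_path": pred_path,
            "model": model, "test_set": test_set}


def stage_recording(edf_path: str | Path, checkpoint_path: str | Path,
                    out_csv: str | Path, channel_names: list[str] | None = None,
                    zscore: bool = True) -> Path:
    """Stage a recording with a trained model; write a hypnogram CSV.

    One row per whole 30-s epoch with predicted stage and per-stage
    probabilities; epochs staged from a tail-padded window are flagged.
    """
    model = load_checkpoint(checkpoint_path)
    if channel_names is None:
        from .data_io import _read_edf_header
        header = _read_edf_header(Path(edf_path))
        usable = [c for c in header["labels"] if c != "EDF Annotations"]
        channel_names = usable[:model.cfg.in_channels]
    rec = read_edf(edf_path, channel_names)
    if abs(rec.fs - model.cfg.fs) > 1e-6:
        raise InvalidConfigError(
            f"recording sampling rate {rec.fs} Hz != model's {model.cfg.fs} Hz; "
            "resample the recording before staging")
    spe = model.cfg.epoch_samples
    n_epochs = rec.n_samples // spe
    es = make_epochset(rec, np.zeros(n_epochs, dtype=np.int64),
                       epoch_seconds=spe / rec.fs)
    es = zscore_epochs(es, enabled=zscore)
    preds, probs, padded = predict_epochset(model, es)
    out_csv = Path(out_csv)
    with open(out_csv, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch_index", "pred", "padded_window"]
                   + [f"p_{s}" for s in STAGE_NAMES])
        for i in range(len(preds)):
            w.writerow([i, STAGE_NAMES[preds[i]], int(padded[i])]
                       + [f"{p:.6f}" for p in probs[i]])
    return out_csv
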