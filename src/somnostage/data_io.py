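"""Reading polysomnography, 30-s epoching and 5-class stage label handling.

Sleep recordings arrive as EDF files with a per-epoch hypnogram.  This module
reads the EEG channels of interest, cuts the signal into fixed 30-second
scoring epochs, and maps the scorer's annotation vocabulary (R&K or AASM)
onto the 5-class scheme used throughout the package: W, S1, S2, S3, REM,
where the R&K S4 stage is merged into S3 (slow-wave sleep).  Unscorable
epochs (movement time, unscored) are marked EXCLUDED and dropped — with a
logged count — before training or evaluation.

Epoch alignment starts at sample 0 of the recording (no lights-off
trimming); hypnogram row ``i`` annotates samples ``[i*30*fs, (i+1)*30*fs)``,
half-open.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import h5py
import numpy as np

logger = logging.getLogger(__name__)

EPOCH_SECONDS_DEFAULT = 30

__all__ = [
    "SleepStage",
    "Recording",
    "EpochSet",
    "ChannelNotFoundError",
    "UnknownLabelError",
    "InvalidConfigError",
    "read_edf",
    "segment_epochs",
    "map_raw_label",
    "class_distribution",
    "make_epochset",
    "drop_excluded",
    "zscore_epochs",
    "save_epoch_store",
    "load_epoch_store",
    "write_hypnogram_csv",
    "read_hypnogram_csv",
]


class SleepStage(IntEnum):
    """The five scoring classes plus a marker for unscorable epochs."""

    W = 0
    S1 = 1
    S2 = 2
    S3 = 3
    REM = 4
    EXCLUDED = -1


STAGE_ORDER = (SleepStage.W, SleepStage.S1, SleepStage.S2, SleepStage.S3, SleepStage.REM)
STAGE_NAMES = tuple(s.name for s in STAGE_ORDER)


class ChannelNotFoundError(KeyError):
    pass


class UnknownLabelError(ValueError):
    pass


class InvalidConfigError(ValueError):
    pass


@dataclass
class Recording:
    """A multichannel EEG series in microvolts.

    All channels share one sampling rate; ``data`` has shape
    (n_channels, n_samples).
    """

    channels: list[str]
    fs: float
    data: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.fs <= 0:
            raise InvalidConfigError("sampling rate must be positive")
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel name count does not match data rows")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Ordered fixed-length epochs with aligned 5-class labels.

    ``data`` has shape (n_epochs, n_channels, samples_per_epoch); temporal
    order of epochs is preserved (the sequence model depends on it).
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    epoch_seconds: float = EPOCH_SECONDS_DEFAULT
    source_id: str = ""
    channels: list[str] = field(default_factory=lambda: ["EEG"])

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (n_epochs, n_channels, n_samples)")
        if len(self.data) != len(self.labels):
            raise ValueError("epochs and labels differ in length")
        expected = int(round(self.epoch_seconds * self.fs))
        if len(self.data) and self.data.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.data.shape[2]} != epoch_seconds*fs = {expected}")

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# EDF input
# ---------------------------------------------------------------------------

def _read_edf_header(path: Path) -> dict:
    """Parse the fixed-layout EDF header (validation and channel listing)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise IOError(f"{path}: truncated EDF header")
        ns = int(head[252:256].decode("ascii").strip())
        n_records = int(head[236:244].decode("ascii").strip())
        record_dur = float(head[244:252].decode("ascii").strip())
        sig = fh.read(256 * ns)
        labels = [sig[16 * i:16 * (i + 1)].decode("ascii", "replace").strip()
                  for i in range(ns)]
        nsamp_off = 216 * ns
        nsamples = [int(sig[nsamp_off + 8 * i:nsamp_off + 8 * (i + 1)].decode("ascii").strip())
                    for i in range(ns)]
    return {"labels": labels, "n_records": n_records,
            "record_dur": record_dur, "nsamples": nsamples}


def read_edf(path: str | Path, channel_names: list[str]) -> Recording:
    """Read the requested channels of an EDF file into a :class:`Recording`.

    Signals are returned in microvolts at the file's native sampling rate.
    Channels sampled at different rates within one file are refused.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise IOError(f"EDF file not found: {path}")
    header = _read_edf_header(path)
    available = header["labels"]
    annotation_names = {"EDF Annotations", "BDF Annotations"}
    missing = [c for c in channel_names if c not in available]
    if missing:
        raise ChannelNotFoundError(
            f"channel(s) {missing} not in file; available: "
            f"{[c for c in available if c not in annotation_names]}")
    rates = {header["nsamples"][available.index(c)] for c in channel_names}
    if len(rates) > 1:
        raise InvalidConfigError(
            f"requested channels have mismatched sampling rates: {sorted(rates)}")
    raw = mne.io.read_raw_edf(path, include=channel_names, preload=True, verbose="error")
    picks = [raw.ch_names.index(c) for c in channel_names]
    data_uv = raw.get_data(picks=picks) * 1e6  # mne works in volts
    return Recording(channels=list(channel_names), fs=float(raw.info["sfreq"]),
                     data=data_uv, source_id=path.stem)


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def segment_epochs(rec: Recording, epoch_seconds: float = EPOCH_SECONDS_DEFAULT) -> list[np.ndarray]:
    """Cut a recording into consecutive non-overlapping epochs.

    Returns a list of (n_channels, samples_per_epoch) arrays; a trailing
    partial window is dropped.
    """
    if epoch_seconds <= 0:
        raise InvalidConfigError("epoch_seconds must be positive")
    spe_f = epoch_seconds * rec.fs
    spe = int(round(spe_f))
    if abs(spe_f - spe) > 1e-9:
        raise InvalidConfigError(
            f"epoch_seconds*fs = {spe_f} is not an integer sample count")
    n = rec.n_samples // spe
    return [rec.data[:, i * spe:(i + 1) * spe].copy() for i in range(n)]


def make_epochset(rec: Recording, labels, epoch_seconds: float = EPOCH_SECONDS_DEFAULT) -> EpochSet:
    """Segment a recording and align it with per-epoch stage labels.

    Extra labels beyond the number of whole epochs (or vice versa) are
    truncated to the common length.
    """
    epochs = segment_epochs(rec, epoch_seconds)
    labels = np.asarray([int(l) for l in labels], dtype=np.int64)
    n = min(len(epochs), len(labels))
    data = (np.stack(epochs[:n]) if n else
            np.empty((0, len(rec.channels), int(round(epoch_seconds * rec.fs))), dtype=np.float32))
    return EpochSet(data=data, labels=labels[:n], fs=rec.fs,
                    epoch_seconds=epoch_seconds, source_id=rec.source_id,
                    channels=list(rec.channels))


# ---------------------------------------------------------------------------
# label vocabulary
# ---------------------------------------------------------------------------

_RK_LABELS = {
    "Sleep stage W": SleepStage.W,
    "Sleep stage 1": SleepStage.S1,
    "Sleep stage 2": SleepStage.S2,
    "Sleep stage 3": SleepStage.S3,
    "Sleep stage 4": SleepStage.S3,  # R&K S4 merged into slow-wave sleep
    "Sleep stage R": SleepStage.REM,
    "Sleep stage ?": SleepStage.EXCLUDED,
    "Movement time": SleepStage.EXCLUDED,
    "W": SleepStage.W,
    "S1": SleepStage.S1,
    "S2": SleepStage.S2,
    "S3": SleepStage.S3,
    "S4": SleepStage.S3,
    "REM": SleepStage.REM,
    "MT": SleepStage.EXCLUDED,
    "?": SleepStage.EXCLUDED,
}

_AASM_LABELS = {
    "Sleep stage W": SleepStage.W,
    "Sleep stage N1": SleepStage.S1,
    "Sleep stage N2": SleepStage.S2,
    "Sleep stage N3": SleepStage.S3,
    "Sleep stage R": SleepStage.REM,
    "Sleep stage ?": SleepStage.EXCLUDED,
    "Movement time": SleepStage.EXCLUDED,
    "W": SleepStage.W,
    "N1": SleepStage.S1,
    "N2": SleepStage.S2,
    "N3": SleepStage.S3,
    "R": SleepStage.REM,
    "REM": SleepStage.REM,
    "S1": SleepStage.S1,  # already-mapped labels pass through unchanged
    "S2": SleepStage.S2,
    "S3": SleepStage.S3,
    "?": SleepStage.EXCLUDED,
}

_DIALECTS = {"RK": _RK_LABELS, "AASM": _AASM_LABELS}


def map_raw_label(raw: str, dialect: str = "RK") -> SleepStage:
    """Map one hypnogram annotation string onto the 5-class scheme.

    Unrecognised annotations raise :class:`UnknownLabelError`; they are never
    silently dropped.
    """
    try:
        table = _DIALECTS[dialect]
    except KeyError:
        raise InvalidConfigError(f"unknown dialect {dialect!r}; use 'RK' or 'AASM'") from None
    key = raw.strip()
    if key in table:
        return table[key]
    raise UnknownLabelError(
        f"unrecognised {dialect} annotation {raw!r}; known: {sorted(table)}")


def drop_excluded(es: EpochSet) -> EpochSet:
    """Remove EXCLUDED epochs, logging how many were discarded."""
    keep = es.labels != int(SleepStage.EXCLUDED)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropping %d EXCLUDED epoch(s) of %d from %s",
                    n_drop, len(es), es.source_id or "<unnamed>")
    return EpochSet(data=es.data[keep], labels=es.labels[keep], fs=es.fs,
                    epoch_seconds=es.epoch_seconds, source_id=es.source_id,
                    channels=list(es.channels))


def class_distribution(labels) -> dict:
    """Per-stage counts and percentages (2 decimals), EXCLUDED removed.

    Returns ``{"counts": {stage: n}, "percent": {stage: pct}, "n": total}``.
    """
    arr = np.asarray([int(l) for l in labels], dtype=np.int64)
    arr = arr[arr != int(SleepStage.EXCLUDED)]
    if arr.size == 0:
        raise ValueError("no scorable labels given")
    counts = {s.name: int((arr == int(s)).sum()) for s in STAGE_ORDER}
    total = int(arr.size)
    percent = {name: round(100.0 * c / total, 2) for name, c in counts.items()}
    return {"counts": counts, "percent": percent, "n": total}


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def zscore_epochs(es: EpochSet, enabled: bool = True, eps: float = 1e-8) -> EpochSet:
    """Per-epoch, per-channel z-scoring (the only preprocessing applied)."""
    if not enabled or len(es) == 0:
        return es
    mu = es.data.mean(axis=2, keepdims=True)
    sd = es.data.std(axis=2, keepdims=True)
    data = (es.data - mu) / (sd + eps)
    return EpochSet(data=data.astype(np.float32), labels=es.labels, fs=es.fs,
                    epoch_seconds=es.epoch_seconds, source_id=es.source_id,
                    channels=list(es.channels))


# ---------------------------------------------------------------------------
# epoch store (HDF5) and hypnogram CSV
# ---------------------------------------------------------------------------

def save_epoch_store(es: EpochSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=es.data, compression="gzip", compression_opts=1)
        f.create_dataset("labels", data=es.labels)
        f.attrs["fs"] = es.fs
        f.attrs["epoch_seconds"] = es.epoch_seconds
        f.attrs["source_id"] = es.source_id
        f.attrs["channels"] = ",".join(es.channels)


def load_epoch_store(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][...],
            labels=f["labels"][...],
            fs=float(f.attrs["fs"]),
            epoch_seconds=float(f.attrs["epoch_seconds"]),
            source_id=str(f.attrs.get("source_id", "")),
            channels=str(f.attrs.get("channels", "EEG")).split(","),
        )


def write_hypnogram_csv(labels, path: str | Path) -> None:
    """Two-column hypnogram: epoch_index, stage name."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch_index", "stage"])
        for i, l in enumerate(labels):
            w.writerow([i, SleepStage(int(l)).name])


def read_hypnogram_csv(path: str | Path) -> np.ndarray:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    out = np.empty(len(rows), dtype=np.int64)
    for i, row in enumerate(rows):
        out[int(row["epoch_index"])] = int(SleepStage[row["stage"]])
    return out
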