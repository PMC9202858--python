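"""Synthetic stage-labelled EEG nights.

The generator produces 30-s single-channel (optionally multichannel) epochs
whose spectral content follows the classical stage signatures — alpha
(8–12 Hz) in wake, theta (4–7 Hz) in S1, theta plus 12–14 Hz spindle bursts
in S2, high-amplitude delta (0.5–2 Hz) in slow-wave sleep, and low-amplitude
mixed theta/beta in REM.  Hypnogram dynamics are a first-order Markov chain
whose stationary distribution defaults to the Sleep-EDF class imbalance
(W 18.90 %, S1 6.68 %, S2 42.43 %, S3 13.59 %, REM 18.40 %), so synthetic
nights reproduce the strongly unbalanced regime (S2:S1 ≈ 6:1) that the
staging model must cope with.

This is not a biophysical EEG model: oscillations are amplitude-modulated
random-phase sinusoids over Gaussian (optionally 1/f-shaped) noise.  It only
needs to be class-separable and spectrally plausible so the full pipeline is
testable offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import (
    STAGE_ORDER,
    EpochSet,
    InvalidConfigError,
    SleepStage,
    write_hypnogram_csv,
)

__all__ = [
    "StageTemplate",
    "SimulationConfig",
    "DEFAULT_TEMPLATES",
    "SLEEP_EDF_PREVALENCE",
    "default_transition_matrix",
    "stationary_distribution",
    "generate_epoch",
    "generate_night",
    "write_edf_fixture",
]

# Sleep-EDF expert-scored stage proportions (percent), renormalised to 1.
SLEEP_EDF_PREVALENCE = np.array([18.90, 6.68, 42.43, 13.59, 18.40]) / 100.0


@dataclass
class StageTemplate:
    """Spectral recipe for one stage.

    ``components`` are (center_freq Hz, bandwidth Hz, amplitude µV) bands
    rendered as amplitude-modulated sinusoids; ``noise_sd`` is broadband
    background; ``burst_prob`` is the chance of a transient event (e.g. a
    spindle) in any given second of the epoch.
    """

    stage: SleepStage
    components: list[tuple[float, float, float]]
    noise_sd: float = 10.0
    burst_prob: float = 0.0
    burst_freq: float = 13.0
    burst_amplitude: float = 0.0


DEFAULT_TEMPLATES: dict[SleepStage, StageTemplate] = {
    SleepStage.W: StageTemplate(SleepStage.W,
                                components=[(10.0, 4.0, 30.0), (20.0, 6.0, 5.0)],
                                noise_sd=10.0),
    SleepStage.S1: StageTemplate(SleepStage.S1,
                                 components=[(5.5, 3.0, 28.0)],
                                 noise_sd=10.0),
    SleepStage.S2: StageTemplate(SleepStage.S2,
                                 components=[(5.5, 3.0, 18.0)],
                                 noise_sd=10.0,
                                 burst_prob=0.35, burst_freq=13.0,
                                 burst_amplitude=35.0),
    SleepStage.S3: StageTemplate(SleepStage.S3,
                                 components=[(1.2, 1.5, 75.0)],
                                 noise_sd=15.0),
    SleepStage.REM: StageTemplate(SleepStage.REM,
                                  components=[(6.0, 2.0, 14.0), (22.0, 6.0, 8.0)],
                                  noise_sd=8.0),
}


def default_transition_matrix(prevalence: np.ndarray | None = None,
                              persistence: float = 0.85) -> np.ndarray:
    """Row-stochastic hypnogram dynamics with sleep-bout persistence.

    ``P = persistence * I + (1 - persistence) * 1 π^T``: with probability
    ``persistence`` the stage continues, otherwise the next stage is drawn
    from the target prevalence π.  By construction π is the stationary
    distribution, so long nights reproduce the configured class imbalance
    while keeping realistic bout lengths (mean self-run ≥ 1/(1-0.85) ≈ 7
    epochs ≈ 3.5 min).
    """
    pi = SLEEP_EDF_PREVALENCE if prevalence is None else np.asarray(prevalence, dtype=float)
    pi = pi / pi.sum()
    k = len(pi)
    return persistence * np.eye(k) + (1.0 - persistence) * np.tile(pi, (k, 1))


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


@dataclass
class SimulationConfig:
    fs: float = 100.0
    epoch_seconds: float = 30.0
    n_epochs: int = 1000
    n_channels: int = 1
    stage_prevalence: np.ndarray = field(default_factory=lambda: SLEEP_EDF_PREVALENCE.copy())
    transition_matrix: np.ndarray | None = None
    seed: int = 0
    pink_noise: bool = False  # 1/f-shape the broadband background
    templates: dict = field(default_factory=lambda: dict(DEFAULT_TEMPLATES))

    def __post_init__(self):
        self.stage_prevalence = np.asarray(self.stage_prevalence, dtype=float)
        if abs(self.stage_prevalence.sum() - 1.0) > 1e-6:
            raise InvalidConfigError("stage_prevalence must sum to 1")
        if self.transition_matrix is None:
            self.transition_matrix = default_transition_matrix(self.stage_prevalence)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.transition_matrix.shape != (5, 5):
            raise InvalidConfigError("transition_matrix must be 5x5")
        if np.any(self.transition_matrix < 0) or \
                not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-8):
            raise InvalidConfigError("transition_matrix rows must be non-negative and sum to 1")

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.fs * self.epoch_seconds))


def _pink_filter(noise: np.ndarray, fs: float) -> np.ndarray:
    """Approximate 1/f spectral shaping via rFFT rescaling."""
    spec = np.fft.rfft(noise)
    freqs = np.fft.rfftfreq(len(noise), d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    shaped = np.fft.irfft(spec * scale, n=len(noise))
    sd = shaped.std()
    return shaped / sd * noise.std() if sd > 0 else shaped


def generate_epoch(stage: SleepStage, cfg: SimulationConfig,
                   template: StageTemplate | None = None,
                   seed: int | np.random.SeedSequence | None = None) -> np.ndarray:
    """One synthetic epoch (n_channels, samples_per_epoch), bit-reproducible
    under the same seed."""
    stage = SleepStage(stage)
    if template is None:
        template = cfg.templates[stage]
    if template.stage != stage:
        raise InvalidConfigError(
            f"template is for {template.stage.name}, requested {stage.name}")
    nyq = cfg.fs / 2.0
    for f0, bw, _ in template.components:
        if f0 + bw / 2.0 >= nyq:
            raise InvalidConfigError(
                f"component at {f0} Hz (bw {bw}) exceeds Nyquist {nyq} Hz")
    if template.burst_amplitude > 0 and template.burst_freq >= nyq:
        raise InvalidConfigError("burst frequency exceeds Nyquist")
    rng = np.random.default_rng(seed)
    n = cfg.samples_per_epoch
    t = np.arange(n) / cfg.fs
    out = np.empty((cfg.n_channels, n), dtype=np.float32)
    for ch in range(cfg.n_channels):
        x = rng.normal(0.0, template.noise_sd, n)
        if cfg.pink_noise:
            x = _pink_filter(x, cfg.fs)
        for f0, bw, amp in template.components:
            freq = rng.uniform(f0 - bw / 2.0, f0 + bw / 2.0)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            # slow amplitude modulation keeps the waveform non-stationary
            am = 1.0 + 0.3 * np.sin(2.0 * np.pi * rng.uniform(0.05, 0.2) * t
                                    + rng.uniform(0.0, 2.0 * np.pi))
            x = x + amp * am * np.sin(2.0 * np.pi * freq * t + phase)
        if template.burst_amplitude > 0 and template.burst_prob > 0:
            # one Bernoulli trial per second; events are ~1-s Hann-windowed bursts
            n_seconds = int(cfg.epoch_seconds)
            burst_len = int(cfg.fs)
            window = np.hanning(burst_len)
            for sec in range(n_seconds):
                if rng.random() < template.burst_prob:
                    start = sec * burst_len
                    stop = min(start + burst_len, n)
                    seg = np.arange(stop - start) / cfg.fs
                    phase = rng.uniform(0.0, 2.0 * np.pi)
                    x[start:stop] += (template.burst_amplitude
                                      * window[:stop - start]
                                      * np.sin(2.0 * np.pi * template.burst_freq * seg + phase))
        out[ch] = x.astype(np.float32)
    return out


def generate_night(cfg: SimulationConfig) -> EpochSet:
    """A full synthetic night: Markov hypnogram (initialised at W) plus
    per-label epochs, deterministic under ``cfg.seed``."""
    ss = np.random.SeedSequence(cfg.seed)
    chain_rng = np.random.default_rng(ss.spawn(1)[0])
    labels = np.empty(cfg.n_epochs, dtype=np.int64)
    state = int(SleepStage.W)
    for i in range(cfg.n_epochs):
        labels[i] = state
        state = int(chain_rng.choice(5, p=cfg.transition_matrix[state]))
    epoch_seeds = ss.spawn(cfg.n_epochs + 1)[1:]
    data = np.empty((cfg.n_epochs, cfg.n_channels, cfg.samples_per_epoch), dtype=np.float32)
    for i in range(cfg.n_epochs):
        data[i] = generate_epoch(SleepStage(labels[i]), cfg, seed=epoch_seeds[i])
    return EpochSet(data=data, labels=labels, fs=cfg.fs,
                    epoch_seconds=cfg.epoch_seconds,
                    source_id=f"synthetic-seed{cfg.seed}",
                    channels=[f"EEG synth{c}" for c in range(cfg.n_channels)])


# ---------------------------------------------------------------------------
# EDF fixture writer
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf_fixture(es: EpochSet, path: str | Path,
                      hypnogram_path: str | Path | None = None) -> Path:
    """Write an EpochSet as a continuous EDF file (16-bit) plus hypnogram CSV.

    The writer emits plain EDF with one-second data records and a symmetric
    physical range covering the signal, so round-tripping through any EDF
    reader agrees with the source to within one quantisation step.
    """
    if len(es) == 0:
        raise ValueError("cannot write an empty EpochSet")
    path = Path(path)
    fs = es.fs
    spr = int(round(fs))  # samples per 1-s record
    if abs(fs - spr) > 1e-9:
        raise InvalidConfigError("EDF fixture writer requires an integer sampling rate")
    signal = es.data.transpose(1, 0, 2).reshape(len(es.channels), -1).astype(np.float64)
    n_records = int(round(len(es) * es.epoch_seconds))
    if signal.shape[1] != n_records * spr:
        raise InvalidConfigError("epoch_seconds must be a whole number of seconds")
    nchan = len(es.channels)

    phys_max = float(np.ceil(np.abs(signal).max() + 1.0))
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((signal - phys_min) * scale + dig_min).astype("<i2")

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),                       # local patient id
        _edf_field(f"Startdate X X X {es.source_id or 'synthetic'}", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(str(256 * (1 + nchan)), 8),
        _edf_field("", 44),
        _edf_field(str(n_records), 8),
        _edf_field("1", 8),                              # record duration (s)
        _edf_field(str(nchan), 4),
    ])
    sig_header = b"".join([
        b"".join(_edf_field(c, 16) for c in es.channels),
        b"".join(_edf_field("synthetic EEG", 80) for _ in range(nchan)),
        b"".join(_edf_field("uV", 8) for _ in range(nchan)),
        b"".join(_edf_field(f"{phys_min:g}", 8) for _ in range(nchan)),
        b"".join(_edf_field(f"{phys_max:g}", 8) for _ in range(nchan)),
        b"".join(_edf_field(str(dig_min), 8) for _ in range(nchan)),
        b"".join(_edf_field(str(dig_max), 8) for _ in range(nchan)),
        b"".join(_edf_field("", 80) for _ in range(nchan)),
        b"".join(_edf_field(str(spr), 8) for _ in range(nchan)),
        b"".join(_edf_field("", 32) for _ in range(nchan)),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        rec = digital.reshape(nchan, n_records, spr)
        for r in range(n_records):
            for ch in range(nchan):
                fh.write(rec[ch, r].tobytes())
    if hypnogram_path is None:
        hypnogram_path = path.with_suffix(".hypnogram.csv")
    write_hypnogram_csv(es.labels, hypnogram_path)
    return path
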