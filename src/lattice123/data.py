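"""EEG ingestion, epoch segmentation and synthetic multichannel generation.

The unit of classification is the *epoch*: one fixed-length, single-channel
segment (default 3750 samples = 15 s at 250 Hz) carrying a binary label
(healthy vs. AD).  Recordings are read from EDF (via mne, optional) or a
delimited numeric matrix (one row per channel) and cut into consecutive
non-overlapping epochs; the trailing remainder is dropped.

The synthetic generator emulates a 59-channel, two-class, imbalanced epoch
collection.  Each epoch is a sum of band-limited Gaussian noise components
(delta/theta/alpha/beta) with class-dependent band powers plus a white
noise floor; the default AD profile has elevated theta and reduced alpha
power relative to healthy controls (the EEG "slowing" convention), and the
default class sizes follow a roughly 3.5:1 healthy:AD imbalance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EpochCollection",
    "SynthConfig",
    "read_recording",
    "generate_synthetic",
    "EPOCH_SAMPLES",
    "SAMPLING_RATE",
    "BANDS",
]

logger = logging.getLogger(__name__)

EPOCH_SAMPLES = 3750
SAMPLING_RATE = 250.0

#: canonical EEG band edges in Hz
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

HEALTHY, AD = "healthy", "AD"


@dataclass
class EpochCollection:
    """Epoch x channel x sample array with aligned per-epoch labels."""

    epochs: np.ndarray  # (n_epochs, n_channels, n_samples)
    labels: np.ndarray  # (n_epochs,) strings
    sampling_rate: float = SAMPLING_RATE
    channel_names: tuple[str, ...] = ()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, n_samples)")
        if self.labels.shape != (self.epochs.shape[0],):
            raise ValueError("labels must align with epochs")
        if self.epochs.shape[1] < 1:
            raise ValueError("need at least one channel")
        if not self.channel_names:
            self.channel_names = tuple(
                f"ch{i + 1:02d}" for i in range(self.epochs.shape[1])
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    def channel(self, index: int) -> np.ndarray:
        """(n_epochs, n_samples) view of one channel."""
        return self.epochs[:, index, :]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic two-class EEG collection."""

    n_channels: int = 59
    n_epochs_healthy: int = 78
    n_epochs_ad: int = 22
    #: per-class band powers (variance contributed by each band)
    healthy_powers: dict = field(
        default_factory=lambda: {
            "delta": 1.0,
            "theta": 1.0,
            "alpha": 2.0,
            "beta": 0.5,
        }
    )
    ad_powers: dict = field(
        default_factory=lambda: {
            "delta": 1.5,
            "theta": 4.0,
            "alpha": 0.5,
            "beta": 0.5,
        }
    )
    noise_floor: float = 0.25  # white-noise variance
    n_samples: int = EPOCH_SAMPLES
    sampling_rate: float = SAMPLING_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.n_epochs_healthy < 0 or self.n_epochs_ad < 0:
            raise ValueError("counts must be positive")
        for powers in (self.healthy_powers, self.ad_powers):
            if any(v < 0 for v in powers.values()):
                raise ValueError("band powers must be non-negative")
        if self.noise_floor < 0:
            raise ValueError("noise floor must be non-negative")


def _segment(data: np.ndarray, epoch_length: int) -> np.ndarray:
    """(channels, samples) -> (n_epochs, channels, epoch_length), remainder dropped."""
    n_channels, n_samples = data.shape
    n_epochs = n_samples // epoch_length
    if n_samples % epoch_length:
        logger.info(
            "dropping %d trailing samples (< one epoch)", n_samples % epoch_length
        )
    trimmed = data[:, : n_epochs * epoch_length]
    return trimmed.reshape(n_channels, n_epochs, epoch_length).transpose(1, 0, 2)


def _read_labels(labels_path: str | Path, n_epochs: int) -> np.ndarray:
    """Labels CSV: either epoch_id,label rows or a single recording label."""
    df = pd.read_csv(labels_path)
    if df.shape[1] == 1:
        df.columns = ["label"]
        if len(df) == 1:
            return np.repeat(df["label"].iloc[0], n_epochs)
        labels = df["label"].to_numpy()
    else:
        key, val = df.columns[0], df.columns[1]
        if len(df) == 1:
            return np.repeat(df[val].iloc[0], n_epochs)
        labels = df.sort_values(key)[val].to_numpy()
    if labels.size < n_epochs:
        raise ValueError(
            f"label file provides {labels.size} labels for {n_epochs} epochs"
        )
    return labels[:n_epochs]


def read_recording(
    path: str | Path,
    format: str | None = None,
    epoch_length: int = EPOCH_SAMPLES,
    labels_path: str | Path | None = None,
    sampling_rate: float | None = None,
) -> EpochCollection:
    """Read an EDF or delimited-matrix recording and cut it into epochs.

    CSV dialect: comma-separated, one row per channel, optional first
    column of channel names.  Epochs are consecutive and non-overlapping;
    the trailing remainder is dropped.
    """
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data()
        names = tuple(raw.ch_names)
        rate = float(raw.info["sfreq"])
    elif fmt == "csv":
        df = pd.read_csv(path, header=None)
        if df.iloc[:, 0].dtype == object:  # leading channel-name column
            names = tuple(df.iloc[:, 0].astype(str))
            data = df.iloc[:, 1:].to_numpy(dtype=np.float64)
        else:
            data = df.to_numpy(dtype=np.float64)
            names = tuple(f"ch{i + 1:02d}" for i in range(data.shape[0]))
        rate = sampling_rate if sampling_rate is not None else SAMPLING_RATE
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'edf' or 'csv'")

    if sampling_rate is not None and abs(rate - sampling_rate) > 1e-9:
        raise ValueError(
            f"recording sampled at {rate} Hz but config expects {sampling_rate} Hz"
        )

    epochs = _segment(data, epoch_length)
    if epochs.shape[0] == 0:
        warnings.warn(
            f"recording shorter than one epoch ({data.shape[1]} < {epoch_length} "
            "samples); returning an empty collection",
            stacklevel=2,
        )
        labels = np.empty(0, dtype=object)
    elif labels_path is None:
        raise ValueError("a labels file is required for a non-empty recording")
    else:
        labels = _read_labels(labels_path, epochs.shape[0])
    return EpochCollection(
        epochs=epochs.reshape(-1, data.shape[0], epoch_length)
        if epochs.size
        else np.empty((0, data.shape[0], epoch_length)),
        labels=labels,
        sampling_rate=rate,
        channel_names=names,
        provenance={"path": str(path), "format": fmt},
    )


def _band_limited_noise(
    rng: np.random.Generator,
    n_samples: int,
    rate: float,
    powers: dict,
    noise_floor: float,
) -> np.ndarray:
    """Spectral synthesis: Gaussian noise with exact per-band variances.

    Each band is white Gaussian noise restricted to its frequency support
    and rescaled so its time-domain variance equals the configured power;
    a white noise floor is added on top.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    x = np.sqrt(noise_floor) * rng.standard_normal(n_samples)
    for band, power in powers.items():
        lo, hi = BANDS[band]
        mask = (freqs >= lo) & (freqs < hi)
        if not mask.any() or power == 0:
            continue
        spectrum = np.zeros(freqs.size, dtype=complex)
        spectrum[mask] = rng.standard_normal(mask.sum()) + 1j * rng.standard_normal(
            mask.sum()
        )
        comp = np.fft.irfft(spectrum, n=n_samples)
        sd = comp.std()
        if sd > 0:
            x += comp * (np.sqrt(power) / sd)
    return x


def generate_synthetic(config: SynthConfig) -> EpochCollection:
    """Deterministic synthetic collection under ``config.seed``.

    Channels receive independent noise realizations but share the
    class-dependent spectral profile.  Epochs are shuffled so classes
    interleave (the shuffle is part of the seeded stream).
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_epochs_healthy + config.n_epochs_ad
    labels = np.array(
        [HEALTHY] * config.n_epochs_healthy + [AD] * config.n_epochs_ad, dtype=object
    )
    epochs = np.empty((n_total, config.n_channels, config.n_samples))
    for e in range(n_total):
        powers = config.healthy_powers if labels[e] == HEALTHY else config.ad_powers
        for c in range(config.n_channels):
            epochs[e, c] = _band_limited_noise(
                rng, config.n_samples, config.sampling_rate, powers, config.noise_floor
            )
    perm = rng.permutation(n_total)
    return EpochCollection(
        epochs=epochs[perm],
        labels=labels[perm],
        sampling_rate=config.sampling_rate,
        provenance={"generator": "synthetic", "seed": config.seed},
    )
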