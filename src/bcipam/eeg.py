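"""Synthetic multichannel EEG epochs for decoder calibration.

Emulates two-class calibration data (motor imagery vs idle) from a 7-channel
montage (F3, F4, C3, Cz, C4, P3, P4) sampled at 250 Hz: broadband noise plus
band-limited mu (8-12 Hz) and beta (13-30 Hz) rhythms concentrated over the
sensorimotor channels.  Motor-imagery epochs show event-related
desynchronization (ERD): the rhythmic band power on the channels over the
contralateral hand area (C3, and the midline Cz) is attenuated by a factor
``1 - erd_depth``.  ``erd_depth = 0`` makes the classes statistically
identical; ``erd_depth = 1`` removes the rhythm entirely during MI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, lfilter

__all__ = ["CHANNELS", "EpochSet", "generate_synthetic_eeg",
           "save_epochs", "load_epochs"]

CHANNELS = ("F3", "F4", "C3", "Cz", "C4", "P3", "P4")
ERD_CHANNELS = ("C3", "Cz")  # contralateral to right-hand MI, plus midline

# per-channel rhythm RMS in microvolt: sensorimotor row carries the strong rhythm
_MU_RMS = {"F3": 1.0, "F4": 1.0, "C3": 3.0, "Cz": 3.0, "C4": 3.0, "P3": 1.5, "P4": 1.5}
_BETA_RMS = {ch: 0.5 * v for ch, v in _MU_RMS.items()}


@dataclass
class EpochSet:
    """Labeled EEG epochs: samples [epoch x channel x time] in microvolt."""

    samples: np.ndarray
    labels: np.ndarray  # "mi" | "idle" per epoch
    rate: float = 250.0
    channel_names: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.samples.ndim != 3:
            raise ValueError("samples must be [epoch x channel x time]")
        if self.samples.shape[0] != len(self.labels):
            raise ValueError("one label per epoch required")
        if self.samples.shape[1] != len(self.channel_names):
            raise ValueError("channel axis must match channel_names")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_epochs(self) -> int:
        return self.samples.shape[0]

    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (mi_samples, idle_samples)."""
        return (self.samples[self.labels == "mi"],
                self.samples[self.labels == "idle"])


def _band_noise(rng: np.random.Generator, band: tuple[float, float], rate: float,
                n: int, shape: tuple[int, ...]) -> np.ndarray:
    """Band-limited Gaussian noise with unit RMS (fixed calibrated gain)."""
    b, a = butter(4, band, btype="bandpass", fs=rate)
    # calibrate the filter's noise gain once on a long reference realization
    ref = lfilter(b, a, np.random.default_rng(12345).normal(size=50000))
    gain = ref[1000:].std()
    x = lfilter(b, a, rng.normal(size=shape + (n,)), axis=-1)
    return x / gain


def generate_synthetic_eeg(n_mi: int, n_idle: int, erd_depth: float = 0.5,
                           noise_sd: float = 1.0, seed: int = 0,
                           duration: float = 4.0, rate: float = 250.0) -> EpochSet:
    """Generate labeled MI/idle calibration epochs (default 4 s at 250 Hz).

    Parameters
    ----------
    n_mi, n_idle : int
        Number of epochs per class (a calibration run uses 30 + 30).
    erd_depth : float in [0, 1]
        Fractional band-power attenuation on the ERD channels during MI.
    noise_sd : float
        Broadband (white) noise standard deviation in microvolt.
    seed : int
        Seed for the single generator driving all randomness.
    """
    if n_mi <= 0 or n_idle <= 0:
        raise ValueError("epoch counts must be positive")
    if not 0.0 <= erd_depth <= 1.0:
        raise ValueError("erd_depth must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    n_ep = n_mi + n_idle
    labels = np.array(["mi"] * n_mi + ["idle"] * n_idle)
    order = rng.permutation(n_ep)
    labels = labels[order]

    X = rng.normal(0.0, noise_sd, size=(n_ep, len(CHANNELS), n))
    mu = _band_noise(rng, (8.0, 12.0), rate, n, (n_ep, len(CHANNELS)))
    beta = _band_noise(rng, (13.0, 30.0), rate, n, (n_ep, len(CHANNELS)))
    is_mi = labels == "mi"
    att = np.sqrt(1.0 - erd_depth)
    for c, ch in enumerate(CHANNELS):
        amp_mu = np.full(n_ep, _MU_RMS[ch])
        amp_beta = np.full(n_ep, _BETA_RMS[ch])
        if ch in ERD_CHANNELS:
            amp_mu[is_mi] *= att
            amp_beta[is_mi] *= att
        X[:, c, :] += amp_mu[:, None] * mu[:, c, :] + amp_beta[:, None] * beta[:, c, :]
    return EpochSet(samples=X, labels=labels, rate=rate)


def save_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write epochs as a compressed array container with a JSON sidecar."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), samples=epochs.samples)
    header = {"labels": epochs.labels.tolist(), "rate": epochs.rate,
              "channel_names": list(epochs.channel_names)}
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    samples = np.load(path.with_suffix(".npz"))["samples"]
    header = json.loads(path.with_suffix(".json").read_text())
    return EpochSet(samples=samples, labels=np.array(header["labels"]),
                    rate=header["rate"],
                    channel_names=tuple(header["channel_names"]))
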