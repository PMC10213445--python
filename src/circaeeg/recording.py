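"""Epoch-aligned EEG/EMG recordings.

The raw-signal entry point of the pipeline: a recording is stored as a
dense ``(n_epochs, samples_per_epoch)`` array per channel, one row per
scoring epoch (10 s at 128 Hz by default, i.e. 1280 samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EpochedRecording", "write_signals_csv", "read_signals_csv"]


@dataclass
class EpochedRecording:
    """EEG and EMG signals reshaped into scoring epochs.

    Parameters
    ----------
    eeg, emg : ndarray, shape (n_epochs, samples_per_epoch)
        One row per epoch.  EEG drives the spectral analysis, EMG the
        muscle-tone wake override.
    fs : float
        Sampling rate in Hz.
    epoch_s : float
        Epoch length in seconds.
    """

    eeg: np.ndarray
    emg: np.ndarray
    fs: float = 128.0
    epoch_s: float = 10.0

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg)
        self.emg = np.asarray(self.emg)
        if self.eeg.ndim != 2 or self.emg.ndim != 2:
            raise ValueError("eeg and emg must be 2-D (n_epochs, samples_per_epoch)")
        if self.eeg.shape != self.emg.shape:
            raise ValueError(
                f"eeg shape {self.eeg.shape} != emg shape {self.emg.shape}"
            )
        expected = self.fs * self.epoch_s
        if abs(self.eeg.shape[1] - expected) > 1e-9:
            raise ValueError(
                f"{self.eeg.shape[1]} samples per epoch inconsistent with "
                f"fs={self.fs} Hz x epoch_s={self.epoch_s} s"
            )

    @property
    def n_epochs(self) -> int:
        return self.eeg.shape[0]

    @property
    def samples_per_epoch(self) -> int:
        return self.eeg.shape[1]

    def epoch_zt(self, zt0_offset: float = 0.0) -> np.ndarray:
        """ZT (h) of each epoch start, wrapped to [0, 24)."""
        t = zt0_offset + np.arange(self.n_epochs) * self.epoch_s / 3600.0
        return np.mod(t, 24.0)


def write_signals_csv(rec: EpochedRecording, path) -> None:
    """Write a recording as a two-column CSV (sample-major: eeg, emg)."""
    df = pd.DataFrame(
        {"eeg": rec.eeg.ravel().astype(np.float32), "emg": rec.emg.ravel().astype(np.float32)}
    )
    df.to_csv(path, index=False)


def read_signals_csv(path, fs: float = 128.0, epoch_s: float = 10.0) -> EpochedRecording:
    """Read a two-column signal CSV written by :func:`write_signals_csv`.

    Trailing samples that do not fill a whole epoch are discarded.
    """
    df = pd.read_csv(path)
    spe = int(round(fs * epoch_s))
    n = (len(df) // spe) * spe
    eeg = df["eeg"].to_numpy()[:n].reshape(-1, spe)
    emg = df["emg"].to_numpy()[:n].reshape(-1, spe)
    return EpochedRecording(eeg=eeg, emg=emg, fs=fs, epoch_s=epoch_s)
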