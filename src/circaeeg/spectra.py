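"""Per-epoch EEG power spectra and stage-conditioned hourly averages.

Each 10-s epoch at 128 Hz yields a native 0.1 Hz frequency grid, so the
power spectrum on 0.0-16.0 Hz (161 bins) is read straight off the
discrete Fourier transform: rectangular window, epoch mean removed, no
interpolation.  The central data structure downstream is the hour x
stage x frequency tensor of mean epoch power with a missing-cell mask
for (hour, stage) combinations that contain no epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import EpochedRecording
from .staging import Hypnogram, STAGE_NAMES, WAKE, NREM, REM

__all__ = [
    "FREQ_STEP",
    "F_MAX",
    "N_FREQ",
    "freq_grid",
    "PowerSpectrum",
    "HourlyStageSpectra",
    "one_sided_power",
    "epoch_power_spectrum",
    "epoch_spectra",
    "hourly_stage_spectra",
    "pooled_hourly_spectra",
    "normalize_distribution",
    "write_spectra_csv",
    "read_spectra_csv",
]

FREQ_STEP = 0.1
F_MAX = 16.0
N_FREQ = 161  # 0.0, 0.1, ..., 16.0 Hz inclusive


def freq_grid() -> np.ndarray:
    """The fixed 0.0-16.0 Hz analysis grid (161 bins, 0.1 Hz step)."""
    return np.round(np.arange(N_FREQ) * FREQ_STEP, 1)


@dataclass
class PowerSpectrum:
    """One epoch's power on the fixed grid (arbitrary units, >= 0)."""

    power: np.ndarray

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (N_FREQ,):
            raise ValueError(f"power must have shape ({N_FREQ},)")

    @property
    def freqs(self) -> np.ndarray:
        return freq_grid()


@dataclass
class HourlyStageSpectra:
    """hour x stage x frequency tensor of mean epoch power.

    ``power[h, s, f]`` is the mean over epochs of stage ``s`` in hour
    ``h``; cells with zero contributing epochs are NaN and flagged in
    ``mask``.  Masked cells must be treated as absent downstream, never
    as zero.
    """

    power: np.ndarray  # (n_hours, 3, N_FREQ), NaN where masked
    n_epochs: np.ndarray  # (n_hours, 3) contributing epoch counts

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.n_epochs = np.asarray(self.n_epochs, dtype=int)
        if self.power.ndim != 3 or self.power.shape[1:] != (3, N_FREQ):
            raise ValueError(f"power must be (n_hours, 3, {N_FREQ})")
        if self.n_epochs.shape != self.power.shape[:2]:
            raise ValueError("n_epochs shape mismatch")

    @property
    def n_hours(self) -> int:
        return self.power.shape[0]

    @property
    def mask(self) -> np.ndarray:
        """True where the (hour, stage) cell has no epochs."""
        return self.n_epochs == 0

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: hour, stage, freq_hz, power, n_epochs."""
        h, s, f = np.meshgrid(
            np.arange(self.n_hours), np.arange(3), freq_grid(), indexing="ij"
        )
        return pd.DataFrame(
            {
                "hour": h.ravel(),
                "stage": np.array(STAGE_NAMES)[s.ravel()],
                "freq_hz": f.ravel(),
                "power": self.power.ravel(),
                "n_epochs": np.repeat(self.n_epochs.ravel(), N_FREQ),
            }
        )


def _check_native_grid(n_samples: int, fs: float) -> int:
    """Return the bin stride mapping the 0.1 Hz grid onto native DFT bins."""
    df = fs / n_samples
    stride = FREQ_STEP / df
    if abs(stride - round(stride)) > 1e-6:
        raise ValueError(
            f"0.1 Hz is not a native DFT bin for {n_samples} samples at {fs} Hz; "
            "no interpolation is performed"
        )
    return int(round(stride))


def one_sided_power(epochs: np.ndarray, fs: float) -> np.ndarray:
    """Full one-sided power of mean-removed epochs (rows), all native bins.

    Scaled so the bins sum to ``n x variance`` of the epoch (Parseval):
    interior bins carry the factor 2, DC and Nyquist do not.
    """
    x = np.atleast_2d(np.asarray(epochs, dtype=float))
    n = x.shape[1]
    x = x - x.mean(axis=1, keepdims=True)
    X = np.fft.rfft(x, axis=1)
    p = np.abs(X) ** 2 / n
    p[:, 1:] *= 2.0
    if n % 2 == 0:
        p[:, -1] /= 2.0  # Nyquist bin is not duplicated
    return p


def epoch_power_spectrum(eeg_epoch: np.ndarray, fs: float) -> PowerSpectrum:
    """Power spectrum of one epoch on the fixed 0-16 Hz, 0.1 Hz grid."""
    x = np.asarray(eeg_epoch, dtype=float)
    if x.ndim != 1:
        raise ValueError("eeg_epoch must be 1-D")
    stride = _check_native_grid(x.size, fs)
    if (N_FREQ - 1) * stride > x.size // 2:
        raise ValueError("epoch too short to reach 16 Hz")
    full = one_sided_power(x[None, :], fs)[0]
    return PowerSpectrum(power=full[: (N_FREQ - 1) * stride + 1 : stride])


def epoch_spectra(rec: EpochedRecording, chunk: int = 512) -> np.ndarray:
    """Power spectra of every epoch of a recording, shape (n_epochs, 161)."""
    stride = _check_native_grid(rec.samples_per_epoch, rec.fs)
    sl = slice(0, (N_FREQ - 1) * stride + 1, stride)
    out = np.empty((rec.n_epochs, N_FREQ))
    for i in range(0, rec.n_epochs, chunk):
        out[i : i + chunk] = one_sided_power(rec.eeg[i : i + chunk], rec.fs)[:, sl]
    return out


def hourly_stage_spectra(spectra: np.ndarray, hyp: Hypnogram) -> HourlyStageSpectra:
    """Stage-conditioned hourly mean of per-epoch spectra.

    ``spectra`` is (n_epochs, 161), aligned with ``hyp``; the recording
    must span whole hours.
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2 or spectra.shape[1] != N_FREQ:
        raise ValueError(f"spectra must be (n_epochs, {N_FREQ})")
    if spectra.shape[0] != hyp.n_epochs:
        raise ValueError("spectra and hypnogram lengths differ")
    eph = 3600.0 / hyp.epoch_s
    if abs(eph - round(eph)) > 1e-9 or hyp.n_epochs % int(round(eph)) != 0:
        raise ValueError("recording does not span a whole number of hours")
    eph = int(round(eph))
    n_hours = hyp.n_epochs // eph
    power = np.full((n_hours, 3, N_FREQ), np.nan)
    counts = np.zeros((n_hours, 3), dtype=int)
    hour = hyp.hour_index()
    for h in range(n_hours):
        in_hour = hour == h
        for s in (WAKE, NREM, REM):
            sel = in_hour & (hyp.stages == s)
            c = int(sel.sum())
            counts[h, s] = c
            if c:
                power[h, s] = spectra[sel].mean(axis=0)
    return HourlyStageSpectra(power=power, n_epochs=counts)


def pooled_hourly_spectra(hss: HourlyStageSpectra) -> np.ndarray:
    """Hourly mean spectrum over all epochs regardless of stage.

    Epoch-count-weighted mean over the unmasked stages of each hour,
    shape (n_hours, 161); hours with no epochs at all are NaN.
    """
    w = hss.n_epochs.astype(float)[:, :, None]  # (H, 3, 1)
    p = np.where(np.isnan(hss.power), 0.0, hss.power)
    tot = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (p * w).sum(axis=1) / tot
    out[tot[:, 0] == 0] = np.nan
    return out


def normalize_distribution(power: np.ndarray) -> np.ndarray:
    """Normalize a spectrum to a unit-sum distribution (scale-invariant)."""
    p = np.asarray(power, dtype=float)
    s = p.sum()
    if not np.isfinite(s) or s <= 0:
        raise ValueError("cannot normalize a spectrum with non-positive total power")
    return p / s


def write_spectra_csv(hss: HourlyStageSpectra, path) -> None:
    hss.to_frame().to_csv(path, index=False)


def read_spectra_csv(path) -> HourlyStageSpectra:
    df = pd.read_csv(path)
    n_hours = int(df["hour"].max()) + 1
    power = np.full((n_hours, 3, N_FREQ), np.nan)
    counts = np.zeros((n_hours, 3), dtype=int)
    stage_idx = {name: i for i, name in enumerate(STAGE_NAMES)}
    f_idx = {round(f, 1): i for i, f in enumerate(freq_grid())}
    h = df["hour"].to_numpy()
    s = df["stage"].map(stage_idx).to_numpy()
    f = df["freq_hz"].round(1).map(f_idx).to_numpy()
    power[h, s, f] = df["power"].to_numpy()
    counts[h, s] = df["n_epochs"].to_numpy()
    return HourlyStageSpectra(power=power, n_epochs=counts)
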