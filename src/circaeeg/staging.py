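"""Hypnogram handling, EMG amplitude, and the muscle-tone wake override.

A hypnogram assigns one of three vigilance stages (WAKE, NREM sleep, REM
sleep) to every 10-s epoch.  Scoring itself is upstream of this package;
here we refine a given hypnogram with an EMG-based rule: epochs whose EMG
amplitude (log10 of the per-epoch standard deviation) exceeds an
Otsu-derived threshold are forced to WAKE, since high muscle tone is
incompatible with sleep regardless of the cortical signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recording import EpochedRecording

__all__ = [
    "WAKE",
    "NREM",
    "REM",
    "STAGE_NAMES",
    "STAGE_LETTERS",
    "Hypnogram",
    "EMGAmplitudeSeries",
    "HourlyStageAmounts",
    "emg_amplitude",
    "otsu_threshold",
    "apply_wake_override",
    "hourly_stage_amounts",
    "read_hypnogram_csv",
    "write_hypnogram_csv",
]

WAKE, NREM, REM = 0, 1, 2
STAGE_NAMES = ("WAKE", "NREM", "REM")
STAGE_LETTERS = ("W", "N", "R")
_LETTER_TO_CODE = {"W": WAKE, "N": NREM, "R": REM}


@dataclass
class Hypnogram:
    """Per-epoch stage labels with the time base needed downstream.

    ``stages`` holds integer codes (0=WAKE, 1=NREM, 2=REM); ``zt0_offset``
    is the ZT of epoch 0 (ZT0 = lights-on; under constant darkness the
    projected ZT labels are kept).
    """

    stages: np.ndarray
    epoch_s: float = 10.0
    zt0_offset: float = 0.0

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=np.int8)
        if self.stages.ndim != 1:
            raise ValueError("stages must be 1-D")
        if self.stages.size and not np.all(np.isin(self.stages, [WAKE, NREM, REM])):
            raise ValueError("stages must be codes 0 (WAKE), 1 (NREM) or 2 (REM)")

    @property
    def n_epochs(self) -> int:
        return self.stages.size

    def zt(self) -> np.ndarray:
        """ZT (h) of each epoch start, wrapped to [0, 24)."""
        t = self.zt0_offset + np.arange(self.n_epochs) * self.epoch_s / 3600.0
        return np.mod(t, 24.0)

    def hour_index(self) -> np.ndarray:
        """0-based recording-hour bin of each epoch (not wrapped)."""
        t = np.arange(self.n_epochs) * self.epoch_s
        return (t // 3600.0).astype(int)


@dataclass
class EMGAmplitudeSeries:
    """Per-epoch log10 standard deviation of the EMG signal.

    Missing values (zero-variance epochs) are stored as NaN; such epochs
    are listed in ``qc_missing`` for the QC log.
    """

    values: np.ndarray
    qc_missing: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_epochs(self) -> int:
        return self.values.size

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass
class HourlyStageAmounts:
    """Minutes of each stage in every hour bin [h, h+1) of the recording."""

    minutes: np.ndarray  # (n_hours, 3) in stage-code order W, N, R

    @property
    def n_hours(self) -> int:
        return self.minutes.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.minutes, columns=list(STAGE_NAMES))
        df.insert(0, "hour", np.arange(self.n_hours))
        return df


def emg_amplitude(rec: EpochedRecording) -> EMGAmplitudeSeries:
    """log10 of the per-epoch EMG standard deviation (population convention).

    Zero-variance epochs are flagged missing (NaN), never -inf.
    """
    if rec.samples_per_epoch < 2:
        raise ValueError("epochs need at least 2 samples")
    sd = rec.emg.std(axis=1)  # ddof=0
    values = np.full(sd.shape, np.nan)
    ok = sd > 0
    values[ok] = np.log10(sd[ok])
    return EMGAmplitudeSeries(values=values, qc_missing=np.flatnonzero(~ok))


def otsu_threshold(amps: EMGAmplitudeSeries | np.ndarray, n_bins: int = 256) -> float:
    """Otsu's between-class-variance threshold on the amplitude histogram.

    The histogram uses ``n_bins`` equal-width bins spanning [min, max] of
    the non-missing values; the returned threshold is the *upper edge* of
    the bin below the chosen class boundary, so classifying with a strict
    ``>`` reproduces the histogram split exactly.
    """
    values = amps.values if isinstance(amps, EMGAmplitudeSeries) else np.asarray(amps, float)
    values = values[np.isfinite(values)]
    if values.size < 2 or np.unique(values).size < 2:
        raise ValueError("Otsu threshold requires >= 2 distinct non-missing values")
    lo, hi = values.min(), values.max()
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    p = counts / counts.sum()
    # class 0 = bins 0..b, class 1 = bins b+1.. ; scan all n_bins-1 boundaries
    w0 = np.cumsum(p)[:-1]
    centers = 0.5 * (edges[:-1] + edges[1:])
    mu = np.cumsum(p * centers)
    mu_total = mu[-1]
    mu0 = np.divide(mu[:-1], w0, out=np.zeros_like(w0), where=w0 > 0)
    w1 = 1.0 - w0
    mu1 = np.divide(mu_total - mu[:-1], w1, out=np.zeros_like(w1), where=w1 > 0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    # the criterion is exactly flat across empty histogram gaps: break ties
    # by the middle boundary of the maximal plateau
    best = between.max()
    ties = np.flatnonzero(between >= best - 1e-12 * max(best, 1.0))
    b = int(ties[len(ties) // 2])
    return float(edges[b + 1])


def apply_wake_override(
    hyp: Hypnogram, amps: EMGAmplitudeSeries, threshold: float
) -> Hypnogram:
    """Force epochs whose EMG amplitude strictly exceeds ``threshold`` to WAKE.

    Missing-amplitude epochs keep their original label.  The rule only
    ever converts labels *to* WAKE, so it is idempotent and monotone in
    the threshold.
    """
    if amps.n_epochs != hyp.n_epochs:
        raise ValueError(
            f"length mismatch: {amps.n_epochs} amplitudes vs {hyp.n_epochs} epochs"
        )
    out = hyp.stages.copy()
    with np.errstate(invalid="ignore"):
        out[amps.values > threshold] = WAKE  # NaN comparisons are False
    return Hypnogram(stages=out, epoch_s=hyp.epoch_s, zt0_offset=hyp.zt0_offset)


def hourly_stage_amounts(hyp: Hypnogram) -> HourlyStageAmounts:
    """Minutes of each stage per hour bin.

    Requires the recording to span a whole number of hours; trim upstream
    otherwise.
    """
    epochs_per_hour = 3600.0 / hyp.epoch_s
    if abs(epochs_per_hour - round(epochs_per_hour)) > 1e-9:
        raise ValueError("epoch_s must divide 3600 s")
    eph = int(round(epochs_per_hour))
    if hyp.n_epochs % eph != 0:
        raise ValueError("recording does not span a whole number of hours")
    n_hours = hyp.n_epochs // eph
    stages = hyp.stages.reshape(n_hours, eph)
    minutes = np.stack(
        [(stages == s).sum(axis=1) * hyp.epoch_s / 60.0 for s in (WAKE, NREM, REM)],
        axis=1,
    )
    return HourlyStageAmounts(minutes=minutes)


def write_hypnogram_csv(hyp: Hypnogram, path) -> None:
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(hyp.n_epochs),
            "zt_hours": hyp.zt(),
            "stage": [STAGE_LETTERS[s] for s in hyp.stages],
        }
    )
    df.to_csv(path, index=False)


def read_hypnogram_csv(path, epoch_s: float = 10.0) -> Hypnogram:
    df = pd.read_csv(path)
    stages = np.array([_LETTER_TO_CODE[s] for s in df["stage"]], dtype=np.int8)
    zt0 = float(df["zt_hours"].iloc[0]) if len(df) else 0.0
    return Hypnogram(stages=stages, epoch_s=epoch_s, zt0_offset=zt0)
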