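"""Circadian rhythm components of EEG power and sleep amounts.

For each sleep-wake stage and frequency bin the hourly power series is
mean-normalized,

    norm_i = (hourly_i - ave) / ave,      ave = mean over hours,

and its first 24-h Fourier harmonic extracted over the T = 72 hourly
points of a 3-day recording:

    COS = (2/T) sum_i norm_i cos(2*pi*i*dt/tau)
    SIN = (2/T) sum_i norm_i sin(2*pi*i*dt/tau)

with tau = 24 h and dt = 1 h, giving the relative amplitude
A = sqrt(COS^2 + SIN^2) and peak time t_p = atan2(SIN, COS)/(2*pi)*24,
wrapped to [0, 24).  Over 72 hourly points (three full cycles) the
discrete harmonics are exactly orthogonal, so a pure 24-h cosine is
recovered without bias.  Hours with a missing (hour, stage) cell are
excluded from both the average and the sums, with T replaced by the
number of non-missing hours.

The module also provides a four-parameter cosinor fit (mesor, amplitude,
acrophase, free period) for hourly stage amounts, and circular statistics
(circular mean, Mardia-Watson-Wheeler two-sample test) for comparing
peak times between groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from lmfit import Parameters, minimize

from .spectra import HourlyStageSpectra, N_FREQ, freq_grid
from .staging import STAGE_NAMES

__all__ = [
    "TAU_H",
    "NormalizedPowerSeries",
    "RhythmComponents",
    "CosinorFit",
    "normalize_power",
    "fourier_component",
    "amplitude_peaktime",
    "rhythm_components",
    "cosinor_fit",
    "mww_test",
    "circular_mean",
    "circular_difference",
]

TAU_H = 24.0  # fixed period of the extracted harmonic (h)


@dataclass
class NormalizedPowerSeries:
    """Mean-normalized hourly power, per stage and frequency.

    ``norm[h, s, f]`` is NaN for missing hours and for invalid series
    (fewer than ``min_hours`` non-missing hours, or zero average power --
    notably the DC bin, which is identically 0 after epoch mean removal).
    """

    norm: np.ndarray  # (n_hours, 3, N_FREQ)
    ave: np.ndarray  # (3, N_FREQ) mean over non-missing hours
    valid: np.ndarray  # (3, N_FREQ) series usable downstream

    @property
    def n_hours(self) -> int:
        return self.norm.shape[0]


@dataclass
class RhythmComponents:
    """First-harmonic COS/SIN, amplitude and peak time per stage x frequency."""

    cos: np.ndarray  # (3, N_FREQ)
    sin: np.ndarray
    amplitude: np.ndarray
    peak_zt: np.ndarray  # NaN where amplitude == 0 or series invalid

    def to_frame(self) -> pd.DataFrame:
        s, f = np.meshgrid(np.arange(3), np.arange(N_FREQ), indexing="ij")
        return pd.DataFrame(
            {
                "stage": np.array(STAGE_NAMES)[s.ravel()],
                "freq_hz": freq_grid()[f.ravel()],
                "cos": self.cos.ravel(),
                "sin": self.sin.ravel(),
                "amplitude": self.amplitude.ravel(),
                "peak_zt": self.peak_zt.ravel(),
            }
        )


@dataclass
class CosinorFit:
    """Least-squares cosine fit y = M + A cos(2 pi (t - phi) / P)."""

    mesor: float
    amplitude: float
    acrophase: float  # h, wrapped to [0, P)
    period: float  # h
    rss: float
    period_identifiable: bool
    success: bool


def normalize_power(hss: HourlyStageSpectra, min_hours: int = 24) -> NormalizedPowerSeries:
    """Mean-normalize each (stage, frequency) hourly series.

    Averages run over non-missing hours only; series with fewer than
    ``min_hours`` non-missing hours or non-positive average power are
    marked invalid (all-NaN) rather than raising, so a whole tensor can
    be processed even though the DC bin is degenerate by construction.
    """
    p = hss.power
    present = ~np.isnan(p[:, :, 0])  # (H, 3)
    n_present = present.sum(axis=0)  # (3,)
    with np.errstate(invalid="ignore"):
        ave = np.nanmean(p, axis=0)  # (3, N_FREQ)
    valid = (n_present[:, None] >= min_hours) & (ave > 0)
    valid[:, 0] = False  # DC: identically ~0 after epoch mean removal
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = (p - ave[None]) / ave[None]
    norm = np.where(valid[None], norm, np.nan)
    return NormalizedPowerSeries(norm=norm, ave=ave, valid=valid)


def _hour_times(n_hours: int, time_assignment: str) -> np.ndarray:
    """Time (h) assigned to hour bins 0..n_hours-1 for the harmonic sums."""
    i = np.arange(1, n_hours + 1, dtype=float)  # 1-based hour index
    if time_assignment == "hour-index":
        return i
    if time_assignment == "bin-center":
        return i - 0.5
    raise ValueError("time_assignment must be 'hour-index' or 'bin-center'")


def fourier_component(
    series: np.ndarray,
    tau: float = TAU_H,
    time_assignment: str = "hour-index",
) -> tuple[float, float]:
    """First Fourier component (COS, SIN) of an hourly series.

    Missing values (NaN) are excluded from the sums and the 2/T factor
    uses the count of non-missing hours.  Hour bin [i-1, i) is assigned
    time i by default; ``time_assignment='bin-center'`` uses i - 0.5 for
    sensitivity analysis.
    """
    y = np.asarray(series, dtype=float)
    t = _hour_times(y.size, time_assignment)
    ok = ~np.isnan(y)
    n = int(ok.sum())
    if n == 0:
        return (np.nan, np.nan)
    ang = 2.0 * np.pi * t[ok] / tau
    c = 2.0 / n * float(np.sum(y[ok] * np.cos(ang)))
    s = 2.0 / n * float(np.sum(y[ok] * np.sin(ang)))
    return (c, s)


def amplitude_peaktime(cos: float, sin: float) -> tuple[float, float]:
    """Amplitude and peak time (h in [0, 24)) from the harmonic components.

    A zero-amplitude component has an undefined peak time, returned NaN.
    """
    if not (np.isfinite(cos) and np.isfinite(sin)):
        return (np.nan, np.nan)
    a = float(np.hypot(cos, sin))
    if a == 0.0:
        return (0.0, np.nan)
    tp = float(np.mod(np.arctan2(sin, cos) / (2.0 * np.pi) * TAU_H, TAU_H))
    if tp >= TAU_H:
        tp = 0.0
    return (a, tp)


def rhythm_components(
    hss: HourlyStageSpectra,
    min_hours: int = 24,
    time_assignment: str = "hour-index",
) -> RhythmComponents:
    """Amplitude and peak time for every (stage, frequency) series."""
    nps = normalize_power(hss, min_hours=min_hours)
    cos = np.full((3, N_FREQ), np.nan)
    sin = np.full((3, N_FREQ), np.nan)
    amp = np.full((3, N_FREQ), np.nan)
    peak = np.full((3, N_FREQ), np.nan)
    for s in range(3):
        for f in range(N_FREQ):
            if not nps.valid[s, f]:
                continue
            c, si = fourier_component(
                nps.norm[:, s, f], time_assignment=time_assignment
            )
            cos[s, f], sin[s, f] = c, si
            amp[s, f], peak[s, f] = amplitude_peaktime(c, si)
    return RhythmComponents(cos=cos, sin=sin, amplitude=amp, peak_zt=peak)


def cosinor_fit(
    t: np.ndarray,
    y: np.ndarray,
    period_bounds: tuple[float, float] = (20.0, 28.0),
) -> CosinorFit:
    """Nonlinear least-squares cosinor fit with a free period.

    Initialization: mesor = mean, amplitude = half-range, acrophase from
    the fixed-24-h first-harmonic estimator, period = 24 h bounded to
    ``period_bounds``.  Amplitude is constrained >= 0 and the acrophase
    wrapped to [0, P).  A flat series (or a fit collapsing to zero
    amplitude) has an unidentifiable period, flagged accordingly.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y) & np.isfinite(t)
    t, y = t[ok], y[ok]
    if t.size < 8:
        raise ValueError("cosinor fit requires >= 8 finite points")
    rng_y = float(y.max() - y.min())
    mesor0 = float(y.mean())
    if rng_y < 1e-12:
        return CosinorFit(mesor0, 0.0, np.nan, np.nan, 0.0, False, True)

    # phase init from the fixed-period harmonic at P = 24 h
    ang = 2.0 * np.pi * t / TAU_H
    c0 = 2.0 / t.size * float(np.sum((y - mesor0) * np.cos(ang)))
    s0 = 2.0 / t.size * float(np.sum((y - mesor0) * np.sin(ang)))
    phi0 = float(np.mod(np.arctan2(s0, c0) / (2.0 * np.pi) * TAU_H, TAU_H))

    params = Parameters()
    params.add("mesor", value=mesor0)
    params.add("amplitude", value=rng_y / 2.0, min=0.0)
    params.add("acrophase", value=phi0, min=phi0 - 12.0, max=phi0 + 12.0)
    params.add("period", value=24.0, min=period_bounds[0], max=period_bounds[1])

    def residual(p):
        return y - (
            p["mesor"]
            + p["amplitude"] * np.cos(2.0 * np.pi * (t - p["acrophase"]) / p["period"])
        )

    res = minimize(residual, params, method="leastsq")
    pv = res.params.valuesdict()
    period = float(pv["period"])
    amp = float(pv["amplitude"])
    phi = float(np.mod(pv["acrophase"], period))
    identifiable = amp > 1e-6 * rng_y
    return CosinorFit(
        mesor=float(pv["mesor"]),
        amplitude=amp,
        acrophase=phi if identifiable else np.nan,
        period=period if identifiable else np.nan,
        rss=float(np.sum(res.residual**2)),
        period_identifiable=identifiable,
        success=bool(res.success),
    )


def _mww_statistic(cosb: np.ndarray, sinb: np.ndarray, in_g1: np.ndarray, n1: int, n2: int) -> float:
    """W from precomputed uniform-score cos/sin and a group-1 membership mask."""
    c1, s1 = cosb[in_g1].sum(), sinb[in_g1].sum()
    c2, s2 = cosb[~in_g1].sum(), sinb[~in_g1].sum()
    return 2.0 * ((c1**2 + s1**2) / n1 + (c2**2 + s2**2) / n2)


def mww_test(
    peaks_group1: np.ndarray,
    peaks_group2: np.ndarray,
    n_permutations: int = 9999,
    seed: int = 0,
) -> dict:
    """Mardia-Watson-Wheeler uniform-scores test on peak times (h).

    Times are mapped to angles 2 pi t / 24, pooled and circularly ranked
    (midranks for ties); the statistic W = 2 (R1^2/n1 + R2^2/n2) is
    compared against the asymptotic chi-square(2 df) null and against a
    label-permutation null.  Returns a dict with ``W``, ``p_chisq`` and
    ``p_permutation``.
    """
    g1 = np.asarray(peaks_group1, dtype=float)
    g2 = np.asarray(peaks_group2, dtype=float)
    n1, n2 = g1.size, g2.size
    if n1 < 4 or n2 < 4:
        raise ValueError("MWW test requires >= 4 observations per group")
    angles = np.mod(np.concatenate([g1, g2]), TAU_H) * 2.0 * np.pi / TAU_H
    ranks = scipy.stats.rankdata(angles)  # midranks for ties
    beta = 2.0 * np.pi * ranks / angles.size
    cosb, sinb = np.cos(beta), np.sin(beta)
    in_g1 = np.zeros(n1 + n2, dtype=bool)
    in_g1[:n1] = True
    w_obs = _mww_statistic(cosb, sinb, in_g1, n1, n2)
    p_chisq = float(scipy.stats.chi2.sf(w_obs, df=2))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(in_g1)
        if _mww_statistic(cosb, sinb, perm, n1, n2) >= w_obs - 1e-12:
            count += 1
    p_perm = (1 + count) / (1 + n_permutations)
    return {"W": float(w_obs), "p_chisq": p_chisq, "p_permutation": float(p_perm)}


def circular_mean(times: np.ndarray) -> float:
    """Circular mean of times on the 24-h clock, NaN if antipodal/degenerate."""
    t = np.asarray(times, dtype=float)
    t = t[np.isfinite(t)]
    if t.size == 0:
        raise ValueError("circular_mean of empty input")
    ang = t * 2.0 * np.pi / TAU_H
    c, s = np.mean(np.cos(ang)), np.mean(np.sin(ang))
    if np.hypot(c, s) < 1e-9:
        return np.nan
    out = float(np.mod(np.arctan2(s, c) / (2.0 * np.pi) * TAU_H, TAU_H))
    return 0.0 if out >= TAU_H else out  # guard the mod-rounding edge at 24.0


def circular_difference(a, b):
    """Signed circular difference a - b on the 24-h clock, in (-12, 12]."""
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), TAU_H)
    d = np.where(d > 12.0, d - TAU_H, d)
    return d if d.ndim else float(d)
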