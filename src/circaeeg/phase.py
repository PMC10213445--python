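"""Estimation of subjective circadian time from hourly EEG spectra.

Environmental time (ZT, hours) is encoded as a point on the unit circle,
(x, y) = (cos(2 pi ZT/24), sin(2 pi ZT/24)), and two independent
single-output regressors are fitted -- one for x, one for y -- with the
hourly unit-sum-normalized spectral distributions as input.  An
estimated time is decoded with the two-argument arctangent,
atan2(y, x)/(2 pi) * 24, which is scale-free, so predictions need not
lie on the unit circle.  Model quality is summarized by the accuracy
statistic

    accuracy = mean over samples of cos(2 pi (estimated - ZT)/24),

which is 1 for perfect estimation, -1 for a constant 12-h (antiphase)
error and 0 for a constant 6-h error, evaluated by leave-one-mouse-out
cross-validation.  Five regressor families are available (linear, ridge,
k-nearest-neighbor, support-vector and random-forest regression, all at
their library defaults); the random forest additionally provides
impurity-based feature importances for the x (COS, morning/evening) and
y (SIN, day/night) models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR

from .rhythm import TAU_H, circular_mean
from .spectra import HourlyStageSpectra, N_FREQ, freq_grid, pooled_hourly_spectra
from .staging import STAGE_NAMES

__all__ = [
    "INPUT_MODES",
    "ALGORITHMS",
    "PhaseFeatures",
    "PhaseModel",
    "encode_time",
    "decode_time",
    "accuracy_statistic",
    "build_features",
    "fit_phase_model",
    "loo_evaluate",
    "cross_cohort_predict",
    "feature_importance",
]

INPUT_MODES = ("wake", "nrem", "rem", "pooled", "all_stages")
_STOCHASTIC = {"random_forest"}
_N_FEAT = N_FREQ - 1  # DC bin excluded: identically ~0 after mean removal


def _make_regressor(algorithm: str, seed: int):
    if algorithm == "linear":
        return LinearRegression()
    if algorithm == "ridge":
        return Ridge()
    if algorithm == "knn":
        return KNeighborsRegressor()
    if algorithm == "svm":
        return SVR()
    if algorithm == "random_forest":
        return RandomForestRegressor(random_state=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from "
                     "linear, ridge, knn, svm, random_forest")


ALGORITHMS = ("linear", "ridge", "knn", "svm", "random_forest")


def encode_time(zt) -> tuple:
    """Encode time-of-day (h) as a unit-circle point (x, y); 24-h periodic."""
    ang = 2.0 * np.pi * np.asarray(zt, dtype=float) / TAU_H
    x, y = np.cos(ang), np.sin(ang)
    if x.ndim == 0:
        return (float(x), float(y))
    return (x, y)


def decode_time(x, y):
    """Decode a planar point back to hours in [0, 24); NaN at the origin.

    Inputs need not lie on the unit circle: regressor outputs are
    unconstrained and the arctangent is scale-free.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t = np.mod(np.arctan2(y, x) / (2.0 * np.pi) * TAU_H, TAU_H)
    t = np.where(t >= TAU_H, 0.0, t)  # guard the mod-rounding edge at 24.0
    t = np.where((x == 0.0) & (y == 0.0), np.nan, t)
    return float(t) if t.ndim == 0 else t


def accuracy_statistic(estimated, actual) -> float:
    """Mean of cos(2 pi (estimated - actual)/24) over samples, in [-1, 1]."""
    est = np.asarray(estimated, dtype=float)
    act = np.asarray(actual, dtype=float)
    return float(np.mean(np.cos(2.0 * np.pi * (est - act) / TAU_H)))


@dataclass
class PhaseFeatures:
    """Feature matrix for phase regression.

    One row per (mouse, hour) sample.  Each constituent spectrum is
    unit-sum normalized over the 160 non-DC bins before (for the
    all-stages mode) concatenation.  ``imputed`` flags all-stages rows
    where a missing (hour, stage) cell was filled with that mouse's
    time-averaged normalized spectrum for the stage.
    """

    X: np.ndarray  # (n_samples, d)
    zt: np.ndarray  # (n_samples,) target time in [0, 24)
    mouse: np.ndarray  # (n_samples,) mouse identifiers
    mode: str
    feature_stage: np.ndarray  # (d,) stage name per column
    feature_freq: np.ndarray  # (d,) frequency (Hz) per column
    imputed: np.ndarray  # (n_samples,) bool

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


def _normalized_rows(power: np.ndarray) -> np.ndarray:
    """Unit-sum normalize rows of non-DC power; NaN rows stay NaN."""
    p = power[:, 1:]
    s = p.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return p / s


def build_features(
    cohort_spectra: Sequence[HourlyStageSpectra],
    mode: str,
    mouse_ids: Sequence | None = None,
) -> PhaseFeatures:
    """Assemble hourly feature vectors for a cohort.

    Target ZT of hour bin [h, h+1) is h mod 24.  For per-stage and
    pooled modes, hours lacking the requested spectrum are dropped; for
    the all-stages mode a missing constituent is imputed with the
    mouse's time-averaged normalized spectrum of that stage so sample
    counts stay comparable across modes without inventing rhythm.
    """
    if mode not in INPUT_MODES:
        raise ValueError(f"mode must be one of {INPUT_MODES}")
    if mouse_ids is None:
        mouse_ids = list(range(len(cohort_spectra)))
    freqs = freq_grid()[1:]
    rows, zts, mice, imputed = [], [], [], []
    for mid, hss in zip(mouse_ids, cohort_spectra):
        hours = np.arange(hss.n_hours)
        zt = hours % 24
        if mode == "pooled":
            feats = _normalized_rows(pooled_hourly_spectra(hss))
            stage_feats = [feats]
        elif mode == "all_stages":
            stage_feats = [_normalized_rows(hss.power[:, s, :]) for s in range(3)]
        else:
            s = ("wake", "nrem", "rem").index(mode)
            stage_feats = [_normalized_rows(hss.power[:, s, :])]
        if mode == "all_stages":
            filled = []
            row_imputed = np.zeros(hss.n_hours, dtype=bool)
            for sf in stage_feats:
                missing = np.isnan(sf[:, 0])
                if missing.any():
                    if missing.all():
                        raise ValueError(
                            "a stage is absent for the entire recording; "
                            "cannot build all-stages features"
                        )
                    fill = np.nanmean(sf, axis=0)
                    sf = sf.copy()
                    sf[missing] = fill
                    row_imputed |= missing
                filled.append(sf)
            mat = np.concatenate(filled, axis=1)
            keep = np.ones(hss.n_hours, dtype=bool)
        else:
            mat = np.concatenate(stage_feats, axis=1)
            keep = ~np.isnan(mat[:, 0])
            row_imputed = np.zeros(hss.n_hours, dtype=bool)
        rows.append(mat[keep])
        zts.append(zt[keep])
        mice.append(np.full(int(keep.sum()), mid, dtype=object))
        imputed.append(row_imputed[keep])
    if mode == "all_stages":
        feature_stage = np.repeat(list(STAGE_NAMES), _N_FEAT)
        feature_freq = np.tile(freqs, 3)
    elif mode == "pooled":
        feature_stage = np.array(["POOLED"] * _N_FEAT)
        feature_freq = freqs
    else:
        feature_stage = np.array([mode.upper()] * _N_FEAT)
        feature_freq = freqs
    return PhaseFeatures(
        X=np.concatenate(rows, axis=0),
        zt=np.concatenate(zts).astype(float),
        mouse=np.concatenate(mice),
        mode=mode,
        feature_stage=feature_stage,
        feature_freq=feature_freq,
        imputed=np.concatenate(imputed),
    )


@dataclass
class PhaseModel:
    """A fitted pair of regressors (x = COS model, y = SIN model)."""

    algorithm: str
    mode: str
    model_x: object
    model_y: object
    n_features: int
    seed: int

    def predict_xy(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimensionality {X.shape[1]} != {self.n_features} "
                f"(input mode mismatch?)"
            )
        return self.model_x.predict(X), self.model_y.predict(X)

    def predict_times(self, X: np.ndarray) -> np.ndarray:
        return decode_time(*self.predict_xy(X))


def fit_phase_model(
    features: PhaseFeatures, algorithm: str, seed: int = 0
) -> PhaseModel:
    """Fit the (x, y) regressor pair on all samples of ``features``."""
    if features.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x, y = encode_time(features.zt)
    mx = _make_regressor(algorithm, seed)
    my = _make_regressor(algorithm, seed)
    mx.fit(features.X, x)
    my.fit(features.X, y)
    return PhaseModel(
        algorithm=algorithm,
        mode=features.mode,
        model_x=mx,
        model_y=my,
        n_features=features.X.shape[1],
        seed=seed,
    )


def _subset(features: PhaseFeatures, keep: np.ndarray) -> PhaseFeatures:
    return PhaseFeatures(
        X=features.X[keep],
        zt=features.zt[keep],
        mouse=features.mouse[keep],
        mode=features.mode,
        feature_stage=features.feature_stage,
        feature_freq=features.feature_freq,
        imputed=features.imputed[keep],
    )


def loo_evaluate(
    features: PhaseFeatures, algorithm: str, n_trials: int = 5
) -> dict:
    """Leave-one-mouse-out accuracy of an algorithm on a cohort.

    Stochastic algorithms are refitted with seeds 0..n_trials-1 and the
    accuracies averaged; deterministic algorithms run a single trial.
    Returns a dict with the mean ``accuracy``, ``per_trial`` accuracies,
    and a tidy ``predictions`` frame from the first trial.
    """
    mice = pd.unique(features.mouse)
    if mice.size < 3:
        raise ValueError("leave-one-out evaluation requires >= 3 mice")
    trials = n_trials if algorithm in _STOCHASTIC else 1
    per_trial = []
    predictions = None
    for trial in range(trials):
        est_all, act_all, mouse_all = [], [], []
        for m in mice:
            test = features.mouse == m
            model = fit_phase_model(_subset(features, ~test), algorithm, seed=trial)
            est = model.predict_times(features.X[test])
            est_all.append(est)
            act_all.append(features.zt[test])
            mouse_all.append(features.mouse[test])
        est_all = np.concatenate(est_all)
        act_all = np.concatenate(act_all)
        per_trial.append(accuracy_statistic(est_all, act_all))
        if trial == 0:
            predictions = pd.DataFrame(
                {
                    "mouse": np.concatenate(mouse_all),
                    "zt": act_all,
                    "estimated_zt": est_all,
                }
            )
    return {
        "algorithm": algorithm,
        "mode": features.mode,
        "accuracy": float(np.mean(per_trial)),
        "per_trial": [float(a) for a in per_trial],
        "n_trials": trials,
        "predictions": predictions,
    }


def cross_cohort_predict(model: PhaseModel, features: PhaseFeatures) -> pd.DataFrame:
    """Predict per-hour subjective times of another cohort with a fitted model.

    Returns a tidy frame (mouse, zt, estimated_zt); per-timepoint
    circular means can be taken with :func:`per_timepoint_circular_mean`.
    """
    if features.X.shape[1] != model.n_features:
        raise ValueError("input mode / dimensionality mismatch between model and features")
    est = model.predict_times(features.X)
    return pd.DataFrame(
        {"mouse": features.mouse, "zt": features.zt, "estimated_zt": est}
    )


def per_timepoint_circular_mean(predictions: pd.DataFrame) -> pd.DataFrame:
    """Circular mean of estimated times at each ZT across mice."""
    rows = []
    for zt, grp in predictions.groupby("zt"):
        rows.append(
            {
                "zt": float(zt),
                "estimated_mean": circular_mean(grp["estimated_zt"].to_numpy()),
                "n": len(grp),
            }
        )
    return pd.DataFrame(rows).sort_values("zt").reset_index(drop=True)


def feature_importance(model: PhaseModel, features: PhaseFeatures) -> pd.DataFrame:
    """Impurity-based importances of a random-forest phase model.

    One row per feature with the COS-model (x) and SIN-model (y)
    importances; each column sums to 1.  Per-stage aggregates are the
    sums over each stage's columns.
    """
    if model.algorithm != "random_forest":
        raise ValueError("feature importance requires a random_forest model")
    return pd.DataFrame(
        {
            "stage": features.feature_stage,
            "freq_hz": features.feature_freq,
            "importance_cos": model.model_x.feature_importances_,
            "importance_sin": model.model_y.feature_importances_,
        }
    )


def stage_importance(importances: pd.DataFrame) -> pd.DataFrame:
    """Aggregate feature importances per sleep-wake stage."""
    return (
        importances.groupby("stage")[["importance_cos", "importance_sin"]]
        .sum()
        .reset_index()
    )
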