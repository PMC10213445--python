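"""End-to-end orchestration: simulate/load -> override -> spectra -> rhythm
-> group comparison -> phase estimation, with provenance.

The pipeline reproduces the full analysis workflow on synthetic cohorts
(or user-provided recordings processed with the same per-mouse steps):

1. per mouse: EMG amplitude, Otsu threshold, muscle-tone wake override,
   hourly stage amounts, per-epoch spectra, hourly stage-conditioned
   spectra, first-harmonic rhythm components, and cosinor fits of the
   hourly stage amounts;
2. cohort level: mean amplitude and circular-mean peak time per
   (stage, frequency);
3. group level (young vs. old): Welch t-tests on rhythm amplitudes and
   the Mardia-Watson-Wheeler test on peak times at configured focus
   frequencies;
4. phase estimation: leave-one-mouse-out accuracy on the young cohort
   and cross-cohort prediction of the old cohort with per-timepoint
   circular means and young-vs-old differences.

Every output directory receives the serialized configuration and root
seed so any artifact can be regenerated exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from . import phase, rhythm, spectra, staging, synthetic
from .staging import STAGE_NAMES

__all__ = ["RunConfig", "run_full_analysis", "process_mouse", "cohort_spectra"]

logger = logging.getLogger("circaeeg")


@dataclass
class RunConfig:
    """Configuration of a full synthetic-cohort analysis run."""

    out_dir: str = "circaeeg_run"
    seed: int = 0
    days: int = 3
    n_young: int = 5
    n_old: int = 5
    include_old: bool = True
    lighting: str = "LD"
    old_attenuation: float = 0.5
    old_delay_h: float = 2.0
    apply_override: bool = True
    input_mode: str = "all_stages"
    algorithm: str = "random_forest"
    n_trials: int = 5
    period_bounds: tuple = (20.0, 28.0)
    focus_freqs: dict = field(
        default_factory=lambda: {"NREM": 4.0, "REM": 7.0, "WAKE": 9.0}
    )
    mww_permutations: int = 9999
    make_figures: bool = False

    def __post_init__(self) -> None:
        self.period_bounds = tuple(self.period_bounds)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.input_mode not in phase.INPUT_MODES:
            raise ValueError(f"input_mode must be one of {phase.INPUT_MODES}")
        if self.algorithm not in phase.ALGORITHMS:
            raise ValueError(f"algorithm must be one of {phase.ALGORITHMS}")
        if self.n_young < 0 or self.n_old < 0 or self.days < 1:
            raise ValueError("cohort sizes must be >= 0 and days >= 1")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def process_mouse(rec, hyp, apply_override: bool = True) -> dict:
    """Run the per-mouse analysis chain on one recording.

    Returns a dict with the (possibly overridden) hypnogram, EMG
    amplitudes and threshold, hourly stage amounts, hourly stage
    spectra, and rhythm components.
    """
    amps = staging.emg_amplitude(rec)
    threshold = np.nan
    if apply_override:
        threshold = staging.otsu_threshold(amps)
        hyp = staging.apply_wake_override(hyp, amps, threshold)
    amounts = staging.hourly_stage_amounts(hyp)
    eps = spectra.epoch_spectra(rec)
    hss = spectra.hourly_stage_spectra(eps, hyp)
    rc = rhythm.rhythm_components(hss)
    return {
        "hypnogram": hyp,
        "emg_amplitudes": amps,
        "emg_threshold": threshold,
        "hourly_amounts": amounts,
        "hourly_spectra": hss,
        "rhythm": rc,
    }


def cohort_spectra(spec: synthetic.CohortSpec, apply_override: bool = True) -> list[dict]:
    """Generate a cohort and run the per-mouse chain, keeping only results.

    Signals are discarded mouse-by-mouse; each returned dict additionally
    carries the injected ``truth``.
    """
    out = []
    for m, (rec, hyp, truth) in enumerate(synthetic.iter_cohort(spec)):
        res = process_mouse(rec, hyp, apply_override=apply_override)
        res["truth"] = truth
        res["mouse"] = m
        out.append(res)
        logger.info("processed mouse %d/%d", m + 1, spec.n_mice)
    return out


def _cohort_rhythm_frame(results: list[dict], cohort: str) -> pd.DataFrame:
    frames = []
    for res in results:
        df = res["rhythm"].to_frame()
        df.insert(0, "mouse", res["mouse"])
        df.insert(0, "cohort", cohort)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _cohort_summary(rhythm_df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (cohort, stage, f), grp in rhythm_df.groupby(["cohort", "stage", "freq_hz"]):
        amp = grp["amplitude"].to_numpy()
        peaks = grp["peak_zt"].to_numpy()
        peaks = peaks[np.isfinite(peaks)]
        rows.append(
            {
                "cohort": cohort,
                "stage": stage,
                "freq_hz": f,
                "mean_amplitude": float(np.nanmean(amp)) if np.isfinite(amp).any() else np.nan,
                "circmean_peak_zt": rhythm.circular_mean(peaks) if peaks.size else np.nan,
                "n_mice": len(grp),
            }
        )
    return pd.DataFrame(rows)


def _group_comparisons(rhythm_df: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Young vs old amplitude t-tests and peak-time MWW at focus frequencies."""
    rows = []
    for stage, f in cfg.focus_freqs.items():
        sel = (rhythm_df["stage"] == stage) & (np.abs(rhythm_df["freq_hz"] - f) < 1e-9)
        young = rhythm_df[sel & (rhythm_df["cohort"] == "young")]
        old = rhythm_df[sel & (rhythm_df["cohort"] == "old")]
        if len(young) < 4 or len(old) < 4:
            continue
        t, p_t = scipy.stats.ttest_ind(
            young["amplitude"], old["amplitude"], equal_var=False
        )
        mww = rhythm.mww_test(
            young["peak_zt"].to_numpy(),
            old["peak_zt"].to_numpy(),
            n_permutations=cfg.mww_permutations,
            seed=cfg.seed,
        )
        rows.append(
            {
                "stage": stage,
                "freq_hz": f,
                "amp_ratio_old_young": float(
                    old["amplitude"].mean() / young["amplitude"].mean()
                ),
                "peak_delay_h": rhythm.circular_difference(
                    rhythm.circular_mean(old["peak_zt"].to_numpy()),
                    rhythm.circular_mean(young["peak_zt"].to_numpy()),
                ),
                "t_statistic": float(t),
                "p_ttest_amplitude": float(p_t),
                "mww_W": mww["W"],
                "mww_p_chisq": mww["p_chisq"],
                "mww_p_permutation": mww["p_permutation"],
            }
        )
    return pd.DataFrame(rows)


def _cosinor_frame(results: list[dict], cohort: str, cfg: RunConfig) -> pd.DataFrame:
    rows = []
    for res in results:
        amounts = res["hourly_amounts"]
        t = np.arange(amounts.n_hours, dtype=float)
        for s, name in enumerate(STAGE_NAMES):
            fit = rhythm.cosinor_fit(
                t, amounts.minutes[:, s], period_bounds=tuple(cfg.period_bounds)
            )
            rows.append(
                {
                    "cohort": cohort,
                    "mouse": res["mouse"],
                    "stage": name,
                    "mesor_min": fit.mesor,
                    "amplitude_min": fit.amplitude,
                    "acrophase_h": fit.acrophase,
                    "period_h": fit.period,
                    "rss": fit.rss,
                    "period_identifiable": fit.period_identifiable,
                }
            )
    return pd.DataFrame(rows)


def _amounts_frame(results: list[dict], cohort: str) -> pd.DataFrame:
    frames = []
    for res in results:
        df = res["hourly_amounts"].to_frame()
        df.insert(0, "mouse", res["mouse"])
        df.insert(0, "cohort", cohort)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _make_figures(out: Path, rhythm_summary: pd.DataFrame, estimates: pd.DataFrame | None):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for cohort, grp in rhythm_summary[rhythm_summary["stage"] == "NREM"].groupby("cohort"):
        axes[0].plot(grp["freq_hz"], grp["mean_amplitude"], label=cohort)
        axes[1].plot(grp["freq_hz"], grp["circmean_peak_zt"], ".", label=cohort)
    axes[0].set(xlabel="frequency (Hz)", ylabel="relative amplitude", title="NREM rhythm amplitude")
    axes[1].set(xlabel="frequency (Hz)", ylabel="peak time (ZT h)", title="NREM rhythm peak time")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(out / "rhythm_nrem.png", dpi=120)
    plt.close(fig)

    if estimates is not None and len(estimates):
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(estimates["zt"], estimates["estimated_zt"], "o", alpha=0.3)
        ax.set(xlabel="actual ZT (h)", ylabel="estimated ZT (h)", title="Phase estimation")
        fig.tight_layout()
        fig.savefig(out / "phase_estimates.png", dpi=120)
        plt.close(fig)


def run_full_analysis(cfg: RunConfig) -> dict:
    """Execute the whole pipeline per ``cfg`` and write the report bundle."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    logger.info("run_full_analysis -> %s", out)

    young = synthetic.young_spec(n_mice=cfg.n_young, seed=cfg.seed, days=cfg.days,
                                 lighting=cfg.lighting)
    cohorts = {"young": cohort_spectra(young, apply_override=cfg.apply_override)}
    if cfg.include_old and cfg.n_old > 0:
        old = synthetic.old_spec(
            n_mice=cfg.n_old,
            seed=cfg.seed + 1,
            days=cfg.days,
            lighting=cfg.lighting,
            attenuation=cfg.old_attenuation,
            delay_h=cfg.old_delay_h,
        )
        cohorts["old"] = cohort_spectra(old, apply_override=cfg.apply_override)

    rhythm_df = pd.concat(
        [_cohort_rhythm_frame(res, name) for name, res in cohorts.items()],
        ignore_index=True,
    )
    rhythm_df.to_csv(out / "rhythm_components.csv", index=False)
    summary = _cohort_summary(rhythm_df)
    summary.to_csv(out / "rhythm_summary.csv", index=False)

    amounts = pd.concat(
        [_amounts_frame(res, name) for name, res in cohorts.items()], ignore_index=True
    )
    amounts.to_csv(out / "hourly_amounts.csv", index=False)
    cosinor = pd.concat(
        [_cosinor_frame(res, name, cfg) for name, res in cohorts.items()],
        ignore_index=True,
    )
    cosinor.to_csv(out / "cosinor_fits.csv", index=False)

    comparisons = pd.DataFrame()
    if "old" in cohorts:
        comparisons = _group_comparisons(rhythm_df, cfg)
        comparisons.to_csv(out / "group_comparisons.csv", index=False)

    # ---- phase estimation -------------------------------------------------
    phase_report: dict = {}
    estimates = None
    young_feats = phase.build_features(
        [r["hourly_spectra"] for r in cohorts["young"]], cfg.input_mode
    )
    if cfg.n_young >= 3:
        loo = phase.loo_evaluate(young_feats, cfg.algorithm, n_trials=cfg.n_trials)
        estimates = loo.pop("predictions")
        estimates.insert(0, "cohort", "young")
        phase_report["young_loo"] = loo
    if "old" in cohorts:
        model = phase.fit_phase_model(young_feats, cfg.algorithm, seed=0)
        old_feats = phase.build_features(
            [r["hourly_spectra"] for r in cohorts["old"]], cfg.input_mode
        )
        old_pred = phase.cross_cohort_predict(model, old_feats)
        old_pred.insert(0, "cohort", "old")
        estimates = (
            pd.concat([estimates, old_pred], ignore_index=True)
            if estimates is not None
            else old_pred
        )
        per_zt = phase.per_timepoint_circular_mean(old_pred)
        lag = rhythm.circular_difference(
            per_zt["zt"].to_numpy() % 24.0, per_zt["estimated_mean"].to_numpy()
        )
        phase_report["old_phase_lag_by_zt"] = {
            "zt": [float(z) for z in per_zt["zt"]],
            "lag_h": [float(v) for v in np.atleast_1d(lag)],
        }
    if estimates is not None:
        estimates.to_csv(out / "phase_estimates.csv", index=False)
    with open(out / "phase_report.json", "w") as fh:
        json.dump(phase_report, fh, indent=2)

    if cfg.make_figures:
        _make_figures(out, summary, estimates)

    return {
        "out_dir": out,
        "cohorts": cohorts,
        "rhythm": rhythm_df,
        "rhythm_summary": summary,
        "hourly_amounts": amounts,
        "cosinor": cosinor,
        "comparisons": comparisons,
        "phase_report": phase_report,
        "estimates": estimates,
    }
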