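"""Synthetic mouse EEG/EMG cohorts with known circadian structure.

Every downstream stage of the pipeline is validated against recordings
whose circadian content is injected and therefore exactly known.  A
cohort is described by a :class:`CohortSpec`:

* per-stage hourly occupancy curves over ZT (a nocturnal profile by
  default: wakefulness peaks at ZT18, NREM and REM sleep in the light
  phase) realized as a time-inhomogeneous Markov chain over WAKE, NREM
  and REM with realistic mean bout durations;
* per-stage spectral templates on the analysis grid (0-16 Hz, 0.1 Hz):
  a delta-band bump for NREM, a theta peak near 7 Hz for REM, a broad
  ~9 Hz component for wakefulness on a 1/f background;
* a per-stage, per-frequency circadian modulation map (a, p): epoch
  power at frequency f and zeitgeber time t is the template multiplied
  by 1 + a cos(2 pi (t - p)/24);
* a bimodal EMG amplitude model (log10 scale): high muscle tone in
  wakefulness, low in sleep;
* an aging transform: a multiplicative attenuation of all modulation
  amplitudes and occupancy-rhythm deviations, and a common phase delay.

EEG epochs are synthesized by inverse FFT of the target one-sided
spectrum with independent uniform random phases per epoch, so the
analysis pipeline's power estimates recover the injected modulation with
tolerances limited only by stage sampling and within-hour averaging.
All randomness flows from a single root seed through per-mouse
``SeedSequence`` streams; identical specs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .recording import EpochedRecording
from .staging import Hypnogram, WAKE, NREM, REM
from .spectra import N_FREQ, freq_grid

__all__ = [
    "CohortSpec",
    "SyntheticTruth",
    "young_spec",
    "old_spec",
    "generate_hypnogram",
    "generate_epoch_signals",
    "generate_cohort",
    "iter_cohort",
]

# mean bout durations (s) used to derive Markov transition rates
_BOUT_S = {WAKE: 60.0, NREM: 100.0, REM: 30.0}


def _default_stage_profile() -> np.ndarray:
    """Hourly stage probabilities (3, 24): nocturnal wake, diurnal sleep."""
    h = np.arange(24.0)
    wake = 0.55 + 0.25 * np.cos(2 * np.pi * (h - 18.0) / 24.0)
    rem = 0.08 + 0.04 * np.cos(2 * np.pi * (h - 6.0) / 24.0)
    nrem = 1.0 - wake - rem
    return np.stack([wake, nrem, rem])


def _default_spectral_template() -> np.ndarray:
    """Per-stage mean power vs frequency (3, 161), arbitrary units."""
    f = freq_grid()
    background = 1.0 / (0.5 + f)
    wake = 0.6 * background + 1.2 * np.exp(-(((f - 9.0) / 2.0) ** 2))
    nrem = 1.0 * background + 3.0 * np.exp(-(((f - 2.5) / 1.5) ** 2))
    rem = 0.5 * background + 2.0 * np.exp(-(((f - 7.0) / 1.0) ** 2))
    return np.stack([wake, nrem, rem])


def _default_modulation() -> tuple[np.ndarray, np.ndarray]:
    """Default (amplitude, peak time) modulation maps (each (3, 161)).

    NREM delta power (maximal a = 0.3 at 4 Hz) peaks mid-dark (ZT18)
    while its lowest frequencies peak in the light phase; REM theta and
    WAKE ~9 Hz components peak mid-light (ZT6).
    """
    f = freq_grid()
    a = np.stack(
        [
            0.05 + 0.20 * np.exp(-(((f - 9.0) / 2.0) ** 2)),  # WAKE
            0.05 + 0.25 * np.exp(-(((f - 4.0) / 2.0) ** 2)),  # NREM
            0.05 + 0.20 * np.exp(-(((f - 7.0) / 1.5) ** 2)),  # REM
        ]
    )
    p = np.stack(
        [
            np.full_like(f, 6.0),
            18.0 - 12.0 * np.exp(-((f / 1.5) ** 2)),
            np.full_like(f, 6.0),
        ]
    )
    return a, p


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; see the module docstring."""

    n_mice: int
    seed: int
    days: int = 3
    epoch_s: float = 10.0
    fs: float = 128.0
    lighting: str = "LD"  # metadata only: the injected rhythms are clock-driven
    stage_profile: np.ndarray = field(default_factory=_default_stage_profile)
    spectral_template: np.ndarray = field(default_factory=_default_spectral_template)
    mod_amplitude: np.ndarray = field(default_factory=lambda: _default_modulation()[0])
    mod_peak: np.ndarray = field(default_factory=lambda: _default_modulation()[1])
    emg_log_mean: np.ndarray = field(
        default_factory=lambda: np.array([1.30, 0.50, 0.35])
    )
    emg_log_sd: np.ndarray = field(default_factory=lambda: np.array([0.15, 0.15, 0.15]))
    aging_attenuation: float = 1.0  # multiplies modulation and profile deviations
    aging_delay_h: float = 0.0  # added to all peak times / profile phases

    def __post_init__(self) -> None:
        for name in (
            "stage_profile",
            "spectral_template",
            "mod_amplitude",
            "mod_peak",
            "emg_log_mean",
            "emg_log_sd",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def validate(self) -> None:
        if self.n_mice < 0:
            raise ValueError("n_mice must be >= 0")
        if self.lighting not in ("LD", "DD"):
            raise ValueError("lighting must be 'LD' or 'DD'")
        if self.stage_profile.shape != (3, 24):
            raise ValueError("stage_profile must be (3, 24)")
        if np.any(self.stage_profile < 0):
            raise ValueError("stage probabilities must be >= 0")
        sums = self.stage_profile.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("hourly stage probabilities must sum to 1")
        if self.spectral_template.shape != (3, N_FREQ):
            raise ValueError(f"spectral_template must be (3, {N_FREQ})")
        if np.any(self.spectral_template <= 0):
            raise ValueError("spectral templates must be strictly positive")
        if self.mod_amplitude.shape != (3, N_FREQ) or self.mod_peak.shape != (3, N_FREQ):
            raise ValueError(f"modulation maps must be (3, {N_FREQ})")
        if np.any(self.mod_amplitude < 0) or np.any(self.mod_amplitude >= 1):
            raise ValueError("modulation amplitudes must lie in [0, 1) to keep power positive")
        if not 0 < self.aging_attenuation <= 1:
            raise ValueError("aging_attenuation must be in (0, 1]")

    # ---- effective (post-aging) parameters -------------------------------

    def effective_modulation(self) -> tuple[np.ndarray, np.ndarray]:
        a = self.mod_amplitude * self.aging_attenuation
        p = np.mod(self.mod_peak + self.aging_delay_h, 24.0)
        return a, p

    def effective_stage_profile(self) -> np.ndarray:
        """Stage profile with rhythm deviations attenuated and delayed.

        Each stage's deviation from its daily mean is scaled by the
        attenuation factor and circularly shifted by the delay; the
        per-hour probabilities still sum to 1 because the same transform
        is applied to every stage.
        """
        prof = self.stage_profile
        if self.aging_attenuation == 1.0 and self.aging_delay_h == 0.0:
            return prof
        h = np.arange(24.0)
        src = np.mod(h - self.aging_delay_h, 24.0)
        shifted = np.stack(
            [np.interp(src, h, prof[s], period=24.0) for s in range(3)]
        )
        mean = prof.mean(axis=1, keepdims=True)
        out = mean + self.aging_attenuation * (shifted - mean)
        return np.clip(out, 0.0, None) / np.clip(out, 0.0, None).sum(axis=0)

    def epochs_per_hour(self) -> int:
        eph = 3600.0 / self.epoch_s
        if abs(eph - round(eph)) > 1e-9:
            raise ValueError("epoch_s must divide 3600 s")
        return int(round(eph))

    @property
    def n_epochs(self) -> int:
        return self.days * 24 * self.epochs_per_hour()


@dataclass
class SyntheticTruth:
    """Injected ground truth aligned to one generated mouse."""

    mod_amplitude: np.ndarray  # (3, N_FREQ) effective a
    mod_peak: np.ndarray  # (3, N_FREQ) effective p (h)
    stage_profile: np.ndarray  # (3, 24) effective hourly probabilities
    stages: np.ndarray  # (n_epochs,) true stage codes


def young_spec(n_mice: int = 10, seed: int = 0, **kwargs) -> CohortSpec:
    """Default young-adult cohort: full-amplitude, undelayed rhythms."""
    return CohortSpec(n_mice=n_mice, seed=seed, **kwargs)


def old_spec(
    n_mice: int = 10,
    seed: int = 1,
    attenuation: float = 0.5,
    delay_h: float = 2.0,
    **kwargs,
) -> CohortSpec:
    """Aged cohort: rhythm amplitudes halved and peaks delayed by 2 h."""
    return CohortSpec(
        n_mice=n_mice,
        seed=seed,
        aging_attenuation=attenuation,
        aging_delay_h=delay_h,
        **kwargs,
    )


def _mouse_rng(spec: CohortSpec, mouse_index: int, stream: int) -> np.random.Generator:
    """Independent, reproducible stream per (seed, mouse, purpose)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), int(mouse_index), int(stream)])
    )


def _transition_matrix(pi: np.ndarray, exit_p: np.ndarray) -> np.ndarray:
    """Markov transition matrix with stationary distribution ``pi``.

    Built from detailed-balance fluxes F_ij = F_ji solving the per-state
    outflow targets pi_i * exit_p_i; negative solutions (flux routes the
    occupancies cannot support) are clamped to zero, which slightly
    lengthens the affected bouts while preserving stationarity exactly.
    """
    b = pi * exit_p
    F = np.zeros((3, 3))
    pairs = [(0, 1, 2), (0, 2, 1), (1, 2, 0)]
    for i, j, k in pairs:
        if pi[i] > 0 and pi[j] > 0:
            F[i, j] = F[j, i] = max(0.0, (b[i] + b[j] - b[k]) / 2.0)
    P = np.zeros((3, 3))
    for i in range(3):
        if pi[i] <= 0:
            P[i] = pi / pi.sum() if pi.sum() > 0 else np.eye(3)[i]
            continue
        row = F[i] / pi[i]
        total = row.sum()
        if total > 1.0:  # pathological profile: rescale fluxes to keep a valid row
            row = row / total
            total = 1.0
        P[i] = row
        P[i, i] = 1.0 - total
    return P


def generate_hypnogram(spec: CohortSpec, mouse_index: int) -> Hypnogram:
    """Simulate one mouse's hypnogram from the ZT-dependent Markov chain.

    The chain's stationary occupancy within each ZT hour equals the
    (post-aging) stage profile; mixing is fast relative to an hour, so
    empirical hourly occupancies match the profile within sampling error.
    """
    profile = spec.effective_stage_profile()  # (3, 24)
    exit_p = np.array([spec.epoch_s / _BOUT_S[s] for s in (WAKE, NREM, REM)])
    exit_p = np.clip(exit_p, 0.0, 1.0)
    cum = np.empty((24, 3, 3))
    for h in range(24):
        cum[h] = np.cumsum(_transition_matrix(profile[:, h], exit_p), axis=1)
    rng = _mouse_rng(spec, mouse_index, 0)
    eph = spec.epochs_per_hour()
    n = spec.n_epochs
    stages = np.empty(n, dtype=np.int8)
    u = rng.random(n)
    state = int(np.searchsorted(np.cumsum(profile[:, 0]), u[0]))
    state = min(state, 2)
    stages[0] = state
    for k in range(1, n):
        zt_hour = (k // eph) % 24
        state = int(np.searchsorted(cum[zt_hour, state], u[k], side="right"))
        state = min(state, 2)
        stages[k] = state
    return Hypnogram(stages=stages, epoch_s=spec.epoch_s, zt0_offset=0.0)


def generate_epoch_signals(
    spec: CohortSpec, hypnogram: Hypnogram, mouse_index: int
) -> EpochedRecording:
    """Synthesize per-epoch EEG/EMG signals for one mouse.

    EEG: each epoch's one-sided spectrum is the stage template modulated
    at the epoch's ZT, realized with independent uniform random phases
    and inverse-FFT'd; the DC bin is zero (epochs are mean-free).  EMG:
    white noise whose standard deviation is drawn from the stage's
    log-normal amplitude model.
    """
    if hypnogram.n_epochs != spec.n_epochs:
        raise ValueError("hypnogram length inconsistent with spec")
    a_map, p_map = spec.effective_modulation()
    n_samp = int(round(spec.fs * spec.epoch_s))
    n_rfft = n_samp // 2 + 1
    rng = _mouse_rng(spec, mouse_index, 1)
    eph = spec.epochs_per_hour()
    eeg = np.empty((spec.n_epochs, n_samp), dtype=np.float32)
    emg = np.empty((spec.n_epochs, n_samp), dtype=np.float32)
    zt = hypnogram.zt()
    stages = hypnogram.stages
    for start in range(0, spec.n_epochs, eph):  # one hour per chunk
        idx = np.arange(start, min(start + eph, spec.n_epochs))
        s = stages[idx]
        t = zt[idx][:, None]  # (m, 1)
        power = spec.spectral_template[s] * (
            1.0 + a_map[s] * np.cos(2.0 * np.pi * (t - p_map[s]) / 24.0)
        )  # (m, N_FREQ)
        amp = np.sqrt(n_samp * power / 2.0)
        amp[:, 0] = 0.0  # mean-free epochs
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(idx.size, N_FREQ))
        coef = np.zeros((idx.size, n_rfft), dtype=complex)
        coef[:, :N_FREQ] = amp * np.exp(1j * phases)
        eeg[idx] = np.fft.irfft(coef, n=n_samp, axis=1).astype(np.float32)
        log_amp = rng.normal(spec.emg_log_mean[s], spec.emg_log_sd[s])
        emg[idx] = (
            rng.standard_normal((idx.size, n_samp)) * 10.0 ** log_amp[:, None]
        ).astype(np.float32)
    return EpochedRecording(eeg=eeg, emg=emg, fs=spec.fs, epoch_s=spec.epoch_s)


def _truth(spec: CohortSpec, hyp: Hypnogram) -> SyntheticTruth:
    a, p = spec.effective_modulation()
    return SyntheticTruth(
        mod_amplitude=a,
        mod_peak=p,
        stage_profile=spec.effective_stage_profile(),
        stages=hyp.stages.copy(),
    )


def generate_mouse(
    spec: CohortSpec, mouse_index: int
) -> tuple[EpochedRecording, Hypnogram, SyntheticTruth]:
    """Generate one mouse of the cohort (hypnogram, signals, truth)."""
    hyp = generate_hypnogram(spec, mouse_index)
    rec = generate_epoch_signals(spec, hyp, mouse_index)
    return rec, hyp, _truth(spec, hyp)


def iter_cohort(
    spec: CohortSpec,
) -> Iterator[tuple[EpochedRecording, Hypnogram, SyntheticTruth]]:
    """Lazily generate the cohort mouse by mouse (memory-friendly)."""
    for m in range(spec.n_mice):
        yield generate_mouse(spec, m)


def generate_cohort(
    spec: CohortSpec,
) -> list[tuple[EpochedRecording, Hypnogram, SyntheticTruth]]:
    """Generate all mice of the cohort as a list."""
    return list(iter_cohort(spec))
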