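"""Shared synthetic cohorts, generated once per session.

All fixtures return per-mouse result dicts from the full per-mouse
analysis chain (EMG override -> spectra -> rhythm components) plus the
injected ground truth, so module tests and end-to-end recovery tests
reuse the same generated data.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from circaeeg import phase, pipeline, synthetic

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

F4 = int(round(4.0 / 0.1))  # 4.0 Hz bin index on the analysis grid


@pytest.fixture(scope="session")
def young_results():
    """Default young cohort, 10 mice x 3 days, fully processed."""
    spec = synthetic.young_spec(n_mice=10, seed=0)
    return pipeline.cohort_spectra(spec)


@pytest.fixture(scope="session")
def young_feats(young_results):
    return phase.build_features(
        [r["hourly_spectra"] for r in young_results], "all_stages"
    )


@pytest.fixture(scope="session")
def old_results():
    """Aged cohort (amplitudes halved, peaks delayed 2 h), 5 mice."""
    spec = synthetic.old_spec(n_mice=5, seed=1)
    return pipeline.cohort_spectra(spec)


@pytest.fixture(scope="session")
def nomod_results():
    """Cohort with every circadian modulation amplitude set to zero.

    Processed on the truth-labeled hypnograms (no EMG override): override
    misclassification mixes a ZT-dependent trace of sleep spectra into the
    WAKE cells via the occupancy rhythm, which would contaminate this
    spectral null condition.
    """
    spec = synthetic.young_spec(
        n_mice=10, seed=2, mod_amplitude=np.zeros((3, 161))
    )
    return pipeline.cohort_spectra(spec, apply_override=False)


@pytest.fixture(scope="session")
def delayed_results():
    """Cohort with a pure 2-h phase delay (no amplitude attenuation)."""
    spec = synthetic.old_spec(n_mice=5, seed=3, attenuation=1.0, delay_h=2.0)
    return pipeline.cohort_spectra(spec)


@pytest.fixture(scope="session")
def singlebin_results():
    """Cohort whose only circadian modulation is NREM 4.0 Hz (a=0.3, p=18)."""
    a = np.zeros((3, 161))
    p = np.zeros((3, 161))
    a[1, F4] = 0.3
    p[1, F4] = 18.0
    spec = synthetic.young_spec(n_mice=4, seed=5, mod_amplitude=a, mod_peak=p)
    return pipeline.cohort_spectra(spec)
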