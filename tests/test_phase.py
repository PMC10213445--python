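"""Circular time encoding/decoding and phase-estimation models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from circaeeg import phase
from circaeeg.phase import (
    PhaseFeatures,
    accuracy_statistic,
    build_features,
    cross_cohort_predict,
    decode_time,
    encode_time,
    feature_importance,
    fit_phase_model,
    loo_evaluate,
    per_timepoint_circular_mean,
    stage_importance,
)
from circaeeg.rhythm import circular_difference

F4 = int(round(4.0 / 0.1))


class TestEncodeDecode:
    @pytest.mark.parametrize("zt,xy", [(0, (1, 0)), (6, (0, 1)), (18, (0, -1))])
    def test_cardinal_points(self, zt, xy):
        x, y = encode_time(zt)
        assert x == pytest.approx(xy[0], abs=1e-12)
        assert y == pytest.approx(xy[1], abs=1e-12)

    @pytest.mark.parametrize(
        "x,y,t", [(1, 0, 0.0), (0, -1, 18.0), (-0.2, -0.2, 15.0)]
    )
    def test_decode(self, x, y, t):
        assert decode_time(x, y) == pytest.approx(t, abs=1e-9)

    def test_origin_decodes_missing(self):
        assert np.isnan(decode_time(0.0, 0.0))

    @given(t=st.floats(0, 24, exclude_max=True))
    def test_roundtrip(self, t):
        assert abs(circular_difference(decode_time(*encode_time(t)), t)) < 1e-9

    @given(t=st.floats(-100, 100, allow_nan=False))
    def test_periodic_in_24(self, t):
        a = encode_time(t)
        b = encode_time(t + 24.0)
        assert a[0] == pytest.approx(b[0], abs=1e-9)
        assert a[1] == pytest.approx(b[1], abs=1e-9)


class TestAccuracyStatistic:
    def test_perfect_and_antiphase_anchors(self):
        zt = np.arange(24.0)
        assert accuracy_statistic(zt, zt) == pytest.approx(1.0, abs=1e-12)
        assert accuracy_statistic((zt + 12) % 24, zt) == pytest.approx(-1.0, abs=1e-12)

    def test_constant_6h_error_is_zero(self):
        zt = np.arange(24.0)
        assert accuracy_statistic((zt + 6) % 24, zt) == pytest.approx(0.0, abs=1e-12)

    @given(k=st.integers(-3, 3))
    def test_invariant_to_24h_offsets(self, k):
        zt = np.arange(24.0)
        est = (zt + 3) % 24
        assert accuracy_statistic(est + 24 * k, zt) == pytest.approx(
            accuracy_statistic(est, zt), abs=1e-12
        )


def _linear_features(n_mice=3, seed=0):
    """Features that are an invertible linear map of the circle encoding."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(2, 6)) + np.eye(2, 6)
    zt = np.tile(np.arange(24.0), n_mice)
    x, y = encode_time(zt)
    X = np.stack([x, y], axis=1) @ A
    return PhaseFeatures(
        X=X,
        zt=zt,
        mouse=np.repeat(np.arange(n_mice), 24),
        mode="pooled",
        feature_stage=np.array(["POOLED"] * 6),
        feature_freq=np.arange(6, dtype=float),
        imputed=np.zeros(zt.size, dtype=bool),
    )


class TestModels:
    def test_linear_recovers_linear_map(self):
        feats = _linear_features()
        model = fit_phase_model(feats, "linear")
        est = model.predict_times(feats.X)
        assert accuracy_statistic(est, feats.zt) > 0.999

    def test_same_seed_identical_predictions(self, young_feats):
        m1 = fit_phase_model(young_feats, "random_forest", seed=3)
        m2 = fit_phase_model(young_feats, "random_forest", seed=3)
        x1, y1 = m1.predict_xy(young_feats.X[:50])
        x2, y2 = m2.predict_xy(young_feats.X[:50])
        assert np.array_equal(x1, x2) and np.array_equal(y1, y2)

    def test_unknown_algorithm(self):
        with pytest.raises(ValueError):
            fit_phase_model(_linear_features(), "deep_net")

    def test_knn_loo_on_smooth_injective_mapping(self, young_feats):
        """A smooth injective spectrum-vs-time mapping: k-NN decodes time."""
        rep = loo_evaluate(young_feats, "knn")
        assert rep["accuracy"] >= 0.95

    def test_train_equals_test_bounds_loo(self, young_feats):
        rep = loo_evaluate(young_feats, "knn")
        model = fit_phase_model(young_feats, "knn")
        est = model.predict_times(young_feats.X)
        assert accuracy_statistic(est, young_feats.zt) >= rep["accuracy"] - 1e-9

    def test_loo_requires_three_mice(self):
        feats = _linear_features(n_mice=2)
        with pytest.raises(ValueError):
            loo_evaluate(feats, "linear")


class TestBuildFeatures:
    def test_modes_and_dimensionality(self, young_results):
        cohort = [r["hourly_spectra"] for r in young_results[:2]]
        for mode, d in [
            ("nrem", 160),
            ("rem", 160),
            ("wake", 160),
            ("pooled", 160),
            ("all_stages", 480),
        ]:
            feats = build_features(cohort, mode)
            assert feats.X.shape[1] == d
            # every constituent spectrum is unit-sum
            for j in range(d // 160):
                block = feats.X[:, 160 * j : 160 * (j + 1)]
                assert np.allclose(block.sum(axis=1), 1.0, atol=1e-9)

    def test_per_stage_mode_drops_missing_hours(self, young_results):
        hss = young_results[0]["hourly_spectra"]
        n_missing = int(hss.mask[:, 2].sum())  # REM
        feats = build_features([hss], "rem")
        assert feats.n_samples == hss.n_hours - n_missing

    def test_mode_mismatch_rejected(self, young_results):
        cohort = [r["hourly_spectra"] for r in young_results[:3]]
        model = fit_phase_model(build_features(cohort, "nrem"), "linear")
        with pytest.raises(ValueError):
            cross_cohort_predict(model, build_features(cohort, "all_stages"))


class TestFeatureImportance:
    def test_importances_normalized_and_localized(self, singlebin_results):
        """Modulation only at 4 Hz NREM: the forest ranks that bin first."""
        feats = build_features(
            [r["hourly_spectra"] for r in singlebin_results], "all_stages"
        )
        hits = 0
        for seed in range(5):
            model = fit_phase_model(feats, "random_forest", seed=seed)
            imp = feature_importance(model, feats)
            assert imp["importance_cos"].sum() == pytest.approx(1.0, abs=1e-9)
            assert imp["importance_sin"].sum() == pytest.approx(1.0, abs=1e-9)
            top = imp.loc[(imp["importance_cos"] + imp["importance_sin"]).idxmax()]
            if top["stage"] == "NREM" and abs(top["freq_hz"] - 4.0) <= 0.3:
                hits += 1
        assert hits >= 4
        agg = stage_importance(feature_importance(model, feats))
        assert set(agg["stage"]) == {"WAKE", "NREM", "REM"}

    def test_permuting_uninformative_feature_is_harmless(self, singlebin_results):
        feats = build_features(
            [r["hourly_spectra"] for r in singlebin_results], "all_stages"
        )
        model = fit_phase_model(feats, "random_forest", seed=0)
        imp = feature_importance(model, feats)
        j = int((imp["importance_cos"] + imp["importance_sin"]).idxmin())
        base = accuracy_statistic(model.predict_times(feats.X), feats.zt)
        rng = np.random.default_rng(0)
        Xp = feats.X.copy()
        Xp[:, j] = rng.permutation(Xp[:, j])
        perm = accuracy_statistic(model.predict_times(Xp), feats.zt)
        assert abs(perm - base) < 0.01

    def test_requires_forest(self, young_feats):
        model = fit_phase_model(young_feats, "linear")
        with pytest.raises(ValueError):
            feature_importance(model, young_feats)


class TestCrossCohort:
    def test_per_timepoint_circular_mean(self):
        pred = pd.DataFrame(
            {"mouse": [0, 1, 0, 1], "zt": [0.0, 0.0, 6.0, 6.0],
             "estimated_zt": [23.0, 1.0, 5.0, 7.0]}
        )
        per = per_timepoint_circular_mean(pred)
        assert per.loc[per["zt"] == 0.0, "estimated_mean"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert per.loc[per["zt"] == 6.0, "estimated_mean"].iloc[0] == pytest.approx(6.0, abs=1e-9)
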