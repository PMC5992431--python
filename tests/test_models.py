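"""Feature sets, GLM fitting, committees, traces, feature consistency."""

import numpy as np
import pytest

import mindmetrics as mm
from mindmetrics.eeg_features import FeatureWindow
from mindmetrics.models import (FEATURE_SETS, CommitteeModel, ElectrodeModel,
                                assemble_design, feature_consistency, fit_glm,
                                predict_trace, train_committee)

BANDS = ("delta", "theta", "alpha", "beta", "gamma", "high_gamma")


def _window(powers, label, cardiac=None, channels=("Fz", "Cz"), start=0.0):
    powers = np.asarray(powers, float)
    return FeatureWindow(start=start, end=start + 10.0, powers=powers,
                         label=label, channel_names=tuple(channels),
                         band_names=BANDS, cardiac=cardiac)


def _labeled_windows(n_per_class=20, seed=0, shift=1.0, with_cardiac=False):
    rng = np.random.default_rng(seed)
    ws = []
    for i in range(2 * n_per_class):
        label = "low" if i < n_per_class else "high"
        mu = 10.0 if label == "low" else 10.0 * shift
        powers = mu * rng.lognormal(0, 0.2, size=(2, 6))
        cardiac = rng.lognormal(0, 0.2, size=3) if with_cardiac else None
        ws.append(_window(powers, label, cardiac, start=10.0 * i))
    return ws


class TestFeatureSetDefinitions:
    def test_band_compositions(self):
        assert FEATURE_SETS["Pf1"].eeg_bands == ("theta", "alpha")
        assert FEATURE_SETS["Pf2"].eeg_bands == BANDS
        assert FEATURE_SETS["Ps3"].eeg_bands == BANDS
        assert FEATURE_SETS["Pa1"].ratio == ("theta", "beta")
        assert FEATURE_SETS["Pa3"].eeg_bands == ("delta", "theta",
                                                 "alpha", "beta")
        for fsid in ("Ps1", "Ps2"):
            assert FEATURE_SETS[fsid].source == "ECG_only"
        assert FEATURE_SETS["Ps4"].source == "EEG_plus_ECG"

    def test_window_lengths(self):
        for fsid, spec in FEATURE_SETS.items():
            expected = 6.0 if spec.biometric == "attention" else 10.0
            assert spec.window == expected


class TestAssembleDesign:
    def test_pa1_ratio_value(self):
        powers = np.zeros((2, 6))
        powers[:, BANDS.index("theta")] = 4.0
        powers[:, BANDS.index("beta")] = 2.0
        ws = [_window(powers, "low"), _window(powers, "high", start=10)]
        X, y = assemble_design(ws, FEATURE_SETS["Pa1"], "Fz",
                               transform="raw")
        assert X.shape == (2, 1)
        assert X[0, 0] == pytest.approx(2.0)

    def test_ps4_has_nine_columns(self):
        ws = _labeled_windows(5, with_cardiac=True)
        X, y = assemble_design(ws, FEATURE_SETS["Ps4"], "Fz")
        assert X.shape[1] == 9

    def test_zero_beta_guarded(self):
        powers = np.zeros((2, 6))
        powers[:, BANDS.index("theta")] = 4.0
        ws = [_window(powers, "low"), _window(powers, "high", start=10)]
        X, _ = assemble_design(ws, FEATURE_SETS["Pa1"], "Fz",
                               transform="raw")
        assert np.all(np.isfinite(X))

    def test_missing_cardiac_rows_dropped(self):
        ws = _labeled_windows(5, with_cardiac=True)
        ws[0].cardiac = None
        X, y = assemble_design(ws, FEATURE_SETS["Ps2"])
        assert X.shape[0] == 9

    def test_single_class_rejected(self):
        ws = [_window(np.ones((2, 6)), "low")] * 4
        with pytest.raises(ValueError):
            assemble_design(ws, FEATURE_SETS["Pf2"], "Fz")


class TestFitGlm:
    def test_all_zero_feature_gives_half(self):
        X = np.zeros((100, 1))
        y = np.array([0.0, 1.0] * 50)
        m = fit_glm(X, y)
        assert abs(m.coef[0]) < 1e-6
        assert m.predict(np.zeros((1, 1)))[0] == pytest.approx(0.5,
                                                               abs=1e-6)

    def test_slope_recovery_matches_grid_search_mle(self):
        """Oracle: grid search over b1 in [0, 4] step 0.01 (b0 fixed 0)."""
        rng = np.random.default_rng(0)
        n = 5000
        x = rng.standard_normal(n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-2 * x))).astype(float)

        grid = np.arange(0.0, 4.0, 0.01)
        ll = [np.sum(y * (b * x) - np.log1p(np.exp(b * x))) for b in grid]
        b_oracle = grid[int(np.argmax(ll))]

        m = fit_glm(x[:, None], y, standardize=False)
        assert abs(m.coef[1] - b_oracle) <= 0.15

    def test_separable_data_finite_and_monotone(self):
        X = np.linspace(-1, 1, 50)[:, None]
        y = (X[:, 0] > 0).astype(float)
        m = fit_glm(X, y)
        assert np.all(np.isfinite(m.coef))
        scores = m.predict(X)
        assert np.all(np.diff(scores) >= -1e-12)

    def test_matches_statsmodels_mle(self):
        """Independent cross-check against the reference GLM fitter."""
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        X = rng.standard_normal((400, 3))
        eta = 0.3 + X @ np.array([0.8, -0.5, 0.2])
        y = (rng.uniform(size=400) < 1 / (1 + np.exp(-eta))).astype(float)
        m = fit_glm(X, y, ridge=0.0, standardize=False)
        ref = sm.GLM(y, sm.add_constant(X),
                     family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(m.coef, ref.params, atol=1e-6)
        np.testing.assert_allclose(m.pvalues, ref.pvalues, atol=1e-5)

    def test_more_features_than_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_glm(np.zeros((3, 5)), np.array([0, 1, 0.0]))


class TestCommittee:
    def test_one_member_per_electrode(self):
        ws = _labeled_windows(15)
        c = train_committee(ws, FEATURE_SETS["Pf2"])
        assert [m.channel for m in c.members] == ["Fz", "Cz"]

    def test_ecg_only_single_member(self):
        ws = _labeled_windows(15, with_cardiac=True, shift=1.5)
        c = train_committee(ws, FEATURE_SETS["Ps2"])
        assert len(c.members) == 1

    def test_mean_aggregation_rule(self):
        spec = FEATURE_SETS["Pf2"]
        members = []
        for ch, b0 in (("Fz", np.log(0.2 / 0.8)), ("Cz", np.log(0.4 / 0.6)),
                       ("Pz", np.log(0.9 / 0.1))):
            members.append(ElectrodeModel(
                channel=ch, coef=np.concatenate([[b0], np.zeros(6)]),
                feature_mean=np.zeros(6), feature_sd=np.ones(6)))
        c = CommitteeModel(spec=spec, members=members)
        w = _window(np.ones((3, 6)), "unlabeled",
                    channels=("Fz", "Cz", "Pz"))
        assert c.predict_window(w) == pytest.approx((0.2 + 0.4 + 0.9) / 3,
                                                    abs=1e-9)

    def test_prediction_invariant_to_electrode_order(self, fatigue_windows):
        c = train_committee(fatigue_windows, FEATURE_SETS["Pf2"])
        w = fatigue_windows[0]
        v1 = c.predict_window(w)
        c.members = c.members[::-1]
        assert c.predict_window(w) == pytest.approx(v1, abs=1e-12)

    def test_trace_tracks_fatigue_ramp(self, fatigue_recordings,
                                       fatigue_windows):
        """Parameter recovery: committee trace follows the latent ramp."""
        c = train_committee(fatigue_windows, FEATURE_SETS["Pf2"])
        rec = fatigue_recordings["nback3"]
        trace = predict_trace(c, rec)
        lat = rec.meta["latents"].at(trace.times)["fatigue"]
        r = np.corrcoef(trace.values, lat)[0, 1]
        assert r >= 0.8
        assert np.all((trace.values >= 0) & (trace.values <= 1))
        assert np.allclose(np.diff(trace.times), 1.0)


class TestFeatureConsistency:
    def _cohort(self, effect=2.0, n_subjects=6, seed=0):
        cohort = []
        rng = np.random.default_rng(seed)
        for s in range(n_subjects):
            models = {}
            for ch in ("Fz", "F3"):
                n = 120
                X = rng.standard_normal((n, 6))
                eta = effect * X[:, 4]          # gamma column drives labels
                y = (rng.uniform(size=n)
                     < 1 / (1 + np.exp(-eta))).astype(float)
                models[ch] = fit_glm(X, y, channel=ch)
            cohort.append(models)
        return cohort

    def test_constructive_gamma_effect_detected(self):
        rows = feature_consistency(self._cohort(), BANDS)
        got = {(r["channel"], r["band"], r["direction"]) for r in rows}
        assert ("Fz", "gamma", "+") in got
        assert ("F3", "gamma", "+") in got

    def test_null_cohort_emits_few_rows(self):
        """Type-I error oracle: expected rows <= alpha * tests + CI."""
        rows = feature_consistency(self._cohort(effect=0.0, n_subjects=8,
                                                seed=3), BANDS)
        # 2 channels x 6 bands = 12 combinations; >50% of 8 subjects
        # jointly significant at 0.05 is vanishingly rare under the null
        assert len(rows) <= 1

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            feature_consistency(self._cohort(n_subjects=1), BANDS)
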