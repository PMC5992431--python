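"""Artifact-removal pipeline: filters, rejection, IC loop, interpolation."""

import numpy as np
import pytest

import mindmetrics as mm
from mindmetrics.preprocessing import (ICDecomposition, apply_ic_rejection,
                                       basic_filters, decompose,
                                       default_quality_index,
                                       interpolate_and_detrend,
                                       iterative_ic_rejection,
                                       rank_noise_components, reject_channels)

FS = 500.0


def _rec(data, names=None, roles=None, fs=FS):
    n = data.shape[0]
    names = names or [f"ch{i}" for i in range(n)]
    roles = roles or ["EEG"] * n
    return mm.Recording(np.asarray(data, float), fs, names, roles)


class TestBasicFilters:
    def test_line_tone_attenuated_30db(self):
        t = np.arange(0, 20, 1 / FS)
        x = np.sin(2 * np.pi * 60 * t)
        rec = _rec(np.vstack([x, np.zeros_like(x)]), ["ECG", "EOG1"],
                   ["ECG", "EOG"])
        out = basic_filters(rec)
        assert np.sqrt(np.mean(out.data[0] ** 2)) <= 0.032 * np.sqrt(0.5)

    def test_dc_offset_removed(self):
        rec = _rec(np.full((4, 5000), 5.0), ["C3", "C4", "Cz", "Pz"])
        out = basic_filters(rec)
        assert np.abs(out.data.mean(axis=1)).max() < 1e-6

    def test_average_reference_symmetry(self):
        t = np.arange(0, 10, 1 / FS)
        x = np.sin(2 * np.pi * 10 * t)
        rec = _rec(np.vstack([x, -x]), ["C3", "C4"])
        out = basic_filters(rec)
        np.testing.assert_allclose(out.data[0], x, atol=1e-9)
        np.testing.assert_allclose(out.data[1], -x, atol=1e-9)

    def test_low_fs_rejected(self):
        rec = _rec(np.zeros((2, 500)), ["C3", "C4"], fs=100.0)
        with pytest.raises(ValueError):
            basic_filters(rec)

    def test_ecg_not_in_eeg_reference(self):
        t = np.arange(0, 10, 1 / FS)
        big = 100 * np.sin(2 * np.pi * 5 * t)
        x = np.sin(2 * np.pi * 10 * t)
        rec = _rec(np.vstack([x, -x, big]), ["C3", "C4", "ECG"],
                   ["EEG", "EEG", "ECG"])
        out = basic_filters(rec)
        np.testing.assert_allclose(out.data[0], x, atol=1e-9)


class TestRejectChannels:
    def test_single_planted_outlier(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((30, 10000))
        data[7] *= np.sqrt(20)
        _, bad = reject_channels(_rec(data))
        assert bad == ["ch7"]

    def test_identical_channels_none_rejected(self):
        x = np.random.default_rng(0).standard_normal(5000)
        _, bad = reject_channels(_rec(np.tile(x, (6, 1))))
        assert bad == []

    def test_two_outliers_match_direct_oracle(self):
        """Oracle: direct mean+3SD computation on the planted powers."""
        rng = np.random.default_rng(2)
        data = rng.standard_normal((30, 10000))
        data[3] *= np.sqrt(20)
        data[11] *= np.sqrt(20)
        rec = _rec(data)
        _, bad = reject_channels(rec)
        # independent oracle on normalized log powers
        from scipy.signal import periodogram

        f, p = periodogram(data, fs=FS, axis=1)
        m = (f >= 1) & (f <= 250)
        tot = p[:, m].sum(axis=1)
        z = np.log10(tot / np.median(tot))
        expect = [f"ch{i}" for i in np.where(z > z.mean() + 3 * z.std())[0]]
        assert bad == expect == ["ch3", "ch11"]

    def test_all_rejected_is_pipeline_failure(self):
        # degenerate: fewer than 4 EEG channels
        with pytest.raises(ValueError):
            reject_channels(_rec(np.zeros((3, 1000))))


class TestRankNoiseComponents:
    def _ics(self, sources):
        k = sources.shape[0]
        return ICDecomposition(mixing=np.eye(k), sources=sources,
                               channel_indices=np.arange(k),
                               mean=np.zeros(k))

    def test_eog_copy_ranked_first(self):
        rng = np.random.default_rng(0)
        eog = rng.standard_normal(5000)
        ics = self._ics(np.vstack([rng.standard_normal(5000), eog]))
        ics = rank_noise_components(ics, eog[None, :])
        assert ics.noise_rank[0] == 1
        assert ics.rank_scores[0] > 0.999

    def test_independent_components_low_correlation(self):
        """Null-correlation oracle at n = 30000 samples."""
        rng = np.random.default_rng(1)
        ics = self._ics(rng.standard_normal((4, 30000)))
        ics = rank_noise_components(ics, rng.standard_normal((2, 30000)))
        assert max(ics.rank_scores) < 0.05

    def test_max_rule_over_nuisance_channels(self):
        rng = np.random.default_rng(2)
        ecg = rng.standard_normal(20000)
        eog = rng.standard_normal(20000)
        ic = 0.9 * ecg + np.sqrt(1 - 0.81) * rng.standard_normal(20000)
        ics = self._ics(ic[None, :])
        ics = rank_noise_components(ics, np.vstack([ecg, eog]))
        assert ics.rank_scores[0] == pytest.approx(0.9, abs=0.02)

    def test_zero_variance_component_ranked_last(self):
        rng = np.random.default_rng(3)
        nu = rng.standard_normal(5000)
        ics = self._ics(np.vstack([np.zeros(5000), 0.5 * nu
                                   + rng.standard_normal(5000)]))
        ics = rank_noise_components(ics, nu[None, :])
        assert ics.noise_rank[-1] == 0


def _brute_force_loop(ics, qi, threshold=-0.001, min_keep=0.25):
    """Independent oracle: same visit order and rule, written afresh."""
    n = ics.n_components
    max_rej = n - int(np.ceil(min_keep * n))
    rejected = set()
    cur = qi(ics.reconstruct(exclude=rejected))
    for c in ics.noise_rank:
        if len(rejected) >= max_rej:
            break
        sc = qi(ics.reconstruct(exclude=rejected | {c}))
        if sc - cur <= threshold:
            rejected = rejected | {c}
            cur = sc
    return rejected


class TestIterativeICRejection:
    def _tone_decomposition(self):
        rng = np.random.default_rng(4)
        t = np.arange(0, 60, 1 / FS)
        tone = 3 * np.sin(2 * np.pi * 60 * t)
        sources = np.vstack([tone, rng.standard_normal((3, t.size))])
        mixing = np.eye(4) + 0.1 * rng.standard_normal((4, 4))
        ics = ICDecomposition(mixing=mixing, sources=sources,
                              channel_indices=np.arange(4),
                              mean=np.zeros(4), noise_rank=[0, 1, 2, 3])
        return ics

    def test_tone_ic_rejected_clean_retained(self):
        ics = self._tone_decomposition()

        def qi(data):  # planted-tone power, sign: lower = better
            from scipy.signal import periodogram

            f, p = periodogram(data, fs=FS, axis=1)
            return float(p[:, (f >= 59) & (f <= 61)].sum()
                         / (p.sum() + 1e-300))

        out = iterative_ic_rejection(ics, qi)
        assert out.rejected == {0}
        assert out.rejected == _brute_force_loop(self._tone_decomposition(),
                                                 qi)

    def test_constant_quality_index_keeps_everything(self):
        ics = self._tone_decomposition()
        out = iterative_ic_rejection(ics, lambda data: 1.0)
        assert out.rejected == set()

    def test_25_percent_floor(self):
        """All removals improve quality, but 1 of 4 ICs must survive."""
        ics = self._tone_decomposition()
        calls = {"n": -1}

        def qi(data):  # strictly improves with every removal
            calls["n"] += 1
            return -0.01 * calls["n"]

        out = iterative_ic_rejection(ics, qi)
        assert len(out.rejected) == 3
        assert len(set(range(4)) - out.rejected) == 1

    def test_nonfinite_quality_index_fails_loudly(self):
        ics = self._tone_decomposition()
        with pytest.raises(RuntimeError):
            iterative_ic_rejection(ics, lambda data: float("nan"))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_loop_matches_brute_force_oracle(self, seed):
        """Random small decompositions: final set equals oracle's."""
        rng = np.random.default_rng(seed)
        k = 6
        sources = rng.standard_normal((k, 4000))
        ics = ICDecomposition(mixing=rng.standard_normal((k, k)),
                              sources=sources,
                              channel_indices=np.arange(k),
                              mean=np.zeros(k),
                              noise_rank=list(rng.permutation(k)))
        weights = rng.uniform(-1, 1, size=k)

        def qi(data):
            return float(np.tanh(weights @ (data ** 2).mean(axis=1)))

        got = iterative_ic_rejection(ics, qi).rejected
        ics.rejected = set()
        assert got == _brute_force_loop(ics, qi)


class TestInterpolateAndDetrend:
    def test_rejected_channel_reconstructed_from_neighbors(self):
        """Oracle: the known source signal carried by the neighbors."""
        rng = np.random.default_rng(5)
        t = np.arange(0, 60, 1 / FS)
        s = np.sin(2 * np.pi * 5 * t) + 0.5 * np.sin(2 * np.pi * 11 * t)
        names = ["F3", "Fz", "F4", "Cz", "Pz"]
        data = np.vstack([s, rng.standard_normal(t.size), s,
                          s, s])
        rec = mm.Recording(data, FS, names, ["EEG"] * 5)
        out = interpolate_and_detrend(rec, ["Fz"])
        r = np.corrcoef(out.data[1], out.data[0])[0, 1]
        assert r > 0.95

    def test_constant_input_becomes_zero(self):
        rec = _rec(np.full((4, 5000), 3.0), ["F3", "Fz", "F4", "Cz"])
        out = interpolate_and_detrend(rec, [])
        assert np.abs(out.data).max() < 1e-9

    def test_ecg_drift_removed(self):
        t = np.arange(0, 60, 1 / FS)
        drift = 0.5 * t / t[-1]
        rec = _rec(drift[None, :], ["ECG"], ["ECG"])
        out = interpolate_and_detrend(rec, [])
        from scipy import stats

        slope_in = stats.linregress(t, drift).slope
        slope_out = stats.linregress(t, out.data[0]).slope
        assert abs(slope_out) < 0.01 * abs(slope_in)

    def test_shape_and_order_preserved(self):
        rng = np.random.default_rng(6)
        names = ["F3", "Fz", "F4", "Cz"]
        rec = _rec(rng.standard_normal((4, 5000)), names)
        out = interpolate_and_detrend(rec, ["F4"])
        assert out.data.shape == rec.data.shape
        assert out.channel_names == names


class TestFullPipeline:
    def test_end_to_end_clean_output(self, clean_session):
        raw, clean = clean_session
        assert clean.data.shape == raw.data.shape
        assert np.all(np.isfinite(clean.data))
        assert "rejected_channels" in clean.meta

    def test_bad_channel_rejected_and_interpolated(self):
        prof = mm.default_profile(42)
        raw = mm.make_session(prof, "nback3", duration=120, fs=250.0,
                              n_channels=20, bad_channel="F4")
        clean = mm.preprocess(raw, ica_seed=0)
        assert clean.meta["rejected_channels"] == ["F4"]
        assert clean.meta.get("interpolated_channels") == ["F4"]

    def test_idempotence_on_clean_data(self, clean_session):
        """Re-running the linear stages changes band powers < 5%."""
        from mindmetrics.eeg_features import window_powers

        _, clean = clean_session
        again = interpolate_and_detrend(basic_filters(clean), [])
        p1 = window_powers(clean, 100, 110)
        p2 = window_powers(again, 100, 110)
        assert np.max(np.abs(p2 - p1) / p1) < 0.05
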