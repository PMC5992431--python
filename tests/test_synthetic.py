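"""Generator tests: latent structure, signal directionality, ground truth."""

import numpy as np
import pytest

import mindmetrics as mm
from mindmetrics.eeg_features import band_power
from mindmetrics.synthetic import LatentStateTraject


def _flat_latents(duration=660.0, stress=0.5):
    t = np.arange(0.0, duration, 0.1)
    return LatentStateTraject(t, np.zeros_like(t),
                              np.full_like(t, stress), np.ones_like(t),
                              [], task="threat_detection")


class TestLatents:
    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError):
            mm.generate_latents("driving", 300, mm.default_profile(0))

    def test_breath_count_structure(self):
        lat = mm.generate_latents("breath_count", 300, mm.default_profile(1))
        assert np.all(np.diff(lat.times) > 0)
        assert np.all(np.diff(lat.fatigue) >= 0)
        assert lat.fatigue[-1] <= 0.15 + 1e-9
        # every button press ends a mind-wandering bout
        for e in lat.mw_events:
            i = np.searchsorted(lat.times, e) - 1
            assert lat.attention[i] == 0

    def test_nback3_no_mind_wandering(self):
        lat = mm.generate_latents("nback3", 300, mm.default_profile(1))
        assert lat.mw_events == []
        assert np.all(lat.attention == 1)
        assert np.allclose(lat.stress, lat.stress[0])

    @pytest.mark.parametrize("seed", range(4))
    def test_stress_ordering_strict(self, seed):
        prof = mm.default_profile(seed)
        levels = [mm.generate_latents(t, 300, prof).stress.mean()
                  for t in ("breath_count", "nback1", "nback3")]
        assert levels[0] < levels[1] < levels[2]


class TestSynthesizeEEG:
    def test_fs_too_low_rejected(self):
        lat = mm.generate_latents("nback3", 10, mm.default_profile(0))
        with pytest.raises(ValueError):
            mm.synthesize_eeg(lat, mm.default_profile(0), n_channels=4,
                              fs=150.0)

    def test_no_effect_band_powers_stationary(self):
        """Zero effects => no time trend in window powers (slope t-test)."""
        from scipy import stats

        prof = mm.default_profile(3, effects={})
        lat = mm.generate_latents("nback3", 600, prof)
        rec = mm.synthesize_eeg(lat, prof, fs=250.0, channels=["Fz", "Cz"])
        powers = [band_power(rec.data[0, i * 2500:(i + 1) * 2500], 250.0,
                             (30, 50)) for i in range(60)]
        res = stats.linregress(np.arange(60), np.log10(powers))
        assert res.pvalue > 0.01

    def test_fatigue_ramp_raises_frontal_gamma(self):
        """Oracle: direct band power on the generated signal, Q4 > Q1."""
        prof = mm.default_profile(4, effects={
            ("fatigue", "gamma", "frontal"): 0.5})
        lat = mm.generate_latents("nback3", 400, prof)
        rec = mm.synthesize_eeg(lat, prof, fs=250.0, channels=["Fz", "F3"])
        win = 2500
        powers = np.array([band_power(rec.data[0, i * win:(i + 1) * win],
                                      250.0, (30, 50)) for i in range(40)])
        assert powers[30:].mean() > powers[:10].mean()
        from scipy import stats

        assert stats.mannwhitneyu(powers[30:], powers[:10],
                                  alternative="greater").pvalue < 0.01

    def test_bad_channel_is_the_power_outlier(self):
        from mindmetrics.recording import EEG_CHANNELS

        prof = mm.default_profile(5)
        lat = mm.generate_latents("nback3", 60, prof)
        # mean+3SD across channels can only flag an outlier when enough
        # channels anchor the spread (max z-score is sqrt(n-1))
        chans = list(EEG_CHANNELS[:20])
        rec = mm.synthesize_eeg(lat, prof, fs=250.0, channels=chans,
                                bad_channel="F4")
        tot = (rec.data ** 2).mean(axis=1)
        z = np.log10(tot / np.median(tot))
        flagged = np.where(z > z.mean() + 3 * z.std())[0]
        assert list(flagged) == [rec.channel_names.index("F4")]

    def test_determinism_same_seed(self):
        prof = mm.default_profile(11)
        lat = mm.generate_latents("nback1", 30, prof)
        a = mm.synthesize_eeg(lat, prof, fs=250.0, channels=["Fz", "Cz"])
        b = mm.synthesize_eeg(lat, prof, fs=250.0, channels=["Fz", "Cz"])
        np.testing.assert_array_equal(a.data, b.data)


class TestSynthesizeECG:
    def test_constant_rate_exact(self):
        prof = mm.default_profile(2).with_(lf_base=0, lf_gain=0, hf_base=0,
                                           hf_gain=0, rr_jitter=0,
                                           rr_mean=1.0)
        lat = mm.generate_latents("breath_count", 60, prof)
        ecg = mm.synthesize_ecg(lat, prof, fs=500.0)
        beats = ecg.meta["beat_times"]
        assert abs(len(beats) - 60) <= 1
        np.testing.assert_allclose(np.diff(beats), 1.0, atol=1e-12)

    def test_hf_modulation_peaks_in_hf_band(self):
        prof = mm.default_profile(3).with_(lf_base=0, lf_gain=0,
                                           hf_base=0.05, hf_gain=0,
                                           rr_jitter=0.001)
        lat = mm.generate_latents("breath_count", 120, prof)
        ecg = mm.synthesize_ecg(lat, prof, fs=500.0)
        spec = mm.hrv_spectrum(mm.BeatSeries(ecg.meta["beat_times"]))
        assert 0.15 <= spec.argmax_freq() < 0.40

    def test_stress_step_raises_lf_hf_ratio(self):
        """Oracle: periodogram of the ground-truth RR series, half vs half."""
        prof = mm.default_profile(4).with_(rr_jitter=0.002)
        t = np.arange(0.0, 600, 0.1)
        stress = np.where(t < 300, 0.0, 1.0)
        lat = LatentStateTraject(t, np.zeros_like(t), stress,
                                 np.ones_like(t), [], task="nback3")
        ecg = mm.synthesize_ecg(lat, prof, fs=500.0)
        beats = mm.BeatSeries(ecg.meta["beat_times"])
        r1 = mm.lf_hf_ratio(mm.hrv_spectrum(beats, (0, 300)))
        r2 = mm.lf_hf_ratio(mm.hrv_spectrum(beats, (300, 600)))
        assert r2 > r1

    def test_ground_truth_always_exported(self):
        prof = mm.default_profile(5)
        lat = mm.generate_latents("nback1", 30, prof)
        ecg = mm.synthesize_ecg(lat, prof, fs=500.0)
        assert "beat_times" in ecg.meta and "rr_true" in ecg.meta
        assert len(ecg.meta["rr_true"]) == len(ecg.meta["beat_times"]) - 1


class TestSynthesizeBehavior:
    def test_null_mode_uncorrelated(self):
        """Independence by construction: mean r over seeds near 0."""
        rs = []
        for seed in range(60):
            prof = mm.default_profile(seed)
            lat = mm.generate_latents("threat_detection", 330, prof)
            trials = mm.synthesize_behavior(lat, prof, 100, null_mode=True)
            f = lat.at(trials["onset"].to_numpy() + 1.0)["fatigue"]
            rs.append(np.corrcoef(f, trials["rt"])[0, 1])
        assert abs(np.mean(rs)) < 0.05

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_linked_rt_correlation_near_half(self, seed):
        """Fisher-z CI oracle: target r ~ 0.5 at n = 200 trials."""
        prof = mm.default_profile(100 + seed)
        lat = mm.generate_latents("threat_detection", 660, prof)
        trials = mm.synthesize_behavior(lat, prof, 200)
        f = lat.at(trials["onset"].to_numpy() + 1.0)["fatigue"]
        r = np.corrcoef(f, trials["rt"])[0, 1]
        assert 0.35 <= r <= 0.62

    def test_constant_latents_rt_variance_is_noise(self):
        prof = mm.default_profile(9)
        lat = _flat_latents(duration=3100.0)
        trials = mm.synthesize_behavior(lat, prof, 1000, spacing=3.0)
        noise_var = prof.behavior.rt_noise ** 2
        assert abs(trials["rt"].var() - noise_var) / noise_var < 0.2

    def test_trials_beyond_span_rejected(self):
        prof = mm.default_profile(1)
        lat = mm.generate_latents("threat_detection", 60, prof)
        with pytest.raises(ValueError):
            mm.synthesize_behavior(lat, prof, 100)

    def test_rt_truncated_to_trial_duration(self):
        prof = mm.default_profile(12)
        lat = mm.generate_latents("threat_detection", 660, prof)
        trials = mm.synthesize_behavior(lat, prof, 200)
        assert ((trials["rt"] > 0) & (trials["rt"] <= 2.0)).all()
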