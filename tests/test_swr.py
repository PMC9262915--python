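import numpy as np
import pytest
from scipy import signal as sps

from hippoquant import swr, synth
from hippoquant.core import IntervalSet, UniformSignal
from hippoquant.scoring import recall_precision


class TestRippleEnvelope:
    def test_bandpass_meets_stopband_spec(self):
        """>= 40 dB attenuation at 0.8*band_lo and 1.2*band_hi, flat in band."""
        for fs in (2000.0, 20000.0):
            k = swr.ripple_bandpass_kernel(fs, 70.0, 250.0)
            w, h = sps.freqz(k, worN=16384, fs=fs)
            gain_db = 20 * np.log10(np.abs(h) + 1e-300)
            assert gain_db[np.argmin(np.abs(w - 56.0))] <= -40
            assert gain_db[np.argmin(np.abs(w - 300.0))] <= -40
            assert abs(gain_db[np.argmin(np.abs(w - 150.0))]) < 1.0

    def test_zero_signal_zero_envelope(self):
        env = swr.ripple_envelope(UniformSignal(np.zeros(10000), 2000.0, units="mV"))
        assert np.allclose(env.values, 0.0)

    def test_in_band_sinusoid_rectified_mean(self):
        # smoothed rectified sinusoid -> mean ~= 2A/pi
        fs, A = 2000.0, 0.5
        t = np.arange(int(30 * fs)) / fs
        env = swr.ripple_envelope(UniformSignal(A * np.sin(2 * np.pi * 150 * t),
                                                fs, units="mV"))
        mid = env.values[int(fs):-int(fs)]
        assert 0.55 * A <= np.mean(mid) <= 0.75 * A

    def test_stopband_sinusoid_suppressed(self):
        fs, A = 2000.0, 0.5
        t = np.arange(int(30 * fs)) / fs
        env = swr.ripple_envelope(UniformSignal(A * np.sin(2 * np.pi * 10 * t),
                                                fs, units="mV"))
        assert np.mean(env.values[int(fs):-int(fs)]) < 0.02 * A

    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="Nyquist"):
            swr.ripple_envelope(UniformSignal(np.zeros(400), 400.0, units="mV"))


class TestBaselineStats:
    def test_definition_matches_sample_formula(self):
        rng = np.random.default_rng(0)
        env = UniformSignal(np.abs(rng.normal(1.0, 0.2, 40000)), 2000.0)
        st = swr.baseline_stats(env, IntervalSet([(0.0, 20.0)]))
        assert st.mu == pytest.approx(float(np.mean(env.values)))
        assert st.sd == pytest.approx(float(np.std(env.values)))

    def test_ignores_samples_outside_intervals(self):
        rng = np.random.default_rng(1)
        vals = np.abs(rng.normal(1.0, 0.2, 40000))
        imm = IntervalSet([(0.0, 10.0)])
        st1 = swr.baseline_stats(UniformSignal(vals, 2000.0), imm)
        vals2 = vals.copy()
        vals2[20000:] = 99.0  # mobility period arbitrarily altered
        st2 = swr.baseline_stats(UniformSignal(vals2, 2000.0), imm)
        assert st1.mu == st2.mu and st1.sd == st2.sd

    def test_minimum_immobility_required(self):
        env = UniformSignal(np.abs(np.random.default_rng(2).normal(1, 0.1, 10000)),
                            2000.0)
        with pytest.raises(ValueError, match="10"):
            swr.baseline_stats(env, IntervalSet([(0.0, 2.0)]))


class TestDetect:
    def test_flat_envelope_no_events(self):
        env = UniformSignal(np.ones(40000), 2000.0)
        st = swr.BaselineStats(mu=1.0, sd=0.1,
                               source_intervals=IntervalSet([(0, 20)]), n_samples=40000)
        assert len(swr.detect_swr(env, st)) == 0

    def test_recovery_against_ground_truth(self, lfp_session):
        truth, events, imm = (lfp_session["truth"], lfp_session["events"],
                              lfp_session["immobility"])
        det = events["peak_s"]
        det = det[imm.contains(det)]  # SWRs are an immobility phenomenon
        recall, precision = recall_precision(det, truth["peak_s"], 0.025)
        assert recall >= 0.90 and precision >= 0.90

    def test_rate_recovery(self, lfp_session):
        rate = swr.swr_rate(lfp_session["events"], lfp_session["immobility"])
        true_rate = len(lfp_session["truth"]) / lfp_session["immobility"].duration()
        assert rate == pytest.approx(true_rate, rel=0.10)

    def test_calibrated_power(self, lfp_session):
        """Programmed 6 SD events measure at 6 SD max power on average."""
        truth, events = lfp_session["truth"], lfp_session["events"]
        det = events["peak_s"]
        matched = [np.min(np.abs(det - g)) <= 0.025 for g in truth["peak_s"]]
        idx = [int(np.argmin(np.abs(det - g))) for g, m
               in zip(truth["peak_s"], matched) if m]
        assert float(np.mean(events["max_power_sd"][idx])) == pytest.approx(6.0, abs=0.5)

    def test_threshold_monotonicity(self, lfp_session):
        env, st = lfp_session["envelope"], lfp_session["stats"]
        counts = [len(swr.detect_swr(env, st, swr.RippleParams(threshold_sd=thr)))
                  for thr in (2.5, 3.0, 4.0, 5.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_scale_invariance(self, lfp_session):
        """Scaling the raw LFP leaves every SD-unit output unchanged."""
        sig, imm = lfp_session["signal"], lfp_session["immobility"]
        env10 = swr.ripple_envelope(sig.with_values(10.0 * sig.values))
        st10 = swr.baseline_stats(env10, imm)
        ev10 = swr.detect_swr(env10, st10)
        ev = lfp_session["events"]
        assert len(ev10) == len(ev)
        assert np.allclose(ev10["max_power_sd"], ev["max_power_sd"], atol=1e-6)
        assert np.allclose(ev10["mean_power_sd"], ev["mean_power_sd"], atol=1e-6)
        assert swr.swr_rate(ev10, imm) == swr.swr_rate(ev, imm)


class TestRate:
    def test_arithmetic(self):
        from hippoquant.core import EventTable
        peaks = np.linspace(1, 299, 90)
        t = EventTable(onset_s=peaks - 0.01, peak_s=peaks, offset_s=peaks + 0.01,
                       amplitude=np.ones(90))
        assert swr.swr_rate(t, IntervalSet([(0.0, 300.0)])) == pytest.approx(0.3)

    def test_zero_events(self):
        from hippoquant.core import EventTable
        assert swr.swr_rate(EventTable.empty(), IntervalSet([(0.0, 10.0)])) == 0.0

    def test_zero_immobility_raises(self):
        from hippoquant.core import EventTable
        with pytest.raises(ValueError):
            swr.swr_rate(EventTable.empty(), IntervalSet())


class TestCommonThreshold:
    @staticmethod
    def _session(seed, noise_scale=1.0, duration=300.0):
        rng = np.random.default_rng(seed)
        fs = 2000.0
        x = synth.one_over_f_noise(int(duration * fs), fs, 1.0, 0.1 * noise_scale, rng)
        env = swr.ripple_envelope(UniformSignal(x, fs, units="mV"))
        return env, IntervalSet([(0.0, duration)])

    def test_identical_sessions_pool_within_one_percent(self):
        s1, s2 = self._session(1), self._session(2)
        _, pooled = swr.detect_swr_common_threshold([s1, s2])
        for env, imm in (s1, s2):
            own = swr.baseline_stats(env, imm)
            t_own = own.mu + 3 * own.sd
            t_pool = pooled.mu + 3 * pooled.sd
            assert abs(t_own - t_pool) / t_pool < 0.01

    def test_single_session_degenerates_to_plain_detection(self):
        env, imm = self._session(3, duration=60.0)
        tables, pooled = swr.detect_swr_common_threshold([(env, imm)])
        plain = swr.detect_swr(env, swr.baseline_stats(env, imm))
        assert tables[0].df.equals(plain.df)

    def test_pooled_threshold_between_heterogeneous_sessions(self):
        quiet, loud = self._session(4, duration=120.0), self._session(5, 1.5, 120.0)
        _, pooled = swr.detect_swr_common_threshold([quiet, loud])
        t = lambda s: s.mu + 3 * s.sd  # noqa: E731
        t_q = t(swr.baseline_stats(*quiet))
        t_l = t(swr.baseline_stats(*loud))
        assert t_q < t(pooled) < t_l

    def test_heterogeneous_rates_rejected(self):
        env, imm = self._session(6, duration=60.0)
        other = UniformSignal(env.values[::2], env.rate_hz / 2)
        with pytest.raises(ValueError, match="rates"):
            swr.detect_swr_common_threshold([(env, imm), (other, imm)])
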