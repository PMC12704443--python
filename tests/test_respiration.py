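import numpy as np
import pytest

from mwbody import respiration as resp
from mwbody import synth
from mwbody.study import participant_phases


def moving_average_gain(freq, window_s, fs):
    """Closed-form amplitude gain of an N-point moving average."""
    n = int(round(window_s * fs))
    x = np.pi * freq * n / fs
    return abs(np.sin(x) / (n * np.sin(np.pi * freq / fs)))


class TestPreprocess:
    fs = 250.0

    def test_sinusoid_survives_with_predicted_attenuation(self):
        t = np.arange(0, 300, 1 / self.fs)
        f = 0.25
        x = np.sin(2 * np.pi * f * t)
        y = resp.preprocess_resp(x, self.fs)
        mid = slice(int(60 * self.fs), int(240 * self.fs))
        amp = (y[mid].max() - y[mid].min()) / 2
        g25 = moving_average_gain(f, 0.025, self.fs)
        g60 = moving_average_gain(f, 60.0, self.fs)
        expected = g25 * (1 - g60)   # smoothing, then sliding-mean removal
        assert amp == pytest.approx(expected, rel=0.05)

    def test_linear_ramp_removed(self):
        t = np.arange(0, 120, 1 / self.fs)
        x = np.sin(2 * np.pi * 0.2 * t) + 0.05 * t
        y = resp.preprocess_resp(x, self.fs)
        slope = np.polyfit(t, y, 1)[0]
        assert abs(slope) < 0.01 * 0.05   # residual < 1% of the input ramp

    def test_constant_maps_to_zero(self):
        y = resp.preprocess_resp(np.full(int(90 * self.fs), 3.7), self.fs)
        assert np.allclose(y, 0.0, atol=1e-9)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            resp.preprocess_resp(np.zeros(3), self.fs)


class TestDetectPhases:
    fs = 250.0

    def test_symmetric_sinusoid_half_inhale(self):
        t = np.arange(0, 300, 1 / self.fs)
        x = np.sin(2 * np.pi * 12 / 60 * t)
        ph = resp.detect_phases(x, self.fs)
        assert ph.inhale_fraction == pytest.approx(0.5, abs=0.02)

    def test_asymmetric_cycle_recovers_inhale_fraction(self):
        cfg = synth.SimConfig(duration=300.0, n_mw_reports=0, seed=2,
                              inhale_frac=1 / 3, noise_sd_resp=0.0,
                              drift_slope=0.0, drift_sin_amp=0.0,
                              rate_jitter=0.0)
        trace, truth = synth.gen_respiration(cfg)
        ph = resp.detect_phases(trace, cfg.fs_physio)
        assert ph.inhale_fraction == pytest.approx(1 / 3, abs=0.03)

    def test_simulator_trace_agreement_with_truth(self, bf_recording):
        ph = participant_phases(bf_recording)
        acc = (ph.inhale == bf_recording.truth["inhale"].astype(bool)).mean()
        assert acc >= 0.95

    def test_flat_trace_flagged_empty(self):
        ph = resp.detect_phases(np.zeros(5000), self.fs)
        assert ph.cycle_onsets.size == 0

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 120, 1 / self.fs)
        x = np.sin(2 * np.pi * 0.2 * t) + 0.05 * rng.standard_normal(t.size)
        a = resp.detect_phases(x, self.fs)
        b = resp.detect_phases(3.5 * x - 11.0, self.fs)
        assert np.array_equal(a.inhale, b.inhale)
        assert np.array_equal(a.cycle_onsets, b.cycle_onsets)


class TestSelectChannel:
    def mk(self, n_cycles):
        onsets = np.arange(n_cycles + 1) * 100 if n_cycles else np.empty(0, int)
        return resp.PhaseSeries(np.zeros(2000, bool), onsets, 250.0)

    def test_more_cycles_wins(self):
        chest, abd = self.mk(30), self.mk(25)
        assert resp.select_channel(chest, abd) is chest
        assert resp.select_channel(self.mk(25), abd := self.mk(30)) is abd

    def test_tie_prefers_chest(self):
        chest = self.mk(20)
        assert resp.select_channel(chest, self.mk(20)) is chest

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            resp.select_channel(self.mk(0), self.mk(0))


class TestCycleCount:
    def test_noiseless_count(self):
        cfg = synth.SimConfig(duration=720.0, n_mw_reports=0, seed=0,
                              resp_rate=12.0, noise_sd_resp=0.0,
                              drift_slope=0.0, drift_sin_amp=0.0,
                              rate_jitter=0.0)
        _, truth = synth.gen_respiration(cfg)
        ph = resp.PhaseSeries(truth.inhale, truth.cycle_onsets, truth.fs)
        # 144 inhalation onsets bound 143 complete onset-to-onset cycles
        assert resp.cycle_count(ph) == 143

    def test_empty_is_zero(self):
        ph = resp.PhaseSeries(np.zeros(10, bool), np.empty(0, int), 250.0)
        assert resp.cycle_count(ph) == 0

    def test_bf_fewer_cycles_than_sf(self, small_study):
        from mwbody.study import analyze_respiration

        cycles, _ = analyze_respiration(small_study, offsets=range(1))
        g = cycles.groupby("condition")["n_cycles"].mean()
        assert g["BF"] < g["SF"]


class TestInhalationBaseline:
    def mk(self, labels):
        return resp.PhaseSeries(np.asarray(labels, bool), np.empty(0, int), 10.0)

    def test_all_inhale_gives_one(self):
        assert resp.inhalation_baseline(self.mk(np.ones(1000))) == 1.0

    def test_balanced_within_binomial_error(self):
        lab = np.arange(10000) % 2 == 0
        base = resp.inhalation_baseline(self.mk(lab), seed=4)
        assert abs(base - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_seeded_determinism(self):
        lab = np.arange(999) % 3 == 0
        a = resp.inhalation_baseline(self.mk(lab), seed=9)
        b = resp.inhalation_baseline(self.mk(lab), seed=9)
        assert a == b

    def test_unbiased_over_seeds(self):
        lab = np.arange(5000) % 5 < 2          # true fraction 0.4
        vals = [resp.inhalation_baseline(self.mk(lab), n_draws=2000, seed=s)
                for s in range(40)]
        assert np.mean(vals) == pytest.approx(0.4, abs=0.01)


def _periodic_phase(fs, duration, rate_cpm, phase0=0.0, inhale_frac=0.5):
    n = int(duration * fs)
    u = (phase0 + np.arange(n) * rate_cpm / 60.0 / fs) % 1.0
    return resp.PhaseSeries(u < inhale_frac, np.empty(0, int), fs)


class TestInhalationRateTest:
    def test_single_participant_rejected(self):
        ph = {"a": _periodic_phase(10, 60, 12)}
        with pytest.raises(ValueError):
            resp.inhalation_rate_test(ph, {"a": [30.0]})

    def test_type_one_error_near_nominal(self):
        # reports independent of the phase stream: the offset-0 test should
        # reject at roughly the nominal 5% rate
        rng = np.random.default_rng(99)
        rejections = 0
        n_sets = 200
        for _ in range(n_sets):
            phases, reports = {}, {}
            for p in range(12):
                phases[p] = _periodic_phase(
                    10, 300, rng.uniform(9, 18), phase0=rng.random()
                )
                reports[p] = rng.uniform(20, 280, size=8)
            out = resp.inhalation_rate_test(
                phases, reports, offsets=[0],
                n_draws=400, seed=int(rng.integers(1 << 30)),
            )
            rejections += int(out["p"].iloc[0] < 0.05)
        rate = rejections / n_sets
        ci = 3 * np.sqrt(0.05 * 0.95 / n_sets)
        assert abs(rate - 0.05) < max(ci, 0.045)

    def test_constructed_effect_detected(self):
        rng = np.random.default_rng(5)
        phases, reports = {}, {}
        for p in range(30):
            ph = _periodic_phase(10, 300, 12, phase0=rng.random())
            phases[p] = ph
            onsets = np.flatnonzero(np.diff(ph.inhale.astype(int)) == 1) / 10.0
            reports[p] = rng.choice(onsets[(onsets > 20) & (onsets < 280)], 8) + 0.5
        out = resp.inhalation_rate_test(phases, reports, offsets=[0], seed=1)
        assert out["mean_rate"].iloc[0] > out["mean_baseline"].iloc[0]
        assert out["p"].iloc[0] < 0.01

    def test_rates_and_exhalation_sum_to_one(self):
        rng = np.random.default_rng(7)
        phases = {p: _periodic_phase(10, 120, 12, phase0=rng.random())
                  for p in range(4)}
        reports = {p: rng.uniform(10, 110, 5) for p in range(4)}
        out = resp.inhalation_rate_test(phases, reports, offsets=[0, 1, 2], seed=0)
        for _, row in out.iterrows():
            exhal = 1.0 - row["mean_rate"]
            assert 0.0 <= row["mean_rate"] <= 1.0
            assert exhal + row["mean_rate"] == pytest.approx(1.0)
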