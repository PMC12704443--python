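import numpy as np
import pytest

from mwbody import synth


def quiet_cfg(**kw):
    base = dict(duration=120.0, n_mw_reports=0, seed=3, condition="SF",
                noise_sd_resp=0.0, drift_slope=0.0, drift_sin_amp=0.0,
                rate_jitter=0.0, noise_sd_ecg=0.0, rsa_gain=0.0,
                event_hr_profile={})
    base.update(kw)
    return synth.SimConfig(**base)


class TestDeterminism:
    def test_identical_config_gives_identical_recording(self):
        cfg = synth.SimConfig(duration=60.0, n_mw_reports=2, seed=7,
                              min_report_gap=15.0)
        a = synth.simulate_recording(cfg)
        b = synth.simulate_recording(synth.SimConfig(
            duration=60.0, n_mw_reports=2, seed=7, min_report_gap=15.0))
        assert np.array_equal(a.eeg, b.eeg)
        assert np.array_equal(a.ecg, b.ecg)
        assert np.array_equal(a.resp_chest, b.resp_chest)
        assert a.events.equals(b.events)

    def test_seed_changes_output(self):
        a = synth.simulate_recording(synth.SimConfig(duration=60.0, seed=1,
                                                     n_mw_reports=0))
        b = synth.simulate_recording(synth.SimConfig(duration=60.0, seed=2,
                                                     n_mw_reports=0))
        assert not np.array_equal(a.ecg, b.ecg)


class TestRespiration:
    def test_noiseless_cycle_count_exact(self):
        cfg = quiet_cfg(duration=720.0, resp_rate=12.0)
        _, truth = synth.gen_respiration(cfg)
        assert truth.cycle_onsets.size == 720 * 12 // 60

    def test_labels_partition_samples(self, bf_recording):
        inhale = bf_recording.truth["inhale"].astype(bool)
        assert inhale.size == bf_recording.resp_chest.size
        # inhale and exhale are complementary by construction; the truth
        # stores one boolean per sample
        assert inhale.dtype == bool

    def test_bf_slower_than_sf(self):
        bf = quiet_cfg(condition="BF", duration=300.0)
        sf = quiet_cfg(condition="SF", duration=300.0)
        _, tb = synth.gen_respiration(bf)
        _, ts = synth.gen_respiration(sf)
        assert tb.cycle_onsets.size < ts.cycle_onsets.size

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            quiet_cfg(resp_rate=0.0)


class TestECG:
    def test_constant_rate_gives_unit_rr(self):
        cfg = quiet_cfg(base_hr=60.0)
        trace, peaks = synth.gen_ecg(cfg, synth.gen_respiration(cfg)[1])
        rr = np.diff(peaks)
        assert np.allclose(rr, 1.0, atol=1.5 / cfg.fs_physio)

    def test_rsa_lengthens_exhalation_rr(self, bf_recording):
        truth = bf_recording.truth
        peaks = np.asarray(truth["r_peak_times"])
        rr = np.diff(peaks)
        idx = np.clip((peaks[:-1] * bf_recording.fs_physio).astype(int), 0,
                      len(truth["inhale"]) - 1)
        inhale = truth["inhale"].astype(bool)[idx]
        assert rr[~inhale].mean() > rr[inhale].mean()

    def test_event_profile_shortens_final_second_rr(self):
        cfg = quiet_cfg(n_mw_reports=4, duration=240.0, min_report_gap=20.0,
                        event_hr_profile={1: 15.0})
        resp = synth.gen_respiration(cfg)[1]
        events, tr = synth.gen_events(cfg, resp)
        _, peaks = synth.gen_ecg(cfg, resp, report_times=tr["report_times"])
        rr = np.diff(peaks)
        on = peaks[:-1]
        lab1, lab4 = [], []
        for r in tr["report_times"]:
            d = r - on
            lab1.extend(rr[(d > 0) & (d <= 1)])
            lab4.extend(rr[(d > 3) & (d <= 4)])
        assert np.mean(lab1) < np.mean(lab4)

    def test_truth_peaks_strictly_increasing_and_inside(self, bf_recording):
        pk = np.asarray(bf_recording.truth["r_peak_times"])
        assert np.all(np.diff(pk) > 0)
        assert pk[0] >= 0 and pk[-1] <= 300.0

    def test_hr_below_rsa_rejected(self):
        with pytest.raises(ValueError):
            quiet_cfg(base_hr=3.0, rsa_gain=4.0)


class TestEEG:
    def test_change_point_outside_window_rejected(self):
        with pytest.raises(ValueError):
            quiet_cfg(alpha_cp_time=12.0)

    def test_flat_trends_give_flat_envelope(self):
        cfg = quiet_cfg(n_mw_reports=2, duration=120.0, min_report_gap=15.0,
                        alpha_trend_pre=0.0, alpha_trend_post=0.0)
        resp = synth.gen_respiration(cfg)[1]
        _, tr = synth.gen_events(cfg, resp)
        _, peaks = synth.gen_ecg(cfg, resp, report_times=tr["report_times"])
        _, truth = synth.gen_eeg(cfg, peaks, tr["report_times"])
        assert np.allclose(truth["alpha_envelope"], cfg.alpha_amp)

    def test_negative_post_trend_lowers_pre_report_envelope(self, bf_recording):
        env = bf_recording.truth["alpha_envelope"]
        fs = bf_recording.fs_eeg
        r = np.asarray(bf_recording.truth["report_times"])[0]
        at = lambda t: env[int(t * fs)]
        assert at(r - 0.5) < at(r - 6.0)

    def test_hep_amplitude_follows_state_map(self, bf_recording):
        truth = bf_recording.truth
        amps = np.asarray(truth["hep_amp_per_peak"])
        peaks = np.asarray(truth["r_peak_times"])
        reports = np.asarray(truth["report_times"])
        for pk, a in zip(peaks, amps):
            in_mw = any(r - 9 <= pk < r - 5 for r in reports)
            if in_mw:
                assert a == 1.5


class TestEvents:
    def test_sf_isis_within_bounds(self, sf_recording):
        tones = sf_recording.events.query("type == 'tone'")["onset_s"].to_numpy()
        reports = sf_recording.events.query("type == 'mw_report'")["onset_s"].to_numpy()
        resumes = sf_recording.events.query("type == 'resume'")["onset_s"].to_numpy()
        isis = np.diff(tones)
        # ISIs not interrupted by a report/resume pause obey the 1.2-2.0 s rule
        for t0, t1 in zip(tones[:-1], tones[1:]):
            crossed = any((t0 < r < t1) or (t0 < s < t1)
                          for r, s in zip(reports, resumes))
            if not crossed:
                assert 1.2 <= t1 - t0 <= 2.0
        assert isis.min() >= 1.2

    def test_zero_reports_gives_tones_and_presses_only(self):
        cfg = quiet_cfg(n_mw_reports=0)
        ev, tr = synth.gen_events(cfg, synth.gen_respiration(cfg)[1])
        assert set(ev["type"]) == {"tone", "press"}
        assert tr["report_times"].size == 0

    def test_reports_respect_min_gap(self, bf_recording):
        rep = np.sort(np.asarray(bf_recording.truth["report_times"]))
        assert np.diff(rep).min() >= 25.0

    def test_hct_trials_have_standard_windows(self):
        cfg = quiet_cfg()
        hct = synth.gen_hct_trials(cfg)
        assert sorted(hct["window_s"]) == [25, 30, 35, 40, 45, 50]
        assert (hct["actual"] > 0).all()


def test_montage_has_parietal_row():
    names, pos = synth.make_montage(16)
    par = synth.parietal_channels(names)
    assert len(names) == 16 and pos.shape == (16, 2)
    assert par.size == 4
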