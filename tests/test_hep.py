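import numpy as np
import pandas as pd
import pytest

from mwbody import hep, synth
from mwbody.study import participant_hep


def mk_recording(data, fs=500.0):
    names, pos = synth.make_montage(data.shape[0])
    return hep.EEGRecording(data=data, fs=fs, ch_names=names, ch_pos=pos)


class TestPreprocess:
    def test_line_noise_attenuated_over_20db(self):
        fs = 500.0
        t = np.arange(0, 20, 1 / fs)
        data = np.tile(np.sin(2 * np.pi * 50.0 * t), (4, 1))
        data[0] += 1.0  # offset so the average reference is nontrivial
        out = hep.preprocess_eeg(mk_recording(data, fs))
        # residual 50 Hz content via projection on the quadrature pair
        tt = np.arange(out.data.shape[1]) / out.fs
        q = np.column_stack([np.sin(2 * np.pi * 50 * tt), np.cos(2 * np.pi * 50 * tt)])
        resid = np.linalg.lstsq(q, out.data.T, rcond=None)[0]
        assert np.abs(resid).max() < 0.1

    def test_average_reference_zero_mean_and_idempotent(self, rng):
        data = rng.standard_normal((6, 5000))
        out = hep.preprocess_eeg(mk_recording(data, 500.0))
        assert np.allclose(out.data.mean(axis=0), 0.0, atol=1e-9)
        again = out.data - out.data.mean(axis=0, keepdims=True)
        assert np.allclose(again, out.data)

    def test_slow_drift_attenuated(self):
        fs = 500.0
        t = np.arange(0, 40, 1 / fs)
        data = np.vstack([np.sin(2 * np.pi * 0.05 * t), -np.sin(2 * np.pi * 0.05 * t)])
        out = hep.preprocess_eeg(mk_recording(data, fs))
        mid = slice(int(5 * 250), int(35 * 250))
        assert np.abs(out.data[0, mid]).max() < 0.2

    def test_downsamples_to_250(self):
        out = hep.preprocess_eeg(mk_recording(np.random.default_rng(0)
                                              .standard_normal((4, 5000)), 500.0))
        assert out.fs == 250.0 and out.data.shape[1] == 2500

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            hep.preprocess_eeg(mk_recording(np.zeros((4, 100)), 100.0))


class TestEpochHep:
    def test_epoch_window_arithmetic(self, rng):
        data = rng.standard_normal((4, 250 * 20))
        rec = mk_recording(data, 250.0)
        hs = hep.epoch_hep(rec, [10.0])
        assert hs.data.shape == (1, 4, 201)
        assert hs.times[0] == pytest.approx(-0.2)
        assert hs.times[-1] == pytest.approx(0.6)
        i = int(round((10.0 - 0.2) * 250))
        assert np.array_equal(hs.data[0, :, 0], data[:, i])

    def test_edge_peaks_dropped(self, rng):
        rec = mk_recording(rng.standard_normal((4, 250 * 10)), 250.0)
        hs = hep.epoch_hep(rec, [0.1, 5.0, 9.95])
        assert len(hs.meta) == 1 and hs.meta["peak_s"].iloc[0] == 5.0

    def test_injected_late_deflection_recovered(self):
        # quieter background so the injected 1.5 µV MW-vs-aware difference
        # dominates the trial-average noise floor
        cfg = synth.SimConfig(duration=300.0, n_mw_reports=6, seed=8,
                              condition="BF", noise_sd_eeg=3.0)
        rec = synth.simulate_recording(cfg)
        hs = participant_hep(rec, residualize=False)
        par = synth.parietal_channels(rec.ch_names)
        mw = hs.select(state="MW").average()
        aware = hs.select(state="aware").average()
        diff = (mw - aware)[par].mean(axis=0)
        late = (hs.times >= 0.38) & (hs.times <= 0.58)
        early = hs.times < 0.3
        assert diff[late].mean() > diff[early].mean() + 0.2
        # peak of the difference near the injected 480 ms latency
        assert abs(hs.times[np.argmax(diff)] - 0.48) < 0.08


class TestInclusionFilter:
    def test_threshold_is_ten_or_more(self):
        kept = hep.inclusion_filter({"a": 10, "b": 9, "c": 40})
        assert kept == ["a", "c"]

    def test_all_below_threshold_rejected(self):
        with pytest.raises(ValueError):
            hep.inclusion_filter({"a": 3, "b": 9})


def mk_hepset(data, states, fs=250.0):
    n_tr, n_ch, n_t = data.shape
    times = np.linspace(-0.2, 0.6, n_t)
    meta = pd.DataFrame({"peak_s": np.arange(n_tr, dtype=float),
                         "state": states,
                         "condition": "BF", "participant": "p"})
    return hep.HEPSet(data=data, times=times, meta=meta,
                      ch_names=[f"c{i}" for i in range(n_ch)], fs=fs)


class TestBaselineRegress:
    def test_zero_baseline_leaves_waveforms_unchanged(self, rng):
        n_tr, n_ch, n_t = 20, 3, 201
        data = np.zeros((n_tr, n_ch, n_t))
        times = np.linspace(-0.2, 0.6, n_t)
        post = times > 0
        data[:, :, post] = rng.standard_normal((n_tr, n_ch, post.sum()))
        hs = mk_hepset(data, ["MW"] * 10 + ["aware"] * 10)
        out = hep.baseline_regress(hs)
        assert np.allclose(out.data, hs.data)

    def test_injected_baseline_dependence_removed(self, rng):
        n_tr, n_ch, n_t = 40, 2, 201
        times = np.linspace(-0.2, 0.6, n_t)
        base = rng.standard_normal(n_tr)
        data = np.zeros((n_tr, n_ch, n_t))
        data[:, :, times <= -0.075] = base[:, None, None]
        states = np.array(["MW"] * 20 + ["aware"] * 20)
        effect = np.where(states == "MW", 1.0, -1.0)
        post = times > 0
        data[:, :, post] += (2.0 * base + effect)[:, None, None]
        data += 0.1 * rng.standard_normal(data.shape)
        hs = mk_hepset(data, list(states))
        out = hep.baseline_regress(hs)
        b = hep.baseline_means(hs)
        for ch in range(n_ch):
            bc = b[:, ch] - b[:, ch].mean()
            resid = out.data[:, ch, :] - out.data[:, ch, :].mean(axis=0)
            cov = bc @ resid / (n_tr - 1)
            assert np.abs(cov).max() < 1e-10

    def test_trial_count_conserved_and_flag_set(self, rng):
        data = rng.standard_normal((12, 2, 201))
        hs = mk_hepset(data, ["MW"] * 6 + ["aware"] * 6)
        out = hep.baseline_regress(hs)
        assert out.data.shape[0] == 12
        assert out.residualized and not hs.residualized

    def test_constant_baseline_covariate_dropped(self):
        data = np.zeros((8, 1, 201))
        hs = mk_hepset(data, ["MW"] * 4 + ["aware"] * 4)
        out = hep.baseline_regress(hs)   # must not raise on rank deficiency
        assert np.allclose(out.data, 0.0)

    def test_shuffled_labels_leave_no_condition_baseline_coupling(self, rng):
        # with labels shuffled the interaction estimate should average ~0:
        # residualized group difference stays centered on the true difference
        n_tr = 60
        times = np.linspace(-0.2, 0.6, 201)
        base = rng.standard_normal(n_tr)
        diffs = []
        for _ in range(30):
            states = np.array(["MW"] * 30 + ["aware"] * 30)
            rng.shuffle(states)
            data = np.zeros((n_tr, 1, 201))
            data[:, :, times <= -0.075] = base[:, None, None]
            data[:, :, times > 0] = (1.5 * base)[:, None, None]
            data += 0.05 * rng.standard_normal(data.shape)
            out = hep.baseline_regress(mk_hepset(data, list(states)))
            post = out.data[:, 0, times > 0].mean(axis=1)
            diffs.append(post[states == "MW"].mean() - post[states == "aware"].mean())
        assert abs(np.mean(diffs)) < 0.02
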