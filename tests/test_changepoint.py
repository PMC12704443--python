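import numpy as np
import pytest
from scipy import stats
from scipy.special import logsumexp

from mwbody import changepoint as cp


class TestDrawAccounting:
    @pytest.mark.parametrize(
        "n_iter,burnin,thin,chains,per_chain",
        [(6000, 1000, 2, 4, 2500), (2000, 500, 1, 2, 1500),
         (1001, 1, 5, 3, 200), (10, 2, 3, 1, 2)],
    )
    def test_exact_retained_counts(self, n_iter, burnin, thin, chains, per_chain):
        pc, total = cp.retained_draws(n_iter, burnin, thin, chains)
        assert pc == per_chain and total == per_chain * chains

    def test_burnin_must_be_shorter(self):
        with pytest.raises(ValueError):
            cp.retained_draws(100, 100, 1, 1)

    def test_fit_honors_accounting(self):
        data, _ = cp.simulate_cp_data(n=3, T=15, tau_step=7, seed=0)
        post = cp.fit_mcmc(cp.build_model(data), chains=2, n_iter=200,
                           burnin=60, thin=2, seed=1, rhat_warn=np.inf)
        assert post.per_chain == 70 and post.total_draws == 140


class TestDensity:
    def rand_params(self, model, rng):
        n, T = model.data.n, model.data.T
        return (rng.standard_normal(n), 0.1 * rng.standard_normal(T - 1),
                0.1 * rng.standard_normal(T - 1), 0.3 + rng.random(n))

    def test_marginal_matches_per_tau_brute_force(self, rng):
        for n, T in [(1, 10), (2, 14), (3, 20)]:
            data, _ = cp.simulate_cp_data(n=n, T=T, tau_step=T // 2,
                                          seed=n)
            model = cp.build_model(data)
            mu1, dp, dq, sy = self.rand_params(model, rng)
            brute = [model.loglik_given_tau(mu1, dp, dq, sy, k)
                     for k in model.candidates]
            assert model.marginal_loglik(mu1, dp, dq, sy) == pytest.approx(
                logsumexp(brute) - np.log(len(brute))
            )

    def test_linear_limit_identifies_break(self):
        # noiseless piecewise-linear rows with constant trends: the per-tau
        # likelihood at the generating parameters peaks at the true break
        tau = 13
        data, truth = cp.simulate_cp_data(n=4, T=30, tau_step=tau,
                                          slope_pre=0.02, slope_post=-0.06,
                                          sd_trend=0.0, sd_obs=0.0, seed=3)
        model = cp.build_model(data)
        t_ll = model.tau_loglik(truth["mu1"], truth["delta_pre"],
                                truth["delta_post"], np.full(4, 0.05))
        assert model.candidates[np.argmax(t_ll)] == tau

    def test_tau_outside_candidates_rejected(self):
        data, _ = cp.simulate_cp_data(n=2, T=12, tau_step=5, seed=0)
        model = cp.build_model(data)
        mu1 = np.zeros(2)
        d = np.zeros(11)
        with pytest.raises(ValueError):
            model.loglik_given_tau(mu1, d, d, np.ones(2), 0)


class TestFit:
    def test_tau_recovery_on_clear_change(self):
        data, truth = cp.simulate_cp_data(n=10, T=50, tau_step=30,
                                          slope_post=-0.06, sd_obs=0.3, seed=9)
        post = cp.fit_mcmc(cp.build_model(data), chains=2, n_iter=1200,
                           burnin=400, thin=2, seed=2, rhat_warn=np.inf)
        s = cp.summarize(post)
        assert abs(s["tau_steps"]["mean"] - 30) <= 2
        assert s["decrease_after_cp"]

    def test_white_noise_single_row_spreads_tau_mass(self):
        rng = np.random.default_rng(0)
        data = cp.CPData(Y=rng.standard_normal((1, 20)))
        post = cp.fit_mcmc(cp.build_model(data), chains=2, n_iter=800,
                           burnin=300, thin=1, seed=4, rhat_warn=np.inf)
        mass = post.tau_mass()
        # no step dominates and essentially every candidate keeps support
        assert mass.max() < 0.5
        assert (mass > 1e-3).sum() >= 10

    def test_null_difference_ci_covers_zero(self):
        data, _ = cp.simulate_cp_data(n=8, T=40, tau_step=20, slope_pre=0.01,
                                      slope_post=0.01, sd_obs=0.3, seed=6)
        post = cp.fit_mcmc(cp.build_model(data), chains=2, n_iter=1000,
                           burnin=400, thin=2, seed=5, rhat_warn=np.inf)
        s = cp.summarize(post)
        d = s["trend_difference"]
        assert d["ci_low"] <= 0.0 <= d["ci_high"]
        assert not s["decrease_after_cp"]

    def test_seeded_fit_reproducible(self):
        data, _ = cp.simulate_cp_data(n=3, T=20, tau_step=10, seed=1)
        m = cp.build_model(data)
        a = cp.fit_mcmc(m, chains=2, n_iter=300, burnin=100, thin=2, seed=7,
                        rhat_warn=np.inf)
        b = cp.fit_mcmc(m, chains=2, n_iter=300, burnin=100, thin=2, seed=7,
                        rhat_warn=np.inf)
        assert np.array_equal(a.draws, b.draws)


def test_alpha_change_point_recovered_from_simulated_eeg():
    """Full chain: EEG with an alpha-envelope bend 4.7 s before each report
    -> wavelet band-power course -> change-point fit.  With 20 simulated
    participants and the course decimated to 0.5-s steps (so neighboring
    observations carry ~independent noise) the posterior-mean change point
    lands within half a second of the generating one."""
    from mwbody import synth, timefreq

    courses = []
    for i in range(20):
        cfg = synth.SimConfig(duration=150.0, n_mw_reports=4, seed=300 + i,
                              condition="BF", min_report_gap=25.0)
        rec = synth.simulate_recording(cfg)
        rep = rec.events.query("type == 'mw_report'")["onset_s"].to_numpy()
        _, course = timefreq.prereport_power_course(
            rec.eeg, rec.fs_eeg, rep, band="alpha")
        courses.append(course)
    Y = np.stack(courses)[:, ::5]          # 0.1-s grid -> 0.5-s steps
    data = cp.CPData(Y=Y, step_dt=0.5, t0_offset=9.4)
    post = cp.fit_mcmc(cp.build_model(data), chains=2, n_iter=1200,
                       burnin=400, thin=2, seed=3, rhat_warn=np.inf)
    s = cp.summarize(post)
    assert abs(s["tau_seconds_before"]["mean"] - 4.7) <= 0.5
    assert s["decrease_after_cp"]
    assert s["tau_seconds_before"]["ci_low"] <= 4.7 <= s["tau_seconds_before"]["ci_high"]


class TestSummaries:
    def test_unit_conversion_matches_grid(self):
        data, _ = cp.simulate_cp_data(n=2, T=90, tau_step=47, seed=0,
                                      step_dt=0.1, t0_offset=9.4)
        assert data.step_to_seconds_before(47) == pytest.approx(4.7)
        assert data.step_to_seconds_before(0) == pytest.approx(9.4)

    def test_concentrated_mass_degenerate_interval(self):
        data, _ = cp.simulate_cp_data(n=2, T=20, tau_step=9, seed=0)
        model = cp.build_model(data)
        post = cp.fit_mcmc(model, chains=1, n_iter=120, burnin=20, thin=1,
                           seed=0, rhat_warn=np.inf)
        # overwrite with a point mass at candidate step 9
        post.tau_ll[:] = -1e8
        post.tau_ll[:, :, list(model.candidates).index(9)] = 0.0
        s = cp.summarize(post)
        assert s["tau_steps"]["mean"] == pytest.approx(9.0)
        assert s["tau_steps"]["ci_low"] == s["tau_steps"]["ci_high"] == 9.0

    def test_tau_mass_sums_to_one(self):
        data, _ = cp.simulate_cp_data(n=3, T=25, tau_step=12, seed=2)
        post = cp.fit_mcmc(cp.build_model(data), chains=2, n_iter=300,
                           burnin=100, thin=2, seed=3, rhat_warn=np.inf)
        assert post.tau_mass().sum() == pytest.approx(1.0)


class TestForwardSimulation:
    def test_zero_scales_give_piecewise_linear_rows(self):
        data, truth = cp.simulate_cp_data(n=3, T=30, tau_step=15,
                                          slope_pre=0.05, slope_post=-0.05,
                                          sd_trend=0.0, sd_obs=0.0, seed=0)
        row = data.Y[0]
        d2 = np.diff(row, 2)
        # the two series are each exactly linear; the switch between them
        # shows up only in the two second-differences straddling the break
        bad = np.flatnonzero(np.abs(d2) > 1e-9)
        assert set(bad) <= {15 - 2, 15 - 1}

    def test_seeded_reproducibility(self):
        a, _ = cp.simulate_from_prior(4, 20, seed=5)
        b, _ = cp.simulate_from_prior(4, 20, seed=5)
        assert np.array_equal(a.Y, b.Y)

    def test_prior_noise_scales_are_half_cauchy(self):
        _, truth = cp.simulate_from_prior(10_000, 10, seed=0)
        ks = stats.kstest(truth["sd_obs"], stats.halfcauchy(scale=5.0).cdf)
        assert ks.pvalue > 0.01

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            cp.simulate_cp_data(n=2, T=20, tau_step=19)
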