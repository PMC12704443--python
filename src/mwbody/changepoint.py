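"""Bayesian dual-trend state-space model with a discrete change point.

The model asks *when* a band-power time course, observed for several
participants on a common pre-report grid, switches from one smooth trend to
another.  Two latent state series share a per-participant starting level
``mu[n, 0]`` but evolve under different trends:

    Y[n, t] ~ Normal(mu_pre[n, t],  sigma_y[n])   if t <  tau
    Y[n, t] ~ Normal(mu_post[n, t], sigma_y[n])   if t >= tau

    mu[n, t]  = mu[n, t-1] + delta[t-1]           (per series)
    delta[t]  = delta[t-1] + sigma_delta * eps[t] ,  eps ~ Normal(0, 1)

with the trends ``delta`` shared across participants, half-Cauchy(0, 5)
priors on the observation scales, half-Cauchy(0, 2.5) on the trend
innovation scales, and a uniform prior on the change point ``tau`` over the
interior steps.

The bundled sampler is a blocked Gibbs scheme: the whole linear-Gaussian
latent block (starting levels and both trend series) is redrawn exactly
from its multivariate-normal full conditional each iteration (the pre/post
cross-precision vanishes because a time step loads on exactly one series),
``tau`` is drawn from its conditional categorical distribution via prefix
sums of pointwise log-likelihoods, and the scale parameters are updated by
univariate slice sampling.  The reported change-point posterior is the
Rao-Blackwellized average of the per-step conditional likelihoods over the
retained draws, and the tau-marginalized log density (log-sum over
candidate steps) is exposed on the model for cross-checking against
per-step fits.

Convergence is summarized by split-chain R-hat and effective sample size
for every sampled parameter; the convergence criterion is R-hat < 1.1.

Grid convention: step ``t`` lies ``t0_offset - t * step_dt`` seconds before
the report (step 0 at the window start), so a change point at step 47 of a
9.4-s window sampled at 0.1 s is 4.7 s before the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
from scipy.special import logsumexp

HC_SCALE_OBS = 5.0       # half-Cauchy scale, observation noise
HC_SCALE_TREND = 2.5     # half-Cauchy scale, trend innovation
SD_TREND_INIT = 1.0      # vague prior sd for the initial trend values
MU_PRIOR_SD_FACTOR = 10.0
RHAT_CRITERION = 1.1
LOG2PI = float(np.log(2.0 * np.pi))


def retained_draws(n_iter: int = 6000, burnin: int = 1000, thin: int = 2,
                   chains: int = 4) -> tuple[int, int]:
    """Exact draw accounting: (per-chain retained, total retained)."""
    if burnin >= n_iter:
        raise ValueError("burnin must be smaller than n_iter")
    per_chain = (n_iter - burnin) // thin
    return per_chain, per_chain * chains


@dataclass
class CPData:
    """Participant x step band-power matrix on the pre-report grid."""

    Y: np.ndarray
    step_dt: float = 0.1
    t0_offset: float = 9.4   # s before report of step 0

    def __post_init__(self):
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.Y.shape[1] < 10:
            raise ValueError("need at least 10 time steps")
        if not np.isfinite(self.Y).all():
            raise ValueError("Y must be finite (no missing interior values)")

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def T(self) -> int:
        return self.Y.shape[1]

    def step_to_seconds_before(self, step) -> np.ndarray:
        return self.t0_offset - np.asarray(step, dtype=float) * self.step_dt


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class CPModel:
    """Priors, candidate grid and density functions for one dataset."""

    data: CPData
    s_d1: float = SD_TREND_INIT
    mu_prior_sd_factor: float = MU_PRIOR_SD_FACTOR
    m0: np.ndarray = field(init=False)
    s_mu: np.ndarray = field(init=False)

    def __post_init__(self):
        Y = self.data.Y
        if self.data.T < 4:
            raise ValueError("too few steps for an interior change point")
        self.m0 = Y.mean(axis=1)
        sd = Y.std(axis=1)
        self.s_mu = self.mu_prior_sd_factor * np.where(sd > 0, sd, 1.0)

    @property
    def candidates(self) -> np.ndarray:
        """Candidate change-point steps (index of the first post-change step)."""
        return np.arange(1, self.data.T - 1)

    def curves(self, mu1, delta_pre, delta_post):
        """Latent level curves (n x T) implied by levels and trend series."""
        cpre = np.concatenate([[0.0], np.cumsum(delta_pre)])
        cpost = np.concatenate([[0.0], np.cumsum(delta_post)])
        return np.add.outer(mu1, cpre), np.add.outer(mu1, cpost)

    def tau_loglik(self, mu1, delta_pre, delta_post, sigma_y) -> np.ndarray:
        """Conditional data log-likelihood per candidate change point."""
        Y = self.data.Y
        m_pre, m_post = self.curves(mu1, delta_pre, delta_post)
        sy = np.asarray(sigma_y, dtype=float)[:, None]
        ll_pre = -0.5 * ((Y - m_pre) / sy) ** 2 - np.log(sy) - 0.5 * LOG2PI
        ll_post = -0.5 * ((Y - m_post) / sy) ** 2 - np.log(sy) - 0.5 * LOG2PI
        pre_cum = np.concatenate([[0.0], np.cumsum(ll_pre.sum(axis=0))])
        post_suf = np.concatenate([np.cumsum(ll_post.sum(axis=0)[::-1])[::-1], [0.0]])
        return pre_cum[self.candidates] + post_suf[self.candidates]

    def marginal_loglik(self, mu1, delta_pre, delta_post, sigma_y) -> float:
        """tau-marginalized log-likelihood: log-sum over candidates of the
        conditional likelihood under the uniform change-point prior."""
        t_ll = self.tau_loglik(mu1, delta_pre, delta_post, sigma_y)
        return float(logsumexp(t_ll) - np.log(t_ll.size))

    def loglik_given_tau(self, mu1, delta_pre, delta_post, sigma_y,
                         tau_step: int) -> float:
        """Conditional log-likelihood for one fixed change point (the
        brute-force route the marginalization is checked against)."""
        idx = int(tau_step) - 1
        if idx < 0 or idx >= self.data.T - 2:
            raise ValueError("tau outside the candidate range")
        return float(self.tau_loglik(mu1, delta_pre, delta_post, sigma_y)[idx])


def build_model(data: CPData, **overrides) -> CPModel:
    return CPModel(data=data, **overrides)


# ---------------------------------------------------------------------------
# Gibbs sampler internals
# ---------------------------------------------------------------------------

def _rw_precision(T1: int, s_init: float, s_step: float) -> np.ndarray:
    """Precision of a Gaussian random walk of length T1 with N(0, s_init^2)
    start and N(0, s_step^2) increments (tridiagonal)."""
    q = np.zeros((T1, T1))
    q[0, 0] = 1.0 / s_init**2
    w = 1.0 / s_step**2
    for t in range(1, T1):
        q[t, t] += w
        q[t - 1, t - 1] += w
        q[t, t - 1] -= w
        q[t - 1, t] -= w
    return q


def _count_outer(T: int, tau: int):
    """Gram matrices of the cumulative-sum designs.

    ``B_pre[t, s] = 1`` iff ``s < t < tau`` and ``B_post[t, s] = 1`` iff
    ``s < t`` and ``t >= tau`` (t in 0..T-1, s in 0..T-2).  Their Gram
    matrices depend only on max(s, s'), and the pre/post cross product is
    zero because every time step loads on exactly one series.
    """
    s = np.arange(T - 1)
    m = np.maximum.outer(s, s)
    gram_pre = np.maximum(0, tau - 1 - m).astype(float)
    gram_post = np.maximum(0, T - np.maximum(m + 1, tau)).astype(float)
    col_pre = np.maximum(0, tau - 1 - s).astype(float)    # 1_T' B_pre
    col_post = np.maximum(0, T - np.maximum(s + 1, tau)).astype(float)
    return gram_pre, gram_post, col_pre, col_post


def _precision_and_b(model: CPModel, tau: int, sigma_y, sd_step_pre: float,
                     sd_step_post: float):
    """Joint posterior precision and linear term of the latent block
    (mu1, delta_pre, delta_post) given tau and the scales."""
    Y = model.data.Y
    n, T = model.data.n, model.data.T
    D = n + 2 * (T - 1)
    w = 1.0 / np.asarray(sigma_y, dtype=float) ** 2      # per-participant
    wsum = w.sum()
    gram_pre, gram_post, col_pre, col_post = _count_outer(T, tau)

    P = np.zeros((D, D))
    b = np.zeros(D)
    sl_mu = slice(0, n)
    sl_pre = slice(n, n + T - 1)
    sl_post = slice(n + T - 1, D)

    P[sl_mu, sl_mu] = np.diag(T * w + 1.0 / model.s_mu**2)
    b[sl_mu] = w * Y.sum(axis=1) + model.m0 / model.s_mu**2
    P[sl_pre, sl_pre] = wsum * gram_pre
    P[sl_post, sl_post] = wsum * gram_post
    P[sl_mu, sl_pre] = np.outer(w, col_pre)
    P[sl_pre, sl_mu] = P[sl_mu, sl_pre].T
    P[sl_mu, sl_post] = np.outer(w, col_post)
    P[sl_post, sl_mu] = P[sl_mu, sl_post].T

    # data terms for the trend blocks: delta[s] multiplies Y[i, t] for the
    # time steps its series covers beyond s
    pre_t = np.arange(T) < tau
    ysum = (w[:, None] * Y).sum(axis=0)                  # weighted over rows
    cum_pre = np.cumsum((ysum * pre_t)[::-1])[::-1]      # sum_{t>=s, t<tau}
    cum_post = np.cumsum((ysum * ~pre_t)[::-1])[::-1]
    b[sl_pre] = cum_pre[1:]
    b[sl_post] = cum_post[1:]

    P[sl_pre, sl_pre] += _rw_precision(T - 1, model.s_d1, sd_step_pre)
    P[sl_post, sl_post] += _rw_precision(T - 1, model.s_d1, sd_step_post)
    return P, b


def _draw_latents(model: CPModel, tau: int, sigma_y, sd_step_pre: float,
                  sd_step_post: float, rng):
    """Exact draw of (mu1, delta_pre, delta_post) from the Gaussian full
    conditional given tau and the scales, by Cholesky of the joint precision."""
    n, T = model.data.n, model.data.T
    D = n + 2 * (T - 1)
    P, b = _precision_and_b(model, tau, sigma_y, sd_step_pre, sd_step_post)
    L = np.linalg.cholesky(P)
    mean = np.linalg.solve(L.T, np.linalg.solve(L, b))
    z = rng.standard_normal(D)
    theta = mean + np.linalg.solve(L.T, z)
    return theta[:n], theta[n : n + T - 1], theta[n + T - 1 : D]


def _tau_marginal_logweights(model: CPModel, sigma_y, sd_step_pre: float,
                             sd_step_post: float) -> np.ndarray:
    """Log p(tau | scales, Y) up to a constant, with the whole latent block
    integrated out analytically.

    Across candidates only the quadratic form and the log-determinant of the
    joint posterior precision differ; prior normalizers and the raw data
    term are tau-free and drop out.
    """
    out = np.empty(model.candidates.size)
    for j, tau in enumerate(model.candidates):
        P, b = _precision_and_b(model, int(tau), sigma_y, sd_step_pre,
                                sd_step_post)
        L = np.linalg.cholesky(P)
        half = np.linalg.solve(L, b)
        out[j] = 0.5 * float(half @ half) - float(np.log(np.diag(L)).sum())
    return out


def _slice_sample(logf, x0: float, rng, width: float = 1.0, max_steps: int = 50):
    """Univariate stepping-out slice sampler (Neal 2003)."""
    y = logf(x0) - rng.exponential()
    lo = x0 - width * rng.random()
    hi = lo + width
    for _ in range(max_steps):
        if logf(lo) < y:
            break
        lo -= width
    for _ in range(max_steps):
        if logf(hi) < y:
            break
        hi += width
    for _ in range(max_steps):
        x1 = rng.uniform(lo, hi)
        if logf(x1) >= y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


def _log_halfcauchy_logscale(log_s: float, gamma: float) -> float:
    # half-Cauchy density on s plus the Jacobian of the log transform
    s = np.exp(log_s)
    return -np.log(1.0 + (s / gamma) ** 2) + log_s


def _gibbs_chain(model: CPModel, n_iter: int, burnin: int, thin: int, seed: int,
                 collapse_every: int = 10):
    rng = np.random.default_rng(seed)
    Y = model.data.Y
    n, T = model.data.n, model.data.T
    cand = model.candidates

    # initialization from the data
    mu1 = Y[:, 0].copy()
    slopes = np.diff(Y, axis=1).mean(axis=0)
    d_pre = slopes.copy()
    d_post = slopes.copy()
    sy = np.maximum(Y.std(axis=1) * 0.5, 1e-3)
    log_sd_pre = np.log(max(np.abs(np.diff(slopes)).mean(), 1e-3))
    log_sd_post = log_sd_pre
    tau = int(rng.choice(cand))

    n_keep = (n_iter - burnin) // thin
    P_cols = n + 2 * (T - 1) + 2 + n + 1
    draws = np.empty((n_keep, P_cols))
    tau_ll_keep = np.empty((n_keep, cand.size))
    kept = 0
    for it in range(n_iter):
        sd_p = float(np.exp(log_sd_pre))
        sd_q = float(np.exp(log_sd_post))
        if it % collapse_every == 0:
            # collapsed move: tau given scales only, latents integrated out
            # (escapes modes the conditional update cannot leave), then the
            # latent block is reinstated from its conditional below
            lw = _tau_marginal_logweights(model, sy, sd_p, sd_q)
            wgt = np.exp(lw - lw.max())
            wgt /= wgt.sum()
            tau = int(rng.choice(cand, p=wgt))
        elif it > 0:
            t_ll = model.tau_loglik(mu1, d_pre, d_post, sy)
            wgt = np.exp(t_ll - t_ll.max())
            wgt /= wgt.sum()
            tau = int(rng.choice(cand, p=wgt))

        mu1, d_pre, d_post = _draw_latents(model, tau, sy, sd_p, sd_q, rng)

        # observation scales: per-participant slice update on log sigma
        m_pre, m_post = model.curves(mu1, d_pre, d_post)
        fit = np.where(np.arange(T)[None, :] < tau, m_pre, m_post)
        ssr = ((Y - fit) ** 2).sum(axis=1)
        for i in range(n):
            def logf(ls, ssr_i=ssr[i]):
                s2 = np.exp(2.0 * ls)
                return (-T * ls - 0.5 * ssr_i / s2
                        + _log_halfcauchy_logscale(ls, HC_SCALE_OBS))
            sy[i] = np.exp(_slice_sample(logf, float(np.log(sy[i])), rng))

        # trend innovation scales: a sufficiency (centered) slice update,
        # then an ancillarity (non-centered) one that rescales the trend
        # increments while holding the standardized innovations fixed --
        # the interweaving breaks the scale/series funnel
        k = T - 2
        for which in ("pre", "post"):
            d = d_pre if which == "pre" else d_post
            ls0 = log_sd_pre if which == "pre" else log_sd_post
            ss = float(((np.diff(d)) ** 2).sum())

            def logf_c(ls, ss=ss):
                s2 = np.exp(2.0 * ls)
                return (-k * ls - 0.5 * ss / s2
                        + _log_halfcauchy_logscale(ls, HC_SCALE_TREND))

            ls1 = _slice_sample(logf_c, ls0, rng)

            inc = np.diff(d) / np.exp(ls1)      # standardized innovations

            def logf_nc(ls, d0=d[0], inc=inc, which=which, tau=tau):
                d_new = d0 + np.concatenate(
                    [[0.0], np.cumsum(np.exp(ls) * inc)]
                )
                a = d_new if which == "pre" else d_pre
                b = d_post if which == "pre" else d_new
                ll = model.tau_loglik(mu1, a, b, sy)[tau - 1]
                return ll + _log_halfcauchy_logscale(ls, HC_SCALE_TREND)

            ls2 = _slice_sample(logf_nc, ls1, rng)
            d_new = d[0] + np.concatenate([[0.0], np.cumsum(np.exp(ls2) * inc)])
            if which == "pre":
                log_sd_pre = ls2
                d_pre = d_new
            else:
                log_sd_post = ls2
                d_post = d_new

        if it >= burnin and (it - burnin) % thin == thin - 1 and kept < n_keep:
            t_ll = model.tau_loglik(mu1, d_pre, d_post, sy)
            draws[kept, :n] = mu1
            draws[kept, n : n + T - 1] = d_pre
            draws[kept, n + T - 1 : n + 2 * (T - 1)] = d_post
            draws[kept, n + 2 * (T - 1)] = log_sd_pre
            draws[kept, n + 2 * (T - 1) + 1] = log_sd_post
            draws[kept, n + 2 * (T - 1) + 2 : P_cols - 1] = np.log(sy)
            draws[kept, P_cols - 1] = tau
            tau_ll_keep[kept] = t_ll
            kept += 1
    return draws[:kept], tau_ll_keep[:kept]


def param_names(n: int, T: int) -> list:
    names = [f"mu1[{i}]" for i in range(n)]
    names += [f"delta_pre[{t}]" for t in range(T - 1)]
    names += [f"delta_post[{t}]" for t in range(T - 1)]
    names += ["log_sigma_delta_pre", "log_sigma_delta_post"]
    names += [f"log_sigma_y[{i}]" for i in range(n)]
    names += ["tau"]
    return names


# ---------------------------------------------------------------------------
# fit / posterior
# ---------------------------------------------------------------------------

@dataclass
class CPPosterior:
    model: CPModel
    draws: np.ndarray           # chains x kept x P
    tau_ll: np.ndarray          # chains x kept x n_candidates
    n_iter: int
    burnin: int
    thin: int

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def per_chain(self) -> int:
        return self.draws.shape[1]

    @property
    def total_draws(self) -> int:
        return self.n_chains * self.per_chain

    def param_names(self) -> list:
        return param_names(self.model.data.n, self.model.data.T)

    def tau_mass(self) -> np.ndarray:
        """Rao-Blackwellized posterior mass over candidate change points."""
        ll = self.tau_ll.reshape(-1, self.tau_ll.shape[-1])
        w = np.exp(ll - ll.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        return w.mean(axis=0)

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def trend_series(self):
        """Per-draw trend series delta_pre, delta_post (flat draws x (T-1))."""
        n, T = self.model.data.n, self.model.data.T
        th = self.flat()
        return th[:, n : n + T - 1], th[:, n + T - 1 : n + 2 * (T - 1)]

    def diagnostics(self):
        """Split-chain R-hat and bulk ESS per sampled parameter.

        A parameter that is constant across all draws (e.g. a change point
        with all its mass on one step) has undefined R-hat and is reported
        as NaN.
        """
        da = az.convert_to_dataset({"theta": self.draws})
        with np.errstate(invalid="ignore", divide="ignore"):
            rhat = az.rhat(da)["theta"].values
            ess = az.ess(da)["theta"].values
        return rhat, ess

    def max_rhat(self) -> float:
        rhat, _ = self.diagnostics()
        finite = rhat[np.isfinite(rhat)]
        return float(finite.max()) if finite.size else float("nan")


def fit_mcmc(
    model: CPModel,
    chains: int = 4,
    n_iter: int = 6000,
    burnin: int = 1000,
    thin: int = 2,
    seed: int = 0,
    rhat_warn: float = RHAT_CRITERION,
) -> CPPosterior:
    """Run the bundled blocked Gibbs sampler.

    The default regime retains (6000 - 1000) / 2 = 2500 draws per chain,
    10,000 in total over 4 chains.  Warns when any parameter's split-chain
    R-hat is at or above 1.1.
    """
    per_chain, _ = retained_draws(n_iter, burnin, thin, chains)
    ss = np.random.SeedSequence(seed)
    all_draws, all_tau = [], []
    for child in ss.spawn(chains):
        d, t_ll = _gibbs_chain(model, n_iter, burnin, thin, child)
        if not np.isfinite(d).all():
            raise RuntimeError("sampler produced non-finite draws")
        all_draws.append(d)
        all_tau.append(t_ll)
    post = CPPosterior(model=model, draws=np.stack(all_draws),
                       tau_ll=np.stack(all_tau), n_iter=n_iter,
                       burnin=burnin, thin=thin)
    if post.per_chain != per_chain:
        raise RuntimeError("draw accounting mismatch")
    mr = post.max_rhat()
    if mr >= rhat_warn:
        import warnings

        warnings.warn(f"max R-hat {mr:.3f} >= {rhat_warn}: chains may not have converged")
    return post


def _central_interval_from_mass(mass: np.ndarray, values: np.ndarray, level=0.95):
    cum = np.cumsum(mass)
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    lo = values[min(np.searchsorted(cum, lo_q), values.size - 1)]
    hi = values[min(np.searchsorted(cum, hi_q), values.size - 1)]
    return float(lo), float(hi)


def summarize(post: CPPosterior, seed: int = 0, level: float = 0.95) -> dict:
    """Posterior report: change point (steps and seconds before report; mean,
    mode and central CI), pre/post trend means with CI, their difference
    (pre - post) with CI and a decrease verdict, plus diagnostics."""
    data = post.model.data
    cand = post.model.candidates
    mass = post.tau_mass()
    tau_mean = float((mass * cand).sum())
    tau_mode = int(cand[np.argmax(mass)])
    tau_lo, tau_hi = _central_interval_from_mass(mass, cand, level)

    # per-draw tau sample -> segment-mean trends
    rng = np.random.default_rng(seed)
    ll = post.tau_ll.reshape(-1, post.tau_ll.shape[-1])
    w = np.exp(ll - ll.max(axis=1, keepdims=True))
    w /= w.sum(axis=1, keepdims=True)
    u = rng.random(w.shape[0])
    tau_draw = cand[(np.cumsum(w, axis=1) < u[:, None]).sum(axis=1)]
    d_pre, d_post = post.trend_series()
    n_draws = d_pre.shape[0]
    trend_pre = np.empty(n_draws)
    trend_post = np.empty(n_draws)
    for i in range(n_draws):
        s = int(tau_draw[i])
        trend_pre[i] = d_pre[i, : max(1, s - 1)].mean()
        trend_post[i] = d_post[i, s - 1 :].mean()
    diff = trend_pre - trend_post

    def ci(x):
        lo, hi = np.quantile(x, [(1 - level) / 2, 1 - (1 - level) / 2])
        return dict(mean=float(x.mean()), ci_low=float(lo), ci_high=float(hi))

    rhat, ess = post.diagnostics()
    rhat_f = rhat[np.isfinite(rhat)]
    ess_f = ess[np.isfinite(ess)]
    sec = data.step_to_seconds_before
    return dict(
        tau_steps=dict(mean=tau_mean, mode=tau_mode, ci_low=float(tau_lo),
                       ci_high=float(tau_hi)),
        tau_seconds_before=dict(
            mean=float(sec(tau_mean)), mode=float(sec(tau_mode)),
            ci_low=float(sec(tau_hi)), ci_high=float(sec(tau_lo)),
        ),
        trend_pre=ci(trend_pre),
        trend_post=ci(trend_post),
        trend_difference=ci(diff),
        decrease_after_cp=bool(np.quantile(diff, (1 - level) / 2) > 0),
        tau_mass=mass,
        max_rhat=float(rhat_f.max()) if rhat_f.size else float("nan"),
        min_ess=float(ess_f.min()) if ess_f.size else float("nan"),
        n_draws=post.total_draws,
    )


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def simulate_cp_data(
    n: int = 10,
    T: int = 50,
    tau_step: int = 25,
    slope_pre: float = 0.0,
    slope_post: float = -0.05,
    sd_trend: float = 0.0,
    sd_obs: float = 0.3,
    level_scale: float = 1.0,
    seed: int = 0,
    step_dt: float = 0.1,
    t0_offset: float = 9.4,
):
    """Generate data with a known change point and (optionally) wandering
    trends.  ``sd_trend = 0`` gives two exact straight lines with a slope
    break at ``tau_step``.  Returns ``(CPData, truth_dict)``."""
    if not 1 <= tau_step <= T - 2:
        raise ValueError("tau_step must be an interior candidate step")
    rng = np.random.default_rng(seed)
    d_pre = slope_pre + np.concatenate(
        [[0.0], np.cumsum(sd_trend * rng.standard_normal(T - 2))]
    )
    d_post = slope_post + np.concatenate(
        [[0.0], np.cumsum(sd_trend * rng.standard_normal(T - 2))]
    )
    mu1 = level_scale * rng.normal(0.0, 1.0, size=n)
    cpre = np.concatenate([[0.0], np.cumsum(d_pre)])
    cpost = np.concatenate([[0.0], np.cumsum(d_post)])
    t_idx = np.arange(T)
    level = np.where(t_idx[None, :] < tau_step,
                     mu1[:, None] + cpre[None, :],
                     mu1[:, None] + cpost[None, :])
    Y = level + sd_obs * rng.standard_normal((n, T))
    data = CPData(Y=Y, step_dt=step_dt, t0_offset=t0_offset)
    truth = dict(tau_step=tau_step, delta_pre=d_pre, delta_post=d_post,
                 mu1=mu1, sd_obs=sd_obs)
    return data, truth


def simulate_from_prior(n: int, T: int, seed: int = 0, step_dt: float = 0.1,
                        t0_offset: float = 9.4):
    """Forward-sample trends, states, tau and noise from the prior.

    Enables simulation-based calibration; heavy half-Cauchy tails are drawn
    as-is.  Returns ``(CPData, truth_dict)``.
    """
    rng = np.random.default_rng(seed)
    sd_pre = abs(rng.standard_cauchy()) * HC_SCALE_TREND
    sd_post = abs(rng.standard_cauchy()) * HC_SCALE_TREND
    sy = np.abs(rng.standard_cauchy(n)) * HC_SCALE_OBS
    tau = int(rng.integers(1, T - 1))
    d_pre = rng.normal(0, SD_TREND_INIT) + np.concatenate(
        [[0.0], np.cumsum(sd_pre * rng.standard_normal(T - 2))]
    )
    d_post = rng.normal(0, SD_TREND_INIT) + np.concatenate(
        [[0.0], np.cumsum(sd_post * rng.standard_normal(T - 2))]
    )
    mu1 = rng.normal(0.0, 1.0, size=n)
    cpre = np.concatenate([[0.0], np.cumsum(d_pre)])
    cpost = np.concatenate([[0.0], np.cumsum(d_post)])
    t_idx = np.arange(T)
    level = np.where(t_idx[None, :] < tau, mu1[:, None] + cpre[None, :],
                     mu1[:, None] + cpost[None, :])
    Y = level + sy[:, None] * rng.standard_normal((n, T))
    data = CPData(Y=Y, step_dt=step_dt, t0_offset=t0_offset)
    truth = dict(tau_step=tau, sd_trend_pre=sd_pre, sd_trend_post=sd_post,
                 sd_obs=sy, delta_pre=d_pre, delta_post=d_post, mu1=mu1)
    return data, truth
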