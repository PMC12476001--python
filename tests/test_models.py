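"""Model mathematics: the Rescorla–Wagner recursion, model means,
likelihood, priors (against independent scipy oracles) and the packed
log-posterior used by the sampler."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import trialwise as tw
from trialwise import models as M
from trialwise._logp import PackedModel, TrialData
from conftest import make_participant_rows


class TestRwUpdate:
    def test_full_update_to_outcome(self):
        assert tw.rw_update(0.0, 1, rate_paired=1 - 1e-12, rate_unpaired=0.5) \
            == pytest.approx(1.0)

    def test_zero_prediction_error(self):
        assert tw.rw_update(1.0, 1, 0.3, 0.7) == pytest.approx(1.0)

    def test_unpaired_decay(self):
        assert tw.rw_update(0.5, 0, 0.9, 0.5) == pytest.approx(0.25)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tw.rw_update(1.5, 1, 0.5, 0.5)
        with pytest.raises(ValueError):
            tw.rw_update(0.5, 2, 0.5, 0.5)
        with pytest.raises(ValueError):
            tw.rw_update(0.5, 1, 0.0, 0.5)


class TestTrajectory:
    def test_all_habituation_strengths_zero(self):
        rows = make_participant_rows(["CSP", "GS1", "CSP", "GS2"],
                                     [0, 0, 0, 0], block="HAB")
        np.testing.assert_array_equal(
            tw.compute_trajectory(rows, 0.7, 0.3), np.zeros(4))

    def test_rate_one_alternation(self):
        rows = make_participant_rows(["CSP", "CSP", "CSP"], [1, 0, 1])
        traj = tw.compute_trajectory(rows, 1 - 1e-12, 1 - 1e-12)
        # strength used at each trial is pre-update; post-update values 1,0,1
        np.testing.assert_allclose(traj, [0.0, 1.0, 0.0], atol=1e-9)

    def test_geometric_approach(self):
        rows = make_participant_rows(["CSP", "CSP", "CSP", "GS1"], [1, 1, 1, 0])
        traj = tw.compute_trajectory(rows, 0.5, 1e-12)
        np.testing.assert_allclose(traj, [0.0, 0.5, 0.75, 0.875], atol=1e-9)

    def test_unordered_trials_rejected(self):
        rows = make_participant_rows(["CSP", "GS1"], [1, 0])
        rows["trial"] = [2, 1]
        with pytest.raises(ValueError, match="increasing"):
            tw.compute_trajectory(rows, 0.5, 0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()),
                    min_size=1, max_size=40),
           st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    def test_strength_stays_in_unit_interval(self, seq, rp, ru):
        cues = ["CSP" if is_csp else "GS1" for is_csp, _ in seq]
        paired = [int(is_csp and p) for is_csp, p in seq]
        rows = make_participant_rows(cues, paired)
        traj = tw.compute_trajectory(rows, rp, ru)
        assert np.all((traj >= 0.0) & (traj <= 1.0))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(1, 30), st.floats(0.01, 0.99))
    def test_all_paired_sequence_is_monotone(self, n, rp):
        rows = make_participant_rows(["CSP"] * n, [1] * n)
        traj = tw.compute_trajectory(rows, rp, 0.5)
        assert np.all(np.diff(traj) >= 0)


def _params(n=2, with_rates=False):
    kw = {}
    if with_rates:
        kw = dict(rate_paired=np.full(n, 0.4), rate_unpaired=np.full(n, 0.6))
    return M.ParticipantParams(intercept=np.full(n, 0.44),
                               adaptation=np.full(n, -0.005),
                               sigma=np.full(n, 1.0), **kw)


class TestPredictMu:
    def test_m1_intercept_at_centered_zero(self):
        rows = make_participant_rows(["GS1"], [0])
        rows["trial"] = [1]
        p = M.ParticipantParams(intercept=[0.44], adaptation=[-0.005], sigma=[1.0])
        mu = tw.predict_mu("m1", p, None, None, rows, n_trials_total=1)
        assert mu[0] == pytest.approx(0.44)

    def test_m3_zero_strength_equals_m1(self, small_table):
        p = _params(3, with_rates=True)
        ce = M.CueEffects(beta_scaling=np.array([1.0, 0.5, 0.2, 0.1]))
        mu1 = tw.predict_mu("m1", p, None, None, small_table)
        mu3 = tw.predict_mu("m3", p, ce, np.zeros(len(small_table)), small_table)
        np.testing.assert_allclose(mu1, mu3)

    def test_m2_zero_betas_equals_m1(self, small_table):
        p = _params(3)
        ce = M.CueEffects(beta_cue=np.zeros((4, 4)))
        mu1 = tw.predict_mu("m1", p, None, None, small_table)
        mu2 = tw.predict_mu("m2", p, ce, None, small_table)
        np.testing.assert_allclose(mu1, mu2)

    def test_unknown_model_rejected(self, small_table):
        with pytest.raises(ValueError, match="model"):
            tw.predict_mu("m9", _params(3), None, None, small_table)


class TestLogLikelihood:
    def _one_trial(self, amplitude, intercept, sigma):
        rows = make_participant_rows(["GS1"], [0])
        rows["amplitude"] = [amplitude]
        p = M.ParticipantParams(intercept=[intercept], adaptation=[0.0],
                                sigma=[sigma])
        return tw.log_likelihood("m1", p, None, rows, n_trials_total=1)[0]

    def test_at_mean_unit_sigma(self):
        assert self._one_trial(0.3, 0.3, 1.0) == pytest.approx(-0.9189385332046727)

    def test_one_sd_away(self):
        assert self._one_trial(1.3, 0.3, 1.0) == pytest.approx(-1.4189385332046727)

    def test_doubling_sigma_costs_log2_at_mean(self):
        assert self._one_trial(0.3, 0.3, 2.0) - self._one_trial(0.3, 0.3, 1.0) \
            == pytest.approx(-math.log(2))

    def test_sigma_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            M.ParticipantParams(intercept=[0.0], adaptation=[0.0], sigma=[0.0])

    def test_missing_values_rejected(self, small_table):
        with pytest.raises(ValueError, match="value"):
            tw.log_likelihood("m1", _params(3), None, small_table)

    def test_m2_m3_reduce_to_m1(self, small_table):
        filled = small_table.copy()
        filled["amplitude"] = filled["amplitude"].fillna(0.0)
        p = _params(3, with_rates=True)
        ll1 = tw.log_likelihood("m1", p, None, filled)
        ll2 = tw.log_likelihood("m2", p, M.CueEffects(beta_cue=np.zeros((4, 4))),
                                filled)
        ll3 = tw.log_likelihood("m3", p, M.CueEffects(beta_scaling=np.zeros(4)),
                                filled)
        np.testing.assert_allclose(ll1, ll2)
        np.testing.assert_allclose(ll1, ll3)


class TestConstrain:
    def test_exp_tanh_logit_identities(self):
        h = M.Hyperparams(tau_raw=0.0, rho_raw=0.0,
                          rate_paired_avg_raw=0.0, rate_unpaired_avg_raw=0.0,
                          sigma_rate_paired_raw=0.0, sigma_rate_unpaired_raw=0.0)
        nat = tw.constrain(h)
        assert nat["tau"] == pytest.approx(1.0)
        assert nat["rho"] == pytest.approx(0.0)
        assert nat["rate_paired_avg"] == pytest.approx(0.5)

    def test_scales_positive_for_any_raw(self):
        h = M.Hyperparams(tau_raw=-40.0, sigma_intercept_raw=-15.0)
        nat = tw.constrain(h)
        assert nat["tau"] > 0 and nat["sigma_intercept"] > 0
        assert -1 < M.constrain(M.Hyperparams(rho_raw=50.0))["rho"] <= 1


def _scipy_log_prior(model, params, hyper, ce):
    """Independent scalar-by-scalar prior summation via scipy."""
    n = params.n
    df = n - 1
    nat = tw.constrain(hyper)
    total = stats.t.logpdf(params.sigma, df, loc=hyper.sigma_avg,
                           scale=nat["tau"]).sum()
    cov = np.array([
        [nat["sigma_intercept"] ** 2,
         nat["rho"] * nat["sigma_intercept"] * nat["sigma_adaptation"]],
        [nat["rho"] * nat["sigma_intercept"] * nat["sigma_adaptation"],
         nat["sigma_adaptation"] ** 2]])
    mvt = stats.multivariate_t(loc=[hyper.intercept_avg, hyper.adaptation_avg],
                               shape=cov, df=df)
    total += mvt.logpdf(np.column_stack([params.intercept, params.adaptation])).sum()
    for name in ("sigma_avg", "tau_raw", "intercept_avg", "adaptation_avg",
                 "sigma_intercept_raw", "sigma_adaptation_raw", "rho_raw"):
        m, s = M.PRIORS[name]
        total += stats.norm.logpdf(getattr(hyper, name), m, s)
    if model == "m2":
        total += stats.t.logpdf(ce.beta_cue, 15, loc=0.0,
                                scale=nat["sigma_cue"]).sum()
        total += stats.norm.logpdf(hyper.sigma_cue_raw, *M.PRIORS["sigma_cue_raw"])
    if model == "m3":
        for which in ("paired", "unpaired"):
            raw = M.logit(getattr(params, f"rate_{which}"))
            total += stats.t.logpdf(raw, df,
                                    loc=getattr(hyper, f"rate_{which}_avg_raw"),
                                    scale=nat[f"sigma_rate_{which}"]).sum()
            total += stats.norm.logpdf(getattr(hyper, f"rate_{which}_avg_raw"),
                                       *M.PRIORS[f"rate_{which}_avg_raw"])
            total += stats.norm.logpdf(getattr(hyper, f"sigma_rate_{which}_raw"),
                                       *M.PRIORS[f"sigma_rate_{which}_raw"])
        total += stats.t.logpdf(ce.beta_scaling, 3, loc=hyper.beta_scaling_avg,
                                scale=nat["sigma_beta_scaling"]).sum()
        total += stats.norm.logpdf(hyper.beta_scaling_avg,
                                   *M.PRIORS["beta_scaling_avg"])
        total += stats.norm.logpdf(hyper.sigma_beta_scaling_raw,
                                   *M.PRIORS["sigma_beta_scaling_raw"])
    return float(total)


@pytest.mark.parametrize("model", ["m1", "m2", "m3"])
def test_log_prior_matches_scipy_oracle(model):
    rng = np.random.default_rng(5)
    n = 4
    params = M.ParticipantParams(
        intercept=rng.normal(0.4, 0.2, n), adaptation=rng.normal(-0.005, 0.002, n),
        sigma=rng.uniform(0.4, 1.2, n),
        rate_paired=rng.uniform(0.2, 0.8, n) if model == "m3" else None,
        rate_unpaired=rng.uniform(0.2, 0.8, n) if model == "m3" else None)
    hyper = M.Hyperparams(
        intercept_avg=0.3, adaptation_avg=-0.004, sigma_intercept_raw=-0.8,
        sigma_adaptation_raw=-4.0, rho_raw=0.3, sigma_avg=0.9, tau_raw=-2.5,
        sigma_cue_raw=-0.4 if model == "m2" else None,
        rate_paired_avg_raw=0.2 if model == "m3" else None,
        rate_unpaired_avg_raw=-0.1 if model == "m3" else None,
        sigma_rate_paired_raw=0.5 if model == "m3" else None,
        sigma_rate_unpaired_raw=0.4 if model == "m3" else None,
        beta_scaling_avg=0.1 if model == "m3" else None,
        sigma_beta_scaling_raw=-0.3 if model == "m3" else None)
    ce = None
    if model == "m2":
        ce = M.CueEffects(beta_cue=rng.normal(0, 0.3, (4, 4)))
    elif model == "m3":
        ce = M.CueEffects(beta_scaling=rng.normal(0, 0.3, 4))
    mine = tw.log_prior(model, params, hyper, ce)
    oracle = _scipy_log_prior(model, params, hyper, ce)
    assert mine == pytest.approx(oracle, abs=1e-8)


def test_log_prior_rejects_single_participant():
    p = M.ParticipantParams(intercept=[0.0], adaptation=[0.0], sigma=[1.0])
    with pytest.raises(ValueError):
        tw.log_prior("m1", p, M.Hyperparams())


def test_packed_logp_equals_public_api_density(small_table, small_data):
    """The sampler's packed log posterior equals the public-API prior +
    likelihood plus the documented change-of-variables terms (log-sigma
    Jacobian; for M3 the non-centered rate scale factors)."""
    for model in ("m1", "m2", "m3"):
        pm = PackedModel(model, small_data)
        theta = pm.initial_theta(np.random.default_rng(3))
        sl = pm.sl
        n = small_data.n_participants
        h = theta[sl.hyper]
        kw = {}
        ce = None
        extra = 0.0
        if model == "m2":
            kw["sigma_cue_raw"] = theta[sl.sigma_cue_raw]
            ce = M.CueEffects(beta_cue=theta[sl.beta_cue].reshape(4, 4))
        if model == "m3":
            m3h = theta[sl.m3_hyper]
            kw.update(rate_paired_avg_raw=m3h[0], rate_unpaired_avg_raw=m3h[1],
                      sigma_rate_paired_raw=m3h[2], sigma_rate_unpaired_raw=m3h[3],
                      beta_scaling_avg=m3h[4], sigma_beta_scaling_raw=m3h[5])
            ce = M.CueEffects(beta_scaling=theta[sl.beta_scaling])
            extra = n * (m3h[2] + m3h[3])  # d(raw rate)/dz Jacobian
        hyper = M.Hyperparams(intercept_avg=h[0], adaptation_avg=h[1],
                              sigma_intercept_raw=h[2], sigma_adaptation_raw=h[3],
                              rho_raw=h[4], sigma_avg=h[5], tau_raw=h[6], **kw)
        rate_kw = {}
        if model == "m3":
            m3h = theta[sl.m3_hyper]
            rate_kw = dict(
                rate_paired=M.inv_logit(m3h[0] + math.exp(m3h[2]) * theta[sl.rate_p_raw]),
                rate_unpaired=M.inv_logit(m3h[1] + math.exp(m3h[3]) * theta[sl.rate_u_raw]))
        params = M.ParticipantParams(intercept=theta[sl.intercept],
                                     adaptation=theta[sl.adaptation],
                                     sigma=np.exp(theta[sl.log_sigma]), **rate_kw)
        filled = small_data.table.copy()
        amp = filled["amplitude"].to_numpy()
        amp[small_data.missing_rows] = theta[sl.missing]
        filled["amplitude"] = amp
        api_lp = tw.log_prior(model, params, hyper, ce) \
            + tw.log_likelihood(model, params, ce, filled).sum() \
            + theta[sl.log_sigma].sum() + extra
        packed_lp = pm.logp_grad(theta)[0]
        assert packed_lp == pytest.approx(api_lp, abs=1e-7)


@pytest.mark.parametrize("model", ["m1", "m2", "m3"])
def test_packed_gradient_matches_finite_differences(model, small_data):
    pm = PackedModel(model, small_data)
    rng = np.random.default_rng(11)
    theta = pm.initial_theta(rng) + rng.normal(0, 0.1, pm.n_params)
    lp, grad = pm.logp_grad(theta)
    idx = rng.choice(pm.n_params, size=min(25, pm.n_params), replace=False)
    eps = 1e-6
    for i in idx:
        up, dn = theta.copy(), theta.copy()
        up[i] += eps
        dn[i] -= eps
        fd = (pm.logp_grad(up)[0] - pm.logp_grad(dn)[0]) / (2 * eps)
        assert grad[i] == pytest.approx(fd, rel=1e-3, abs=1e-4)


def test_model_parameter_counts():
    """M1 samples 3 per participant + 7 hypers (79 at 24 participants);
    M3 adds 2 rates per participant + 4 scalings + 6 hypers (137); M2's
    cue-effect array has 16 entries."""
    design = tw.generate_design(24, seed=1)
    truth = tw.default_true_params(24, seed=2)
    table = tw.simulate_amplitudes(design, truth, seed=3)
    data = TrialData(table)
    assert PackedModel("m1", data).n_model_params == 79
    assert PackedModel("m3", data).n_model_params == 137
    m2 = PackedModel("m2", data)
    assert len([nm for nm in m2.param_names if nm.startswith("beta_cue[")]) == 16
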