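"""Packed log-posterior and analytic gradients for the amplitude models.

The sampler works on a flat unconstrained vector; this module owns the
packing layout, the vectorized forward pass (predicted means, imputed
amplitudes) and hand-derived gradients of log prior + log likelihood.
Positive parameters are sampled on the log scale; participant sigmas
carry the +log(sigma) Jacobian because their Student-T prior is stated
on the natural scale, while hyperparameters whose priors are stated on
the raw scale contribute no Jacobian (see `models`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import models as M
from .design import BLOCKS, CUES

_LOG_2PI = math.log(2.0 * math.pi)


class TrialData:
    """Preprocessed arrays for one trial table (possibly many participants)."""

    def __init__(self, table: pd.DataFrame, n_trials_total: int | None = None):
        table = table.sort_values(["participant", "trial"], kind="mergesort")
        self.table = table.reset_index(drop=True)
        self.participants = np.unique(table["participant"].to_numpy())
        self.n_participants = len(self.participants)
        pid = self.table["participant"].to_numpy()
        self.p_idx = np.searchsorted(self.participants, pid)
        self.trial = self.table["trial"].to_numpy()
        self.n_trials_total = n_trials_total or int(self.trial.max())
        self.tc = self.trial - (self.n_trials_total + 1) / 2.0
        self.cue_idx, self.block_idx = M._indices(self.table)
        self.paired = self.table["paired"].to_numpy().astype(float)
        amp = self.table["amplitude"].to_numpy(dtype=float) \
            if "amplitude" in self.table else np.full(len(self.table), np.nan)
        self.amp = amp
        self.obs_mask = np.isfinite(amp)
        self.missing_rows = np.flatnonzero(~self.obs_mask)
        self.n_obs = int(self.obs_mask.sum())
        self.n_missing = len(self.missing_rows)
        self.n_rows = len(self.table)
        # CS+ event structure for the learning trajectory: per participant,
        # the time-ordered CSP trials; k[i] counts CSP trials of the same
        # participant strictly before row i, indexing into the strength
        # array S of shape (max_events + 1, n_participants).
        is_csp = self.cue_idx == 0
        counts = np.bincount(self.p_idx[is_csp], minlength=self.n_participants)
        E = int(counts.max()) if len(counts) else 0
        self.n_events = E
        self.event_outcome = np.zeros((E, self.n_participants))
        self.event_valid = np.zeros((E, self.n_participants), dtype=bool)
        self.k = np.zeros(self.n_rows, dtype=np.int64)
        seen = np.zeros(self.n_participants, dtype=np.int64)
        for i in range(self.n_rows):
            p = self.p_idx[i]
            self.k[i] = seen[p]
            if is_csp[i]:
                self.event_outcome[seen[p], p] = self.paired[i]
                self.event_valid[seen[p], p] = True
                seen[p] += 1
        self.is_csp = is_csp


def _strength_kernel(outcome, valid, rate_p, rate_u, S, dSp, dSu):
    E, n = outcome.shape
    for p in range(n):
        s = 0.0
        dp = 0.0
        du = 0.0
        for e in range(E):
            if valid[e, p]:
                o = outcome[e, p]
                err = o - s
                if o == 1.0:
                    r = rate_p[p]
                    dp = dp * (1.0 - r) + err
                    du = du * (1.0 - r)
                else:
                    r = rate_u[p]
                    dp = dp * (1.0 - r)
                    du = du * (1.0 - r) + err
                s = s + r * err
            S[e + 1, p] = s
            dSp[e + 1, p] = dp
            dSu[e + 1, p] = du


try:  # pragma: no cover - exercised implicitly
    from numba import njit
    _strength_kernel = njit(cache=False)(_strength_kernel)
except ImportError:  # pragma: no cover
    pass


def compute_strengths(outcome: np.ndarray, valid: np.ndarray,
                      rate_p: np.ndarray, rate_u: np.ndarray,
                      with_grad: bool = False):
    """Associative strength after each CSP event, vectorized over
    participants.  Returns S of shape (E+1, n); S[e] is the strength
    after e updates.  With ``with_grad`` also returns the forward-mode
    derivatives dS/d(rate_paired), dS/d(rate_unpaired)."""
    E, n = outcome.shape
    S = np.zeros((E + 1, n))
    dSp = np.zeros((E + 1, n))
    dSu = np.zeros((E + 1, n))
    _strength_kernel(np.ascontiguousarray(outcome),
                     np.ascontiguousarray(valid),
                     np.ascontiguousarray(rate_p, dtype=np.float64),
                     np.ascontiguousarray(rate_u, dtype=np.float64),
                     S, dSp, dSu)
    if with_grad:
        return S, dSp, dSu
    return S


@dataclass
class _Slices:
    intercept: slice
    adaptation: slice
    log_sigma: slice
    hyper: slice          # i_avg, a_avg, sI_raw, sA_raw, rho_raw, sigma_avg, tau_raw
    beta_cue: slice | None
    sigma_cue_raw: int | None
    rate_p_raw: slice | None
    rate_u_raw: slice | None
    beta_scaling: slice | None
    m3_hyper: slice | None  # rp_avg, ru_avg, s_rp, s_ru, bs_avg, s_bs
    missing: slice


class PackedModel:
    """Flat-vector parameterization of one amplitude model on one dataset."""

    def __init__(self, tag: str, data: TrialData):
        if tag not in M.MODEL_TAGS:
            raise ValueError(f"unknown model tag {tag!r}")
        self.tag = tag
        self.data = data
        n = data.n_participants
        if n < 2:
            raise ValueError("need at least 2 participants")
        self.df = n - 1
        pos = 0

        def take(k):
            nonlocal pos
            s = slice(pos, pos + k)
            pos += k
            return s

        intercept = take(n)
        adaptation = take(n)
        log_sigma = take(n)
        hyper = take(7)
        beta_cue = sigma_cue_raw = None
        rate_p = rate_u = beta_scaling = m3_hyper = None
        if tag == "m2":
            beta_cue = take(16)
            sigma_cue_raw = pos
            pos += 1
        elif tag == "m3":
            rate_p = take(n)
            rate_u = take(n)
            beta_scaling = take(4)
            m3_hyper = take(6)
        self.n_model_params = pos
        missing = take(data.n_missing)
        self.n_params = pos
        self.sl = _Slices(intercept, adaptation, log_sigma, hyper, beta_cue,
                          sigma_cue_raw, rate_p, rate_u, beta_scaling,
                          m3_hyper, missing)
        self.param_names = self._names()

    # -- naming ------------------------------------------------------------
    def _names(self) -> list[str]:
        ids = self.data.participants
        names = []
        names += [f"intercept[{p}]" for p in ids]
        names += [f"adaptation[{p}]" for p in ids]
        names += [f"log_sigma[{p}]" for p in ids]
        names += ["intercept_avg", "adaptation_avg", "sigma_intercept_raw",
                  "sigma_adaptation_raw", "rho_raw", "sigma_avg", "tau_raw"]
        if self.tag == "m2":
            names += [f"beta_cue[{c},{b}]" for c in CUES for b in BLOCKS]
            names += ["sigma_cue_raw"]
        elif self.tag == "m3":
            names += [f"rate_paired_z[{p}]" for p in ids]
            names += [f"rate_unpaired_z[{p}]" for p in ids]
            names += [f"beta_scaling[{c}]" for c in CUES]
            names += ["rate_paired_avg_raw", "rate_unpaired_avg_raw",
                      "sigma_rate_paired_raw", "sigma_rate_unpaired_raw",
                      "beta_scaling_avg", "sigma_beta_scaling_raw"]
        d = self.data
        names += [f"amp_missing[{d.participants[d.p_idx[i]]},{d.trial[i]}]"
                  for i in d.missing_rows]
        return names

    # -- initialization ----------------------------------------------------
    def initial_theta(self, rng: np.random.Generator) -> np.ndarray:
        d = self.data
        theta = np.zeros(self.n_params)
        means = np.zeros(d.n_participants)
        sds = np.ones(d.n_participants)
        for j in range(d.n_participants):
            a = d.amp[(d.p_idx == j) & d.obs_mask]
            if len(a) >= 2:
                means[j] = a.mean()
                sds[j] = max(a.std(), 0.05)
        theta[self.sl.intercept] = means + rng.normal(0, 0.05, d.n_participants)
        theta[self.sl.adaptation] = rng.normal(0, 5e-4, d.n_participants)
        theta[self.sl.log_sigma] = np.log(sds) + rng.normal(0, 0.05, d.n_participants)
        theta[self.sl.hyper] = np.array([0.0, 0.0, -1.0, -4.5, 0.0, 1.0, -3.0]) \
            + rng.normal(0, [0.05, 0.002, 0.1, 0.1, 0.1, 0.05, 0.1])
        if self.tag == "m2":
            theta[self.sl.beta_cue] = rng.normal(0, 0.05, 16)
            theta[self.sl.sigma_cue_raw] = -0.5 + rng.normal(0, 0.1)
        elif self.tag == "m3":
            z_p, z_u, bs0 = self._m3_data_init(means)
            theta[self.sl.rate_p_raw] = z_p + rng.normal(0, 0.2, d.n_participants)
            theta[self.sl.rate_u_raw] = z_u + rng.normal(0, 0.2, d.n_participants)
            theta[self.sl.beta_scaling] = bs0 + rng.normal(0, 0.05, 4)
            # rate-scale hypers start high: learning rates pile up near 0
            # and 1, i.e. |logit(rate)| ~ 3, which needs scale ~ e^1
            theta[self.sl.m3_hyper] = np.array([0.0, 0.0, 1.0, 1.0, 0.0, -0.5]) \
                + rng.normal(0, 0.1, 6)
        theta[self.sl.missing] = rng.normal(0, 0.1, d.n_missing)
        return theta

    def _m3_data_init(self, means: np.ndarray):
        """Mode-finding heuristic for the learning model.

        The 'nobody learns' mode (rates and cue scalings all near zero)
        is locally stable for gradient samplers because zero scalings
        kill the rate gradients.  To start near the data-supported
        mode, cue scalings are initialized by regressing detrended
        residuals on a high-rate reference trajectory, and each
        participant starts in the learner regime only when that raises
        its own fit.
        """
        d = self.data
        n = d.n_participants
        resid = d.amp - means[d.p_idx]
        resid[~d.obs_mask] = 0.0
        # detrend per participant
        for j in range(n):
            rows = (d.p_idx == j) & d.obs_mask
            if rows.sum() >= 4:
                tc = d.tc[rows]
                denom = float(np.sum(tc * tc))
                if denom > 0:
                    resid[rows] -= np.sum(tc * resid[rows]) / denom * tc
        S = compute_strengths(d.event_outcome, d.event_valid,
                              np.full(n, 0.95), np.full(n, 0.05))
        s_row = S[d.k, d.p_idx]

        def estimate_bs(participant_mask):
            bs = np.zeros(4)
            keep = participant_mask[d.p_idx]
            for c in range(4):
                rows = (d.cue_idx == c) & d.obs_mask & (s_row > 0.05) & keep
                denom = float(np.sum(s_row[rows] ** 2))
                if denom > 0:
                    bs[c] = float(np.clip(
                        np.sum(resid[rows] * s_row[rows]) / denom, -2.0, 2.0))
            return bs

        def gains(bs):
            pred = bs[d.cue_idx] * s_row
            return np.bincount(
                d.p_idx,
                weights=np.where(d.obs_mask,
                                 resid * pred - 0.5 * pred * pred, 0.0),
                minlength=n)

        # pass 1 pools everyone (attenuated when only some participants
        # learn); pass 2 re-estimates the scalings from the provisional
        # learners so their regime assignment sees an undiluted effect
        learner = np.ones(n, dtype=bool)
        bs0 = estimate_bs(learner)
        for _ in range(2):
            learner = gains(bs0) > 0
            if learner.any():
                bs0 = estimate_bs(learner)
        z_p = np.where(learner, 1.2, -1.2)
        z_u = np.where(learner, -1.2, 0.0)
        return z_p, z_u, bs0

    def initial_mass(self) -> np.ndarray:
        """Rough per-parameter posterior variances used as the initial
        inverse-mass diagonal (parameters live on very different
        scales: adaptation slopes ~1e-3, imputed amplitudes ~sigma)."""
        d, sl = self.data, self.sl
        minv = np.full(self.n_params, 0.01)
        per_p = max(d.n_rows / d.n_participants, 2.0)
        minv[sl.intercept] = 0.01
        minv[sl.adaptation] = (2.0 / per_p) ** 2
        minv[sl.log_sigma] = 1.0 / per_p
        minv[sl.hyper] = [0.01, 1e-6, 0.02, 0.02, 0.1, 0.01, 0.05]
        if self.tag == "m2":
            minv[sl.beta_cue] = 0.01
        elif self.tag == "m3":
            minv[sl.rate_p_raw] = 1.0
            minv[sl.rate_u_raw] = 1.0
            minv[sl.beta_scaling] = 0.01
            minv[sl.m3_hyper] = [0.25, 0.25, 0.1, 0.1, 0.04, 0.1]
        if d.n_missing:
            obs_var = float(np.nanvar(d.amp[d.obs_mask])) if d.n_obs else 1.0
            minv[sl.missing] = max(obs_var, 0.05)
        return minv

    # -- forward pass ------------------------------------------------------
    def forward(self, theta: np.ndarray, with_grad_parts: bool = False):
        """Predicted mean, per-row sigma and (possibly imputed) amplitude."""
        d, sl = self.data, self.sl
        intercept = theta[sl.intercept]
        adaptation = theta[sl.adaptation]
        sigma = np.exp(theta[sl.log_sigma])
        mu = intercept[d.p_idx] + adaptation[d.p_idx] * d.tc
        parts = {}
        if self.tag == "m2":
            bc = theta[sl.beta_cue]
            mu = mu + bc[d.cue_idx * 4 + d.block_idx]
        elif self.tag == "m3":
            m3h = theta[sl.m3_hyper]
            scale_p = np.exp(np.clip(m3h[2], -20.0, 20.0))
            scale_u = np.exp(np.clip(m3h[3], -20.0, 20.0))
            raw_p = m3h[0] + scale_p * theta[sl.rate_p_raw]
            raw_u = m3h[1] + scale_u * theta[sl.rate_u_raw]
            rp = 1.0 / (1.0 + np.exp(-raw_p))
            ru = 1.0 / (1.0 + np.exp(-raw_u))
            bs = theta[sl.beta_scaling]
            res = compute_strengths(d.event_outcome, d.event_valid, rp, ru,
                                    with_grad=with_grad_parts)
            S = res[0] if with_grad_parts else res
            s_row = S[d.k, d.p_idx]
            mu = mu + bs[d.cue_idx] * s_row
            parts.update(rp=rp, ru=ru, bs=bs, s_row=s_row,
                         scale_p=scale_p, scale_u=scale_u)
            if with_grad_parts:
                parts.update(dSp_row=res[1][d.k, d.p_idx],
                             dSu_row=res[2][d.k, d.p_idx])
        amp = d.amp.copy()
        if d.n_missing:
            amp[d.missing_rows] = theta[sl.missing]
        return mu, sigma, amp, parts

    def pointwise_loglik(self, theta: np.ndarray, observed_only: bool = True):
        mu, sigma, amp, _ = self.forward(theta)
        d = self.data
        sd = sigma[d.p_idx]
        ll = -0.5 * _LOG_2PI - np.log(sd) - 0.5 * ((amp - mu) / sd) ** 2
        return ll[d.obs_mask] if observed_only else ll

    # -- log posterior + gradient ------------------------------------------
    def logp_grad(self, theta: np.ndarray):
        d, sl, n = self.data, self.sl, self.data.n_participants
        grad = np.zeros_like(theta)
        mu, sigma, amp, parts = self.forward(theta, with_grad_parts=True)
        sd = sigma[d.p_idx]
        inv_var = 1.0 / (sd * sd)
        resid = amp - mu
        ls = theta[sl.log_sigma]
        lp = float(-0.5 * _LOG_2PI * d.n_rows - ls[d.p_idx].sum()
                   - 0.5 * np.sum(resid * resid * inv_var))
        g_mu = resid * inv_var
        grad[sl.intercept] += np.bincount(d.p_idx, weights=g_mu, minlength=n)
        grad[sl.adaptation] += np.bincount(d.p_idx, weights=g_mu * d.tc, minlength=n)
        grad[sl.log_sigma] += np.bincount(
            d.p_idx, weights=-1.0 + resid * resid * inv_var, minlength=n)
        if self.tag == "m2":
            grad[sl.beta_cue] += np.bincount(d.cue_idx * 4 + d.block_idx,
                                             weights=g_mu, minlength=16)
        elif self.tag == "m3":
            rp, ru, bs = parts["rp"], parts["ru"], parts["bs"]
            s_row = parts["s_row"]
            grad[sl.beta_scaling] += np.bincount(d.cue_idx, weights=g_mu * s_row,
                                                 minlength=4)
            tmp = g_mu * bs[d.cue_idx]
            g_raw_p = np.bincount(
                d.p_idx, weights=tmp * parts["dSp_row"], minlength=n) * rp * (1 - rp)
            g_raw_u = np.bincount(
                d.p_idx, weights=tmp * parts["dSu_row"], minlength=n) * ru * (1 - ru)
            grad[sl.rate_p_raw] += g_raw_p * parts["scale_p"]
            grad[sl.rate_u_raw] += g_raw_u * parts["scale_u"]
            g_m3_lik = np.zeros(6)
            g_m3_lik[0] = g_raw_p.sum()
            g_m3_lik[1] = g_raw_u.sum()
            g_m3_lik[2] = float(np.sum(g_raw_p * parts["scale_p"] * theta[sl.rate_p_raw]))
            g_m3_lik[3] = float(np.sum(g_raw_u * parts["scale_u"] * theta[sl.rate_u_raw]))
            grad[sl.m3_hyper] += g_m3_lik
        if d.n_missing:
            grad[sl.missing] += -g_mu[d.missing_rows]

        # ---- priors -------------------------------------------------------
        h = theta[sl.hyper]
        i_avg, a_avg, sIr, sAr, rr, s_avg, t_raw = h
        gh = np.zeros(7)
        df = self.df

        # participant sigma: StudentT(df, sigma_avg, tau) on the natural
        # scale, sampled as log(sigma) -> +log(sigma) Jacobian
        tau = math.exp(t_raw)
        lp_s, dx, dloc, dlogscale = M.student_t_derivs(sigma, df, s_avg, tau)
        lp += float(lp_s.sum() + ls.sum())
        grad[sl.log_sigma] += dx * sigma + 1.0
        gh[5] += dloc.sum()
        gh[6] += dlogscale.sum()
        m, s = M.PRIORS["sigma_avg"]
        lp += float(M.norm_logpdf(s_avg, m, s))
        gh[5] += float(M.dnorm_dx(s_avg, m, s))
        m, s = M.PRIORS["tau_raw"]
        lp += float(M.norm_logpdf(t_raw, m, s))
        gh[6] += float(M.dnorm_dx(t_raw, m, s))

        # (intercept, adaptation): bivariate StudentT with correlation
        sI, sA, rho = math.exp(sIr), math.exp(sAr), math.tanh(rr)
        c = max(1.0 - rho * rho, 1e-15)
        u = (theta[sl.intercept] - i_avg) / sI
        v = (theta[sl.adaptation] - a_avg) / sA
        q = (u * u - 2.0 * rho * u * v + v * v) / c
        const = (math.lgamma((df + 2.0) / 2.0) - math.lgamma(df / 2.0)
                 - math.log(df * math.pi))
        lp += float(n * (const - sIr - sAr - 0.5 * math.log(c))
                    - (df + 2.0) / 2.0 * np.sum(np.log1p(q / df)))
        gq = -(df + 2.0) / (2.0 * (df + q))
        dq_du = (2.0 * u - 2.0 * rho * v) / c
        dq_dv = (2.0 * v - 2.0 * rho * u) / c
        grad[sl.intercept] += gq * dq_du / sI
        grad[sl.adaptation] += gq * dq_dv / sA
        gh[0] += -np.sum(gq * dq_du) / sI
        gh[1] += -np.sum(gq * dq_dv) / sA
        gh[2] += -n - np.sum(gq * dq_du * u)
        gh[3] += -n - np.sum(gq * dq_dv * v)
        dq_drho = (-2.0 * u * v + 2.0 * rho * q) / c
        dlp_drho = n * rho / c + np.sum(gq * dq_drho)
        gh[4] += dlp_drho * c  # d tanh / d raw = 1 - rho^2
        for j, name in enumerate(("intercept_avg", "adaptation_avg",
                                  "sigma_intercept_raw", "sigma_adaptation_raw",
                                  "rho_raw")):
            m, s = M.PRIORS[name]
            lp += float(M.norm_logpdf(h[j], m, s))
            gh[j] += float(M.dnorm_dx(h[j], m, s))
        grad[sl.hyper] += gh

        if self.tag == "m2":
            scr = theta[sl.sigma_cue_raw]
            sC = math.exp(scr)
            bc = theta[sl.beta_cue]
            lp_b, dx, _, dlogscale = M.student_t_derivs(bc, 15.0, 0.0, sC)
            lp += float(lp_b.sum())
            grad[sl.beta_cue] += dx
            m, s = M.PRIORS["sigma_cue_raw"]
            lp += float(M.norm_logpdf(scr, m, s))
            grad[sl.sigma_cue_raw] += float(dlogscale.sum() + M.dnorm_dx(scr, m, s))
        elif self.tag == "m3":
            m3h = theta[sl.m3_hyper]
            gm3 = np.zeros(6)
            # non-centered rates: z ~ StudentT(df, 0, 1); the implied prior
            # on logit(rate) = avg + exp(s_raw) * z is the centered
            # StudentT(df, avg, exp(s_raw)) of the model statement
            for j, (sl_z, which) in enumerate(((sl.rate_p_raw, "paired"),
                                               (sl.rate_u_raw, "unpaired"))):
                z = theta[sl_z]
                avg, lsr = m3h[j], m3h[2 + j]
                lp_r, dx, _, _ = M.student_t_derivs(z, df, 0.0, 1.0)
                lp += float(lp_r.sum())
                grad[sl_z] += dx
                m, s = M.PRIORS[f"rate_{which}_avg_raw"]
                lp += float(M.norm_logpdf(avg, m, s))
                gm3[j] += float(M.dnorm_dx(avg, m, s))
                m, s = M.PRIORS[f"sigma_rate_{which}_raw"]
                lp += float(M.norm_logpdf(lsr, m, s))
                gm3[2 + j] += float(M.dnorm_dx(lsr, m, s))
            bs_avg, s_bs_raw = m3h[4], m3h[5]
            sB = math.exp(s_bs_raw)
            bs = theta[sl.beta_scaling]
            lp_b, dx, dloc, dlogscale = M.student_t_derivs(bs, 3.0, bs_avg, sB)
            lp += float(lp_b.sum())
            grad[sl.beta_scaling] += dx
            gm3[4] += dloc.sum()
            gm3[5] += dlogscale.sum()
            m, s = M.PRIORS["beta_scaling_avg"]
            lp += float(M.norm_logpdf(bs_avg, m, s))
            gm3[4] += float(M.dnorm_dx(bs_avg, m, s))
            m, s = M.PRIORS["sigma_beta_scaling_raw"]
            lp += float(M.norm_logpdf(s_bs_raw, m, s))
            gm3[5] += float(M.dnorm_dx(s_bs_raw, m, s))
            grad[sl.m3_hyper] += gm3
        return lp, grad

    def logp(self, theta: np.ndarray) -> float:
        return self.logp_grad(theta)[0]
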