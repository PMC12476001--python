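"""Bayesian first-level ROI regression with temporally correlated noise.

The BOLD series of one region is modelled as ``y = X beta + eps`` with
a 19-column design matrix (12 cue-by-phase regressors, 1 US regressor,
6 motion regressors) and stationary noise whose covariance is Toeplitz
with entries ``sigma^2 * lambda^|i-j|`` (an AR(1) structure; ``lambda``
is the lag-1 correlation between volumes).  Censored volumes are
removed by row deletion, which for a Markov process leaves an exact
innovations factorization over the retained volumes.

Two variants are provided: *independent* fits every participant with
weak priors (the standard first-level analysis), while *multilevel*
gives each of the 19 betas, the noise correlation (on the logit scale)
and the log noise SD a participant-level Normal prior whose group mean
and spread are estimated simultaneously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.linalg import cho_factor, cho_solve, toeplitz

from .design import CUES
from .hmc import run_chain
from .inference import ModelPosterior, SamplerConfig, diagnose, RHAT_THRESHOLD, ConvergenceWarning
from .loo import LogLikMatrix

PHASES = ("HAB", "ACQ", "EXT")
_LOG_2PI = math.log(2.0 * math.pi)

N_DESIGN_COLUMNS = 19
MOTION_COLUMNS = ("mot_x", "mot_y", "mot_z", "mot_roll", "mot_pitch", "mot_yaw")


@dataclass(frozen=True)
class HrfKernel:
    """Gamma-variate impulse response h(t) ~ t^shape * exp(-t / scale),
    peaking at shape * scale seconds (about 4.7 s by default); the
    kernel is config-swappable."""
    shape: float = 8.6
    scale: float = 0.547

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        peak = self.shape * self.scale
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(t > 0, (t / peak) ** self.shape
                         * np.exp((peak - t) / self.scale), 0.0)
        return h


@dataclass
class NoiseModel:
    """AR(1) noise: lag-1 correlation ``lam`` in [0, 1) and residual SD."""
    lam: float
    sigma: float

    def __post_init__(self):
        if not (0.0 <= self.lam < 1.0):
            raise ValueError("lambda must lie in [0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class FmriDataset:
    """One participant's ROI series: BOLD per volume, 19-column design
    matrix, per-volume censoring mask (True = censored) and TR."""
    bold: np.ndarray
    design: np.ndarray
    censored: np.ndarray
    tr: float = 2.0

    def __post_init__(self):
        self.bold = np.asarray(self.bold, dtype=float)
        self.design = np.asarray(self.design, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.design.ndim != 2 or self.design.shape[1] != N_DESIGN_COLUMNS:
            raise ValueError(f"design matrix must have {N_DESIGN_COLUMNS} columns")
        n = len(self.bold)
        if self.design.shape[0] != n or len(self.censored) != n:
            raise ValueError("bold, design and censoring mask lengths differ")

    @property
    def retained(self) -> np.ndarray:
        return np.flatnonzero(~self.censored)


# ---------------------------------------------------------------------------
# design matrix construction

def hrf_regressor(onsets, duration: float, n_volumes: int, tr: float,
                  kernel: HrfKernel | None = None, dt: float = 0.05) -> np.ndarray:
    """Boxcar-convolved hemodynamic regressor sampled at volume times.

    A boxcar of ``duration`` seconds at each onset is convolved with the
    gamma-variate kernel and rescaled so an isolated event peaks at
    exactly 1 (the BLOCK-style fixed-height convention).
    """
    kernel = kernel or HrfKernel()
    onsets = np.asarray(onsets, dtype=float)
    scan_len = n_volumes * tr
    if onsets.size and (onsets.min() < 0 or onsets.max() >= scan_len):
        raise ValueError("onsets must lie within the scan")
    grid_len = int(math.ceil(scan_len / dt)) + 1
    h = kernel.evaluate(np.arange(0, 40.0, dt))
    box_len = max(1, int(round(duration / dt)))
    single = np.convolve(np.ones(box_len), h)
    peak = single.max()
    if peak <= 0:
        raise ValueError("degenerate HRF kernel")
    stick = np.zeros(grid_len)
    for onset in onsets:
        stick[int(round(onset / dt))] += 1.0
    box = np.convolve(stick, np.ones(box_len))[:grid_len]
    conv = np.convolve(box, h)[:grid_len] / peak
    vol_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
    return conv[vol_idx]


def design_column_names() -> list[str]:
    names = [f"{cue}_{phase}" for phase in PHASES for cue in CUES]
    return names + ["US"] + list(MOTION_COLUMNS)


def build_design_matrix(events: dict, us_onsets, motion: np.ndarray,
                        n_volumes: int, tr: float,
                        kernel: HrfKernel | None = None,
                        cue_duration: float = 2.0,
                        us_duration: float = 0.1) -> pd.DataFrame:
    """Assemble the 19-column design matrix.

    ``events`` maps (cue, phase) to onset lists for the 12 cue-by-phase
    regressors (phases HAB, ACQ, EXT); the US regressor uses a shorter
    boxcar; ``motion`` supplies the 6 nuisance columns.  Column order is
    phase-major cue regressors, then US, then motion.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (n_volumes, 6):
        raise ValueError("motion must have shape (n_volumes, 6)")
    cols = {}
    for phase in PHASES:
        for cue in CUES:
            onsets = events.get((cue, phase), [])
            cols[f"{cue}_{phase}"] = hrf_regressor(onsets, cue_duration,
                                                   n_volumes, tr, kernel)
    cols["US"] = hrf_regressor(us_onsets, us_duration, n_volumes, tr, kernel)
    for j, name in enumerate(MOTION_COLUMNS):
        cols[name] = motion[:, j]
    return pd.DataFrame(cols, columns=design_column_names())


# ---------------------------------------------------------------------------
# noise model

def toeplitz_covariance(noise: NoiseModel, n: int) -> np.ndarray:
    """n x n covariance with entries sigma^2 * lambda^|i-j|."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return noise.sigma ** 2 * toeplitz(noise.lam ** np.arange(n))


def gls_loglik(y: np.ndarray, X: np.ndarray, beta: np.ndarray,
               noise: NoiseModel, censored: np.ndarray | None = None) -> float:
    """Multivariate-normal log density of ``y - X beta`` under the
    Toeplitz covariance, via Cholesky; censored volumes are removed from
    the data and from the covariance (rows and columns dropped)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    keep = np.arange(n) if censored is None else np.flatnonzero(~np.asarray(censored, dtype=bool))
    r = y[keep] - X[keep] @ np.asarray(beta, dtype=float)
    lags = np.abs(keep[:, None] - keep[None, :])
    cov = noise.sigma ** 2 * noise.lam ** lags
    try:
        c, low = cho_factor(cov, lower=True)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular covariance") from err
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    quad = float(r @ cho_solve((c, low), r))
    m = len(keep)
    return float(-0.5 * (m * _LOG_2PI + logdet + quad))


def ar1_pointwise_loglik(resid: np.ndarray, times: np.ndarray, lam: float,
                         sigma: float) -> np.ndarray:
    """Exact per-volume log density under the AR(1) Toeplitz model.

    Uses the Markov innovations factorization over the retained volume
    times: the first retained volume is marginal N(0, sigma^2) and each
    later one is N(lam^d * prev, sigma^2 (1 - lam^(2d))) given its
    predecessor at lag d.  The sum equals the joint MVN log density.
    """
    resid = np.asarray(resid, dtype=float)
    times = np.asarray(times, dtype=float)
    out = np.empty(len(resid))
    if len(resid) == 0:
        return out
    out[0] = -0.5 * _LOG_2PI - math.log(sigma) - 0.5 * (resid[0] / sigma) ** 2
    if len(resid) > 1:
        d = np.diff(times)
        lamd = lam ** d
        c = 1.0 - lamd ** 2
        e = resid[1:] - lamd * resid[:-1]
        out[1:] = (-0.5 * _LOG_2PI - math.log(sigma) - 0.5 * np.log(c)
                   - 0.5 * e * e / (sigma ** 2 * c))
    return out


# ---------------------------------------------------------------------------
# packed Bayesian models

_BETA_PRIOR_SD = 10.0      # weak percent-signal prior, independent variant
_LOGSIGMA_PRIOR = (0.0, 1.5)
_HYPER_MU_SD = 5.0
_HYPER_LTAU_PRIOR = (-1.0, 1.0)
_HYPER_SCALAR_MU_PRIOR = (0.0, 1.0)

P_PER_PARTICIPANT = N_DESIGN_COLUMNS + 2  # betas + lambda_raw + log_sigma
N_MULTILEVEL_HYPERS = 2 * N_DESIGN_COLUMNS + 4


class FmriPackedModel:
    """Flat parameterization of the first-level regression for HMC."""

    def __init__(self, datasets: list[FmriDataset], variant: str):
        if variant not in ("independent", "multilevel"):
            raise ValueError("variant must be 'independent' or 'multilevel'")
        if variant == "multilevel" and len(datasets) < 2:
            raise ValueError("multilevel variant needs >= 2 participants")
        self.variant = variant
        self.datasets = datasets
        self.P = len(datasets)
        self._y = [ds.bold[ds.retained] for ds in datasets]
        self._X = [ds.design[ds.retained] for ds in datasets]
        self._t = [ds.retained.astype(float) for ds in datasets]
        self.n_params = self.P * P_PER_PARTICIPANT \
            + (N_MULTILEVEL_HYPERS if variant == "multilevel" else 0)
        self.param_names = self._names()

    def _names(self):
        names = []
        base = "beta" if self.variant == "independent" else "beta_z"
        lam_nm = "lambda_raw" if self.variant == "independent" else "lambda_z"
        sig_nm = "log_sigma" if self.variant == "independent" else "sigma_z"
        for p in range(1, self.P + 1):
            names += [f"{base}[{p},{name}]" for name in design_column_names()]
            names += [f"{lam_nm}[{p}]", f"{sig_nm}[{p}]"]
        if self.variant == "multilevel":
            names += [f"beta_mu[{name}]" for name in design_column_names()]
            names += [f"beta_ltau[{name}]" for name in design_column_names()]
            names += ["lambda_mu", "lambda_ltau", "sigma_mu", "sigma_ltau"]
        return names

    def _hypers(self, theta):
        h0 = self.P * P_PER_PARTICIPANT
        nb = N_DESIGN_COLUMNS
        beta_mu = theta[h0: h0 + nb]
        beta_ltau = np.clip(theta[h0 + nb: h0 + 2 * nb], -20.0, 20.0)
        lam_mu, lam_ltau, sig_mu, sig_ltau = theta[h0 + 2 * nb:]
        return (beta_mu, np.exp(beta_ltau),
                lam_mu, math.exp(min(lam_ltau, 20.0)),
                sig_mu, math.exp(min(sig_ltau, 20.0)))

    def participant_params(self, theta, p):
        """Natural-scale (beta, lambda_raw, log_sigma) for participant p
        (multilevel draws are stored non-centered)."""
        sl = self._slice(p)
        nb = N_DESIGN_COLUMNS
        b = theta[sl.start: sl.start + nb]
        l = theta[sl.start + nb]
        s = theta[sl.start + nb + 1]
        if self.variant == "multilevel":
            beta_mu, beta_tau, lam_mu, lam_tau, sig_mu, sig_tau = self._hypers(theta)
            b = beta_mu + beta_tau * b
            l = lam_mu + lam_tau * l
            s = sig_mu + sig_tau * s
        return b, l, s

    def _slice(self, p: int) -> slice:
        return slice(p * P_PER_PARTICIPANT, (p + 1) * P_PER_PARTICIPANT)

    def initial_theta(self, rng: np.random.Generator) -> np.ndarray:
        theta = np.zeros(self.n_params)
        betas = []
        lsigs = []
        for p in range(self.P):
            X, y = self._X[p], self._y[p]
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid_sd = max(float(np.std(y - X @ beta)), 1e-3)
            sl = self._slice(p)
            theta[sl.start: sl.start + N_DESIGN_COLUMNS] = beta
            theta[sl.start + N_DESIGN_COLUMNS] = 0.0
            theta[sl.start + N_DESIGN_COLUMNS + 1] = math.log(resid_sd)
            betas.append(beta)
            lsigs.append(math.log(resid_sd))
        if self.variant == "multilevel":
            h0 = self.P * P_PER_PARTICIPANT
            mu0 = np.mean(betas, axis=0)
            tau0 = np.clip(np.std(betas, axis=0), 0.05, None)
            theta[h0: h0 + N_DESIGN_COLUMNS] = mu0
            theta[h0 + N_DESIGN_COLUMNS: h0 + 2 * N_DESIGN_COLUMNS] = np.log(tau0)
            sig_mu0 = float(np.mean(lsigs))
            theta[h0 + 2 * N_DESIGN_COLUMNS:] = [0.0, -1.0, sig_mu0, -1.0]
            # re-express per-participant blocks as standardized offsets
            for p in range(self.P):
                sl = self._slice(p)
                theta[sl.start: sl.start + N_DESIGN_COLUMNS] = \
                    (betas[p] - mu0) / tau0
                theta[sl.start + N_DESIGN_COLUMNS] = 0.0
                theta[sl.start + N_DESIGN_COLUMNS + 1] = \
                    (lsigs[p] - sig_mu0) / math.exp(-1.0)
        return theta + rng.normal(0, 0.02, self.n_params)

    def initial_mass(self) -> np.ndarray:
        if self.variant == "multilevel":
            minv = np.ones(self.n_params)
            h0 = self.P * P_PER_PARTICIPANT
            minv[h0: h0 + 2 * N_DESIGN_COLUMNS] = 0.01
            minv[h0 + 2 * N_DESIGN_COLUMNS:] = [0.1, 0.1, 0.01, 0.1]
            return minv
        minv = np.full(self.n_params, 0.01)
        for p in range(self.P):
            sl = self._slice(p)
            minv[sl.start + N_DESIGN_COLUMNS] = 0.1      # lambda_raw
            minv[sl.start + N_DESIGN_COLUMNS + 1] = 0.01  # log_sigma
        return minv

    def _participant_ll_grad(self, p: int, beta, lam, log_sigma):
        """Log likelihood and gradients (d/dbeta, d/dlam, d/dlog_sigma)."""
        y, X, t = self._y[p], self._X[p], self._t[p]
        sigma2 = math.exp(2.0 * max(min(log_sigma, 300.0), -150.0))
        r = y - X @ beta
        m = len(r)
        d = np.diff(t)
        lamd = lam ** d if lam > 0 else np.where(d > 0, 0.0, 1.0)
        c = 1.0 - lamd ** 2
        e = np.empty(m)
        e[0] = r[0]
        e[1:] = r[1:] - lamd * r[:-1]
        cfull = np.empty(m)
        cfull[0] = 1.0
        cfull[1:] = c
        # extreme warmup proposals can push lambda -> 1 or sigma -> 0;
        # the resulting non-finite density is rejected as a divergence
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            ll = float(-0.5 * m * _LOG_2PI - m * log_sigma
                       - 0.5 * np.sum(np.log(cfull))
                       - 0.5 * np.sum(e * e / cfull) / sigma2)
            a = e / (cfull * sigma2)          # dll/de_j = -a_j
        g_r = -a
        g_r[:-1] += lamd * a[1:]
        g_beta = -X.T @ g_r
        g_ls = float(-m + np.sum(e * e / cfull) / sigma2)
        if m > 1 and lam > 0:
            dlamd = d * lam ** (d - 1.0)
            dc = -2.0 * lamd * dlamd
            de = -dlamd * r[:-1]
            g_lam = float(np.sum(-0.5 * dc / c - a[1:] * de
                                 + 0.5 * (e[1:] ** 2) / (c * c * sigma2) * dc))
        else:
            g_lam = 0.0
        return ll, g_beta, g_lam, g_ls

    def logp_grad(self, theta: np.ndarray):
        lp = 0.0
        grad = np.zeros_like(theta)
        nb = N_DESIGN_COLUMNS
        if self.variant == "multilevel":
            h0 = self.P * P_PER_PARTICIPANT
            beta_mu, beta_tau, lam_mu, lam_tau, sig_mu, sig_tau = \
                self._hypers(theta)
            beta_ltau = np.log(beta_tau)
            lam_ltau, sig_ltau = math.log(lam_tau), math.log(sig_tau)
            gh = np.zeros(N_MULTILEVEL_HYPERS)
        for p in range(self.P):
            sl = self._slice(p)
            beta, lam_raw, log_sigma = self.participant_params(theta, p)
            lam = 1.0 / (1.0 + math.exp(-np.clip(lam_raw, -30.0, 30.0)))
            ll, g_beta, g_lam, g_ls = self._participant_ll_grad(
                p, beta, lam, log_sigma)
            lp += ll
            g_lraw = g_lam * lam * (1.0 - lam)
            if self.variant == "independent":
                grad[sl.start: sl.start + nb] += g_beta
                grad[sl.start + nb] += g_lraw
                grad[sl.start + nb + 1] += g_ls
                lp += float(np.sum(-0.5 * _LOG_2PI - math.log(_BETA_PRIOR_SD)
                                   - 0.5 * (beta / _BETA_PRIOR_SD) ** 2))
                grad[sl.start: sl.start + nb] += -beta / _BETA_PRIOR_SD ** 2
                m0, s0 = _LOGSIGMA_PRIOR
                lp += -0.5 * _LOG_2PI - math.log(s0) - 0.5 * ((log_sigma - m0) / s0) ** 2
                grad[sl.start + nb + 1] += -(log_sigma - m0) / s0 ** 2
                # uniform prior on lambda, sampled on the logit scale
                lp += math.log(lam * (1.0 - lam))
                grad[sl.start + nb] += 1.0 - 2.0 * lam
            else:
                # non-centered: sampled blocks are standardized offsets z
                zb = theta[sl.start: sl.start + nb]
                zl = theta[sl.start + nb]
                zs = theta[sl.start + nb + 1]
                grad[sl.start: sl.start + nb] += g_beta * beta_tau - zb
                gh[:nb] += g_beta
                gh[nb: 2 * nb] += g_beta * beta_tau * zb
                grad[sl.start + nb] += g_lraw * lam_tau - zl
                gh[2 * nb] += g_lraw
                gh[2 * nb + 1] += g_lraw * lam_tau * zl
                grad[sl.start + nb + 1] += g_ls * sig_tau - zs
                gh[2 * nb + 2] += g_ls
                gh[2 * nb + 3] += g_ls * sig_tau * zs
                lp += float(np.sum(-0.5 * _LOG_2PI - 0.5 * zb * zb))
                lp += -0.5 * _LOG_2PI - 0.5 * zl * zl
                lp += -0.5 * _LOG_2PI - 0.5 * zs * zs
        if self.variant == "multilevel":
            lp += float(np.sum(-0.5 * _LOG_2PI - math.log(_HYPER_MU_SD)
                               - 0.5 * (beta_mu / _HYPER_MU_SD) ** 2))
            gh[:nb] += -beta_mu / _HYPER_MU_SD ** 2
            m0, s0 = _HYPER_LTAU_PRIOR
            for j, val in enumerate(beta_ltau):
                lp += -0.5 * _LOG_2PI - math.log(s0) - 0.5 * ((val - m0) / s0) ** 2
                gh[nb + j] += -(val - m0) / s0 ** 2
            for j, val in zip((2 * nb, 2 * nb + 2), (lam_mu, sig_mu)):
                ms, ss = _HYPER_SCALAR_MU_PRIOR
                lp += -0.5 * _LOG_2PI - math.log(ss) - 0.5 * ((val - ms) / ss) ** 2
                gh[j] += -(val - ms) / ss ** 2
            for j, val in zip((2 * nb + 1, 2 * nb + 3), (lam_ltau, sig_ltau)):
                lp += -0.5 * _LOG_2PI - math.log(s0) - 0.5 * ((val - m0) / s0) ** 2
                gh[j] += -(val - m0) / s0 ** 2
            grad[h0:] += gh
        return lp, grad

    def pointwise_loglik(self, theta: np.ndarray) -> np.ndarray:
        out = []
        for p in range(self.P):
            beta, lam_raw, log_sigma = self.participant_params(theta, p)
            lam = 1.0 / (1.0 + math.exp(-np.clip(lam_raw, -30.0, 30.0)))
            sigma = math.exp(log_sigma)
            r = self._y[p] - self._X[p] @ beta
            out.append(ar1_pointwise_loglik(r, self._t[p], lam, sigma))
        return np.concatenate(out)


def fit_first_level(datasets: list[FmriDataset], variant: str,
                    config: SamplerConfig,
                    check_convergence: bool = True) -> ModelPosterior:
    """Fit the first-level regression to all participants by HMC."""
    import warnings as _warnings
    packed = FmriPackedModel(datasets, variant)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    all_draws, stats = [], []
    for ss in seeds:
        child_init, child_chain = ss.spawn(2)
        theta0 = packed.initial_theta(np.random.default_rng(child_init))
        chain_seed = int(child_chain.generate_state(1)[0] % (2 ** 31))
        draws, cs = run_chain(packed.logp_grad, theta0, config.n_warmup,
                              config.n_draws, seed=chain_seed,
                              target_accept=config.target_acceptance,
                              max_leapfrog=config.max_leapfrog,
                              mass0=packed.initial_mass())
        all_draws.append(draws)
        stats.append(cs)
    post = ModelPosterior(np.stack(all_draws), packed.param_names,
                          model=f"fmri_{variant}", seed=config.seed,
                          config=config, chain_stats=stats,
                          attrs={"variant": variant, "n_participants": packed.P})
    if check_convergence and config.n_chains >= 2:
        report = diagnose(post)
        if not report.passed:
            finite = report.rhat.dropna()
            cw = ConvergenceWarning(
                message=f"max R-hat {report.max_rhat:.3f} >= {RHAT_THRESHOLD}",
                max_rhat=report.max_rhat,
                offenders=finite.index[finite >= RHAT_THRESHOLD].tolist())
            post.warnings.append(cw)
            _warnings.warn(cw.message, RuntimeWarning, stacklevel=2)
        post.attrs["max_rhat"] = report.max_rhat
    return post


def fmri_beta_draws(posterior: ModelPosterior,
                    datasets: list[FmriDataset]) -> np.ndarray:
    """Natural-scale beta draws, shape (S, participants, 19), for either
    variant (the multilevel posterior stores standardized offsets)."""
    packed = FmriPackedModel(datasets, posterior.attrs["variant"])
    if packed.param_names != posterior.param_names:
        raise ValueError("posterior parameters do not match these datasets")
    flat = posterior.samples.reshape(-1, posterior.samples.shape[2])
    out = np.empty((flat.shape[0], packed.P, N_DESIGN_COLUMNS))
    for s in range(flat.shape[0]):
        for p in range(packed.P):
            out[s, p] = packed.participant_params(flat[s], p)[0]
    return out


def fmri_pointwise_loglik(posterior: ModelPosterior,
                          datasets: list[FmriDataset]) -> LogLikMatrix:
    """Per-draw per-retained-volume log likelihood (innovations form)."""
    packed = FmriPackedModel(datasets, posterior.attrs["variant"])
    if packed.param_names != posterior.param_names:
        raise ValueError("posterior parameters do not match these datasets")
    flat = posterior.samples.reshape(-1, posterior.samples.shape[2])
    rows = [packed.pointwise_loglik(flat[s]) for s in range(flat.shape[0])]
    meta = pd.DataFrame({
        "participant": np.concatenate([[p + 1] * len(ds.retained)
                                       for p, ds in enumerate(datasets)]),
        "trial": np.concatenate([ds.retained for ds in datasets]),
    })
    meta["block"] = "NA"
    meta["cue"] = "NA"
    return LogLikMatrix(ll=np.vstack(rows), meta=meta)


def highpass_detrend(series: np.ndarray, order: int = 5,
                     cutoff: float = 0.0065, tr: float = 2.0) -> np.ndarray:
    """Zero-phase high-pass detrending (Butterworth, forward-reverse)."""
    series = np.asarray(series, dtype=float)
    nyquist = 0.5 / tr
    if cutoff >= nyquist:
        raise ValueError("cutoff must be below the Nyquist frequency")
    if len(series) <= 6 * order:
        raise ValueError("series too short for the requested filter order")
    sos = signal.butter(order, cutoff, btype="highpass", fs=1.0 / tr, output="sos")
    return signal.sosfiltfilt(sos, series)


# ---------------------------------------------------------------------------
# synthetic experiment harness

def synthetic_fmri_experiment(n_participants: int, n_volumes: int, seed: int,
                              tr: float = 2.0, group_betas: np.ndarray | None = None,
                              beta_sd: float = 0.3, ar_coef: float = 0.4,
                              noise_sd: float = 1.0, censor_rate: float = 0.05):
    """Simulate a small group fMRI experiment with group structure.

    Participant betas scatter around ``group_betas`` with SD
    ``beta_sd``; events are laid out with jittered inter-trial
    intervals; volumes are censored at random.  Returns (datasets list,
    true beta matrix).
    """
    from .simulate import simulate_bold
    rng = np.random.default_rng(seed)
    if group_betas is None:
        group_betas = np.zeros(N_DESIGN_COLUMNS)
        group_betas[0] = 0.2            # CSP_HAB
        group_betas[4] = 0.8            # CSP_ACQ
        group_betas[5] = 0.3            # GS1_ACQ
        group_betas[8] = 0.4            # CSP_EXT
        group_betas[12] = 1.0           # US
    scan_len = n_volumes * tr
    datasets = []
    true_betas = np.empty((n_participants, N_DESIGN_COLUMNS))
    for p in range(n_participants):
        events = {}
        t = 5.0
        keys = [(cue, phase) for phase in PHASES for cue in CUES]
        while t < scan_len - 30.0:
            phase_frac = t / scan_len
            phase = PHASES[min(2, int(phase_frac * 3))]
            cue = CUES[int(rng.integers(0, 4))]
            events.setdefault((cue, phase), []).append(t)
            t += float(rng.uniform(6.0, 10.0))
        for key in keys:
            events.setdefault(key, [])
        us_onsets = [o + 1.9 for o in events.get(("CSP", "ACQ"), [])
                     if o + 1.9 < scan_len - 1]
        motion = rng.normal(0, 0.1, (n_volumes, 6)).cumsum(axis=0) * 0.05
        X = build_design_matrix(events, us_onsets, motion, n_volumes, tr)
        betas = group_betas + rng.normal(0, beta_sd, N_DESIGN_COLUMNS)
        true_betas[p] = betas
        y = simulate_bold(X.to_numpy(), betas, ar_coef, noise_sd,
                          seed=int(rng.integers(0, 2 ** 31)))
        censored = rng.random(n_volumes) < censor_rate
        censored[:2] = False  # keep the series anchored
        datasets.append(FmriDataset(bold=y, design=X.to_numpy(),
                                    censored=censored, tr=tr))
    return datasets, true_betas
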