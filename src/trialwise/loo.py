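"""PSIS-LOO cross-validation, model comparison and stacking.

Leave-one-out expected log predictive density (ELPD) is estimated from
posterior draws by importance sampling: for observation i the ratios
``1 / p(y_i | theta_s)`` are tail-stabilized by fitting a generalized
Pareto distribution to the largest ratios and replacing them with the
fitted quantiles (Pareto-smoothed importance sampling).  The shape
diagnostic ``k`` flags observations whose importance weights are too
heavy-tailed for the estimate to be reliable (k > 0.7); such
observations are flagged but never dropped.  Cross-validation accuracy
is always measured over observed trials only, never over imputed
missing-trial parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from ._logp import PackedModel, TrialData
from .inference import ModelPosterior

K_THRESHOLD = 0.7


@dataclass
class LogLikMatrix:
    """Pointwise log-likelihoods (S draws x N observed trials) with the
    trial metadata aligned to columns."""
    ll: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self):
        self.ll = np.asarray(self.ll, dtype=float)
        if self.ll.ndim != 2:
            raise ValueError("ll must be 2-D (draws x observations)")
        if len(self.meta) != self.ll.shape[1]:
            raise ValueError("metadata rows must match observation columns")

    @property
    def n_draws(self) -> int:
        return self.ll.shape[0]

    @property
    def n_obs(self) -> int:
        return self.ll.shape[1]


@dataclass
class LOOResult:
    elpd_i: np.ndarray
    pareto_k: np.ndarray
    elpd: float
    se: float
    p_loo: float
    p_loo_se: float
    n_bad_k: int
    meta: pd.DataFrame | None = None


def pointwise_loglik(posterior: ModelPosterior, table: pd.DataFrame,
                     model: str | None = None) -> LogLikMatrix:
    """Per-draw per-observed-trial Normal log density under a fitted model.

    Imputed (missing) trials are excluded: the matrix has one column per
    observed trial only.
    """
    model = model or posterior.model
    data = TrialData(table, n_trials_total=posterior.attrs.get("n_trials_total"))
    packed = PackedModel(model, data)
    if packed.param_names != posterior.param_names:
        raise ValueError("posterior parameters do not match this model/table")
    flat = posterior.samples.reshape(-1, posterior.samples.shape[2])
    S = flat.shape[0]
    ll = np.empty((S, data.n_obs))
    for s in range(S):
        ll[s] = packed.pointwise_loglik(flat[s], observed_only=True)
    meta = data.table.loc[data.obs_mask,
                          ["participant", "trial", "block", "cue"]].reset_index(drop=True)
    return LogLikMatrix(ll=ll, meta=meta)


# ---------------------------------------------------------------------------
# generalized Pareto tail fit (profile-likelihood method)

def fit_gpd(x: np.ndarray):
    """Fit a generalized Pareto shape/scale to exceedances ``x`` >= 0.

    Profile-likelihood point estimate over a grid of candidate shapes
    (Zhang & Stephens 2009), with the weakly informative shape
    adjustment used by the PSIS reference implementation.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 5 or x[-1] <= 0:
        return np.nan, np.nan
    m_grid = 30 + int(math.sqrt(n))
    prior_bs = 3.0
    quart = x[int(n / 4 + 0.5) - 1]
    if quart <= 0:
        # heavy ties at the tail cutoff; no usable Pareto fit
        return np.nan, np.nan
    j = np.arange(1, m_grid + 1)
    b = 1.0 / x[-1] + (1.0 - np.sqrt(m_grid / (j - 0.5))) / (prior_bs * quart)
    k_b = -np.mean(np.log1p(-b[:, None] * x[None, :]), axis=1)
    profile = n * (np.log(b / k_b) + k_b - 1.0)
    profile -= profile.max()
    w = np.exp(profile)
    b_star = np.sum(b * w) / np.sum(w)
    # standard shape convention: k > 0 means heavy tail
    k = float(np.mean(np.log1p(-b_star * x)))
    sigma = float(-k / b_star)
    k = (n * k + 5.0) / (n + 10.0)  # regularize toward 0.5 at tiny n
    return k, sigma


def _gpd_quantile(p: np.ndarray, k: float, sigma: float) -> np.ndarray:
    if abs(k) < 1e-12:
        return -sigma * np.log1p(-p)
    return sigma / k * (np.power(1.0 - p, -k) - 1.0)


def smooth_log_weights(neg_ll: np.ndarray):
    """Pareto-smooth one observation's log importance ratios.

    ``neg_ll`` is the vector of log ratios (-log-likelihood per draw, up
    to a constant).  Returns (smoothed log weights, k-hat).  The tail
    size is M = min(0.2 S, 3 sqrt(S)); after smoothing, weights are
    truncated at S^(3/4) times the mean weight.
    """
    lw = neg_ll - neg_ll.max()
    S = len(lw)
    M = int(min(0.2 * S, 3.0 * math.sqrt(S)))
    khat = np.nan
    if M >= 5:
        order = np.argsort(lw)
        tail_idx = order[-M:]
        cutoff_lw = lw[order[-M - 1]]
        cutoff = math.exp(cutoff_lw)
        exceed = np.exp(lw[tail_idx]) - cutoff
        if np.ptp(exceed) > 0:
            khat, sigma = fit_gpd(exceed)
            if np.isfinite(khat):
                p = (np.arange(1, M + 1) - 0.5) / M
                smoothed = cutoff + _gpd_quantile(p, khat, sigma)
                # assign fitted quantiles in rank order of the raw tail
                rank = np.argsort(lw[tail_idx])
                new_lw = lw.copy()
                new_lw[tail_idx[rank]] = np.log(smoothed)
                lw = np.minimum(new_lw, 0.0)
    # truncate at S^(3/4) * mean weight
    cap = logsumexp(lw) - math.log(S) + 0.75 * math.log(S)
    lw = np.minimum(lw, cap)
    return lw, khat


def psis_loo(ll: LogLikMatrix) -> LOOResult:
    """PSIS-LOO ELPD for one fitted model.

    Per observation, ``elpd_i = log(sum_s w_s exp(ll_s) / sum_s w_s)``
    with Pareto-smoothed weights ``w``; ``p_loo = sum_i (lpd_i -
    elpd_i)`` with ``lpd_i`` the log mean pointwise density; the
    standard error is ``sqrt(N * var(elpd_i))``.
    """
    mat = ll.ll
    if not np.all(np.isfinite(mat)):
        raise ValueError("non-finite log-likelihood entries")
    S, N = mat.shape
    elpd_i = np.empty(N)
    lpd_i = np.empty(N)
    k = np.empty(N)
    for i in range(N):
        col = mat[:, i]
        lpd_i[i] = logsumexp(col) - math.log(S)
        if np.ptp(col) == 0.0:
            # all draws identical: importance ratios are constant
            elpd_i[i] = col[0]
            k[i] = np.nan
            continue
        lw, khat = smooth_log_weights(-col)
        elpd_i[i] = logsumexp(col + lw) - logsumexp(lw)
        k[i] = khat
    # numerical guard: the importance-sampling penalty is non-negative
    elpd_i = np.minimum(elpd_i, lpd_i)
    elpd = float(elpd_i.sum())
    se = float(math.sqrt(N * np.var(elpd_i, ddof=1))) if N > 1 else 0.0
    p_i = lpd_i - elpd_i
    p_loo = float(p_i.sum())
    p_loo_se = float(math.sqrt(N * np.var(p_i, ddof=1))) if N > 1 else 0.0
    finite_k = k[np.isfinite(k)]
    return LOOResult(elpd_i=elpd_i, pareto_k=k, elpd=elpd, se=se,
                     p_loo=p_loo, p_loo_se=p_loo_se,
                     n_bad_k=int((finite_k > K_THRESHOLD).sum()), meta=ll.meta)


def _check_aligned(results: list[LOOResult]):
    n = results[0].elpd_i.shape[0]
    for r in results[1:]:
        if r.elpd_i.shape[0] != n:
            raise ValueError("LOO results cover different observation sets")
        if r.meta is not None and results[0].meta is not None and \
                not r.meta[["participant", "trial"]].equals(results[0].meta[["participant", "trial"]]):
            raise ValueError("LOO results cover different observation sets")


def compare(loos: list[LOOResult], names: list[str]) -> pd.DataFrame:
    """ELPD comparison table, best model first.

    Differences are taken against the best model, with the SE of each
    difference computed from the pointwise elpd differences via
    ``sqrt(N * var(diff_i))``.
    """
    if len(loos) != len(names):
        raise ValueError("need one name per LOO result")
    _check_aligned(loos)
    order = np.argsort([-r.elpd for r in loos])
    best = loos[order[0]]
    rows = []
    for rank, j in enumerate(order):
        r = loos[j]
        d_i = r.elpd_i - best.elpd_i
        n = len(d_i)
        d_se = float(math.sqrt(n * np.var(d_i, ddof=1))) if n > 1 and rank else 0.0
        rows.append({"model": names[j], "rank": rank, "elpd": r.elpd,
                     "se": r.se, "elpd_diff": float(d_i.sum()), "diff_se": d_se,
                     "p_loo": r.p_loo, "n_bad_k": r.n_bad_k})
    return pd.DataFrame(rows).set_index("model")


def stacking_weights(lls: list[LogLikMatrix] | list[LOOResult],
                     n_starts: int = 5, seed: int = 0) -> np.ndarray:
    """Simplex weights maximizing the stacked LOO predictive density
    ``sum_i log sum_m w_m exp(elpd_im)``.

    Solved by L-BFGS on softmax-parameterized weights with multiple
    starts; a vanishing ridge on the unconstrained parameters breaks
    ties uniformly (two identical models share their weight equally).
    """
    if len(lls) == 0:
        raise ValueError("need at least one model")
    results = [r if isinstance(r, LOOResult) else psis_loo(r) for r in lls]
    _check_aligned(results)
    m = len(results)
    if m == 1:
        return np.array([1.0])
    ld = np.stack([r.elpd_i for r in results], axis=1)  # (N, m)
    ld = ld - ld.max(axis=1, keepdims=True)
    expld = np.exp(ld)

    def objective(a):
        w = np.exp(a - logsumexp(a))
        dens = expld @ w
        f = -np.sum(np.log(dens)) + 1e-9 * np.dot(a, a)
        gw = -(expld / dens[:, None]).sum(axis=0)
        ga = w * (gw - np.dot(gw, w)) + 2e-9 * a
        return f, ga

    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        a0 = np.zeros(m) if s == 0 else rng.normal(0, 1, m)
        res = minimize(objective, a0, jac=True, method="L-BFGS-B")
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("stacking optimizer failed to converge")
    w = np.exp(best.x - logsumexp(best.x))
    return w / w.sum()


def elpd_breakdown(loo: LOOResult, grouping: str) -> pd.Series:
    """Group sums of pointwise ELPD by cue, block or participant.

    The sums over all groups partition the total ELPD exactly.
    """
    if loo.meta is None:
        raise ValueError("LOO result carries no column metadata")
    if grouping not in loo.meta.columns:
        raise ValueError(f"unknown grouping key {grouping!r}")
    s = pd.Series(loo.elpd_i, index=pd.Index(loo.meta[grouping], name=grouping))
    return s.groupby(level=0, sort=False).sum()
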