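"""Posterior summaries: intervals, LOO-R2, generalization contrasts,
missing-trial distributions and grand-mean recreation.

All functions are pure in the posterior draws: repeated calls on the
same inputs return identical results (bootstrap routines take explicit
seeds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._logp import PackedModel, TrialData
from .inference import ModelPosterior
from .loo import LogLikMatrix, smooth_log_weights

#: linear-trend contrast over (CSP, GS1, GS2, GS3); configurable, not
#: hard-coded into the contrast routine
DEFAULT_CONTRAST_WEIGHTS = (3.0, 1.0, -1.0, -3.0)


@dataclass
class Summary:
    median: float
    lo95: float
    hi95: float
    excludes_zero: bool


def summarize(draws: np.ndarray) -> Summary:
    """Median and central 95% interval (linear-interpolation quantiles),
    with a flag for whether the interval excludes zero."""
    draws = np.asarray(draws, dtype=float).reshape(-1)
    if len(draws) == 0:
        raise ValueError("empty draw vector")
    lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
    excludes = bool(lo > 0.0 or hi < 0.0)
    return Summary(float(med), float(lo), float(hi), excludes)


def loo_weight_matrix(ll: LogLikMatrix) -> np.ndarray:
    """Pareto-smoothed log importance weights, one column per observation."""
    S, N = ll.ll.shape
    lw = np.empty((S, N))
    for i in range(N):
        col = ll.ll[:, i]
        if np.ptp(col) == 0.0:
            lw[:, i] = -math.log(S)
        else:
            lw[:, i], _ = smooth_log_weights(-col)
    return lw


def _weighted_var(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    m = w @ x
    return w @ (x * x) - m * m


def loo_r2(predictions: np.ndarray, observed: np.ndarray,
           log_weights: np.ndarray | None = None, n_boot: int = 4000,
           seed: int = 0) -> np.ndarray:
    """Posterior of LOO-adjusted R2 = 1 - var(LOO residuals)/var(data).

    ``predictions`` holds per-draw per-observation means (S x N); the
    LOO-expected prediction per observation is their PSIS-weighted
    posterior mean (plain mean when ``log_weights`` is None).
    Uncertainty comes from Dirichlet(1,..,1) weight resampling over
    observations (Bayesian bootstrap); samples can be negative when the
    model predicts worse than the data mean.
    """
    predictions = np.atleast_2d(np.asarray(predictions, dtype=float))
    observed = np.asarray(observed, dtype=float)
    N = len(observed)
    if N < 2:
        raise ValueError("need at least 2 observations")
    if predictions.shape[1] != N:
        raise ValueError("predictions and observations are not aligned")
    if log_weights is None:
        yhat = predictions.mean(axis=0)
    else:
        w = np.exp(log_weights - log_weights.max(axis=0, keepdims=True))
        w /= w.sum(axis=0, keepdims=True)
        yhat = np.sum(w * predictions, axis=0)
    resid = observed - yhat
    rng = np.random.default_rng(seed)
    omega = rng.dirichlet(np.ones(N), size=n_boot)
    return 1.0 - _weighted_var(resid, omega) / _weighted_var(observed, omega)


def generalization_contrast(effect_draws: np.ndarray,
                            weights=DEFAULT_CONTRAST_WEIGHTS):
    """Linear generalization contrast over (CSP, GS1, GS2, GS3).

    ``effect_draws`` is (S, 4) for a global contrast (M3 beta_scaling)
    or (S, 4, n_blocks) for per-block contrasts (M2 beta_cue); weights
    must sum to zero.  Returns contrast draws (S,) or (S, n_blocks).
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (4,) or abs(weights.sum()) > 1e-12:
        raise ValueError("contrast weights must be a zero-sum 4-vector")
    effect_draws = np.asarray(effect_draws, dtype=float)
    if effect_draws.ndim == 2:
        return effect_draws @ weights
    if effect_draws.ndim == 3:
        return np.einsum("scb,c->sb", effect_draws, weights)
    raise ValueError("effect_draws must be (S, 4) or (S, 4, n_blocks)")


def missing_trial_summaries(posterior: ModelPosterior,
                            table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Median and central 95% interval of each imputed missing trial,
    with its participant/trial (and cue/block when a table is given)."""
    labels = posterior.missing_labels()
    rows = []
    lookup = None
    if table is not None:
        lookup = table.set_index(["participant", "trial"])[["cue", "block"]]
    for p, t in labels:
        s = summarize(posterior.flat(f"amp_missing[{p},{t}]"))
        row = {"participant": p, "trial": t, "median": s.median,
               "lo95": s.lo95, "hi95": s.hi95}
        if lookup is not None:
            row["cue"] = lookup.loc[(p, t), "cue"]
            row["block"] = lookup.loc[(p, t), "block"]
        rows.append(row)
    cols = ["participant", "trial", "median", "lo95", "hi95"] \
        + (["cue", "block"] if table is not None else [])
    return pd.DataFrame(rows, columns=cols)


def posterior_mean_mu(posterior: ModelPosterior, table: pd.DataFrame,
                      thin: int = 1) -> np.ndarray:
    """Posterior-mean predicted amplitude for every row of ``table``
    (rows in (participant, trial) sort order)."""
    data = TrialData(table, n_trials_total=posterior.attrs.get("n_trials_total"))
    packed = PackedModel(posterior.model, data)
    if packed.param_names != posterior.param_names:
        raise ValueError("posterior parameters do not match this model/table")
    flat = posterior.samples.reshape(-1, posterior.samples.shape[2])[::thin]
    acc = np.zeros(data.n_rows)
    for s in range(flat.shape[0]):
        acc += packed.forward(flat[s])[0]
    return acc / flat.shape[0]


def mu_draws(posterior: ModelPosterior, table: pd.DataFrame,
             observed_only: bool = True, thin: int = 1) -> np.ndarray:
    """Per-draw predicted means (S x N), observed trials only by default."""
    data = TrialData(table, n_trials_total=posterior.attrs.get("n_trials_total"))
    packed = PackedModel(posterior.model, data)
    if packed.param_names != posterior.param_names:
        raise ValueError("posterior parameters do not match this model/table")
    flat = posterior.samples.reshape(-1, posterior.samples.shape[2])[::thin]
    out = np.empty((flat.shape[0], data.n_obs if observed_only else data.n_rows))
    for s in range(flat.shape[0]):
        mu = packed.forward(flat[s])[0]
        out[s] = mu[data.obs_mask] if observed_only else mu
    return out


@dataclass
class GrandMeanResult:
    cells: pd.DataFrame
    r: float
    t: float
    n_cells: int


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average over +/- window entries, NaN-aware,
    truncated at the edges."""
    n = len(x)
    out = np.full(n, np.nan)
    for i in range(n):
        seg = x[max(0, i - window): i + window + 1]
        if np.any(np.isfinite(seg)):
            out[i] = np.nanmean(seg)
    return out


def recreate_grand_mean(posterior: ModelPosterior, table: pd.DataFrame,
                        smoothing_window: int = 2) -> GrandMeanResult:
    """Observed vs model-predicted grand mean per session trial and cue.

    Cell (cue, trial) averages, over participants shown that cue at
    that trial, the observed amplitude and the posterior-mean predicted
    amplitude.  Both surfaces are smoothed per cue with a centered
    moving average over ``smoothing_window`` surrounding trials, then
    correlated (Pearson r over paired non-empty cells, with
    ``t = r sqrt((n-2)/(1-r^2))``, reported as inf when r = 1).
    """
    data = TrialData(table, n_trials_total=posterior.attrs.get("n_trials_total"))
    pred = posterior_mean_mu(posterior, table)
    tab = data.table.copy()
    tab["pred"] = pred
    obs_cells = tab.pivot_table(index="trial", columns="cue", values="amplitude",
                                aggfunc="mean")
    pred_cells = tab.pivot_table(index="trial", columns="cue", values="pred",
                                 aggfunc="mean")
    frames = []
    for cue in obs_cells.columns:
        obs_s = _moving_average(obs_cells[cue].to_numpy(), smoothing_window)
        pred_s = _moving_average(pred_cells[cue].reindex(obs_cells.index).to_numpy(),
                                 smoothing_window)
        frames.append(pd.DataFrame({
            "cue": cue, "trial": obs_cells.index,
            "observed": obs_cells[cue].to_numpy(),
            "predicted": pred_cells[cue].reindex(obs_cells.index).to_numpy(),
            "observed_smooth": obs_s, "predicted_smooth": pred_s,
        }))
    cells = pd.concat(frames, ignore_index=True)
    ok = np.isfinite(cells.observed_smooth) & np.isfinite(cells.predicted_smooth)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need at least 3 non-empty cells")
    x = cells.observed_smooth[ok].to_numpy()
    y = cells.predicted_smooth[ok].to_numpy()
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-15:
        t = math.inf if r > 0 else -math.inf
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return GrandMeanResult(cells=cells, r=r, t=float(t), n_cells=n)
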