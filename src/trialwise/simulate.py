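"""Synthetic trial-wise amplitudes, missingness, and ROI BOLD series.

The generator inverts the learning model (M3): each participant has an
intercept, a linear adaptation slope, a trial-level noise SD and a pair
of Rescorla–Wagner learning rates; a shared ``beta_scaling`` vector
maps latent CS+ associative strength into z-scored amplitude units per
cue.  Trials are lost completely at random at a single rate.

Default ground truth emulates the study sample: 24 participants whose
learning rates fall into three regimes (non-learners with a paired
rate near 0; learners with paired rate near 1 and unpaired near 0; and
a couple of volatile participants with both rates near 1), trial noise
around 0.5 z-units, an average downward adaptation of -0.005 z-units
per trial around an intercept of 0.44, roughly 16% missing trials, and
a generalization gradient over (CSP, GS1, GS2, GS3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._logp import TrialData, compute_strengths
from .models import inv_logit  # noqa: F401  (re-exported convenience)


@dataclass
class TrueParams:
    """Ground truth for the simulation harness (per-participant arrays
    plus the shared cue-scaling vector and the missing-trial rate)."""
    intercept: np.ndarray
    adaptation: np.ndarray
    sigma: np.ndarray
    rate_paired: np.ndarray
    rate_unpaired: np.ndarray
    beta_scaling: np.ndarray = field(default_factory=lambda: np.zeros(4))
    missing_rate: float = 0.0

    def __post_init__(self):
        for name in ("intercept", "adaptation", "sigma", "rate_paired",
                     "rate_unpaired", "beta_scaling"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        for name in ("rate_paired", "rate_unpaired"):
            v = getattr(self, name)
            if np.any((v <= 0) | (v >= 1)):
                raise ValueError(f"{name} must lie in the open unit interval")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.beta_scaling.shape != (4,):
            raise ValueError("beta_scaling must be a 4-vector")

    @property
    def n(self) -> int:
        return len(self.intercept)


def default_true_params(n_participants: int, seed: int, sigma: float = 0.5,
                        missing_rate: float = 0.16) -> TrueParams:
    """Ground truth mirroring the study's reported participant regimes.

    Roughly 70% non-learners (paired rate near 0, unpaired rate split
    between the two extremes), 21% learners (paired near 1, unpaired
    near 0) and 8% volatile (both near 1), with at least one learner
    always present.
    """
    rng = np.random.default_rng(seed)
    n = n_participants
    n_learn = max(1, round(0.21 * n))
    n_vol = max(1, round(0.08 * n)) if n >= 10 else 0
    n_non = n - n_learn - n_vol
    rate_p = np.concatenate([
        rng.uniform(0.005, 0.05, n_non),
        rng.uniform(0.90, 0.99, n_learn),
        rng.uniform(0.90, 0.99, n_vol),
    ])
    # non-learners' unpaired rates pile up at both extremes
    n_lo = n_non // 2
    rate_u = np.concatenate([
        rng.uniform(0.01, 0.10, n_lo),
        rng.uniform(0.90, 0.99, n_non - n_lo),
        rng.uniform(0.01, 0.10, n_learn),
        rng.uniform(0.90, 0.99, n_vol),
    ])
    perm = rng.permutation(n)
    return TrueParams(
        intercept=0.44 + rng.normal(0, 0.2, n),
        adaptation=-0.005 + rng.normal(0, 0.002, n),
        sigma=sigma * np.exp(rng.normal(0, 0.15, n)),
        rate_paired=rate_p[perm],
        rate_unpaired=rate_u[perm],
        beta_scaling=np.array([0.35, 0.20, 0.08, 0.0]),
        missing_rate=missing_rate,
    )


def true_learner_mask(truth: TrueParams, threshold: float = 0.8) -> np.ndarray:
    """Participants whose true paired learning rate is near 1."""
    return truth.rate_paired >= threshold


def simulate_amplitudes(design: pd.DataFrame, truth: TrueParams,
                        seed: int) -> pd.DataFrame:
    """Draw trial amplitudes from the learning model's forward equations.

    mu = intercept + adaptation * trialCentered + beta_scaling[cue] *
    strength, with strength evaluated before each trial's own update,
    and Normal(mu, sigma[participant]) noise.
    """
    data = TrialData(design)
    if data.n_participants != truth.n:
        raise ValueError("participant count mismatch between design and truth")
    rng = np.random.default_rng(seed)
    S = compute_strengths(data.event_outcome, data.event_valid,
                          truth.rate_paired, truth.rate_unpaired)
    s_row = S[data.k, data.p_idx]
    mu = (truth.intercept[data.p_idx]
          + truth.adaptation[data.p_idx] * data.tc
          + truth.beta_scaling[data.cue_idx] * s_row)
    amp = mu + truth.sigma[data.p_idx] * rng.standard_normal(len(mu))
    out = data.table.copy()
    out["amplitude"] = amp
    return out


def apply_missingness(table: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Flag each trial missing independently with probability ``rate``
    (missing completely at random); design columns are untouched."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0, 1)")
    out = table.copy()
    if rate > 0.0:
        rng = np.random.default_rng(seed)
        drop = rng.random(len(out)) < rate
        out.loc[drop, "amplitude"] = np.nan
    return out


def zscore_within_participant(table: pd.DataFrame) -> pd.DataFrame:
    """Standardize observed amplitudes to mean 0, SD 1 per participant
    (population SD over observed trials); missing entries untouched."""
    out = table.copy()
    amp = out["amplitude"].to_numpy(dtype=float)
    for p in out["participant"].unique():
        rows = (out["participant"] == p).to_numpy()
        obs = rows & np.isfinite(amp)
        if obs.sum() < 2:
            raise ValueError(f"participant {p}: need >= 2 observed trials to z-score")
        m = amp[obs].mean()
        sd = amp[obs].std()  # population convention (divide by n)
        if sd == 0:
            raise ValueError(f"participant {p}: constant observed amplitudes")
        amp[obs] = (amp[obs] - m) / sd
    out["amplitude"] = amp
    return out


def simulate_bold(design_matrix: np.ndarray, betas: np.ndarray, ar_coef: float,
                  noise_sd: float, seed: int) -> np.ndarray:
    """ROI BOLD series ``y = X beta + eps`` with stationary AR(1) noise
    whose correlation between volumes i, j is ``ar_coef ** |i - j|``."""
    X = np.asarray(design_matrix, dtype=float)
    betas = np.asarray(betas, dtype=float)
    if X.ndim != 2 or X.shape[1] != betas.shape[0]:
        raise ValueError("design matrix and beta vector are not conformable")
    if not (0.0 <= ar_coef < 1.0):
        raise ValueError("ar_coef must lie in [0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    eps = np.zeros(n)
    if noise_sd > 0 and n:
        z = rng.standard_normal(n)
        eps[0] = noise_sd * z[0]
        innov_sd = noise_sd * np.sqrt(1.0 - ar_coef ** 2)
        for t in range(1, n):
            eps[t] = ar_coef * eps[t - 1] + innov_sd * z[t]
    return X @ betas + eps
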