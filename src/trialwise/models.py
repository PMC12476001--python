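"""Generative models of trial-wise ssVEP amplitude.

Three nested models predict the z-scored single-trial ssVEP amplitude
``Amplitude[i] ~ Normal(mu[i], sigma[participant[i]])``:

* **M1 (adaptation only)** — a per-participant linear trend over the
  session: ``mu = intercept[p] + adaptation[p] * trialCentered``, with
  the trial index centered at the median trial ((T+1)/2).
* **M2 (cue-by-block)** — M1 plus a fixed effect for each of the four
  cues in each of the four blocks (a 4x4 ``beta_cue`` array).
* **M3 (Rescorla–Wagner learning)** — M1 plus ``beta_scaling[cue] *
  strength[i]`` where ``strength`` is the latent CS+ associative
  strength accumulated by a Rescorla–Wagner update with separate
  paired/unpaired learning rates per participant.

All participant-level parameters receive multilevel (partial-pooling)
priors; given the small sample, group distributions are Student-T with
``df = n_participants - 1``.  Scale hyperparameters are sampled on an
unbounded log scale ("raw") and exponentiated; the group correlation of
intercept and adaptation is ``tanh`` of an unbounded raw parameter.
Learning rates live on the logit scale with a Student-T multilevel
prior and are mapped to (0, 1) by the inverse logit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import BLOCKS, CUES

MODEL_TAGS = ("m1", "m2", "m3")

#: Normal prior (mean, sd) for each hyperparameter, on its sampled scale.
PRIORS: dict[str, tuple[float, float]] = {
    "sigma_avg": (1.0, 0.5),
    "tau_raw": (-3.0, 1.0),
    "intercept_avg": (0.0, 0.2),
    "adaptation_avg": (0.0, 0.01),
    "sigma_intercept_raw": (-1.0, 1.0),
    "sigma_adaptation_raw": (-4.5, 0.75),
    "rho_raw": (0.0, 1.0),
    "sigma_cue_raw": (-0.5, 1.5),
    "rate_paired_avg_raw": (0.0, 1.5),
    "rate_unpaired_avg_raw": (0.0, 1.5),
    "sigma_rate_paired_raw": (-0.5, 1.5),
    "sigma_rate_unpaired_raw": (-0.5, 1.5),
    "beta_scaling_avg": (0.0, 1.0),
    "sigma_beta_scaling_raw": (-0.5, 1.5),
}

_LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# density helpers (value + derivatives, vectorized)

def norm_logpdf(x, mean, sd):
    z = (np.asarray(x, dtype=float) - mean) / sd
    return -0.5 * _LOG_2PI - math.log(sd) - 0.5 * z * z


def dnorm_dx(x, mean, sd):
    return -(np.asarray(x, dtype=float) - mean) / (sd * sd)


def student_t_const(df: float) -> float:
    return (math.lgamma((df + 1.0) / 2.0) - math.lgamma(df / 2.0)
            - 0.5 * math.log(df * math.pi))


def student_t_logpdf(x, df, loc, scale):
    z = (np.asarray(x, dtype=float) - loc) / scale
    return (student_t_const(df) - np.log(scale)
            - (df + 1.0) / 2.0 * np.log1p(z * z / df))


def student_t_derivs(x, df, loc, scale):
    """Return (logpdf, d/dx, d/dloc, d/dlog_scale), elementwise."""
    x = np.asarray(x, dtype=float)
    z = (x - loc) / scale
    lp = student_t_const(df) - np.log(scale) - (df + 1.0) / 2.0 * np.log1p(z * z / df)
    w = (df + 1.0) * z / (df + z * z)
    return lp, -w / scale, w / scale, -1.0 + w * z


def mv_student_t2_logpdf(x1, x2, df, loc1, loc2, sd1, sd2, rho):
    """Bivariate Student-T log density (dimension 2), vectorized."""
    u = (np.asarray(x1, dtype=float) - loc1) / sd1
    v = (np.asarray(x2, dtype=float) - loc2) / sd2
    c = 1.0 - rho * rho
    q = (u * u - 2.0 * rho * u * v + v * v) / c
    const = (math.lgamma((df + 2.0) / 2.0) - math.lgamma(df / 2.0)
             - math.log(df * math.pi))
    return (const - math.log(sd1) - math.log(sd2) - 0.5 * math.log(c)
            - (df + 2.0) / 2.0 * np.log1p(q / df))


def inv_logit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


# ---------------------------------------------------------------------------
# parameter containers (natural scale)

@dataclass
class ParticipantParams:
    """Per-participant parameters on the natural scale (arrays of length
    n_participants; learning rates only for M3)."""
    intercept: np.ndarray
    adaptation: np.ndarray
    sigma: np.ndarray
    rate_paired: np.ndarray | None = None
    rate_unpaired: np.ndarray | None = None

    def __post_init__(self):
        self.intercept = np.atleast_1d(np.asarray(self.intercept, dtype=float))
        self.adaptation = np.atleast_1d(np.asarray(self.adaptation, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        for name in ("rate_paired", "rate_unpaired"):
            val = getattr(self, name)
            if val is not None:
                val = np.atleast_1d(np.asarray(val, dtype=float))
                if np.any((val <= 0) | (val >= 1)):
                    raise ValueError(f"{name} must lie in the open unit interval")
                setattr(self, name, val)

    @property
    def n(self) -> int:
        return len(self.intercept)


@dataclass
class Hyperparams:
    """Group-level parameters on their sampled (raw) scales."""
    intercept_avg: float = 0.0
    adaptation_avg: float = 0.0
    sigma_intercept_raw: float = -1.0
    sigma_adaptation_raw: float = -4.5
    rho_raw: float = 0.0
    sigma_avg: float = 1.0
    tau_raw: float = -3.0
    sigma_cue_raw: float | None = None
    rate_paired_avg_raw: float | None = None
    rate_unpaired_avg_raw: float | None = None
    sigma_rate_paired_raw: float | None = None
    sigma_rate_unpaired_raw: float | None = None
    beta_scaling_avg: float | None = None
    sigma_beta_scaling_raw: float | None = None


@dataclass
class CueEffects:
    """Cue effects: a 4x4 [cue, block] array for M2, a 4-vector (z-units
    per unit associative strength) for M3."""
    beta_cue: np.ndarray | None = None
    beta_scaling: np.ndarray | None = None

    def __post_init__(self):
        if self.beta_cue is not None:
            self.beta_cue = np.asarray(self.beta_cue, dtype=float)
            if self.beta_cue.shape != (len(CUES), len(BLOCKS)):
                raise ValueError("beta_cue must be 4x4 [cue, block]")
        if self.beta_scaling is not None:
            self.beta_scaling = np.asarray(self.beta_scaling, dtype=float)
            if self.beta_scaling.shape != (len(CUES),):
                raise ValueError("beta_scaling must have one entry per cue")


def constrain(hyper: Hyperparams) -> dict:
    """Map raw hyperparameters to their natural scales."""
    out = {
        "tau": math.exp(hyper.tau_raw),
        "sigma_intercept": math.exp(hyper.sigma_intercept_raw),
        "sigma_adaptation": math.exp(hyper.sigma_adaptation_raw),
        "rho": math.tanh(hyper.rho_raw),
        "sigma_avg": hyper.sigma_avg,
        "intercept_avg": hyper.intercept_avg,
        "adaptation_avg": hyper.adaptation_avg,
    }
    if hyper.sigma_cue_raw is not None:
        out["sigma_cue"] = math.exp(hyper.sigma_cue_raw)
    if hyper.rate_paired_avg_raw is not None:
        out["rate_paired_avg"] = float(inv_logit(hyper.rate_paired_avg_raw))
        out["rate_unpaired_avg"] = float(inv_logit(hyper.rate_unpaired_avg_raw))
        out["sigma_rate_paired"] = math.exp(hyper.sigma_rate_paired_raw)
        out["sigma_rate_unpaired"] = math.exp(hyper.sigma_rate_unpaired_raw)
    if hyper.beta_scaling_avg is not None:
        out["beta_scaling_avg"] = hyper.beta_scaling_avg
        out["sigma_beta_scaling"] = math.exp(hyper.sigma_beta_scaling_raw)
    return out


# ---------------------------------------------------------------------------
# Rescorla-Wagner machinery

def rw_update(strength, paired, rate_paired, rate_unpaired):
    """One Rescorla–Wagner step: the associative strength moves toward
    the trial outcome (1 = US delivered, 0 = omitted) in proportion to
    the prediction error, with the rate picked by the pairing flag."""
    strength = np.asarray(strength, dtype=float)
    paired = np.asarray(paired)
    if np.any((strength < 0) | (strength > 1)):
        raise ValueError("strength must lie in [0, 1]")
    if not np.all((paired == 0) | (paired == 1)):
        raise ValueError("paired must be binary")
    for name, r in (("rate_paired", rate_paired), ("rate_unpaired", rate_unpaired)):
        if np.any((np.asarray(r) <= 0) | (np.asarray(r) >= 1)):
            raise ValueError(f"{name} must lie in the open unit interval")
    rate = np.where(paired == 1, rate_paired, rate_unpaired)
    out = strength + rate * (paired - strength)
    return out if out.ndim else float(out)


def compute_trajectory(design_rows: pd.DataFrame, rate_paired: float,
                       rate_unpaired: float) -> np.ndarray:
    """CS+ associative strength at each trial of one participant.

    The returned value at trial ``i`` is the strength *before* the
    outcome of trial ``i`` is applied: the cue response is measured
    before/through US delivery, so the update from trial ``i`` only
    affects later trials.  Strength starts at zero, is updated on every
    CSP trial, and is carried forward unchanged on non-CSP trials (so it
    is zero throughout habituation, where all CSPs are unpaired and the
    prediction error is zero).
    """
    trials = design_rows["trial"].to_numpy()
    if np.any(np.diff(trials) <= 0):
        raise ValueError("trials must be strictly increasing")
    is_csp = (design_rows["cue"] == "CSP").to_numpy()
    paired = design_rows["paired"].to_numpy()
    strength = np.empty(len(design_rows))
    s = 0.0
    for i in range(len(design_rows)):
        strength[i] = s
        if is_csp[i]:
            s = float(rw_update(s, paired[i], rate_paired, rate_unpaired))
    return strength


# ---------------------------------------------------------------------------
# model mean, likelihood, prior

def _indices(table: pd.DataFrame):
    cue_idx = pd.Categorical(table["cue"], categories=CUES).codes
    block_idx = pd.Categorical(table["block"], categories=BLOCKS).codes
    if (cue_idx < 0).any() or (block_idx < 0).any():
        raise ValueError("unknown cue or block label")
    return np.asarray(cue_idx), np.asarray(block_idx)


def centered_trial(trial, n_trials_total: int | None = None):
    """Center the 1-based session trial index at the median trial
    (T + 1) / 2, e.g. 88.5 for the standard 176-trial session."""
    trial = np.asarray(trial, dtype=float)
    total = n_trials_total if n_trials_total is not None else int(trial.max())
    return trial - (total + 1) / 2.0


def predict_mu(model: str, params: ParticipantParams,
               cue_effects: CueEffects | None, trajectory: np.ndarray | None,
               table: pd.DataFrame, n_trials_total: int | None = None) -> np.ndarray:
    """Model-specific predicted mean for every row of ``table``.

    ``table`` may hold several participants; participant ids are mapped
    to ``params`` entries in sorted order.  ``trajectory`` (M3) must be
    aligned with the rows of ``table``.
    """
    if model not in MODEL_TAGS:
        raise ValueError(f"unknown model tag {model!r}")
    pid = np.asarray(table["participant"])
    uniq = np.unique(pid)
    if len(uniq) != params.n:
        raise ValueError("participant count mismatch between table and params")
    p_idx = np.searchsorted(uniq, pid)
    tc = centered_trial(table["trial"].to_numpy(), n_trials_total)
    mu = params.intercept[p_idx] + params.adaptation[p_idx] * tc
    if model == "m2":
        cue_idx, block_idx = _indices(table)
        mu = mu + cue_effects.beta_cue[cue_idx, block_idx]
    elif model == "m3":
        if trajectory is None:
            raise ValueError("M3 requires a strength trajectory")
        cue_idx, _ = _indices(table)
        mu = mu + cue_effects.beta_scaling[cue_idx] * np.asarray(trajectory, dtype=float)
    return mu


def log_likelihood(model: str, params: ParticipantParams,
                   cue_effects: CueEffects | None, table: pd.DataFrame,
                   trajectory: np.ndarray | None = None,
                   n_trials_total: int | None = None) -> np.ndarray:
    """Pointwise Normal log density of the amplitudes in ``table``.

    Every row must carry a value (observed or imputed).  For M3 the
    trajectory is computed from ``params`` rates when not supplied.
    """
    amp = np.asarray(table["amplitude"], dtype=float)
    if np.any(~np.isfinite(amp)):
        raise ValueError("every trial needs a value (impute missing amplitudes first)")
    if np.any(params.sigma <= 0):
        raise ValueError("sigma must be positive")
    if model == "m3" and trajectory is None:
        parts = []
        uniq = np.unique(table["participant"])
        for j, p in enumerate(uniq):
            rows = table[table["participant"] == p]
            parts.append(compute_trajectory(rows, params.rate_paired[j],
                                            params.rate_unpaired[j]))
        trajectory = np.concatenate(parts)
    mu = predict_mu(model, params, cue_effects, trajectory, table, n_trials_total)
    pid = np.asarray(table["participant"])
    p_idx = np.searchsorted(np.unique(pid), pid)
    sd = params.sigma[p_idx]
    z = (amp - mu) / sd
    return -0.5 * _LOG_2PI - np.log(sd) - 0.5 * z * z


def log_prior(model: str, params: ParticipantParams, hyper: Hyperparams,
              cue_effects: CueEffects | None = None) -> float:
    """Joint log prior of all sampled parameters.

    Densities are evaluated on the sampled scales: hyperparameters with
    priors stated on a raw scale (``tau_raw`` etc.) contribute plain
    Normal terms with no Jacobian; participant sigmas have their
    Student-T prior on the natural scale; learning rates have their
    multilevel Student-T prior on the logit scale.
    """
    if model not in MODEL_TAGS:
        raise ValueError(f"unknown model tag {model!r}")
    n = params.n
    df = n - 1
    if df <= 0:
        raise ValueError("need at least 2 participants (df > 0)")
    nat = constrain(hyper)
    lp = float(np.sum(student_t_logpdf(params.sigma, df, hyper.sigma_avg, nat["tau"])))
    lp += float(np.sum(mv_student_t2_logpdf(
        params.intercept, params.adaptation, df,
        hyper.intercept_avg, hyper.adaptation_avg,
        nat["sigma_intercept"], nat["sigma_adaptation"], nat["rho"])))
    for name in ("sigma_avg", "tau_raw", "intercept_avg", "adaptation_avg",
                 "sigma_intercept_raw", "sigma_adaptation_raw", "rho_raw"):
        m, s = PRIORS[name]
        lp += float(norm_logpdf(getattr(hyper, name), m, s))
    if model == "m2":
        sigma_cue = nat["sigma_cue"]
        n_cells = cue_effects.beta_cue.size
        lp += float(np.sum(student_t_logpdf(cue_effects.beta_cue, n_cells - 1,
                                            0.0, sigma_cue)))
        m, s = PRIORS["sigma_cue_raw"]
        lp += float(norm_logpdf(hyper.sigma_cue_raw, m, s))
    elif model == "m3":
        for which in ("paired", "unpaired"):
            raw = logit(getattr(params, f"rate_{which}"))
            avg = getattr(hyper, f"rate_{which}_avg_raw")
            scale = nat[f"sigma_rate_{which}"]
            lp += float(np.sum(student_t_logpdf(raw, df, avg, scale)))
            for name in (f"rate_{which}_avg_raw", f"sigma_rate_{which}_raw"):
                m, s = PRIORS[name]
                lp += float(norm_logpdf(getattr(hyper, name), m, s))
        n_cues = len(cue_effects.beta_scaling)
        lp += float(np.sum(student_t_logpdf(
            cue_effects.beta_scaling, n_cues - 1, hyper.beta_scaling_avg,
            nat["sigma_beta_scaling"])))
        for name in ("beta_scaling_avg", "sigma_beta_scaling_raw"):
            m, s = PRIORS[name]
            lp += float(norm_logpdf(getattr(hyper, name), m, s))
    return lp
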