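"""Adaptive Hamiltonian Monte Carlo.

A single-trajectory HMC sampler with dual-averaging step-size
adaptation and diagonal mass-matrix estimation during warmup.  The
number of leapfrog steps is jittered uniformly up to a maximum to avoid
resonant trajectories.  Any model exposing ``logp_grad(theta) -> (lp,
grad)`` can be sampled; the fit front-ends in `inference` and `fmri`
plug their packed models into this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class ChainStats:
    accept_rate: float
    step_size: float
    divergences: int
    seed: int


@dataclass
class _DualAveraging:
    """Nesterov dual averaging of log step size (target acceptance delta)."""
    mu: float
    delta: float = 0.9
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75
    count: int = 0
    h_bar: float = 0.0
    log_eps_bar: float = 0.0

    def update(self, accept_prob: float) -> float:
        self.count += 1
        w = 1.0 / (self.count + self.t0)
        self.h_bar = (1.0 - w) * self.h_bar + w * (self.delta - accept_prob)
        log_eps = self.mu - math.sqrt(self.count) / self.gamma * self.h_bar
        eta = self.count ** -self.kappa
        self.log_eps_bar = eta * log_eps + (1.0 - eta) * self.log_eps_bar
        return math.exp(log_eps)


def _find_initial_step(logp_grad, theta, minv, rng, eps0=None):
    """Crude bracketing: double/halve until the one-step acceptance
    probability crosses 1/2."""
    dim = len(theta)
    eps = eps0 if eps0 is not None else 0.1 / max(dim, 1) ** 0.25
    lp, grad = logp_grad(theta)
    p = rng.standard_normal(dim) / np.sqrt(minv)
    h0 = -lp + 0.5 * np.sum(minv * p * p)

    def h_after(eps):
        p1 = p + 0.5 * eps * grad
        t1 = theta + eps * minv * p1
        lp1, g1 = logp_grad(t1)
        p1 = p1 + 0.5 * eps * g1
        return -lp1 + 0.5 * np.sum(minv * p1 * p1)

    try:
        diff = h0 - h_after(eps)
    except (FloatingPointError, ValueError, OverflowError):
        diff = -np.inf
    direction = 1 if diff > math.log(0.5) else -1
    for _ in range(50):
        eps_new = eps * (2.0 ** direction)
        try:
            diff = h0 - h_after(eps_new)
        except (FloatingPointError, ValueError, OverflowError):
            diff = -np.inf
        if (direction == 1 and diff <= math.log(0.5)) or \
           (direction == -1 and diff >= math.log(0.5)):
            return eps_new if direction == -1 else eps
        eps = eps_new
    return eps


def run_chain(logp_grad, theta0: np.ndarray, n_warmup: int, n_draws: int,
              seed: int, target_accept: float = 0.9, max_leapfrog: int = 32,
              divergence_threshold: float = 1000.0,
              mass0: np.ndarray | None = None):
    """Run one HMC chain; returns (draws array (n_draws, dim), ChainStats).

    Warmup schedule: 15% step-size-only adaptation (with ``mass0`` as
    the initial inverse-mass guess when the model provides parameter
    scales), then two expanding variance windows ending at 50% and 80%
    of warmup, each refreshing the diagonal mass from the accumulated
    posterior variances and restarting step-size adaptation.
    Post-warmup the step size is frozen at the dual-averaged value.
    """
    rng = np.random.default_rng(seed)
    theta = np.asarray(theta0, dtype=float).copy()
    dim = len(theta)
    # inverse mass diagonal ~ posterior variance
    minv = np.ones(dim) if mass0 is None else np.asarray(mass0, dtype=float).copy()
    eps = _find_initial_step(logp_grad, theta, minv, rng)
    da = _DualAveraging(mu=math.log(2.0 * eps), delta=target_accept)

    stage1 = max(1, int(0.15 * n_warmup))
    boundaries = sorted({max(stage1 + 10, int(0.5 * n_warmup)),
                         max(stage1 + 20, int(0.8 * n_warmup))})
    acc_sum = np.zeros(dim)
    acc_sq = np.zeros(dim)
    acc_n = 0

    draws = np.empty((n_draws, dim))
    lp, grad = logp_grad(theta)
    n_div = 0
    n_accept = 0.0

    old_err = np.seterr(over="raise", invalid="raise")
    try:
        for it in range(n_warmup + n_draws):
            p = rng.standard_normal(dim) / np.sqrt(minv)
            h0 = -lp + 0.5 * np.sum(minv * p * p)
            n_steps = int(rng.integers(1, max_leapfrog + 1))
            theta_new, lp_new, grad_new = theta, lp, grad
            p_new = p.copy()
            diverged = False
            try:
                p_new = p_new + 0.5 * eps * grad_new
                for s in range(n_steps):
                    theta_new = theta_new + eps * minv * p_new
                    lp_new, grad_new = logp_grad(theta_new)
                    if not np.isfinite(lp_new):
                        raise FloatingPointError
                    if s < n_steps - 1:
                        p_new = p_new + eps * grad_new
                p_new = p_new + 0.5 * eps * grad_new
                h1 = -lp_new + 0.5 * np.sum(minv * p_new * p_new)
                delta_h = h1 - h0
                if not np.isfinite(delta_h) or delta_h > divergence_threshold:
                    diverged = True
            except (FloatingPointError, ValueError, OverflowError):
                diverged = True
            if diverged:
                accept_prob = 0.0
                if it >= n_warmup:
                    n_div += 1
            else:
                accept_prob = min(1.0, math.exp(-max(delta_h, -700.0)))
                if rng.random() < accept_prob:
                    theta, lp, grad = theta_new, lp_new, grad_new
            if it < n_warmup:
                eps = da.update(accept_prob)
                if it >= stage1:
                    acc_sum += theta
                    acc_sq += theta * theta
                    acc_n += 1
                if it + 1 in boundaries and acc_n >= 10:
                    var = acc_sq / acc_n - (acc_sum / acc_n) ** 2
                    minv = np.clip(var, 1e-10, None) + 1e-8
                    eps = _find_initial_step(logp_grad, theta, minv, rng, eps0=eps)
                    da = _DualAveraging(mu=math.log(2.0 * eps), delta=target_accept)
                    acc_sum[:] = 0.0
                    acc_sq[:] = 0.0
                    acc_n = 0
                if it == n_warmup - 1:
                    eps = math.exp(da.log_eps_bar)
            else:
                n_accept += accept_prob
                draws[it - n_warmup] = theta
    finally:
        np.seterr(**old_err)

    stats = ChainStats(accept_rate=n_accept / max(n_draws, 1),
                       step_size=eps, divergences=n_div, seed=seed)
    return draws, stats
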