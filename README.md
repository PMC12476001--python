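# trialwise

Bayesian multilevel models for single-trial aversive-conditioning data.

In differential conditioning experiments, a conditioned cue (CS+) is
paired with an aversive outcome (US) while perceptually similar
generalization cues (GS1–GS3) are never paired. The steady-state
visually evoked potential (ssVEP) gives one amplitude per trial, but
single trials are noisy, participants differ widely, and trials go
missing. `trialwise` implements a hierarchical Bayesian workflow for
such data:

* **Three generative models** of trial-wise amplitude
  `Amplitude[i] ~ Normal(mu[i], sigma[participant[i]])`:
  * **M1 (adaptation only)** — `mu = intercept_p + adaptation_p · trialCentered`,
    a per-participant linear decline over the session;
  * **M2 (cue-by-block)** — M1 plus a 4×4 `betaCue[cue, block]` array of
    fixed cue effects;
  * **M3 (Rescorla–Wagner learning)** — M1 plus `betaScaling[cue] · strength[i]`,
    where the latent CS+ associative strength follows
    `strength ← strength + rate · (paired − strength)` with separate
    paired/unpaired learning rates per participant (logit scale,
    multilevel Student-T priors).
* **Bayesian missing-trial imputation**: missing amplitudes are sampled
  parameters whose draws are posterior-predictive interpolations.
* **PSIS-LOO model comparison**: Pareto-smoothed importance-sampling
  leave-one-out ELPD with standard errors `sqrt(N · var(elpd_i))`,
  Pareto-k diagnostics, effective parameters (p_loo), stacking weights,
  ELPD breakdowns by cue/block/participant, and Bayesian-bootstrap
  LOO-R² (`1 − var(LOO residuals)/var(data)`).
* **Posterior analyses**: central 95% intervals, a linear
  generalization contrast over (CS+, GS1, GS2, GS3) with weights
  (+3, +1, −1, −3), missing-trial summaries, and grand-mean recreation
  with observed-vs-predicted correlation.
* **fMRI first-level regression** of one ROI's BOLD series with a
  19-column design matrix (12 cue-by-phase regressors, US, 6 motion)
  and AR(1)-Toeplitz noise (`cov[i,j] = sigma² λ^|i−j|`), in an
  *independent* (weak priors per participant) and a *multilevel*
  (group-regularized) variant.
* **A synthetic-data generator** that emulates the 4-block design
  (32 habituation + 3×48 trials, four cues, 100% reinforcement for the
  first six CS+ pairings then exactly 50%), per-participant adaptation
  and noise, extreme-regime learning rates, missing-at-random trial
  loss, and AR(1) BOLD series — so the entire workflow is testable
  without any data download.

Sampling is by an adaptive Hamiltonian Monte Carlo sampler with
hand-derived analytic gradients, dual-averaging step-size adaptation
and diagonal mass estimation; convergence is reported via
rank-normalized split R-hat (< 1.05) and effective sample size.

## Worked example

```python
import numpy as np
import trialwise as tw

design = tw.generate_design(n_participants=24, seed=11)
truth  = tw.default_true_params(24, seed=12)          # study-condition defaults
table  = tw.simulate_amplitudes(design, truth, seed=13)
table  = tw.apply_missingness(table, truth.missing_rate, seed=14)

cfg  = tw.SamplerConfig(n_chains=2, n_warmup=400, n_draws=400, seed=100)
fits = {m: tw.fit_model(m, table, cfg) for m in ("m1", "m2", "m3")}
loos = {m: tw.psis_loo(tw.pointwise_loglik(fits[m], table)) for m in fits}
print(tw.compare([loos[m] for m in ("m1", "m2", "m3")], ["m1", "m2", "m3"]))

bs = fits["m3"].vector("beta_scaling").reshape(-1, 4)
print(tw.summarize(tw.generalization_contrast(bs)))
```

On one such run this prints (fit times a few seconds per model):

```
       rank    elpd       se  elpd_diff  diff_se  p_loo  n_bad_k
model
m3        0 -2627.0  45.1        0.0      0.0   82.9        0
m2        1 -2631.6  45.1       -4.7      4.2   75.4        0
m1        2 -2640.9  45.0      -13.9      5.8   64.3        0

Summary(median=1.144, lo95=0.724, hi95=1.559, excludes_zero=True)
```

The learning model (m3) has the best leave-one-out accuracy on data it
generated, the multilevel priors keep the effective parameter count
(p_loo) far below the nominal count, and the generalization contrast is
credibly positive: the CS+ and near-similar cues respond more strongly
as associative strength accumulates.

The same workflow is available from the shell:

```
trialwise simulate --n-participants 24 --seed 1 --out trials.csv
trialwise fit --model m3 --data trials.csv --out m3.csv --seed 2
trialwise compare --posteriors m1.csv m2.csv m3.csv --data trials.csv --out comparison.csv
trialwise analyze --posterior m3.csv --data trials.csv --out-dir analysis/
trialwise pipeline --config config.yaml
```

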