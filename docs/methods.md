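# Methods

## The data and the models

The dependent variable is the single-trial ssVEP amplitude of a
4-block differential-conditioning session: 32 habituation trials (8
per cue) followed by two acquisition blocks and one extinction block of
48 trials each (12 per cue), 176 trials in total. Cues are the CS+ and
three generalization stimuli (GS1–GS3) of decreasing similarity. The
first six CS+ presentations of acquisition are always paired with the
US (100% reinforcement, with at most two GS trials between consecutive
boosted CS+ trials); afterwards exactly half of the remaining
acquisition CS+ trials are paired; habituation and extinction are never
paired. Within a block the same cue never appears more than twice in a
row.

Every model shares the likelihood

    Amplitude[i] ~ Normal(mu[i], sigma[participant[i]])

with trial index centered at the median trial, trialCentered = trial −
(T+1)/2 (88.5 for T = 176). Missing amplitudes are entered as sampled
parameters, so the posterior imputes them from the model's prediction
and the participant's trial-level error; cross-validation is computed
over observed trials only.

**M1 (adaptation only).** mu = intercept_p + adaptation_p · trialCentered.
Participant pairs (intercept, adaptation) share a bivariate Student-T
prior with df = nParticipants − 1, estimated means, scales
sigmaIntercept = exp(raw), sigmaAdaptation = exp(raw) and correlation
rho = tanh(raw). Hyperpriors (on the sampled scales):
interceptAverage ~ N(0, 0.2), adaptationAverage ~ N(0, 0.01),
sigmaInterceptRaw ~ N(−1, 1), sigmaAdaptationRaw ~ N(−4.5, 0.75),
rhoRaw ~ N(0, 1). Trial noise: sigma_p ~ StudentT(df = n−1,
sigmaAverage, tau), sigmaAverage ~ N(1, 0.5), tau = exp(tauRaw),
tauRaw ~ N(−3, 1). At 24 participants M1 has 79 sampled scalars
(3 × 24 + 7) excluding imputed amplitudes.

**M2 (cue-by-block)** adds betaCue[cue, block] (16 entries), each with
a StudentT(df = 16 − 1, 0, sigmaCue) prior, sigmaCue = exp(raw),
sigmaCueRaw ~ N(−0.5, 1.5). The zero location lets cue effects deviate
from each participant's adaptation line.

**M3 (Rescorla–Wagner learning)** adds betaScaling[cue] · strength[i].
Strength starts at 0, is updated on every CS+ trial by
strength ← strength + rate · (paired − strength), with the paired or
unpaired learning rate chosen by the US flag, and is carried forward
unchanged on other trials; the value used to predict trial i is the
one *before* trial i's own update (the cue response is measured
before/through US delivery). Rates live on the logit scale with
multilevel StudentT(df = n−1, avgRaw, exp(scaleRaw)) priors,
avgRaw ~ N(0, 1.5) and scaleRaw ~ N(−0.5, 1.5) for each of the paired
and unpaired families; betaScaling has its own multilevel prior
StudentT(df = 3, avg, exp(scaleRaw)), avg ~ N(0, 1),
scaleRaw ~ N(−0.5, 1.5). At 24 participants M3 has 137 sampled
scalars.

Jacobian convention: priors stated on a raw sampled scale (all the
`*Raw` hyperparameters and the logit-scale rates) contribute no
Jacobian; the participant sigmas have their prior on the natural scale
and are sampled as log(sigma), so a +log(sigma) term is included.

## Sampling

No probabilistic-programming backend is assumed: the package ships an
adaptive Hamiltonian Monte Carlo sampler over hand-derived analytic
gradients (verified against finite differences in the test suite).
Warmup uses dual-averaging step-size adaptation (target acceptance
0.9) with a model-informed initial diagonal inverse-mass (parameters
span scales from ~1e−3 adaptation slopes to ~0.5 z-unit imputed
amplitudes) refreshed from accumulated posterior variances at 50% and
80% of warmup; the number of leapfrog steps is jittered uniformly up to
a cap (default 32). Chains are seeded deterministically from the fit
seed and are exactly reproducible.

Two reparameterizations keep the posterior geometry tractable:

* learning rates are sampled non-centered, z ~ StudentT(df, 0, 1) with
  logit(rate) = avgRaw + exp(scaleRaw) · z, which is the same prior in
  better-conditioned coordinates;
* the multilevel fMRI variant samples standardized offsets for all
  participant-level parameters (betas, logit noise correlation, log
  noise SD) around the estimated group means and spreads.

The learning model is additionally multimodal (see Limitations), so
chains start from a short L-BFGS polish of a data-informed initial
point: cue scalings are first estimated by regressing per-participant
detrended residuals on a high-rate reference strength trajectory (with
a second pass restricted to provisionally learning participants, since
pooling non-learners attenuates the estimate), and each participant
starts in the learner regime only if that raises its own likelihood.

Convergence is reported per sampled scalar by rank-normalized split
R-hat and effective sample size (via arviz); any fit with R-hat ≥ 1.05
carries an explicit warning object. Reference budgets at which all
models converge (R-hat < 1.05 everywhere) on the standard synthetic
conditions: M1/M2 2 chains × (600 + 600); M3 4 chains × (1200 + 1500)
with leapfrog cap 48; both fMRI variants 2 chains × (300 + 300). The
acceptance harness uses lighter chains (2 × (300 + 350)) for its 20-seed
recovery and comparison sweeps, trading some R-hat headroom for
runtime; these sizes are package choices recorded here.

## Model comparison

PSIS-LOO follows the reference procedure: per observation the log
importance ratios −loglik are tail-smoothed by a generalized-Pareto
fit (profile-likelihood point estimate with the weakly informative
shape regularization) to the M = min(0.2 S, 3 √S) largest ratios,
replaced by the fitted quantiles, and truncated at S^(3/4) times the
mean weight; elpd_i = log(Σ w exp(ll) / Σ w). The Pareto shape k is
reported per observation and k > 0.7 is flagged, never auto-dropped.
SE = sqrt(N · var(elpd_i)) with the sample-variance (ddof = 1)
convention; p_loo = Σ (lpd_i − elpd_i). The implementation is checked
against exact refit-LOO on a conjugate toy and against arviz.
Stacking weights maximize Σ_i log Σ_m w_m exp(elpd_im) on the simplex
via softmax-parameterized L-BFGS with multi-start and a vanishing
ridge, which breaks exact ties uniformly. LOO-R² uses the
PSIS-weighted posterior-mean prediction per observation and
Dirichlet(1,…,1) weight resampling over observations (4,000 replicates
by default); samples can be negative.

The generalization contrast is a zero-sum linear trend over (CS+, GS1,
GS2, GS3), default weights (+3, +1, −1, −3), applied per block to M2's
betaCue and once to M3's betaScaling; the weights are configurable
since only the direction, not the exact contrast, is canonical.
Grand-mean recreation averages observed amplitudes and posterior-mean
predictions per (cue, session trial) cell over the participants shown
that cue at that trial, smooths both surfaces per cue with a centered
±2-trial moving average (edges truncated), and reports Pearson r over
paired non-empty cells with t = r sqrt((n−2)/(1−r²)). Quantiles
everywhere use linear interpolation between order statistics.

## fMRI first-level model

One ROI's BOLD series (percent-signal units) is regressed on 19
columns: 12 cue-by-phase regressors (phases: habituation, acquisition,
extinction), one US regressor, six motion parameters. Stimulus
regressors are boxcars (2 s cues, 0.1 s US) convolved with a
gamma-variate kernel h(t) ∝ t^8.6 exp(−t/0.547) (peak ≈ 4.7 s),
rescaled so an isolated event's ideal response peaks at exactly 1; the
kernel is config-swappable. Noise is stationary AR(1) with Toeplitz
covariance sigma² λ^|i−j|; λ gets a uniform(0, 1) prior sampled on the
logit scale (with the corresponding Jacobian), and censored volumes are
removed by row deletion. Because AR(1) is Markov, the censor-reduced
joint density factorizes exactly into per-volume innovations
N(λ^d · prev, sigma²(1 − λ^{2d})) at gap d; this factorization is the
gradient path and supplies the per-volume pointwise log-likelihood for
PSIS-LOO (the public `gls_loglik` computes the same value by Cholesky
of the reduced Toeplitz covariance, and the two are tested equal to
1e−8 against a dense multivariate-normal oracle). The independent
variant uses beta ~ N(0, 10) and log sigma ~ N(0, 1.5) per participant;
the multilevel variant gives every per-participant parameter a Normal
prior with simultaneously estimated group mean and spread
(hyperpriors: beta means N(0, 5), scalar means N(0, 1), all log
spreads N(−1, 1)). High-pass detrending is a 5th-order Butterworth
(default cutoff 0.0065 Hz) applied forward and reverse (zero phase).

## Synthetic-data calibration

The generator's defaults are the study conditions and are not tuned:

* 24 participants × 176 trials; intercepts ~ N(0.44, 0.2), adaptation
  slopes ~ N(−0.005, 0.002) (z-units per trial), trial noise ~0.5
  z-units (lognormal spread 0.15) — the strong-signal recovery regime;
* learning-rate regimes mirroring the three reported participant
  patterns: ~70% non-learners (paired rate near 0, unpaired rate split
  between the extremes), ~21% learners (paired near 1, unpaired near
  0), ~8% volatile (both near 1);
* shared betaScaling = (0.35, 0.20, 0.08, 0.0) z-units per unit
  strength, chosen so the implied generalization contrast
  (3·0.35 + 0.20 − 0.08 ≈ 1.17) sits at the magnitude reported for
  learning-model fits of such data;
* 16% missing trials, completely at random (≈148/176 retained, the
  reported average retention); the real missingness mechanism is
  unknown, so MCAR is an idealization;
* fMRI: 8 participants × 160 volumes (TR 2 s), group betas with SD 0.3
  between participants, λ = 0.4, unit noise SD, 5% censoring.

What the generator does *not* emulate: EEG artifact structure and
non-MCAR trial loss, non-linear or plateauing adaptation, per-cue
intercepts, between-participant differences in the generalization
gradient, and fMRI spatial structure (a single ROI series is
simulated). Passing tests therefore certify the statistical machinery
under the model's own assumptions, not robustness to violations of
them.

Z-scoring within participant (population-SD convention, observed
trials only) is provided as a preprocessing operation; recovery
harnesses fit the un-standardized simulated amplitudes so group-level
truths remain well-defined.

## Pipeline configuration

`trialwise pipeline --config config.yaml` reads a YAML mapping with
keys (defaults in parentheses): `seed` (required), `out_dir`
(required), `n_participants` (24), `sigma` (0.5), `missing_rate`
(0.16), `models` ([m1, m2, m3]), `n_chains` (4), `n_warmup` (500),
`n_draws` (500), `target_acceptance` (0.9), `max_leapfrog` (32),
`contrast_weights` ([3, 1, -1, -3]), `data` (null — a trial-table CSV
path to ingest instead of simulating), `allow_nonconverged` (false),
`loo_r2_boot` (2000). Unknown keys are rejected by name. Every output
CSV carries a `# config_hash=` comment derived from the scientific
settings (the output path is excluded), and posterior sidecars record
the model tag, seed and sampler settings.

## Numerical choices

* tanh-saturated correlations are clamped away from ±1 (1e−15) in the
  bivariate Student-T; overflow in any leapfrog step is treated as a
  divergent trajectory (rejected and counted).
* The strength recursion and its forward-mode rate derivatives run in a
  numba kernel; gradients of every model are validated against central
  finite differences at 1e−3 relative tolerance.
* Exact ties in stacking are resolved uniformly by the vanishing ridge;
  identical models receive equal weights.
* Degenerate PSIS inputs (all draws identical for an observation)
  short-circuit to elpd_i = loglik with an undefined (NaN) Pareto k.
* CSV round-trips use 17-significant-digit formatting and round-trip
  float parsing, so persisted posteriors reload bit-identically.

## Known limitations

* **Learning-rate identifiability.** With continuous trial-level data
  at realistic noise, the Rescorla–Wagner rate trades off against the
  cue scalings: a fast-step trajectory (rate ≈ 1, moderate
  betaScaling, large hierarchical rate spread — a U-shaped implied
  rate distribution) and a slow-ramp trajectory (rates ≈ 0.03–0.05,
  inflated betaScaling, small rate spread) produce nearly identical
  late-session predictions and differ only on a handful of early
  acquisition trials. The joint posterior is bimodal; the fast basin
  has the higher mode but the broad slow basin carries comparable
  mass, and HMC chains settle in one basin per run (about half the
  synthetic replicates each way, regardless of initialization).
  Per-participant paired-rate medians above 0.8 are therefore only
  recovered in fast-basin replicates; group-level quantities
  (adaptation, cue contrasts, ELPD ordering, imputation) are stable
  across basins. Sharper identification would need stronger cue
  effects, lower noise, or designs that separate the trajectory shapes
  (e.g. more unpaired CS+ early in acquisition).
* Split R-hat at the light 2-chain harness budgets can sit slightly
  above 1.05 for heavy-tailed rate offsets and a few imputed trials;
  the reference budgets above push all R-hat below 1.05.
* The AR(1) Toeplitz form is a deliberate simplification of the
  ARMA(1,1) used by REML-based fMRI packages; the HRF kernel is a
  standard gamma-variate, not a bit-exact reproduction of any
  particular toolbox's kernel. Both are config-exposed.
* Stacking assumes aligned observation sets; no k-fold or WAIC
  alternatives are provided.
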