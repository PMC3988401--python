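# Methods

## The model

`satddm` analyses two-alternative forced-choice behavior (leftward vs
rightward coherent motion) with the drift-diffusion model (DDM). Evidence
X(t) accumulates as a Wiener process with drift between absorbing
boundaries 0 and a, starting at z·a; absorption at the upper boundary is
the rightward response, at the lower the leftward one, and the observed
response time is the absorption time plus a non-decision time Ter covering
stimulus encoding and motor execution. The full model carries seven
parameters per design cell:

| parameter | meaning | units / domain |
|---|---|---|
| a | boundary separation (response caution) | evidence units, > 0 |
| v | mean drift rate (evidence quality) | evidence / s, signed |
| z | mean relative starting point (response bias) | (0, 1); 0.5 = unbiased |
| Ter | mean non-decision time | s, >= 0 |
| sv | SD of normal trial-to-trial drift variability | >= 0 |
| sz | range of uniform starting-point variability | >= 0, z ± sz/2 in (0, 1) |
| st | range of uniform non-decision-time variability | s, Ter − st/2 >= 0 |

**Noise scaling.** All parameters live on the s = 1 intra-trial noise
scale, not the historical s = 0.1 convention; magnitudes are therefore 10×
the Ratcliff-style values. This matches the scale used by the hierarchical
Bayesian DDM toolboxes this package's workflow resembles.

**Response coding.** Stimulus coding throughout: the upper boundary is
always "right". A leftward stimulus negates the drift sign at both
simulation and likelihood time, so one v per cell measures sensitivity and
z > 0.5 means a rightward button bias.

## Likelihood

The pure 4-parameter first-passage density is computed by the standard
infinite-series expansions with adaptive switching: for each evaluation the
small-time and large-time representations' required term counts at the
requested truncation error (eps, default 1e-7 absolute) are compared and
the cheaper one is used. sv is integrated in closed form (the Gaussian
drift integral has an analytic solution); sz and st are integrated by
fixed-node Gauss-Legendre quadrature, 11 nodes per dimension by default.
At the generator's variability magnitudes (sz = 0.05, st = 0.1) 5 nodes
already reproduce the 41-node density to < 1e-3 relative error, so the
reduced-scale fits in the test-suite and analysis drivers use 5 nodes.
Densities are clamped at 1e-15 before logging so outlier RTs keep the
posterior finite; no explicit contaminant mixture is modelled.

**Censoring correction.** Preprocessing removes trials slower than 2200 ms
(and faster than 100 ms). The hierarchical likelihood therefore conditions
each trial's density on a response within 2.2 s by default: per cell and
drift sign, P(RT <= 2.2) is computed from the closed-form large-time series
CDF, with Gauss-Hermite integration (15 nodes) over sv and Gauss-Legendre
over sz/st, and subtracted in log per trial. With the generator's slowest
cells carrying 2-3% censored mass, omitting this correction biases a
downward and Ter upward by several posterior SDs; `censor_s=None` gives the
plain likelihood, appropriate when censoring is negligible.

## Hierarchy and priors

Subject-level a, v, Ter vary by session and (depending on the constraint
variant) by instruction condition; z varies by session only; sv, sz, st
are single group-level scalars shared across subjects, sessions and
conditions. Subject-level parameters are draws from session/condition
group distributions: Normal for v, zero-truncated Normal for a and Ter,
logit-Normal for z. Hyperpriors (weakly informative on the s = 1 scale):
group means a ~ N(1.5, 1) on (0, 5], v ~ N(2, 3²),
Ter ~ N(0.4, 0.25²) on (0, 1], logit z ~ N(0, 1); group SDs
~ Half-N(0.5); sv ~ Half-N(2); sz ~ Uniform(0, 0.5) jointly constrained so
every z ± sz/2 stays in (0, 1); st ~ Half-N(0.3) constrained by
Ter − st/2 >= 0. These are declared defaults, not values inferred from any
dataset.

The seven constraint variants are the non-empty subsets of {a, v, Ter}
free to differ between speed and accuracy instructions: model 1 = all
three, model 2 = {a, v}, model 3 = {a, Ter}, model 4 = {v, Ter},
model 5 = {a}, model 6 = {v}, model 7 = {Ter}. Labels 1, 3 and 6 are
fixed by the reported best / second-best / worst ranking; the remaining
assignment is this package's convention.

## Sampling

Adaptive Metropolis-within-Gibbs with blocks chosen for the posterior's
correlation structure: per subject × session, condition-specific
(a, v, Ter) random-walk blocks against their own cell's trials and a
scalar z update against both cells; one joint block for the free
variability parameters (swept 3× per iteration); per group a joint
(mean, SD) block (swept 2×). Per-block proposal scales adapt by
Robbins-Monro toward 0.44 (scalar) / 0.3 (small blocks) acceptance during
burn-in only and are frozen afterwards, preserving detailed balance of
retained draws.

Componentwise sweeps alone cross the weakly identified (sz, sv) ↔ (v, a)
ridge of the full DDM too slowly for short chains, so the sampler adds
Haario-style global moves: a multivariate normal proposal over the
subject-level + variability subspace with covariance estimated from the
burn-in history (updated every 25 iterations, frozen at burn-in), scaled
2.38/√d and adapted toward 0.25 acceptance, three proposals per
iteration. Cell log-likelihoods are cached and only recomputed for blocks
whose slots changed, which also makes per-iteration deviance recording
free.

Chains start from EZ-style closed-form moment estimates (accuracy, RT mean
and variance per cell), refined by a short blockwise Nelder-Mead pass
toward conditional posterior modes. Defaults are 15,000 samples with 5,000
burn-in and a single chain; the API accepts n_chains for multi-chain
diagnostics. Everything is reproducible bit-for-bit from
(data, variant, priors, seed).

**Convergence.** The Geweke statistic compares the means of the first 10%
and last 50% of a chain, with spectral-density-at-zero variances estimated
by a Bartlett window whose lag length uses the Andrews AR(1) plug-in
bandwidth; this calibrates to ~95% |z| < 2 on white-noise chains while
still flagging trends at |z| > 20. Constant chains return 0 with a
warning.

**Model comparison.** DIC = mean deviance + pD with Spiegelhalter's
pD = mean deviance − deviance at the posterior mean (the half-variance pV
is available as an option). On a conjugate k-free-means reference model
the sampler + DIC machinery reproduce pD = k within 0.1. All variant fits
share priors, seeds and sampler settings so DIC differences reflect the
constraints alone.

## Posterior analysis

Posterior predictive checks draw whole rows of the draw matrix per
participant (preserving joint posterior correlations; 500 draws by
default), simulate the observed number of trials per session × condition
cell, and average per-draw signed-RT histograms (errors on the negative
axis, correct responses positive; 0.1 s bins over ±2.4 s) into the
predicted curve, pooled across participants. Hypothesis probabilities
P(contrast > 0) are the fraction of retained draws in which a signed
combination of group-level slots exceeds zero, with strict inequality, so
a degenerate contrast returns 0 (with a warning), not 0.5.

## Behavioral statistics

Trials are retained when 100 ms <= RT <= 2200 ms and a response exists
(both boundaries inclusive; filtering is idempotent). Block summaries give
mean RT, accuracy and trial count per subject × session × block — 36
speed and 36 accuracy blocks for a complete subject. The single-subject
randomization test uses t = (mean₁ − mean₂)/SE with the unpooled (Welch)
standard error and a label-shuffling null (100,000 permutations by
default); the one-sided p is the plain proportion of shuffled statistics
strictly exceeding the observed one, with |t| for the two-sided option and
no add-one correction (available by flag). When the number of distinct
assignments is at most n_perm the null is enumerated exhaustively and p is
exact. The speed-condition deadline is the 40% empirical quantile (linear
interpolation) of the session's first accuracy block.

## Synthetic experiment generator

The generator emulates the study design exactly: 6 participants × 6
sessions × 12 blocks × 56 trials; 6 accuracy + 6 speed blocks per session
with the first always accuracy and the rest shuffled; 28 leftward + 28
rightward stimuli per block; trained direction pairs (30/210 or 150/330)
alternated across participants and switched to the untrained pair in
session 6; a 2400 ms response window with non-responses emitted as missing.

Generating trajectories (group means, s = 1 scale): a declines linearly
1.8 → 1.2 over sessions 1-5 with a constant +0.3 accuracy-condition
effect; v rises 1.5 → 3.6 (session 6 drops to 2.2, the transfer pattern)
with a +0.6 condition effect decaying to zero by session 4; Ter = 0.38 s
with a +0.06 s condition effect under the same decay; z = 0.5; sv = 1.0,
sz = 0.05, st = 0.1 s. Between-subject SDs 0.15 (a), 0.30 (v), 0.03 s
(Ter), 0.02 (z), drawn independently per cell to match the fitted
hierarchy's exchangeability assumption. These magnitudes were chosen once
so simulated behavior lands in realistic ranges (accuracy ~0.8-0.98, mean
RT ~500-890 ms, ~0.6% of trials discarded by the RT filter); late-session
accuracies run a few points above a typical trained observer's ~0.95.
They are generator choices, not estimates from any dataset.

What the generator does **not** emulate: sequential and fatigue effects,
within-block learning, the feedback/bonus economy, direction-specific
biases, and any contaminant (non-decision) responses. Passing tests
therefore demonstrate that the estimation machinery is correct and well
calibrated under the model's own assumptions at realistic magnitudes —
not that the model is a complete account of real data.

## Problem sizes used by the test-suite and acceptance script

- Simulator/likelihood agreement: 5 parameter sets × 10⁶ trials at
  dt = 1e-3 with the bridge correction, chi-square over 0.1 s bins.
- Recovery: 2 subjects × 2 sessions × 672 trials, full variant,
  3,000 samples / 1,000 burn-in, 5 quadrature nodes.
- Identification: 3 subjects × 1 session per replicate, sz = st = 0 in
  generator and models (sv free), 7 variants × 10 replicates per effect
  pattern, 1,200 / 400 chains.
- Randomization calibration: 2,000 null tests × 2,000 permutations.

## Numerical choices

Series truncation eps = 1e-7; Euler step dt = 1e-4 by default with a
Brownian-bridge within-step crossing test (bulk simulation uses 1e-3,
validated by chi-square at 10⁶ trials); crossing times recorded at step
midpoints; density floor 1e-15; censor normalization floored at 1e-12;
ties at zero in contrasts count as not exceeding; empty predictive cells
are skipped with a warning; a constant chain yields Geweke z = 0 with a
warning.

## Known limitations

- Single-chain Geweke checking follows the original workflow; between-chain
  diagnostics require passing n_chains > 1.
- sz and st are weakly identified at realistic magnitudes; their posteriors
  are prior-sensitive, and short chains rely on the global moves to span
  the (sz, sv, v) ridge.
- The censoring correction ignores the (negligible) mass below the 100 ms
  cutoff.
- DIC is the only comparison metric, mirroring the workflow this package
  reimplements; WAIC/LOO are out of scope.
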