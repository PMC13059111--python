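# Methods

This note documents the models, algorithms, defaults and design choices in
`causalddm`, and what the synthetic-data tests do and do not establish.

## The task and the measured quantities

In a launching display, one disc collides with another that starts moving
after a lag of 0–144 ms (10 levels, 16-ms steps). Observers report a causal
or non-causal impression on each of 400 trials (20 per lag per motion
direction, four blocks). Two behavioral summaries drive the analysis:

- **PCA (point of causality ambiguity).** The proportion of non-causal
  reports as a function of lag x is fit per subject with the bounded logistic
  `y = 1 / (1 + exp(b (t − x)))`, asymptotes fixed at 0 and 1, both free
  parameters positive. The PCA is the fitted `t`, the lag of 50% non-causal
  responding; the predicted proportion at `x = t` is exactly 0.5. Fitting is
  unweighted nonlinear least squares on the 10 lag-aggregated proportions,
  with a deterministic multi-start (b ∈ {.02,.05,.1,.2} × t ∈ {40,80,120},
  bounds b ∈ (1e-4, 1], t ∈ (1e-3, 500] ms). Adjusted R² is computed on the
  aggregated points (n = lag levels, p = 2); subjects with all-trials
  adjusted R² below 0.9 are excluded (0.90 itself is kept: the exclusion rule
  is "< 0.9").
- **Serial dependence.** Trials are binned by the previous trial's response
  (block-initial trials have no history and enter neither bin), each bin is
  fit separately, and the index is PCA(t-1 causal) − PCA(t-1 non-causal).
  Positive values mean judgments are pulled toward the previous report. The
  sign convention follows the direction in which all group summaries of this
  literature are positive.

## Trait clustering

The 5 AQ and 9 SPQ subscale scores are z-scored per column (sample sd,
n−1) and clustered with Hartigan–Wong k-means (squared Euclidean distance,
≤ 25 sweeps, best of 50 k-means++ restarts; the transfer criterion
`n_j/(n_j+1)·d²(x,c_j) < n_i/(n_i−1)·d²(x,c_i)` makes the objective
non-increasing). K = 2..10 solutions are scored by mean silhouette,
R² = 1 − WSS/TSS, and a spherical-Gaussian BIC with pooled variance
σ̂² = WSS/(d(n−K)) and penalty (Kd + K)·ln n; K is selected by maximum
silhouette. K = 1 is omitted (silhouette undefined there). BIC formulas for
k-means vary across packages; ours is stated so a constant offset against
other software is diagnosable — silhouette and R² are the primary surface.

A K = 3 solution is labeled by centroid profile: highest mean z over the
cognitive-perceptual SPQ subscales (ideas of reference, odd beliefs, unusual
perceptual experiences, odd behavior, odd speech, suspiciousness) → SSD-like;
highest over the socio-affective set (no close friends, social anxiety,
constricted affect, AQ social skills, communication) → ASD-like; remainder →
low-trait (LT). Ties fall back to the overall centroid mean (lowest → LT).

## Drift-diffusion model

Decisions are modeled as a unit-variance Wiener process with drift `v`
from start `z·a` between absorbing boundaries 0 and `a`; the upper boundary
is a non-causal judgment, the lower causal, and RT = decision time + `t0`.
The likelihood is the Wiener first-passage density via the dual
small-time/large-time series with the standard crossover rule, truncated at
absolute error 1e-7. The closed-form choice probability is
P(upper) = (1 − e^{−2vaz}) / (1 − e^{−2va}) (expm1-stabilized; limit z as
v → 0) — the form that satisfies both driftless and strong-drift limits.
The simulator is Euler–Maruyama (default dt = 1e-4 s) with a
Brownian-bridge within-step absorption correction, which removes the
O(√dt) boundary-discretization bias; at 1e6 draws its defective CDFs agree
with the density to KS < 0.002.

### Hierarchy and the 18 specifications

Each of z, v, a, t0 may depend on collision lag, trait cluster, both, or
neither; the 18 candidate dependency structures enumerate the combinations
of interest, from the fully pooled baseline (model 1) through the structure
in which z, v, a vary with lag × cluster and t0 with lag (model 16). For
every parameter there is one group-level Normal (mean, sd) per dependency
cell on a transformed scale — logit for z, log for a and t0, identity for v
— and one subject-level value per subject per applicable cell, drawn from
the subject's cell distribution. Informative group-mean priors mirror the
hierarchical-DDM defaults published for perceptual tasks: v ~ N(2, 3),
a ~ Gamma(1.5, scale 0.75), t0 ~ Gamma(0.4, scale 0.2) (both applied to the
natural-scale mean with the log Jacobian), logit z ~ N(0, 0.5); group sds
get boundary-avoiding Gamma(2, s/2) priors with prior-mean spread s = 0.5
(z), 1.0 (v), 0.3 (a, t0) on the transformed scales — a density vanishing
at zero is the standard stabilizer for centered hierarchical samplers,
whose classic failure mode is a funnel at group-sd ≈ 0 (with ~10 subjects
per cell a zero spread is unidentifiable anyway). The non-informative
regime widens all of these. Inter-trial variability parameters (sv, st,
sz) are not modeled.

### Sampling and comparison

Adaptive Metropolis-within-Gibbs: every subject-level value is a scalar
random-walk block with its proposal scale adapted toward 0.44 acceptance in
25-iteration batches during burn-in (diminishing gain); subject updates
touch only that instance's trials, and per-trial log densities are cached
so each proposal costs one likelihood pass over the affected trials.
Group-level means and sds use independence proposals drawn from their
likelihood-only conditionals — mu' ~ N(x̄, sd²/n) and sd'² ~
InvGamma(n/2, S/2) — so the Metropolis ratio reduces to the prior ratio
and these blocks mix essentially iid. Every 5th iteration an interweaved
rescaling move proposes jointly scaling a cell's group sd and its members'
deviations from the group mean (acceptance ratio L'/L · λ ·
p(λ·sd)/p(sd)), which breaks the residual sd/subject-value funnel
coupling. Initialization is data-driven (t0 from the subject's minimum RT,
v from the choice fraction, a and z near neutral) with per-chain jitter. Desk-scale default is 4 chains × 2000 iterations (burn-in
1000); the full-scale setting (4 × 10000/5000) is the same code path with
different arguments.

Convergence is the classic Gelman–Rubin R̂ (floored at 1); model comparison
uses DIC = D̄ + pD with pD = D̄ − D(θ̄), deviance −2 log L evaluated from
the cached per-iteration likelihood and at the posterior mean of the
subject-level parameters. Credible differences subtract paired posterior
draws and check whether the 95% shortest (HDI) interval excludes zero.
Validation utilities: posterior predictive checks (replicates simulated
from posterior draws, compared per cluster × lag on RT quantiles
10/30/50/70/90% and choice rates), parameter recovery (synthesize from a
posterior draw, refit, correlate truth with estimates), and prior-robustness
refits (correlating posterior means across the two prior regimes).

## Nonparametric statistics

- **ART ANOVA** (mixed designs, one between × up to two within factors):
  responses are aligned per effect from cell means — the full-cell mean plus
  an additive subject effect is removed for within-effect targets, while
  between-effect targets retain subject deviations (their error stratum) —
  the inclusion-exclusion marginal estimate of the target effect is added
  back, values are mid-ranked, and a balanced split-plot ANOVA on ranks
  supplies the target effect's F. The split-plot engine tests between
  effects against subjects-within-groups and within effects against their
  factor × subjects-within-groups stratum, with Greenhouse–Geisser epsilon
  applied to within effects with more than two levels (and their
  interactions with the between factor). Under a null 2 × 3 design the
  pooled type-I rate is ≈ 0.05 (measured 0.052 over 1000 replicates).
- **Wilcoxon tests**: signed-rank W = sum of positive-difference ranks
  (zeros dropped, mid-ranks), rank-sum U, both with tie-corrected normal
  approximations. The effect size is r = Z/√N. (The matched-pairs
  rank-biserial formula would give different values; Z/√N is the form
  consistent with the published magnitudes this field reports, e.g.
  W = 11,049 at N = 150 → r = 0.83.)
- **Kruskal–Wallis** with η²[H] = (H − k + 1)/(n − k); **DSCF** post-hocs
  re-rank each pair and refer √2·|z| to the studentized range (k, df → ∞).
- **Holm** step-down correction; one-way ANOVA with η² and pooled-sd
  Cohen's d; Pearson correlations; normality diagnostics (bias-corrected
  skewness/excess kurtosis, Shapiro–Wilk).

## Synthetic data generator

The generator emulates the study conditions: 150 subjects in three trait
clusters (44 ASD-like / 56 LT / 50 SSD-like), the 0–144 ms lag grid, 400
trials over four blocks. Questionnaire scores are integer subscale totals
clipped to item counts (AQ 10 per subscale; SPQ 9/8/7/9/7/9/9/8/8), with
cluster profiles elevated by `trait_effect` (default 1.5) × `noise_sd`
(default 2.0) on the subscales characteristic of each profile: the
socio-affective set (plus the remaining AQ subscales) for ASD-like, the
cognitive-perceptual SPQ set for SSD-like, and — matching the reported
profile structure — attention switching and imagination elevated in *both*
non-LT clusters. The shared elevations keep the three centroids
non-collinear, so silhouette selection resolves K = 3 rather than collapsing
the continuum to K = 2; after z-scoring, each profile's unelevated
dimension lands below the column mean, reproducing the diametric radar-plot
shape. The synthetic K = 3 silhouette (≈ 0.2) is lower than the ≈ 0.36
reported for real questionnaire data — integer clipping and independent
per-subscale noise make the synthetic clusters fuzzier — so silhouette
*values* should not be compared across the two, only the selection
behavior. Task data are
drawn from the diffusion process itself: drift
`v(lag) = drift_slope · (lag − drift_offset_ms)`, cluster parameters chosen
so that the synthetic study reproduces the phenomenology of the real one —
SSD-like with a causal starting bias (z = 0.46), the lowest boundary
(a = 0.90), fastest responses and the latest drift zero-crossing (82 ms);
ASD-like with the highest boundary (1.18); LT intermediate. With these
defaults the full-scale synthetic study lands near the reported group
structure (mean adjusted R² ≈ 0.94, group PCAs ≈ 74/73/91 ms, mean RTs
≈ 0.47/0.45/0.33 s).

Serial dependence is generated by a starting-point shift: ± `history_shift_delta`
(default 0.10, in z units) after a causal/non-causal response,
block-initial trials unshifted. This z-shift mechanism is this package's
generative assumption — the behavioral literature links choice-history bias
to starting-point shifts, but no generative model is fixed by the task
itself, so the generator should be read as one concrete instantiation.
Between-subject spread uses transformed-scale normals
(sd 0.25 logit-z, 0.15 v, 0.12 log-a, 0.15 log-t0); these fields exist so
that parameter-recovery correlations are a meaningful quantity. Motion
direction is carried as metadata only.

The `recovery_config` fixture (2 clusters, 3 lags, no history shift) exists
so that the generative process matches the fitted model exactly; recovery
runs use it rather than the full study configuration.

### What the synthetic tests do not show

The generator draws from the same model family the DDM stage fits, so
recovery results certify the estimation machinery, not the adequacy of the
DDM for real behavior. Real data bring contaminant RTs, lapses, fatigue and
questionnaire measurement structure that the generator does not emulate;
the psychometric and clustering stages would face heavier tails and weaker
separations there. The pipeline's reader accepts third-party deposits via a
column map precisely so the same code can be pointed at real data.

## Numerical and scale choices

- Lag labels in circulation differ by a frame (46/62/78 vs 48/64/80); the
  reader snaps lags to the canonical 16-ms grid within ±1 ms and rejects
  anything farther.
- WFPT series tolerance 1e-7 (absolute); densities at or below t0 are 0,
  log-densities −inf; proposals leaving hard transformed-scale bounds are
  rejected.
- HDI mass defaults to 95%.
- Desk-scale problem sizes: the recovery fit uses 20 subjects, 2 clusters,
  3 lags, 100 trials/lag with 4 × 2000 MCMC; the DIC model-recovery sweep
  uses 48 subjects × 12 trials/lag with 2 × 1000 MCMC per fit, a regime of
  many weakly informed subjects in which group-level structure matters most
  — the study-scale analogue (150 subjects) is the same code at larger
  arguments.
- The seed governs every random draw (generator, k-means restarts, chain
  seeds); identical seeds give byte-identical outputs.

## Known limitations

- Single constant drift within a trial; no inter-trial variability
  parameters, collapsing bounds, or lapse mixtures.
- The ART engine requires balanced complete designs (cell means are
  averaged; missing subject × cell combinations are an error).
- DIC is reported as the only model-comparison score (no WAIC/LOO); its
  absolute value is implementation-sensitive (likelihood constants,
  parameterization), so only differences within one implementation are
  meaningful.
- The Hartigan–Wong implementation handles ties and empty-cluster guards
  deterministically but is O(n·K) per sweep without the live-set
  bookkeeping of the classic Fortran code; at questionnaire scale this is
  irrelevant.
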