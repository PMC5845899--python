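# Methods

## The task and its observables

Two-voice polyphonic excerpts (bassoon + cello, 28 s) carry a four-triplet
rhythmic pattern in the upper voice, the lower voice, across both voices, or
not at all.  Under attend-bassoon the upper-voice pattern is the target and
lower-voice/no-triplet excerpts are controls; attend-cello mirrors this; under
attend-aggregate only voice-crossing patterns are targets.  A present/absent
button press after each excerpt yields hit/miss/false-alarm/correct-rejection
outcomes per trial; missing responses are marked invalid, excluded from all
counts, and logged per subject (the conservative choice — inventing a
response would bias hit or false-alarm rates).

Per subject × attention (× timbre distance) cell the package reports the
edge-corrected sensitivity d'_ec (add ½ to each count and 1 to each total
before the probit transform) and the analogous criterion
c = −½(z_hit + z_fa).  The edge-corrected criterion has no canonical
definition in the source analysis chain; it is provided purely for
initialisation and description, mirroring the standard equal-variance SDT
criterion.

## Hierarchical probit-binomial model

Counts per cell m:

    H_m  ~ Binomial(n_tri_m,  Φ(½·d'_m − bias_m))
    FA_m ~ Binomial(n_ntri_m, Φ(−½·d'_m − bias_m))

The ½·d' factor is the equal-variance SDT placement of the two evidence
distributions at ±d'/2; with bias 0 and d' 0 both probabilities are ½.

Latent layer and priors (bias carries a fully mirrored structure):

    d'_m ~ N(μ_m, σ²_att(m)),   σ_att ~ Uniform(0, 4)   per attention level
    μ_m  = β₀ + β_att(m) + β_timb(m) + β_att×timb(m) + β_subj(m)
    β₀   ~ N(0, 1000)            (variance 1000: a deliberately flat intercept)
    β_g  ~ N(0, σ²_β_g),  σ_β_g ~ Gamma(shape 1.64, rate 0.32)  per group g

Γ(1.64, 0.32) has mode 2 and standard deviation 4 — wide enough for the
plausible d' range, tight enough to stop the effect scales from drifting to
implausible magnitudes at these sample sizes.  Residual variances are
heteroscedastic across attention conditions only (equal across subjects and
timbre levels).  The experiment-1 model is the exact restriction without the
timbre and interaction blocks; the package verifies this restriction
property analytically in its test suite.

### Identification and reporting

The raw parameterisation is over-parameterised — no sum-to-zero constraints
bind the effect blocks, so only sums like β₀ + mean(β_subj) + … are
likelihood-identified.  Hierarchical shrinkage keeps the posterior proper,
and all inference is reported through a recentered re-expression: cell means
are reconstructed draw-wise, the grand mean is their average, main effects
are marginal deviations, and interactions the residuals.  These functionals
mix well even when individual raw blocks (notoriously β₀) move slowly along
the flat direction; raw-block split-R̂ above 1.1 therefore triggers a
warning attached to the output rather than an error.

### Sampler

Adaptive Metropolis-within-Gibbs, written directly in numpy:

- latent (d'_m, bias_m): per-cell scalar random-walk Metropolis, vectorised
  over all cells (they are conditionally independent given the upper
  layers); proposal scales adapt in batches of 50 toward 44% acceptance,
  adaptation confined to burn-in;
- all effect blocks: exact conjugate Gaussian draws (given the latents the
  ANOVA layer is linear-Gaussian with per-attention precisions);
- σ_att: exact draws from the conjugate inverse-gamma for σ² truncated to
  (0, 16) via the cdf-inversion identity — no Metropolis rejection noise;
- σ_β: random-walk Metropolis on log σ with the Jacobian term.

Defaults follow the analysis as reported: 10,000 retained draws after 2,000
burn-in; the package adds 4 chains with split-R̂ and bulk ESS (via arviz)
because single-chain estimation leaves convergence unquantified.  Latents
initialise at the cell's edge-corrected values, effects at zero, scales at
one.  Chain seeds descend from one `ModelConfig.seed` through numpy's
`SeedSequence`, so every fit is exactly reproducible.

Sampler correctness is established three ways in the test suite: the joint
density matches an independently coded term-by-term oracle to 1e-10; rank
statistics of prior-predictive truths are uniform on a reduced model
(simulation-based calibration); and null-truth 95% HDIs of the recentered
attention effects cover zero at their nominal rate.

### HDI

`hdi(draws, mass)` returns the shortest window containing ⌈mass·n⌉ sorted
draws; among tied-width windows the left-most is returned (deterministic).
At 10⁷ standard-normal draws the 95% HDI reproduces ±1.96 within 0.01; the
window endpoints are noisier than plain quantiles because width is flat
near the optimum, so small draw counts should not be over-read.

## Synthetic cohorts

The generator is the generative twin of the model: subject offsets
N(0, subject_sd²), cell-level true d' around the ANOVA mean with the
attention-specific residual sd, Bernoulli responses through the same probit
link, classified by the same rules as real data.  Default truth places the
cohort in the regime the experiments report: experiment-2 grand mean 4.7
and a −0.7 deficit at minimum timbre distance (the other two levels at
+0.35 each so the main effect sums to zero — the max−min and int−min
contrasts are then 1.05, matching the reported contrast regime);
experiment-1 grand mean 3.45; biases centred on zero with small spread
(subject sd 0.3, residual sd 0.3); subject sd 0.8 and residual sd 0.5 for
sensitivity, moderate values for trained cohorts.  Rating sessions add
Gaussian noise (default sd 0.5) to the perceptual sigmoid and round half-up
to the integer 1–5 scale.

What the generator does **not** emulate: learning or fatigue across blocks,
serial dependence between trials (responses are i.i.d. given the cell),
lapses or finger errors, reaction times, and any acoustic confound between
compositions.  Passing recovery tests therefore shows the estimation chain
is self-consistent under the model's own assumptions — not that real
listeners satisfy them.

A consequence of the defaults worth knowing: at grand d' 4.7 most 10-trial
cells are perfect, the likelihood only lower-bounds those latents, and the
posterior magnitudes of the grand mean and of injected effects overshoot
the simulated means even though per-cell recovery stays calibrated (truth
inside three posterior sds).  This is a genuine feature of probit-binomial
inference at ceiling, not a sampler artifact — the same behaviour is why
edge-corrected point estimates alone are not trusted at ceiling.

## Experimental-design generation

All generators are pure functions of their seed, re-validate their own
output before returning, and fail loudly (naming the constraint) if the
randomised search exhausts its 10,000-proposal budget.

- **Experiment 1**: six 16-trial blocks; condition order is a base
  permutation of (bassoon, cello, aggregate) plus its forward rotation —
  rotating the base by participant index balances every condition over
  every serial position across six participants.  Block mixes: aggregate
  8 crossing + 8 none; bassoon 8 upper + 4 lower + 4 none; cello mirrored.
  Within a block a composition never repeats back-to-back nor occurs more
  than twice (the 10-composition variant doubles six pieces per block).
- **Experiment 2**: runs of three 5-trial attention blocks, 6 runs (LAB) or
  9 (SCAN).  A run is exactly the 15 composition × timbre cells, once each,
  with 8 targets + 7 controls; per composition and repetition the
  run × condition → timbre assignment is a 3 × 3 Latin square, the five
  squares chosen jointly so every block's timbre multiset is {2,2,1}; the
  per-block target counts form a {2,3} matrix with all margins 8.  Equal
  timbre distances never sit adjacent, a block never opens with the
  previous block's closing composition, bassoon/cello control trials
  alternate 3 none + 4 opposite-voice and 4 + 3 across repetitions, and
  within a repetition every condition occupies every within-run position
  and covers all 15 cells.  Target placement additionally guarantees every
  condition × timbre cell at least one target and one control per
  repetition, since the analysis models every cell binomially on both
  trial types.
- **Rating session**: 8 blocks × 22 trials; strict global voice alternation
  (the only arrangement in which neither voice ever repeats), each
  voice × morph step once per block, compositions dealt round-robin from
  the five morphed pieces (which makes back-to-back composition repeats
  impossible).

## Psychometric fit

S(r) = 1 + 4/(1 + 10^((x50 − r)·m)) on the morph axis r ∈ [0, 1] (fraction
of the other instrument; 0 = pure original).  Fitting is nonlinear least
squares with asymptotes fixed at 1 and 5, Levenberg–Marquardt (damped
Gauss–Newton), at most 200 residual evaluations, rss-change tolerance
1e-10.  Slope initialises at 1; the centre initialises at the morph step
whose mean rating is nearest the scale midpoint 3 — a data-driven start on
the correct axis (initialising at the literal mean rating would put a 1–5
quantity on a 0–1 axis).  Ratings are fit trial-wise, not step-averaged.
Derived timbre distances: maximum = 0, minimum = x50, intermediate =
max(0, x50 − 0.20); the floor at zero is never reached for the observed
centre range 0.4–0.7.

## Reliability statistics

Split-half: trials split by odd/even serial position within each
subject × condition cell, halves pooled across conditions, d'_ec per half,
Pearson correlation across subjects, permutation p-value.  No
Spearman–Brown correction is applied.  Spearman correlations use average
ranks; p-values are exact by full permutation enumeration for n ≤ 9 and the
t-approximation beyond.  Quartiles interpolate linearly between order
statistics.

## Problem sizes used in the shipped checks

The acceptance script and test suite run the full-scale model fit at
19 subjects × 171 cells × 10,000 draws × 4 chains (about a minute), the
calibration study at 100 replicates of 10-subject experiment-1 cohorts with
1,000 retained single-chain draws each, sigmoid recovery at the 11-step ×
8-repetition rating design over 100 noisy replicates, and schedule
validation over several hundred seeds per generator.  These sizes give
Monte-Carlo error comfortably inside every asserted tolerance while keeping
a full run in the minutes range on one core.

## Known limitations

- The probit-binomial likelihood is weakly informative above ceiling;
  posterior effect magnitudes in saturated regimes should be read as
  lower-bounded rather than point-identified (see above).
- The sampler is single-threaded; chains run sequentially.
- The rating simulator's integer rounding is one plausible choice among
  several; only the continuous sigmoid layer is identified by the data.
- LAB and SCAN groups are compared descriptively (median/IQR) only; no
  inferential group contrast is implemented.
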