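# polystream

Behavioral analysis pipeline for auditory stream **segregation and
integration** experiments with two-voice polyphonic music.  Listeners attend
to the bassoon, the cello, or the aggregate of both voices, and report
whether a rhythmic triplet pattern occurred in the attended stream; a second
experiment additionally morphs the instruments' timbres toward each other at
three perceptually calibrated distances.  The package is written for
auditory psychophysicists who want the full analysis chain — trial
classification, sensitivity estimation, hierarchical Bayesian inference,
psychometric calibration, and constrained trial sequencing — as tested,
reusable code, with a synthetic-cohort generator standing in for human
subjects.

## What it computes

**Signal detection.** Each trial is a hit, miss, false alarm, or correct
rejection depending on whether the triplet sat in the attended stream.
Because trained listeners perform near ceiling, per-cell sensitivity is the
edge-corrected d':

    d'_ec = Φ⁻¹((H + ½)/(H + M + 1)) − Φ⁻¹((FA + ½)/(FA + CR + 1))

which stays finite for perfect scores.

**Hierarchical Bayesian model.** Hits and false alarms of each
subject × attention (× timbre) cell *m* are binomial with probit success
probabilities,

    H_m  ~ Bin(n_tri,  Φ(½·d'_m − bias_m))
    FA_m ~ Bin(n_ntri, Φ(−½·d'_m − bias_m))

latent sensitivities are exchangeable within attention condition,
`d'_m ~ N(μ_m, σ²_att)` with `σ_att ~ Unif(0, 4)`, and the cell means follow
an ANOVA-like decomposition `μ_m = β₀ + β_att + β_timb + β_att×timb + β_subj`
with `β₀ ~ N(0, 1000)` and every other effect shrunk through its own scale,
`σ_β ~ Γ(1.64, 0.32)` (mode 2, sd 4).  The response criterion carries a
fully mirrored structure.  Estimation is adaptive Metropolis-within-Gibbs
(10,000 retained draws after 2,000 burn-in per chain, 4 chains by default)
and inference is reported through **highest density intervals** of the
recentered grand mean, main effects, interactions and contrasts.

**Psychometrics.** Per voice, 1–5 instrument-identity ratings of timbre
morphs are fit with the logistic curve
`S(r) = 1 + 4 / (1 + 10^((x50 − r)·m))`; the fitted center x50 defines each
subject's *minimum* timbre distance, with *intermediate* 20 points back
toward the original instrument.

**Design generation.** Seeded generators produce the 96-trial attention
sessions (experiment 1), the 90/135-trial timbre sessions (experiment 2,
LAB/SCAN) and the 176-trial rating session, satisfying every
counterbalancing and pseudo-randomisation constraint; a standalone
validator audits any schedule and names each violated constraint.

**Reliability.** Split-half reliability of d'_ec, Spearman rank
correlations (exact permutation p at small n), per-subject morph-effect
scores, and median/IQR group summaries.

## Worked example

```python
from polystream import (TruthParams, ModelConfig, aggregate_counts,
                        cell_effects, contrast, fit_model, hdi,
                        simulate_cohort)

truth = TruthParams(n_subjects=19, seed=42)        # grand d' 4.7,
trials, _ = simulate_cohort(truth, group="LAB")    # minimum-timbre deficit -0.7
cells = aggregate_counts(trials)
print(f"{len(trials)} trials -> {len(cells)} measurement cells")
print(f"example cell d'_ec = {cells[0].dprime_ec:.3f}")

config = ModelConfig(experiment="exp2", n_samples=2000, burn_in=1000,
                     n_chains=2, seed=7)
post = fit_model(cells, config)
eff = cell_effects(post)
g = hdi(eff.grand_mean, 0.95)
print(f"grand mean 95% HDI: [{g.low:.2f}, {g.high:.2f}]")
t = eff.timb_levels.index("minimum")
iv = hdi(eff.timbre[:, t], 0.95)
print(f"minimum-timbre effect 95% HDI: [{iv.low:.2f}, {iv.high:.2f}]")
c = contrast(post, "timbre", "maximum", "minimum")
print(f"max-min contrast 95% HDI: [{c.interval.low:.2f}, {c.interval.high:.2f}]"
      f" (excludes zero: {c.excludes_zero})")
```

prints

```
1710 trials -> 171 measurement cells
example cell d'_ec = 2.747
grand mean 95% HDI: [5.06, 6.59]
minimum-timbre effect 95% HDI: [-1.46, -0.38]
max-min contrast 95% HDI: [0.56, 2.86] (excludes zero: True)
```

Nineteen simulated subjects on the LAB design yield 171 measurement cells
(9 per subject).  The minimum-timbre effect interval sits clearly below
zero and the maximum-minus-minimum contrast excludes zero: the injected
deficit at minimum timbre distance is detected.  In this near-ceiling
regime the posterior magnitudes run higher than the simulated means —
perfect 10-trial cells only lower-bound the latent sensitivity — see
`docs/methods.md` for discussion.

A command-line surface wraps the same functions:

```sh
polystream design --experiment exp2 --group LAB --participant 3 --seed 11
polystream rate-fit --input ratings.csv --output fits.json
polystream fit --input trials.csv --experiment exp2 --samples 10000 \
    --burnin 2000 --chains 4 --seed 7
polystream run --config pipeline.yaml     # design -> simulate -> fit -> report
```

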