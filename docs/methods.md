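# Methods

## The problem

Isobaric-tag (iTRAQ 8-plex) proteomics quantifies eight samples at once:
each sample's peptides are labelled with a different mass tag, pooled, and
fragmented together, so every identified MS/MS spectrum carries eight
reporter-ion intensities (channels 113–119 and 121). On time-of-flight
instruments these are discrete ion counts. The analysis question is
protein-level differential abundance between cases and controls, with the
evidence scattered over many spectra of many peptides, measured across
several independent 8-plex runs that each contain two digests of a common
reference pool, three case samples and three control samples.

`plexdiff` implements a two-stage Bayesian Poisson–lognormal mixed-model
pipeline for this design, together with a synthetic-data generator that
reproduces the generative structure exactly, so every inferential claim
the package makes can be checked against known truth without any raw
instrument data.

## The model

For spectrum *s* (peptide *p* of protein *i*, run *r*) and channel *c*,

    y[s,c] ~ Poisson(exp(eta[s,c]))
    eta[s,c] = beta_s + g[r,c] + theta_i * x_c + u[subject(r,c)]
               + d[p, digest(r,c)] + eps[s,c]

* `beta_s` — per-spectrum baseline (fixed effect): selection, ionisation
  and fragmentation efficiency vary per spectrum.
* `g[r,c]` — run-by-channel effect with the reference channel (113)
  pinned to 0, so `g` is the protein-level natural-log ratio of channel
  *c* against 113 within run *r*.
* `theta_i` — the condition effect (stage 2 only): natural-log fold
  change of cases over controls; `x_c = 1` for case channels.
* `u[j]` — subject random effects, split into *separate* case and
  control variance components because biological variance differs
  between groups.
* `d[p,k]` — peptide-by-digest random effects; repeated digests of the
  reference pool are what make digestion variance estimable.
* `eps[s,c]` — per-observation lognormal residual with channel-specific
  variance `sigma_c^2`, absorbing over-dispersion from background
  contamination and misidentified spectra.

Priors: inverse-Gamma(0.001, 0.001) on the residual variances;
half-Cauchy(1) on random-effect standard deviations, implemented by the
Huang–Wand inverse-Gamma mixture (a parameter expansion that keeps every
variance update an exact Gibbs draw). Exp-scale fixed effects carry a
Gamma(shape 0.01, rate 1e-8) prior: effectively flat for any group with
observed ions, proper for all-zero groups, and conjugate, so the
baseline, stage-1 channel and condition updates are exact Gamma-Gibbs
draws. The near-zero rate matters: a rate comparable to the shape would
penalise large baselines by `rate * exp(beta)` and measurably bias the
fit at realistic count magnitudes.

### Stage 1 — normalization

Each protein is fitted with run-by-channel fixed effects only (no
condition or subject terms). Because most proteins do not change between
samples, the across-protein *median* of the channel log ratios reflects
only how much material each channel received. The median is taken
draw-wise: chains are concatenated, proteins' draws paired by iteration
index (valid because the per-protein posteriors are independent),
subsampled evenly to the shortest draw count, and the median across
proteins formed per draw. Its posterior mean and SD per (run, channel)
are the normalization factors. Proteins whose fit fails the convergence
gate are excluded from the median with a logged warning. A `point` mode
(median of per-protein posterior means) exists behind a flag; draw-wise
is the default.

The median's validity rests on the nulls forming the central mass.
When a large fraction of proteins is differential and the up/down split
is imbalanced, the case-channel medians shift toward the majority
direction and every condition effect inherits the opposite bias; at the
default 20% differential fraction the recovery study shows no such bias
(the acceptance run recovers all 21 factors within max(0.05, 3·SD) of
truth). Users with globally shifted proteomes should treat the factors
with suspicion — as with any median-based normalization.

### Stage 2 — differential quantification

The full design is fitted per protein. Rather than subtracting point
estimates, sample fixed effects get Normal(m, s²) priors from the
stage-1 posterior, so normalization uncertainty propagates. The
condition effect has control as baseline; reference-pool samples carry
condition status 0 and a pinned (zero) subject effect — with per-spectrum
baselines and per-sample effects in the model, a subject term for the
single pool "subject" would be completely confounded with the sample
effects, and a variance component estimated from one level is
meaningless; pinning is the identifiable rendering of keeping the pools
out of both biological variance pools. Latent per-sample protein levels
(sample effect + condition + subject) are summarised for every sample.

### Significance

P(1.05 fc) is the posterior probability that the fold change exceeds the
threshold in its dominant direction: `p_up = P(theta > ln 1.05)`,
`p_down = P(theta < -ln 1.05)`, `p_fc = max(p_up, p_down)` with ties
going up. The local FDR is the complement `1 − p_fc` (the probability
that calling this protein is a false discovery). The global-FDR set is
the largest lFDR-sorted prefix whose average lFDR is at or below the
level (default 5%); ties in lFDR break lexicographically by protein id.
Both the threshold (1.05) and the level (0.05) are configuration, not
constants.

## Sampling

The sampler is Metropolis-within-Gibbs, authored in-package and
vectorized across chains (state arrays carry a leading chain axis).
Exact conjugate Gibbs draws cover the spectrum baselines, stage-1
channel effects, condition effect, residual variances and (via
Huang–Wand) the random-effect variances; adaptive random-walk Metropolis
(target acceptance 0.44, per-unit step sizes tuned during burn-in only)
covers the residuals, random effects and stage-2 sample effects.

Two classes of structural moves make the posterior geometry tractable:

* **Translation (recentering) moves.** The likelihood is flat along
  several directions — a channel effect against the mean of its digest
  effects or residuals, the baselines of a run against all of that run's
  channel effects (compensated on the reference channel), the condition
  effect against the mean case-subject effect, a sample effect against
  its subject effect. Each move draws the shift from the exact Gaussian
  implied by the Normal priors (with a Metropolis correction, acceptance
  ≈ 1, for the vague prior of an exp-scale parent) and leaves the cached
  Poisson rates untouched. Without these moves the within-run common
  modes mix with effective sample sizes in the tens; with them,
  thousands.

* **Marginalized variance updates (stage 1).** The flat directions mean
  the group means of `eps` and `d` are absorbed by the flat fixed
  effects and carry no likelihood information. Feeding them into the
  variance Gibbs updates creates a feedback loop (the translation moves
  re-plant the means at N(0, v/n) each sweep, and the variance then
  tracks them) that diverges geometrically when a protein has few
  spectra. Stage 1 therefore updates `sigma_c^2` and `tau_d^2` from
  within-group-centred residuals with correspondingly reduced degrees of
  freedom — the identifiable parametrization. A consequence we consider
  a feature: a single-peptide protein contributes *zero* identifiable
  digest-variance information (its digest effects are fully confounded
  with the channel effects), and the marginalized update says exactly
  that. Stage 2 needs none of this because the informative sample-effect
  priors anchor every direction.

Numerical guards: exp-scale Gibbs draws are clamped to ±30 (active only
for all-zero count groups), variances are capped at 100 (log-SD 10, far
beyond any real reporter-ion dispersion), and the inverse-Gamma sampler
floors the underlying Gamma draw at 1e-290.

### Chain regimes

* `desk` (default): 4 chains × 2000 kept iterations after 500 burn-in —
  full-study runs in minutes on one CPU.
* `paper`: 10 chains (stage 1) / 100 chains (stage 2) × 10000 kept
  iterations after 3000 burn-in — the heavyweight published regime.
* The replicated calibration studies use 2 chains × 500 kept after 200
  burn-in (1000 draws, the floor for the fold-change test).

### Convergence

The gate is split-R̂ ≤ 1.05 and bulk ESS ≥ 400 on the reported
parameters (channel log ratios in stage 1, the condition effect in
stage 2), computed with ArviZ. A Raftery–Lewis-style run-length estimate
(smallest chain length that pins the 2.5% quantile to ±0.005 with 95%
confidence; dichotomize at the quantile, thin to first-order Markov by
BIC, size burn-in and run from the transition probabilities) is exposed
as advisory. The thresholds are this package's stated gate — the intent
(error-bounded run length plus between/within-chain variance) in
standard modern form; they are deliberately configuration, not
constants.

## The synthetic-data generator

`simulate_study` is the generative inverse of the model, plus a design
generator: per plex, reference-pool digests on channels 113 and 119 (the
model is channel-symmetric given the design table; the placement is a
convention), and the three case / three control samples assigned to the
remaining six channels by a seeded permutation so condition is not
confounded with channel label. Defaults — the package's study
conditions — are 60 proteins, 1–4 peptides each, 1–5 spectra per peptide
per run, three plexes, baseline counts around 150 ions (log-mean ln 150,
log-SD 1), 20% truly differential proteins at |log fc| = ln 1.5 with
random sign, subject SDs 0.2 (case) and 0.1 (control), digest SD 0.1,
channel over-dispersion SD 0.2, and per-(run, channel) loading biases
drawn with SD 0.2. `corrupt_spectra` adds heavy lognormal contamination
to a seeded fraction of spectra for robustness experiments.

What the generator does *not* emulate: ratio compression from co-isolated
precursors, isotope-impurity cross-talk between channels, chromatographic
effects, or shared (non-unique) peptides. Passing recovery and
calibration tests therefore validates the *inference* given the model's
assumptions, not the instrument physics; on real data, ratio compression
in particular will shrink fold changes toward 1.

## Calibration studies (what the tests and acceptance script compute)

All studies run the real pipeline end to end on synthetic data, from a
single seed, at these reference sizes:

* **Conjugate oracle.** A one-spectrum protein with variance components
  pinned at zero reduces to independent Poisson counts; the posterior
  factorizes as a 1-D baseline marginal (sampled exactly by grid
  inverse-CDF) times Gamma conditionals. Gibbs and exact sampler must
  agree within 3 Monte-Carlo SEs, as must the generic engine on
  Normal-mean and Poisson-rate conjugate toys.
* **Normalization recovery.** The default 60-protein study at the desk
  regime; ≥ 90% of the 21 injected loading biases must be recovered
  within max(0.05, 3·posterior SD).
* **Coverage.** 100 proteins under default conditions with uniform
  2-peptide × 2-spectra structure (so the cohort fits in one batched
  sampler); 95% HPD intervals must cover the true condition effect at
  95 ± 5 percentage points with unbiased posterior means.
* **FDR calibration.** 50 regions of 24 uniform proteins at 20%
  differential, plus 10 pure-null regions: realized false-discovery
  proportion of the 5% global-FDR set, spurious discoveries per null
  region, and the recovery power for well-measured differential proteins
  (≥ 6 spectra, |log fc| ≥ ln 1.5).

  **What this study shows — read before trusting the 5% label.** Power
  is excellent (the acceptance run measures ≈ 0.996), but the realized
  FDP of the selection lands near 0.3 at these conditions — several
  times the nominal level — while the posterior itself is sound (the
  coverage study measures 95% HPD coverage with no detectable bias).
  The reason is structural, not a bug: the lFDR here is `1 − P(1.05 fc)`
  under the model's effectively flat prior on the condition effect. It
  has no spike at zero, so when 80% of proteins are truly null and any
  noise source makes a ±5% contrast likely under the null —
  between-subject biological SD 0.2 against a threshold of
  ln 1.05 ≈ 0.049 at 9-vs-9 subjects, or the *correlated* part of the
  median-normalization error (all case channels shift together when the
  differential minority has a chance sign imbalance, which independent
  per-channel priors cannot represent) — a correctly calibrated
  posterior still honestly assigns null proteins high P(1.05 fc). The
  "average lFDR ≤ 5%" of the selected set is therefore a model-based
  statement, not an ensemble false-discovery rate, and larger regions do
  not rescue it, because neither noise source above shrinks with the
  number of proteins. Users who need ensemble FDR control should raise
  the fold-change threshold well above the biological noise floor or
  post-process with an empirical-null method.

The batched sampler used by the replicated studies stacks structurally
identical proteins along the chain axis; it executes exactly the same
update rules and is regression-tested against individual fits.

## Known limitations

* lFDR here is the posterior complement of P(1.05 fc), not an
  empirical-Bayes mixture estimate; its calibration inherits the model's
  assumptions (in particular, normally distributed subject effects and a
  null majority for normalization).
* Median normalization degrades gracefully but measurably when the
  differential fraction is large or directionally imbalanced (numbers
  above).
* Convergence gating at desk scale occasionally flags data-rich proteins
  whose within-run common modes mix slowly; they are excluded from
  normalization and flagged (never dropped) in results.
* Shared peptides are excluded at load; proteins inferred only from
  non-unique evidence are invisible to the pipeline.
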