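# Methods

This note records the models, the numerical choices, and what the synthetic
generators do and do not emulate.

## Mk model of molt-strategy evolution

The three-state character (absent = 0, partial = 1, complete = 2; this
order is fixed everywhere, including rate names such as `q01`) evolves
under a continuous-time Markov chain with generator Q (rates in Myr⁻¹,
rows summing to zero).  Parameterizations: ER (one rate), SYM (three rates,
upper triangle row-major), ARD (six rates, off-diagonal row-major).

* **Likelihood.**  Pruning (post-order dynamic programming) with per-node
  rescaling to avoid underflow; polytomies are products over all children;
  missing tip states contribute all-ones conditional vectors; zero-length
  branches use the identity transition matrix.  Branch propagators
  exp(Qt) for all edges come from one eigendecomposition of Q (complex-safe
  for ARD), with a `scipy.linalg.expm` fallback when the eigenvector matrix
  is ill-conditioned (condition number > 1e8); rows are clipped to [0, 1]
  and renormalized, absorbing roundoff at the 1e-12 level.
* **Root prior.**  Flat (1/3, 1/3, 1/3) by default; `stationary` (left
  null vector of Q) and `fitzjohn` (likelihood-weighted) are available.
  The flat default matches the common default of reference
  implementations; the choice matters only when the root is far from
  stationarity.
* **Fitting.**  Box-constrained L-BFGS-B on log-rates, bounds
  [1e-8, 1e3] Myr⁻¹.  Multi-start (default 5): the first start sets every
  rate to 1/tree-height, the rest perturb it with seeded lognormal noise
  (σ = 1.5 on the log scale) — ARD likelihoods can be multimodal.
  Monomorphic tip data are not identifiable: the fit warns, pins rates at
  the lower bound and flags itself.
* **Model choice.**  AICc with n = number of tips.  The minimum-AICc model
  is *decisive* only when it leads the runner-up by strictly more than the
  threshold (default 2.00); otherwise the fewest-parameter model within the
  threshold is kept and the indecision is flagged.

## Marginal ancestral states

Posteriors are empirical Bayes: rates fixed at their ML estimates, no
propagation of rate uncertainty.  One post-order pass computes subtree
conditional likelihoods L, one pre-order pass computes the complement
partial likelihoods U (seeded with the root prior and following the
root-to-tip direction, so non-reversible ARD generators are handled
correctly), and the node posterior is the normalized product U·L.  This is
algebraically the same as re-rooting at every node but costs one O(n)
sweep; correctness is tested against exhaustive enumeration of all
internal-state assignments on small trees.

## Brownian-motion body-mass reconstruction

Gaussian belief propagation on the tree in unit-rate time: upward messages
(mean, variance) are combined by precision weighting, and the sequential
pairwise combinations yield the independent-contrast decomposition of the
likelihood, giving σ̂² = (Σ contrastᵢ²/wᵢ)/n — the ML (1/n) estimator, not
REML, matching the reference ancestral-state routine — and the GLS root
value.  A downward pass then gives every node the estimate that re-rooting
at that node would give (the conditional ML reconstruction); tips carry
their observations with variance zero.  Point masses from zero-length
branches are handled exactly; conflicting values joined by zero-length
branches raise an error.  The default reconstructs raw grams; a log10
option is exposed (and recorded in the fit) because Brownian motion on raw
mass allows negative excursions — on the synthetic data the raw scale is
used so the ancestral value is directly a mass in grams.

## Phylogenetic logistic regression

Model: y_i ∈ {0, 1} with mean p_i = logit⁻¹(xᵢᵀβ), variance p_i(1−p_i),
and working correlation exp(−α d_ij) with d_ij the patristic distance —
the correlation a two-state switching process with relaxation rate α
(Myr⁻¹) induces.  Large α ⇒ independent tips; the fit then reduces to
ordinary logistic regression (tested to 1e-3 against IRLS).

Estimation: for fixed α, β solves the GEE Dᵀ V⁻¹ (y − p) = 0 by Fisher
scoring (≤ 100 iterations, convergence at max |step| < 1e-6); α maximizes
the Gaussian working quasi-likelihood −(log|V| + rᵀV⁻¹r)/2 on a 13-point
log grid over [1e-6, 1e3], refined by bounded scalar search; boundary hits
are flagged.  Standard errors are model-based (DᵀV⁻¹D)⁻¹; p-values are
two-tailed Wald against the normal reference.  Nearly singular correlation
matrices (very small α) get an adaptive diagonal jitter, and grid points
whose working fit diverges are skipped rather than failing the whole fit.

Separation: a data-level certificate (the IRLS direction classifies every
success above every failure with a running-away margin) raises a flagged
error — boundary estimates are refused.  A Firth-type option
(`firth=True`, Jeffreys-penalized working score) returns finite estimates
for separated data instead.  The penalty is *off* by default so that the
default estimator is exactly the GEE solution (a permanent Firth penalty
would shift estimates O(1/n) away from the MLE in the independence limit).

**Assumption the simulations respect.**  The generative two-state process
only equilibrates toward the tip-specific probability p_i along the
pendant edge, so realized tip means are attenuated toward the grand mean
by E[exp(−α t_pendant)] (≈ 2λ/(2λ + α) for birth-rate-λ trees).  The
estimator targets the stationary tip probabilities, so recovery and
calibration simulations use trees with pendant edges long relative to 1/α
(birth rate λ = α/20); under faster trees the slope is attenuated — a
property of the model, not the optimizer.

## Synthetic generators

* **Trees.**  Forward birth–death simulation from a crown split,
  conditioned on the target number of extant tips, stopped just before the
  next event (ultrametric by construction), extinct subtrees pruned.
  Study-scale default: 1,808 tips, pure birth with λ = ln(904)/95 ≈ 0.072
  Myr⁻¹, giving a crown age near 95–110 Myr.
* **Characters.**  Discrete states by edge-wise CTMC waiting-time
  simulation (latent internal states returned for recovery tests);
  continuous traits by Gaussian increments; binary traits by the two-state
  switching process described above (internal edges equilibrate toward the
  grand-mean probability, pendant edges toward p_i).
* **Study-like dataset.**  Strategies evolve from an "absent" root under
  an equal-row CTMC whose stationary frequencies are solved so the
  *expected* tip frequencies after one relaxation time (m·height = 1)
  equal the target 58.6/12.0/29.4%; residual multinomial fluctuation is
  removed by minimally reassigning random tips to hit the exact
  1,059/217/532 counts.  Body mass is truncated-lognormal per strategy
  group, moment-matched (arithmetic mean/SD after truncation) to
  50.0 ± 106.1 g on [2.5, 1250] for complete-molt species and
  387.5 ± 1016.9 g on [4.5, 11000] otherwise; absolute mid-latitude is
  truncated-normal matched to 17.4 ± 12.1° on [0, 50] (complete; no
  complete-molt species occurs above 50°) and 26.8 ± 16.0° on [0, 90]
  (others).  Orders (27) and families (146) are the monophyletic clades
  obtained by cutting the tree at its 26 and 145 oldest splits, so
  families nest within orders; 179 random species carry the
  placed-without-genetic-data flag.
* **What it does not emulate.**  Mass and latitude are independent across
  species *given* the strategy group — they carry no Brownian signal of
  their own, so the BM reconstruction on synthetic mass estimates a large
  σ² and the regression covariates are phylogenetically unstructured.
  Passing tests therefore demonstrate the estimators' correctness and the
  pipeline's integrity, not how strong the mass or latitude effects are in
  real birds.  Tree uncertainty (the consensus-of-1,000-trees input) and
  the literature-based classification of molt states are likewise outside
  the generator's scope.

## Problem sizes and determinism

Stochastic validation uses sizes chosen to make the Monte-Carlo error small
relative to the tested tolerance: enumeration oracles on trees of 3–6 tips
(100 draws), dense-GLS comparisons on 4–20 tips (100 draws), ER-rate
recovery on 1,000-tip trees (50 replicates), Wald calibration at 300 tips ×
400 replicates, slope recovery at 500 tips × 200 replicates, and the full
pipeline at the study scale of 1,808 tips.  All randomness flows from
integer seeds through named `numpy.random.Generator` objects; reruns of the
pipeline with the same configuration are byte-identical (the manifest
records the seed, the analysis parameters and their hash, but not the
output location).

## Known limitations

* Empirical-Bayes posteriors understate uncertainty because rate estimates
  are plugged in; no integration over Q.
* AICc uses n = tips; other effective-sample-size conventions exist.
* The regression's α is estimated by working quasi-likelihood, which is a
  pragmatic profile criterion, not an exact likelihood; its SE is not
  reported.
* The latitude index for long-distance migrants is taken as given in the
  input table (an override column), not derived from range maps.
* Family-level branch lengths are whatever the pruned species tree
  carries; no re-dating is attempted.
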