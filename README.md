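# moltevo

Phylogenetic comparative analysis of how the wing flight-feather molt
strategy of first-year birds evolved across modern birds (Neornithes), and
how it relates to body mass and geographic distribution.

First-year birds either replace all wing flight-feathers within their first
year ("complete" molt), replace some ("partial"), or none ("absent").  This
package implements the full comparative analysis of that three-state
character on a time-calibrated phylogeny:

* **Discrete ancestral-state reconstruction.**  The strategy evolves under a
  continuous-time Markov (Mk) model with generator *Q*; branch transition
  probabilities are *P(t) = exp(Qt)*.  Three parameterizations are fitted by
  maximum likelihood (equal rates ER, symmetric SYM, all-rates-different
  ARD) via the pruning algorithm, compared by AICc
  (−2 ln L + 2k + 2k(k+1)/(n−k−1)), with a model accepted only when it leads
  by ΔAICc > 2.00.  Marginal (empirical-Bayes) posterior probabilities of
  each strategy are computed exactly at every node by an up–down pass.
* **Continuous ancestral reconstruction.**  Body mass evolves by Brownian
  motion; the rate σ² and the ancestral (root) mass are estimated by ML
  through a linear-time Gaussian message-passing recursion that reproduces
  the dense GLS formulas with phylogenetic covariance
  V<sub>ij</sub> = root-to-MRCA(i,j) path length.
* **Phylogenetic logistic regression** (Ives–Garland two-state switching
  model): a binary trait (complete = 1, absent = 0; partial excluded) with
  tip means logit⁻¹(xᵢᵀβ) and residual correlation exp(−α d<sub>ij</sub>)
  decaying with patristic distance; β solves generalized estimating
  equations and the signal parameter α is profiled on a log grid.
  Univariate fits for body mass (g) and absolute mid-distribution
  latitude (°), overall and within orders having > 20 species per category.
* **Family-level robustness.**  Each family is assigned the strategy with
  the highest posterior at its MRCA; a one-tip-per-family tree is rebuilt
  and the reconstruction rerun on two alternative backbone topologies.
* **Synthetic data generators** reproducing the study conditions (1,808
  species, 146 families, 27 orders; strategy counts 1,059/217/532;
  group-wise mass and latitude distributions; 179 species flagged as placed
  without genetic data), so every stage is testable without downloads.

## Worked example

```bash
python analysis/01_simulate_dataset.py --seed 0   # writes results/synthetic/
python analysis/02_molt_asr.py --seed 0
```

The first command generates the study-scale dataset and prints its
descriptive summary:

```
species: 1808  (complete 532, partial 217, absent 1059)
orders: 27  families: 146  bdpr-flagged: 179
tree: 1808 tips, crown age 106.7 Myr
         group         variable    n       mean          sd    min        max
      complete      body_mass_g  532  51.947452   96.653466 2.5038   872.7749
      complete mid_latitude_deg  532  16.953028   11.643410 0.2015    49.9611
partial_absent      body_mass_g 1276 414.172499 1147.111923 4.5141 10766.5129
partial_absent mid_latitude_deg 1276  27.479516   16.086994 0.0244    82.0910
```

Complete-molt species are light (~52 g on average versus ~414 g) and live
near the equator (~17° versus ~27° absolute mid-latitude), as the generator
is designed to emulate.  The second command fits the three Mk models,
selects by AICc and reconstructs ancestral states:

```
model         logL  n_params        aicc  delta_aicc  selected
   ER -1418.401622         1 2838.805459  398.303674     False
  SYM -1289.776264         3 2585.565832  145.064047     False
  ARD -1214.227572         6 2440.501785    0.000000      True
selected model: ARD (decisive)
root posterior: absent 38.1%, partial 8.2%, complete 53.7%
```

The all-rates-different model wins decisively (ΔAICc ≈ 145 over the next
model).  The root posterior is the marginal probability of each strategy at
the crown node; with the generator's moderate signal (about one expected
state relaxation from root to tip) the root call varies between seeds —
root-state recovery is quantified in the test suite, not from a single run.
The remaining drivers (`03`–`06`) reconstruct body mass, fit the regression
tables, run the family-level dual-topology comparison, and reproduce the
whole bundle in one deterministic pipeline run.

## Layout

```
src/moltevo/      library: treeio, mk, asr, brownian, phyloglm, traits,
                  families, simulate, pipeline
analysis/         numbered narrative drivers (simulate → reconstruct →
                  regress → compare topologies → full pipeline)
tests/            pytest suite with independent oracles (enumeration,
                  dense GLS, IRLS, phytools)
docs/methods.md   model assumptions, parameter choices, limitations
```
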