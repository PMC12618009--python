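# Methods

`cogproxy` re-creates, as a tested pipeline, a proxy-measure analysis of the
link between children's cognitive abilities and their mental health in a
multi-site, family-nested, two-wave developmental cohort. This note
documents the model, the synthetic study conditions, the numerical choices,
and what the tests do and do not establish.

## The analysis in one paragraph

Cognitive ability is operationalized as the factor score of a second-order
confirmatory factor model (a g-factor over language, mental-flexibility and
memory-recall factors, each measured by two tasks). Four feature sets —
mental health (CBCL + temperament summaries), multimodal neuroimaging
blocks, polygenic scores, and socio-demographic/lifestyle/adversity
("environment") variables — each predict the g-factor score under nested
leave-one-site-out cross-validation. The held-out predictions are "proxy
measures": scalar summaries of the variance in cognition that each feature
set can capture. Random-intercept linear mixed models (families nested in
sites) then regress observed cognition on the proxies, and the marginal
R² of every predictor subset is decomposed by commonality analysis into
effects unique to each proxy and common to every combination — in
particular, the share of the cognition–mental-health association that
neuroimaging, genetics, or environment can account for.

## Measurement model

Six standardized task scores load pairwise on three first-order factors;
the factors load on a single second-order g. All latent variances are fixed
at 1, so the implied covariance is
`Σ = Λ(γγ' + diag(1−γ²))Λ' + diag(θ)`. Estimation is plain maximum
likelihood by quasi-Newton on a log-variance / tanh-loading
parameterization with fixed starting values (loadings 0.5, residuals 0.5),
making fits deterministic. Factor scores use the regression (Thurstone)
method `w = Σ⁻¹Λγ`. Fit is reported via conventional (non-robust) CFI,
TLI, RMSEA (90% CI from the noncentral χ²), SRMR, and OmegaL2 — the share
of total score variance attributable to the second-order factor. Robust /
scaled corrections are deliberately out of scope: only point estimates and
factor scores feed the downstream pipeline, and those are identical under
the robust variants.

A consequence worth stating plainly: the factor score is not g. The
default task loadings are anchored so that OmegaL2 is 0.78, which puts the
score's population validity (its correlation with latent g) near 0.90.
Every prediction r and every mixed-model R² in the pipeline therefore
refers to the *score*, and all closed-form targets are provided for both
the latent (`target="g"`) and the operational (`target="score"`) estimand;
the two differ exactly by the squared validity. Parameter-recovery checks
for the measurement model pool both waves' task administrations: the two
waves share their latent values but carry independent measurement noise,
so the pooled fit is the better-posed recovery estimator.

## Cross-validation protocol

One site is held out per fold; the rest train. Within a training set,
seeded 10-fold cross-validation grouped by family tunes hyperparameters.
Standardization is split-wise: the training split uses its own statistics,
the test split its own, and follow-up splits reuse the corresponding
baseline statistics (for task scores, features, and the g score alike).
The CFA is estimated on the baseline training split only and its weights
applied unchanged everywhere else, so both waves share one target
definition per fold. Because families never span sites, leave-one-site-out
also guards against family leakage, which matters most for the
family-correlated polygenic scores.

Learner tuning rules:

* **PLS** (mental health, environment): components added greedily; stop
  when a component fails to reduce inner-CV RMSE by 0.1% of the total RMSE
  (the intercept-only RMSE, i.e. the training-split standard deviation of
  the target). Loadings and per-component variance explained are computed
  on the full data, separately from the cross-validated predictions.
* **Elastic net** (each neuroimaging block, polygenic scores): loss
  `Σ(y−xβ)²/2n + λ((1−α)/2‖β‖² + α‖β‖₁)`; λ on a 20-point log₁₀ grid over
  [1e-10, 10], α on an 11-point linear grid over [0, 1]; lowest inner-CV
  RMSE wins, ties to the larger λ.
* **Random forest** (stacking layer): 500 trees; (mtry, min_n) from 3000
  Latin-hypercube candidates over [1, 90] × [2, 2000]; ties to the larger
  min_n.

Neuroimaging preprocessing per block and split: participants are excluded
from a block when QC-flagged, when any feature is missing, or when more
than 5% of the block's features lie strictly more than 3 interquartile
ranges beyond the nearest quartile (type-7 quantiles, so boundary cases
are reproducible); other blocks are kept. Features are standardized and
harmonized with ComBat fitted on the training split; held-out sites are
adjusted toward the harmonized training reference. Environment features
are mode-imputed (categorical, ties to the lowest label), dummy-coded,
standardized, and KNN-imputed (k = 5). Polygenic scores pick, per GWAS
definition, the p-value threshold with the strongest training-split
correlation with the g score (ties to the larger threshold), then are
residualized on four ancestry PCs within each split.

**Opportunistic stacking.** Per-block elastic-net predictions (training
split in-sample, same training set for both layers) are duplicated; missing
entries become +1000 in the first copy and −1000 in the second (canonical
alphabetical block order), so any participant with at least one block
survives. A random forest learns from the encoded matrix. Block importance
is the mean |Shapley value| on held-out participants, duplicate pairs
summed, averaged within and then across test sites. Shapley values are
estimated by permutation sampling with a background sample (default 100
rows): walking each sampled permutation from a background row to the
instance telescopes exactly to `f(x) − f(b)`, so local accuracy holds for
the averaged estimate as well.

## Mixed models and commonality

Observed and proxy cognition are first residualized (OLS) on sex, age and
14 medication-category dummies. Each proxy enters the model as two fixed
effects: its within-site centred values (cws) and its site averages (savg);
the polygenic proxy is centred within family first and then within site
(cws,cwf / savg,favg). The model is `y ~ proxies + (1 | site:family)`,
fitted by REML (ML fallback on singular fits). Because single optimizers
occasionally stop at poor points without reporting failure, each model is
fitted with two quasi-Newton methods and the higher-likelihood solution
kept. Marginal R² is Var(Xβ̂)/(Var(Xβ̂)+τ₀₀+σ²) and conditional R² adds
τ₀₀ to the numerator (the standard mixed-model definitions).

Commonality coefficients follow the general inclusion–exclusion
construction: for predictor set V and any non-empty T ⊆ V,
`C(T) = −Σ_{S⊆T} (−1)^{|S|} R²((V∖T) ∪ S)` with `R²(∅) = 0`. The 15
four-set coefficients sum to the full-model R² as an arithmetic identity,
which the tests assert to 1e-10; a brute-force solve of the defining
linear system `R²(S) = Σ_{T∩S≠∅} C(T)` serves as an independent oracle.
Negative coefficients (suppression) are reported, not clipped. Sharing
percentages are `100·common/total`, rounded to the nearest integer.
Per-analysis samples follow data availability for the included sources
(no listwise deletion across all sources for pairwise analyses).

## Synthetic study conditions

The generator draws 21 sites of 120–230 families (1–3 children each,
probabilities 0.70/0.25/0.05; ≈5,000 baseline participants), a 60%
follow-up retention, and three correlated latent sources: family-shared
environment E, genetic G (50% family-shared), and mental-health liability
M (30% family-shared). Latent g is a fixed linear combination of (E, G, M)
plus an orthogonal residual with family (18%) and site (2%) shares, scaled
to unit variance. The family/individual split of the source covariance is
exact: Σ_fam = D^{1/2}LD^{1/2} with D the family-share fractions,
Σ_ind = L − Σ_fam, so the marginal correlation is L regardless of the
shares. Blocks are exchangeable features `a'z + site_batch + noise`:
mental health loads on M, environment on E, polygenic scores on G (ten
thresholds per definition, the inverted-U peaking at 0.01, plus a PC1
stratification loading), and four neuroimaging blocks load on g directly
with site batch effects, block-wise MCAR missingness and QC flags.
Covariates (sex, age, a nervous-system medication category) shift the
score-generating g additively and are residualized out downstream.

Default loadings were set once, by covariance algebra, so the population
out-of-sample r's sit near the anchor values the pipeline is meant to
exhibit (mental health ≈ 0.36, neuroimaging ≈ 0.54, polygenic ≈ 0.25,
environment ≈ 0.49 — all at the score level).

**Closed-form targets.** Because the model is linear-Gaussian, the
population R² of any source subset is available in closed form in two
bases. `basis="features"` is the best linear predictor from all features
of the subset jointly — the information ceiling. `basis="proxies"` first
collapses each source to its own best linear predictor and regresses on
the scalars — the population analogue of a proxy-measure analysis, and
hence the estimand against which the fitted pipeline is validated. The
two coincide for single sources; for overlapping sources the feature
basis makes them more redundant than separately trained scalars can be.

What the generator does **not** emulate: item-level instruments, imaging
voxels or genotypes, non-Gaussian features (beyond a few discretized
ordinal environment columns), informative missingness (an optional
site-dependent mechanism exists but defaults to MCAR), measurement
non-invariance across waves, and selection effects. Passing tests
therefore show that the pipeline recovers known structure under clean
conditions — not that real cohort data meet these assumptions.

## Problem sizes and numerical choices

The default study runs 21 folds × 4 feature sets on ≈5,000 participants
with compact feature blocks (8–30 features each), scaled-down tuning grids
(elastic net 5×3; random forest 100 candidates, 25-tree forests on a
1,000-row subsample with 3 inner folds during the search, full 500-tree
refit), and 15 + 9 mixed-model fits; it completes in roughly ten minutes
on one CPU. The full grids of the tuning rules remain the defaults of the
config objects. Other fixed choices: Heywood residuals floored at 1e-4
with a warning; IQR quantiles type-7; KNN imputation Euclidean over
mutually observed standardized dimensions; percentile bootstrap
(n = 1000) for pooled-r CIs; sentinel fills ±1000 with the +1000 copy
first; all randomness routed through explicit integer seeds.

Two honest caveats, both verified by tests at their true magnitudes: the
centring decomposition reconstructs its input to within one floating-point
ulp (exact bit-for-bit equality is not achievable for a subtract-then-add
round trip), and ComBat's fit+apply is an exact fixed point only for the
plain location/scale estimator — the default empirical-Bayes shrinkage
converges toward that fixed point (second-pass RMS change < 0.02)
rather than reaching it in one pass.

## Known limitations

* Follow-up wave support is implemented and tested at the contract level
  (baseline-anchored standardization, baseline-trained CFA), but the
  default study and its validation run on the baseline wave.
* Fixed-effect inference (Wald CIs, p-values) is not a tested surface; no
  Satterthwaite or Kenward–Roger corrections.
* The stacking layer's Shapley estimator is a permutation-sampling
  approximation; its variance is controlled by the permutation and
  background sample sizes, which are deliberately small in tests.
* Proxy-measure commonality inherits the estimand subtleties discussed
  above: it partitions the variance captured by separately trained scalar
  predictions, not the joint feature information.
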