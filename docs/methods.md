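# Methods

## The problem

Across vertebrates, males and females often differ in body mass (sexual
size dimorphism) and, if the sexes partition food resources, in diet.
Stable-isotope ratios of animal tissues summarize diet quantitatively:
δ¹⁵N increases with trophic level and δ¹³C tracks the basal carbon
resource of the food chain, both expressed in permil (‰) relative to
international standards via δ = (R_sample − R_standard)/R_standard × 1000.
`isodimorph` implements a meta-analytic pipeline that asks whether the
magnitude of sex differences in these ratios covaries, across species,
with the magnitude of size dimorphism — and how dietary class, mean
species size and gape limitation moderate that association.

## Effect sizes

Each literature record is one study × species × tissue × isotope row of
per-sex summaries (mean, SD, n).  From these the package computes:

- **MD** — raw mean difference, male − female, in ‰.  Sampling variance is
  the unpooled two-sample form `sd_m²/n_m + sd_f²/n_f` (studies report
  per-sex dispersions, so pooling is not assumed).
- **lnVR** — log of the male:female SD ratio with the small-sample bias
  correction, `ln(sd_m/sd_f) + 1/(2(n_m−1)) − 1/(2(n_f−1))`, sampling
  variance `1/(2(n_m−1)) + 1/(2(n_f−1))`.  |lnVR| > ln 2 means one sex is
  more than twice as variable as the other.
- **lnCVR** — log ratio of coefficients of variation with the same
  correction terms; sampling variance
  `CV_m²/n_m + 1/(2(n_m−1)) + CV_f²/n_f + 1/(2(n_f−1))` under
  within-sex independence of means and SDs.  Provided for mean–variance
  sensitivity checks; lnVR is the primary variability metric because CV
  standardization can misstate variation when the sexes differ in mean
  enrichment.

Moderators: the dimorphism index defaults to `log2(male_mass/female_mass)`
so that +1 unit = a twofold (100 %) male bias, matching the interpretation
"a 100 % size dimorphism raises δ¹⁵N sex difference by β ‰".  A
`relative` convention, `(male − female)/mean`, is available because ratio
transforms of dimorphism are not standardized across the literature.
Mean species size is the arithmetic mean of the two masses (kg).

## Multilevel model

Effect sizes y_i with known sampling variances v_i follow

    y ~ N(Xβ, V),   V = σ²_study Z_s Z_sᵀ + σ²_species Z_p Z_pᵀ
                        + σ²_phylo Z_p A Z_pᵀ + diag(v)

where A is a Brownian-motion correlation matrix from the phylogeny (shared
root-to-MRCA path length, standardized to unit diagonal).  Study and
species levels absorb pseudoreplication from multiple tissues per study
and multiple rows per species; the phylogenetic level absorbs similarity
due to shared ancestry.  An optional observation-level component exists
but is off by default, since the three named levels define the model.

Estimation is REML (default) or ML.  The criterion is optimized over
log σ² by L-BFGS-B within bounds [1e−10, 10·var(y)], from three
deterministic starting points (the moment estimate of the total component
split evenly across levels, and that value ×0.1 and ×10), convergence
tolerance 1e−8 on the criterion; restarts that tie within 1e−8 are
resolved in favour of a cleanly terminated run.  Components at the lower
bound are reported as exact zeros.  The REML log-likelihood includes the
`½log|XᵀX|` constant, so values are directly comparable with metafor's
`rma.mv`; a test cross-checks coefficients, standard errors, variance
components and log-likelihood against that independent implementation.

Fixed effects are the GLS solution at the optimum with Wald z inference
(normal 95 % CIs); prediction bands use the fixed-effect covariance only.
Wald intervals ignore variance-component uncertainty; at the ~300-effect
scale simulated here the slope CI is well calibrated (see below), but the
intercept of a phylogenetic model undercovers somewhat because deep shared
branches make the effective sample size for the grand mean much smaller
than n.

**Heterogeneity.**  For intercept-only fits, the typical sampling variance
is v̄ = (k−1)Σw / ((Σw)² − Σw²), w_i = 1/v_i, and
I² = 100·Σσ²_L/(Σσ²_L + v̄), decomposed across levels in proportion to
their components.

**Model selection.**  AICc = −2ℓ + 2p + 2p(p+1)/(n−p−1) with p counting
fixed effects plus estimated variance components.  Comparisons across
fixed-effect structures use ML by default (REML criteria are not
comparable when X changes); a REML mode exists to mirror common R
toolchains and the mode is recorded in every table.  AICc ties closer
than 0.01 share a rank.

## Phylogeny handling

Trees are Newick inputs.  Correlations are computed on the full tree
restricted to the requested tips, which makes subsetting species commute
exactly with matrix construction.  Trees without branch lengths get
Grafen heights — node height = (descendant tips − 1), normalized to unit
depth — the standard fallback for topologies returned by open tree
services.  Name matching tolerates space/underscore differences; synonyms
require an explicit alias map (no automatic taxonomy resolution).

Local phylogenetic signal uses the local Moran statistic
I_i = n(x_i − x̄)·Σ_j w_ij(x_j − x̄) / Σ_k(x_k − x̄)² with row-standardized
off-diagonal correlations as weights (an alternative proximity matrix may
be passed in), and one-sided upper-tail permutation p-values
(p = (1 + #{I_perm ≥ I_obs})/(n_perm + 1)).  Constant traits return zero
statistics with p = 1 and a warning.

## Diagnostics

- **Funnel data**: (value, √v) pairs with pseudo-CI boundaries centered on
  the fixed-effect mean (center ± 1.96·se); emitted as plain tables so
  plots are optional.
- **Time-lag bias**: meta-regression on mean-centered publication year
  (centering keeps the intercept interpretable as the pooled estimate at
  the mean year); the slope CI is the indicator.
- **Weight sensitivity**: the standard fit versus a fit with all variance
  components pinned to zero, i.e. weights from within-study sampling
  variances alone, with per-coefficient deltas.
- **Influence**: leave-one-out refits give Cook's distances
  D_i = (β̂ − β̂₋ᵢ)ᵀ Cov(β̂)⁻¹ (β̂ − β̂₋ᵢ); the default flag threshold is
  4/n (configurable, and recorded in the report since no single convention
  dominates).  Non-convergent refits mark the observation indeterminate
  rather than aborting.
- **Complete-case filter**: rows missing any field required by the chosen
  metric and formula are dropped with named reasons and logged counts.

## Synthetic data

The generator's defaults emulate the compiled-literature conditions the
pipeline is designed for: 158 studies over 163 species (68 mammals, 60
birds, 18 fish, 17 reptiles, 1 amphibian); every species appears and a few
studies carry more than one species; tissues per study-species pair are
1 + Poisson(0.73), giving ≈ 280 δ¹⁵N rows; dietary classes drawn with
fish/reptiles skewed carnivorous (0.60/0.25/0.15 versus 0.40/0.33/0.27
elsewhere) and gape limitation assigned to carnivorous fish/reptiles with
probability 0.8, which yields a gape-limited subset of ≈ 30 effects;
dimorphism indices N(0, 1) on the log2 scale, spanning the observed
extremes of ~10× female-biased to ~7× male-biased at n ≈ 163; female
masses lognormal(0, 2.5) kg.  True sex differences are
θ_i = x_iᵀβ + u_study + u_species + u_phylo with default components
(0.55, 0.25, 0.10) ‰² — totalling ≈ 0.9 ‰² so that intercept-only I² sits
near 90 %, as observed in this literature — and default δ¹⁵N slope
0.126 ‰ per dimorphism unit; δ¹³C has no signal by default.  Random
effects are drawn independently per isotope because isotopes are modelled
separately.  Per-sex summaries are then emitted: n = 3 + Poisson(8) per
sex, SDs lognormal(ln 0.7, 0.35) with χ²-distributed observed SDs, which
puts the median sampling variance near 0.1 ‰².  Sub-streams of one seed
drive tree, species, study and row draws, so everything is reproducible.

What the generator does *not* emulate: publication bias, digitization
error, non-normal effect distributions, correlated tissue measurements
beyond the study effect, isotopic baseline shifts between ecosystems, and
measurement error in body masses.  Passing calibration tests therefore
show the estimator is correct under its own assumptions at realistic
scale, not that those assumptions hold in any particular literature.

## Experiments and problem sizes

- **Calibration**: 200 replicates of 160 studies / 160 species /
  ≈ 300 δ¹⁵N effects with all three variance components; the dimorphism
  slope (truth 0.15) shows |bias| < 0.01, CI coverage ≈ 0.95, and the
  Wald test's type-I error ≈ 0.05 under a zero slope.  These sizes put
  each replicate at the scale of the emulated literature while keeping the
  full experiment at a few minutes on one CPU.
- **Selection power**: the interaction experiment generates diet-specific
  dimorphism slopes (carnivore 0.15, omnivore 0.60, herbivore −0.25).
  These magnitudes are within the range reported for dietary subsets in
  this literature, and an a-priori power calculation (slope-contrast
  noncentrality ≈ 19 at ≈ 300 effects with ≈ 1 ‰² residual variance) puts
  the AICc win rate of the true interaction model near 95 %; the
  experiment checks ≥ 90 % over 100 replicates.

## Limitations and open choices

- Wald (normal) inference throughout; no t-type small-sample adjustments,
  robust variance estimation, or Bayesian fitting.
- Species and phylogenetic components are only jointly identified when the
  correlation matrix is close to identity; tests therefore constrain their
  sum in that regime.
- lnCVR assumes independent means and SDs within sex (no mean–SD
  correlation term).
- The dimorphism transform used as a regression predictor is a genuine
  ambiguity in this literature; both provided conventions are exposed, and
  slope magnitudes depend on the choice.
- Reproduction of published numbers requires the corresponding deposited
  dataset as an input file; the `reproduce` driver runs the full battery
  on any table in the package's schema but ships no third-party data.
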