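# isodimorph

Multilevel phylogenetic meta-analysis of **sex differences in stable-isotope
ratios** and their association with **sexual size dimorphism**.

Stable isotopes summarize diet: δ¹⁵N rises with trophic level and δ¹³C
tracks the basal carbon resource of a food chain (both in ‰ relative to
international standards).  If the sexes of a species partition food
resources, their tissues should differ isotopically — and if ecological
character displacement between the sexes matters, species with stronger
size dimorphism should show larger isotopic sex differences.  This package
provides the statistical machinery to test that prediction on a compiled
literature of per-sex isotope summaries, for ecologists and meta-analysts
working with study-level summary data and a phylogeny.

## The model

Per-row effect sizes — the raw mean difference MD = m̄ − f̄ (‰), the
bias-corrected log variability ratio lnVR = ln(sd_m/sd_f) + ½(n_m−1)⁻¹ −
½(n_f−1)⁻¹, or lnCVR — with known sampling variances v_i enter a
three-level Gaussian mixed model

    y ~ N(Xβ, V),  V = σ²_study Z_sZ_sᵀ + σ²_species Z_pZ_pᵀ
                       + σ²_phylo Z_p A Z_pᵀ + diag(v)

fitted by REML (or ML), where A is the Brownian-motion correlation matrix
from a Newick tree.  On top of the fitter sit multilevel heterogeneity
(I²), AICc model selection over moderator formulas (size dimorphism ×
dietary class × mean species size), subset analyses (gape-limited
carnivores), publication-bias checks (funnel data, publication-year
meta-regression, within-study-only weighting) and leave-one-out Cook's
distances.  A seeded synthetic-data generator reproduces the statistical
structure of the compiled literature so every stage is testable without
any downloads.

## Worked example

```python
import isodimorph as iso

truth = iso.SimTruth(seed=42)                  # literature-scale defaults
records, tree = iso.simulate_dataset(truth)
effects = iso.effect_table(records, "MD", "N15")
corr = iso.correlation_from_tree(tree, sorted(effects["species"].unique()))

m0 = iso.fit_multilevel(effects, iso.ModelSpec(formula="value ~ 1"), corr)
het = iso.i_squared(m0)
print(f"k = {m0.n_obs}, I2 = {het.i2_total:.1f}%")

m1 = iso.fit_multilevel(effects, iso.ModelSpec(formula="value ~ dimorphism"), corr)
print(m1.coefficients().round(3))
```

prints

```
k = 278, I2 = 92.5%
            estimate     se      z      p  ci_low  ci_high
Intercept      0.083  0.171  0.483  0.629  -0.253    0.418
dimorphism     0.103  0.060  1.704  0.088  -0.015    0.221
```

278 δ¹⁵N mean-difference effect sizes; 92.5 % of their between-study
variation is true heterogeneity rather than sampling noise; and a
dimorphism slope of 0.103 ‰ per dimorphism unit, i.e. a species whose
males are twice the mass of females (one log2 unit) shows a δ¹⁵N sex
difference about 0.1 ‰ larger on average — close to this dataset's
generating slope of 0.126, with a CI that reflects the modest signal.

The same pipeline runs from the shell:

```sh
isodimorph simulate --seed 42 --outdir demo/
isodimorph fit --data demo/study_table.csv --tree demo/tree.nwk \
    --formula "value ~ dimorphism"
isodimorph select --data demo/study_table.csv --tree demo/tree.nwk \
    --formula "value ~ dimorphism * diet_class + mean_size" \
    --formula "value ~ dimorphism + diet_class + mean_size"
isodimorph reproduce --data <deposited_table.csv> --tree <tree.nwk> --outdir out/
```

`reproduce` runs the standard battery (intercept-only heterogeneity for
all four metric/isotope pairs, dimorphism meta-regressions, the nine-model
moderator AICc table, gape-limitation subset contrasts) over any dataset
in the package's column schema.

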