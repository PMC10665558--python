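# phyloallom

Phylogenetic comparative analysis of brain-volume allometry, built around a
34-species primate dataset of cerebellar, cerebral, and ansiform-area
(cerebellar crura I–II) volumes.

## The problem

Across primates, brain compartments scale with each other as power laws:
`y = c · x^b`, i.e. `log₁₀ y = a + b · log₁₀ x`, where the exponent *b*
distinguishes isometry (*b* = 1, proportional growth) from hyper-allometry
(*b* > 1, `y` outpaces `x`) and hypo-allometry (*b* < 1).  Species values are
not independent samples — closely related species resemble each other because
they share most of their evolutionary history — so ordinary regression
overstates the evidence.  This package implements the standard comparative
toolkit for that problem:

- **Phylogenetic covariance.**  For a dated tree, `C[i,j]` is the shared
  root-to-MRCA branch length of species *i* and *j*; under Brownian motion
  (BM) trait covariance is `σ²C`.  Transforms give Pagel's λ (off-diagonals
  scaled by λ; λ = 0 is the independent-species "star" model),
  Ornstein–Uhlenbeck (pull toward an optimum with strength α, fixed-root
  form), and Early Burst (exponentially decaying rate, parameter r ≤ 0).
- **Model selection.**  Joint ML fits of the trait matrix under each model,
  ranked by AIC (Δ < 4 comparable, 4–7 significantly less, 7–10 weak, > 10
  no support), plus a χ² contrast of λ = 1 vs λ = 0 (phylogenetic signal).
  Missing trait values are handled exactly by row-deletion on the stacked
  trait ⊗ species covariance.
- **Ancestral character estimation (ACE).**  GLS/ML reconstruction of
  internal-node states under BM with per-node variances and 95% CIs,
  back-transformed to mm³.
- **PGLS.**  `β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y` with t-based 95%/99% slope CIs; the
  isometry test asks whether the CI excludes *b* = 1.  Grade shifts between
  clades (different intercept, slope, or both) are tested by phylogenetic
  ANCOVA F-tests; `R²_likelihood = 1 − exp(−(2/n)(lnL₁ − lnL₀))` with
  Fisher's r-to-z compares fit between subsets.
- **Robustness.**  Monte-Carlo perturbation of volumes by random per-species
  shrinkage factors (within-brain or across-brain), provenance-subset
  comparisons, and literature-based outlier exclusion.
- **Synthetic data.**  Yule chronograms, BM-coupled allometric traits,
  intraspecific specimen noise calibrated to a target MAD%, and injected
  grade shifts — every statistical property of the pipeline is testable
  without downloads.

The bundled species table (`phyloallom.data/species_medians.csv`) carries the
published median volumes in mm³ with raw median absolute deviations (MAD) and
percentage ratios.  The dated consensus tree used by the original analyses
comes from the 10kTrees project (10ktrees.nunn-lab.org) and is not
redistributable here; a clearly-labelled **synthetic stand-in chronogram**
(approximate literature divergence dates, root at 73 My) is bundled so every
analysis runs out of the box.  Tree-dependent numbers computed on the
stand-in are approximate reproductions — supply the real tree via
`phyloallom.read_newick(path)` for faithful ones.

## Worked example

```python
import phyloallom as pa

study = pa.make_study_fixture()          # 34 species, 13 with ansiform volumes
tree  = pa.load_synthetic_consensus_tree()
lt    = study.log_traits()

fit = pa.pgls_fit(tree, lt["log_cerebrum"], lt["log_cerebellum"])
print(fit.slope, fit.ci95)
print(pa.isometry_test(fit)["at95"])

ace = pa.ace_bm(tree, lt["log_cerebellum"])
print(float(ace[ace.is_root]["estimate_mm3"].iloc[0]))
```

prints (stand-in tree):

```
0.9539270023636423 (0.837161936941337, 1.0706920677859475)
isometric
1818.0799662597883
```

The cerebello-cerebral exponent is 0.954 with a CI spanning 1 — the two
volumes grow proportionally — and the reconstructed cerebellum of the last
common ancestor of the sample is ≈ 1.8 cm³, about the size of a ring-tailed
lemur's.  The `examples/` scripts walk through each capability: species
summaries and ratios (01), allometric scaling and isometry (02), model
selection and ACE (03), grade shifts and Fisher's r-to-z (04), shrinkage
robustness (05), and synthetic-data parameter recovery (06).

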