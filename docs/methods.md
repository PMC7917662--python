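# Methods

## Study design model

The package models a two-factor acute-colitis experiment: DSS dose
∈ {0, 1, 2, 3} % crossed with exposure duration ∈ {0, 2, …, 12} days, four
mice sacrificed per (dose, day) cell, cecal 16S profiles per mouse, and
fecal inflammatory biomarkers measured per (dose, day) group — lipocalin-2
(Lcn2) and myeloperoxidase (MPO) in ng/g feces as neutrophil-derived
indicators and hemoglobin (Hgb) in mg/g feces as a bleeding indicator.
Biomarkers are stored at group level because they are assayed on pooled
group feces; per-mouse input is accepted and mean-aggregated with a log
note. The *negative control* is the union of all 0 %-dose samples and the
day-0 samples of every dose group — every observation made without DSS
exposure.

## Analysis pipeline

1. **Rarefaction.** Samples are subsampled without replacement to a common
   depth (default 10,000 reads) via the multivariate hypergeometric
   distribution; shallower samples are dropped and logged. One draw per
   sample; the seed is recorded in the run manifest. All downstream stages
   consume the rarefied table.
2. **Alpha diversity.** Chao1 in the bias-corrected form
   S_obs + F₁(F₁−1)/(2(F₂+1)) (finite when doubletons are absent, the
   library default) and Shannon entropy with natural log by default; the
   log base is a parameter because pipelines differ and the choice is a
   convention, not a result.
3. **Generalized UniFrac.** Branch clade proportions are computed by a
   single post-order accumulation; pairs are scored with the moderated
   formula (see README). α defaults to 0.5, the variant generally
   recommended for sensitivity to moderately abundant lineages; α is
   exposed because no single value is canonical. Branches with zero
   combined abundance in a pair are excluded from numerator and
   denominator. α = 1 reproduces normalized weighted UniFrac and is
   cross-checked in the tests against both a naive per-branch traversal
   and scikit-bio's independent implementation.
4. **Ordination and group separation.** NMDS minimizes Kruskal stress-1 by
   SMACOF (iterative majorization with isotonic regression on distance
   ranks), best of `restarts` random starts, deterministic under seed.
   PERMANOVA/ADONIS decomposes the Gower-centered squared-distance matrix;
   R² = SS_between/SS_total, pseudo-F on (a−1, n−a) degrees of freedom,
   and p by free label permutation with the (1+#{null ≥ obs})/(1+B) rule —
   samples are treated as freely exchangeable because the design is a
   single pooled test. Per-sample dysbiosis is the mean distance to the
   day-0 0 %-dose samples (self-distances excluded).
5. **Exposure screen.** Feature counts are agglomerated to genus (features
   unassigned at genus are binned under their deepest assigned ancestor as
   "uncultured *Family*", fully unassigned features as "Unassigned");
   samples of each (dose, day) cell are merged by summing counts and
   renormalizing (equivalently, a depth-weighted mean of mouse
   compositions — a mean-of-RA mode exists for sensitivity analysis). For
   each dose series the genus trajectory over its seven time points
   (day 0 included as zero exposure) is correlated with day; genera pass
   at strictly |r| > 0.7 and p < 0.05 (two-tailed t transform on n−2 df).
   Serial-dose categories: pass in 1–2–3 % with one sign → *all doses*;
   2–3 % only → *2–3 %*; 3 % only → *3 % only*; every other pattern —
   including 1 %-only and sign-flips — is not selected. A genus that also
   passes in the 0 % series is discarded as temporal drift unrelated to
   exposure. No multiple-testing correction is applied by default, keeping
   the criteria exactly as stated; a Benjamini–Hochberg option exists.
6. **Susceptibility.** Per biomarker, treated (non-control) groups are
   split into mild "A" and severe "B" sections at a threshold; the default
   is the median of the treated group values that exceed the control mean,
   which is scale-free and reproducible, with explicit numeric overrides
   in the config (the biologically "correct" cutoffs are not derivable
   from data alone). Fold change per genus is mean section RA over mean
   control RA; a zero-control genus yields an explicit +∞ sentinel (or 1
   when absent from both) and a flag rather than a pseudocount — a
   pseudocount would silently manufacture finite ratios. Pairs (FC_A,
   FC_B) are classified against a ±5 % band around 1 (consistent
   increase/decrease, dynamic, unchanged); the band absorbs sampling noise
   and is configurable. Genus–biomarker correlations pair group mean RA
   with the group biomarker value over all treated groups pooled across
   doses; selection is strict |r| > 0.6, p < 0.05, and the summary
   separates genera selected by all indices, by Hgb only, and by
   Lcn2/MPO only.

### Null behavior of the screen

The selection rule at seven time points is an exact ≈5 %-level test
(p < 0.05 implies |r| > 0.754 at 5 df), and the *3 % only* category lets a
single dose series qualify a genus. Under any exchangeable null the
expected number of selected genera is therefore ≈ n_genera × 0.045 — about
2–3 bystanders per 60-genus cohort with zero planted effects, as the test
suite measures. This is a property of the published selection rule itself,
not of an implementation or simulation choice; interpret small selected
sets accordingly, or enable the Benjamini–Hochberg option.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with known ground truth.

* **Composition.** Sixty genera by default over five phyla
  (*Firmicutes*, *Bacteroidetes*, *Proteobacteria*, *Actinobacteria*,
  *Verrucomicrobia*), two ASV-like features per genus (fixed Dirichlet
  split) so agglomeration does real work; two bystander genera carry
  family-only lineages to exercise "uncultured" binning. Baseline log
  abundances are Gaussian per class; bystanders use sd 2.0, giving the
  heavy rare tail real genus tables have.
* **Planted classes.** 6 induced (+0.30 log-RA/day at 3 %) and 10 depleted
  (−0.25 log-RA/day) genera, scaled linearly by dose/3; 2 bleeding-coupled
  and 2 neutrophil-coupled genera following the z-scored deterministic
  biomarker trajectory with coupling ±0.7 on the log scale; 40 bystanders.
  Effects enter on the log scale and are renormalized (softmax), so a
  bloom displaces the rest of the community exactly as real compositional
  data do. Induced genera start rare (~0.05 % each) and end dominant
  (tens of percent jointly at 3 %, day 12), matching the
  orders-of-magnitude blooms of acute DSS colitis; their gained mass is
  balanced per cohort against the depleted collapse (`balance_planted`)
  so bystanders experience turnover, not a monotone drift — without this
  the compositional ramp masquerades as dozens of depleted genera.
* **Counts.** Per mouse, Dirichlet-multinomial with concentration 200–800
  (default 800: cohoused, genetically identical mice sampled from the
  cecum are tight replicates — such studies house each dose group in one
  cage precisely to avoid cage effects) at a lognormal depth (median 3×10⁵ reads, sd 0.5 logs,
  floor 10⁴ — the deep-sequencing regime where rarefaction, not library
  size, limits resolution), plus a small per-mouse lognormal wobble
  (sd 0.1 logs).
* **Biomarkers.** Deterministic group surfaces with multiplicative
  lognormal noise (sd 0.10; 0.05 for Hgb). Lcn2/MPO are flat until day 4
  then rise linearly, with a saturating dose response — they respond even
  at 1 %. Hgb rises progressively (√day) only at ≥2 %, strongly dose
  graded; the 1 % group shows a small day-symmetric mid-course excursion
  (transient bleeding) rather than a trend, so its duration correlation is
  near zero — mirroring the qualitative kinetics of neutrophil markers vs
  occult blood in this model, and keeping the two indicator families
  statistically distinguishable (their cross-correlation over treated
  groups is ≈0.5).
* **Truth and scoring.** The truth object records class and effect per
  genus plus the deterministic biomarker surface;
  `score_against_truth` computes precision/recall of any selected set,
  counting false positives among planted bystanders only.

### What the generator does not emulate

No sequence-level artifacts (chimeras, copy-number variation), no cage or
litter effects (each group is one cage by design), no mouse-level biomarker
variation (biomarkers are group-pooled), no phylogenetic signal in the
planted classes (the tree is random, so UniFrac tests geometry, not
ecology), and genus identities are synthetic labels. Passing recovery tests
therefore demonstrates that the statistical machinery detects the planted
structure at realistic noise levels — not that the thresholds are optimal
for any particular real community.

## Numerical choices

* Correlation p-values come from the exact t transform; constant series
  return a tagged *undefined* result that downstream screens treat as
  not-selected, never a NaN.
* Two-way ANOVA accepts balanced complete designs only (the study design
  is balanced); type-I SS equal type-III there. Sums of squares at
  floating-point-noise level are pinned to F = 0 to avoid arbitrary ratios
  on degenerate (exactly fitted or constant) data.
* Permutation p-values use the +1 rule and can never be 0; ADONIS
  permutations, rarefaction draws, NMDS starts, and the generator all
  draw from explicitly seeded generators, and every pipeline run writes
  its seeds to the manifest.
* NMDS reports the best stress over restarts; at near-zero stress,
  adjacent distance ranks may still swap (isotonic fits are piecewise
  constant), so recovery is judged by rank correlation, not rank identity.
* TSV orientation for count tables is resolved from the header token or
  by matching ids against metadata; ambiguous tables are rejected, never
  guessed. Trees must carry branch lengths on every edge; a missing length
  is an error, not zero.

## Problem sizes

Default verification runs use the full 112-sample design: 20 cohorts for
recovery and type-I screens, 200 simulations for PERMANOVA size, 50 random
8-leaf instances for kernel-oracle equivalence. These sizes put the
Monte-Carlo error of each rate well inside the margins being asserted
while keeping a full verification run in the tens of seconds.

## Known limitations

* The serial-dose categories are not monotone in the selection thresholds:
  tightening the r-threshold can move a dose-gap pattern (1 % and 3 % pass)
  into *3 % only*, adding a genus. Per-dose selection is monotone.
* Group-level correlation (n = 7 per dose; n = 18 pooled) has limited
  power and the screen inherits the multiplicity behavior described above.
* Unweighted UniFrac is not provided; the generalized kernel's α → 0 limit
  still weights by (p+q)⁰ on *present* branches, which is not the
  presence/absence metric.
* BIOM support covers the JSON (v1) schema only.
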