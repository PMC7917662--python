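# dsslong

Longitudinal 16S microbiome analysis for two-factor DSS-colitis mouse
studies: dose (0–3 % dextran sulfate sodium in drinking water) crossed with
exposure duration (days 0–12, sampled every other day, 4 mice per cell).
The package is aimed at microbiome researchers who want the full
longitudinal workflow — diversity, phylogenetic ordination, trend-based
differential abundance, and severity susceptibility — as reusable, tested
Python, exercised end-to-end on a synthetic cohort generator with planted
ground truth.

## What it computes

* **Community metrics** — rarefaction to a common depth (default 10,000
  reads, without replacement), relative abundances, taxonomic agglomeration
  with `uncultured <parent>` binning for rank-unassigned features, Chao1
  (bias-corrected: S_obs + F₁(F₁−1)/(2(F₂+1))) and Shannon entropy
  (H = −Σ pᵢ ln pᵢ), and phylum-ratio trajectories (e.g.
  *Bacteroidetes*/*Proteobacteria* vs day).
* **Beta diversity** — generalized UniFrac,

      d^(α)(A,B) = Σᵢ bᵢ (pᵢ+qᵢ)^α |pᵢ−qᵢ|/(pᵢ+qᵢ) / Σᵢ bᵢ (pᵢ+qᵢ)^α,

  over tree branches i with length bᵢ and clade proportions pᵢ, qᵢ
  (α = 0.5 default; α = 1 is normalized weighted UniFrac), nonmetric MDS
  (Kruskal stress-1, SMACOF with restarts), PERMANOVA/ADONIS (R², pseudo-F,
  permutation p with the +1 rule), and per-sample mean distance to the
  untreated day-0 baseline as a dysbiosis trajectory.
* **Exposure screen** — genus-level group compositions per (dose, day)
  cell (counts summed across mice, then renormalized), Pearson correlation
  of each genus's relative abundance with exposure duration within every
  dose series, strict selection at |r| > 0.7 and p < 0.05, and serial-dose
  categorization (*all doses*, *2–3 % only*, *3 % only*); a significant
  trend in the untreated 0 % series disqualifies a genus as temporal drift.
* **Susceptibility** — per biomarker (fecal lipocalin-2 and
  myeloperoxidase in ng/g, hemoglobin in mg/g), treated groups are split
  into mild ("A") and severe ("B") sections, per-genus fold changes of
  section mean abundance over the negative control (0 % mice plus day-0
  mice of every dose) are classified as consistent/dynamic, and pooled
  group-level genus–biomarker correlations are selected at |r| > 0.6,
  p < 0.05 — separating bleeding-associated from neutrophil-associated
  taxa.
* **Synthetic cohorts** — Dirichlet-multinomial counts at lognormal
  library depths with planted induced/depleted dose-scaled log-linear
  trends, biomarker-coupled genera, realistic biomarker kinetics, a random
  phylogeny, and a truth object for scoring precision/recall.

## Worked example

```python
from dsslong import CohortConfig, generate
from dsslong.community_metrics import rarefy
from dsslong.exposure_screen import run_screen
from dsslong.synthetic_cohort import score_against_truth

cohort = generate(CohortConfig(seed=7))           # 112 samples, 60 genera
rare = rarefy(cohort.table, 10000, seed=7)
screen = run_screen(rare, cohort.taxonomy, cohort.metadata)
print(screen.to_frame()[["genus", "direction", "category",
                         "r_3pct", "p_3pct"]].head(8).to_string(index=False))
score = score_against_truth([r.genus for r in screen.selected], cohort.truth)
print("recall:", score["recall"], "null FPs:", score["false_positives_null"])
```

prints

```
   genus direction  category   r_3pct   p_3pct
Genus_01   induced all-doses 0.932790 0.002169
Genus_00   induced      2-3% 0.930859 0.002325
Genus_02   induced      2-3% 0.949734 0.001059
Genus_03   induced      2-3% 0.938650 0.001732
Genus_04   induced      2-3% 0.932468 0.002194
Genus_05   induced      2-3% 0.860051 0.013032
Genus_16   induced      2-3% 0.884902 0.008106
Genus_17   induced      2-3% 0.837497 0.018694
recall: 0.9375 null FPs: 2
```

Each row is a genus whose relative abundance tracks exposure duration: the
direction says whether it blooms or collapses under DSS, the category how
far down the dose series the trend stays significant, and `r_3pct`/`p_3pct`
the Pearson correlation with day in the 3 % group. Here the screen
recovered 15 of the 16 planted colitis-associated genera with two bystander
false positives.

The same pipeline is scriptable from the shell:

```
dsslong run --seed 7 --outdir out/          # full pipeline, synthetic cohort
dsslong simulate --seed 7 --outdir cohort/  # write the five input artifacts
dsslong screen --indir cohort/ --seed 7 --outdir out/
```

`out/manifest.json` captures the configuration, seeds, and stage summaries
(ADONIS R²/p, NMDS stress, selection counts) needed to reproduce a run.

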