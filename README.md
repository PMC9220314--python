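# soilmultifun

Plot-scale **biodiversity–ecosystem functioning (BEF)** analysis for soil
microbial studies: how does microbial diversity relate to a soil's ability to
sustain many functions at once?

The package is aimed at soil ecologists who have (i) a plot × soil-function
table (enzyme activities, N-cycling rates), (ii) bacterial and fungal OTU
count tables, (iii) plot metadata (site, plant-diversity level, above-/
below-ground biomass), and optionally (iv) a FUNGuild-style OTU → trophic
guild table. From these it computes:

* **Soil multifunctionality (SMF)**, three ways.
  *Averaging*: each function Z-scored, `z_ij = (F_ij − mean_j)/sd_j`, and the
  index is the per-plot mean of the z's. *Single-threshold*: the number of
  functions with `F_ij ≥ t·max_j`, where `max_j` is the mean of the top 5% of
  observed values of function *j* and *t* ∈ {25, 50, 75, 90}%.
  *Multiple-threshold*: the single-threshold count regressed (OLS) on
  microbial richness at every threshold from 5% to 99%, summarized by
  **T_min** (smallest threshold with a significant positive richness effect),
  **T_mde** (threshold of the maximum effect) and **R_mde** (the slope there,
  in functions gained per added OTU).
* **Six-way OTU rarity classes** from each OTU's minimum/maximum relative
  abundance across samples, with 1% (abundant) and 0.01% (rare) cutoffs:
  always abundant (AAT), conditionally abundant (CAT), always rare (ART),
  conditionally rare (CRT), moderate (MT) and conditionally rare-and-abundant
  (CRAT); AAT∪CAT = abundant taxa, ART∪CRT = rare taxa.
* **Microbial carbon limitation** via enzymatic stoichiometry:
  `L = sqrt((ln βG / ln(NAG+LAP))² + (ln βG / ln ALP)²)` — the vector length
  of C:N and C:P enzyme ln-ratios; longer vectors mean stronger C limitation.
* A **statistics layer**: independent two-sample t-tests gated on
  Shapiro–Wilk normality and Bartlett homoscedasticity (log-transforming on
  failure), and simple OLS regressions linking richness, guild abundances,
  C limitation and SMF.
* A **synthetic-data generator** that emulates the whole study design
  (6 sites × 5 plots, two plant-diversity levels, latent-richness-driven
  functions, long-tailed OTU tables) with known ground truth, so every
  stage can be validated without field data.

## Worked example

Run the whole pipeline on a simulated study:

```python
from soilmultifun.config import load_config
from soilmultifun.pipeline import run_pipeline

cfg = load_config(overrides={"simulation": {}, "seed": 3, "out_dir": "out"})
run_pipeline(cfg)
```

`out/threshold_summary.tsv` then contains

```
domain	t_min_pct	t_mde_pct	r_mde
bacteria	62.0	73.0	0.0256049434232
fungi	50.0	72.0	0.0870301449206
```

i.e. fungal richness starts to affect the number of sustained functions at
the 50% threshold, the effect peaks at 72%, and at the peak each additional
fungal OTU sustains ~0.087 more functions. `out/group_tests.tsv` holds the
low- vs high-diversity contrasts:

```
variable	mean_low	mean_high	t	df	pvalue	transform
bgb_agb_ratio	1.09739530213	1.70789881295	-7.05498113143	28.0	1.12775083534e-07	none
smf_average	-0.607470352575	0.607470352575	-8.02188011419	28.0	9.79235049287e-09	none
vector_length	1.77058828344	1.26291535252	41.6345685379	28.0	9.90380373647e-27	none
```

High-diversity plots allocate more biomass below ground (BGB:AGB 1.71 vs
1.10), sustain higher multifunctionality, and are less C-limited (vector
length 1.26 vs 1.77) — the causal chain the generator builds in and the
pipeline recovers. The same stages are available from the shell:

```sh
soilmultifun simulate --seed 3 --out-dir fixtures/
soilmultifun classify-rarity --otu-table fixtures/otu_fungi.tsv --domain fungi --out-dir out/
soilmultifun vector-length --functions fixtures/enzyme_activities.tsv --units nmol_g_h \
    --metadata fixtures/plot_metadata.tsv --out-dir out/
soilmultifun pipeline --config pipeline.yaml --seed 3
```

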