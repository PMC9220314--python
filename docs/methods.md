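# Methods

## Multifunctionality indices

**Averaging.** Each function column is standardized with the sample (n−1)
standard deviation; the index is the per-plot mean of Z-scores. The index is
therefore unitless, has grand mean 0 across plots, and is invariant to any
affine rescaling of a raw function column. A zero-variance function is an
error by default; `drop_constant=True` excludes it instead, because silently
carrying a degenerate column would redefine the index denominator.

**Function "maximum".** The threshold family needs a per-function reference
maximum; following the standard practice for this index family we use the
mean of the top 5% of observed values (`top_fraction`, at least one value:
`ceil(0.05·n)`), which is robust to a single outlier plot while tracking the
observed ceiling. With 30 plots this is the mean of the top 2 values.

**Negative-valued functions.** Net nitrification and net N mineralization
can be negative, and "≥ t × maximum" is ill-posed when the maximum is ≤ 0.
The package errors on a non-positive maximum and offers an explicit
`shift_nonneg` transform (subtract each function's observed minimum) as the
opt-in remedy — loud rather than silent, because the shift changes what the
thresholds mean.

**Single vs multiple threshold.** Single-threshold counts are reported at
25/50/75/90% of the maximum. The multiple-threshold analysis fits plain OLS
of counts on richness at every threshold of a 5–99% grid in steps of 1%
(grid values are exact hundredths, so 16% is exactly 0.16). Counts, not
proportions, are regressed, which keeps the slope in functions per added
OTU. Summaries:

* **T_min** — smallest grid threshold with slope > 0 and two-sided p < α
  (α = 0.05 default); reported absent when no threshold qualifies.
* **T_mde** — grid threshold of maximum slope; ties resolve to the smallest
  such threshold for determinism.
* **R_mde** — the slope attained at T_mde. (The literature uses both
  "R_mde" and "R_med" for this quantity; this package standardizes on
  R_mde.)

A threshold where counts are constant is a flat observation, not an error:
slope 0 with p = 1. Because the per-threshold test is applied at α with no
multiplicity control — matching the method as practiced — the *family* of
~95 correlated tests has a false-positive ("T_min defined under a true
null") probability well above α; see Limitations.

## Rarity classification

Each OTU's (min, max) relative abundance across samples is pushed through a
decision tree with abundant cutoff A = 1% and rare cutoff R = 0.01%:
min ≥ A → AAT; else max ≥ A and min < R → CRAT; else max ≥ A → CAT;
else max < R → ART; else min < R → CRT; else MT. Boundary conventions that
make the six categories a true partition:

* at max exactly A, the abundant-side category (CAT/CRAT) wins — "never
  reaching 1%" is read strictly;
* AAT requires ≥ A in *all* samples (otherwise AAT would be a subset of
  CAT and the partition would collapse);
* MT requires R ≤ min and max < A strictly, so MT and CAT cannot overlap;
* an OTU never detected (all zeros) has max < R and is ART.

Category summaries report the share of OTUs and the share of total relative
abundance (mean across samples) per category; both sum to 100%. No
rarefaction or depth normalization is applied — classification operates on
per-sample relative abundances as given, so it is invariant to per-sample
count rescaling. Bacterial and fungal tables are always classified
separately.

## Enzymatic stoichiometry

`L = sqrt((ln βG / ln(NAG+LAP))² + (ln βG / ln ALP)²)`, per plot. The two
coordinates compare carbon acquisition (β-glucosidase) against nitrogen
(N-acetylglucosaminidase + leucine aminopeptidase) and phosphorus (alkaline
phosphatase) acquisition; the Euclidean norm is the "vector length", larger
meaning stronger microbial C limitation. The statistic is a norm, hence the
square root; `sqrt=False` reproduces the bare sum of squares for
comparison with sources that print the expression without the radical.
Ratios of logarithms are not invariant to unit rescaling, so activities
must be declared in nmol g⁻¹ h⁻¹ (`units="nmol_g_h"`), and every log
argument (βG, NAG+LAP, ALP) must exceed 1 so all logarithms are positive.
Only vector *length* is computed; the vector angle (N- vs P-limitation
direction) is out of scope.

## Statistics layer

Two-sample comparisons: Shapiro–Wilk per group and Bartlett across groups
at α = 0.05; if any of the three fails, both groups are natural-log
transformed (an error if non-positive values are present, with an explicit
`log_offset` opt-in) and the gate re-run for the record; then a Student
(equal-variance) t-test on the possibly transformed data — the remedy for
heteroscedasticity in this workflow is the transform, not Welch, though
`welch=True` exists for sensitivity analysis. If the transform still fails
the gate, the test proceeds with a warning. Regressions are simple OLS with
the two-sided slope test; p-values are reported unadjusted throughout.

## Synthetic data

The generator emulates the study design the pipeline targets, not the
underlying ecology: 6 sites × 5 plots, sites 1–3 low diversity (single
species) and 4–6 high.

* **Latent richness** per plot: fungal N(350, 30) low / N(450, 30) high;
  bacterial N(900, 50) / N(1000, 50). The ~100-OTU group separation makes
  the between-level richness contrast clearly significant at n = 15/15, as
  observed in such studies.
* **Functions**: `F_ij = a_j + b_j·S_f(i) + ε_ij`, with b_j = 0.01
  functions per fungal OTU, σ_j = 0.5 and a_j = 0. The zero baseline makes
  function values span roughly threefold across plots (CV ≈ 23%), the
  magnitude of variation typical of soil enzyme assays; a large baseline
  would compress the relative range to a few percent and render the
  threshold family degenerate. The design-implied averaging-index slope is
  `mean_j b_j / sqrt(b_j² Var(S) + σ_j²)` with Var(S) the realized latent
  richness variance; `GroundTruth.expected_average_index_slope()` computes
  it for recovery tests.
* **Biomass**: AGB ~ N(300, 40) g m⁻²; BGB = AGB × (ratio + N(0, 0.25))
  with ratio 1.0 (low) vs 1.8 (high), so high-diversity plots allocate more
  biomass below ground by design.
* **Enzyme activities** (for the stoichiometry stage): lognormal per
  diversity level, sdlog 0.1; βG meanlog ln 400 (low) vs ln 75 (high) with
  NAG/LAP/ALP shared, which places the designed vector-length difference at
  ≈ +0.49 (low − high): C limitation stronger under low diversity.
* **OTU tables**: per-sample proportions = seeded abundance tiers plus a
  lognormal (meanlog 0, sdlog 3) species-abundance tail, jittered per
  sample, renormalized, then multinomial at depth 50,000. The tiers pin a
  few OTUs inside each rarity category's band (with jitter widths that make
  the "conditionally" categories cross the 1%/0.01% cutoffs), so all six
  categories are populated in expectation; the tail makes rare taxa roughly
  80% of observed OTUs. Richer plots draw from more of the ranked tail
  (depth-independent truncation at the latent richness), so realized
  richness tracks latent richness (r ≈ 0.86 at defaults). Never-observed
  OTUs are dropped, as in a real clustering output.
* **Guilds**: labels drawn per OTU (saprotroph 0.30, pathotroph 0.15,
  symbiotroph 0.10, unassigned 0.45); saprotroph proportions are scaled by
  e^{±0.4} (up in high-diversity plots) and pathotrophs oppositely, giving
  the designed positive saprotroph and negative pathotroph associations
  with diversity.

One PCG64 root seed; component substreams are spawned in a fixed order so
adding a component never perturbs another's draws.

What the generator does **not** emulate: spatial autocorrelation between
plots, phylogenetic structure, compositional coupling between domains,
sequence-level artifacts (chimeras, clustering noise), or any mechanistic
link from OTUs to functions (functions are driven by the latent richness
directly). Passing recovery tests therefore demonstrates that the
statistical machinery recovers designed effects under the stated sampling
model — not that the biological conclusions transfer to any particular
field dataset.

## Numerical choices

* Z-scores use the sample (n−1) standard deviation.
* Threshold grid values are exact hundredths; T_min/T_mde are reported in
  percent and are always members of the grid.
* Constant-response regressions return slope 0, p 1, R² 0 rather than NaN.
* Identical t-test groups return t = 0, p = 1 without consulting the gate.
* Pipeline TSVs round floats to 12 significant digits, making reruns with
  the same config and seed byte-identical.
* Problem sizes in tests: recovery checks run on one 30-plot default
  simulation; calibration uses 2,000 t-test replicates and 200 permutation
  re-analyses of the full 95-point grid; oracle sweeps use 100 random
  30×10 matrices and 10,000 random OTU profiles.

## Known limitations

* **Familywise behavior of T_min.** With ~95 per-threshold tests at
  α = 0.05 and only partial dependence between neighbouring thresholds, the
  probability that a true-null dataset yields *some* significant positive
  threshold (hence a defined T_min) is ≈ 14% at the default design, not α.
  The per-threshold test level is faithful to the method as published; a
  familywise-calibrated T_min would need max-statistic permutation
  calibration, which is deliberately not added here.
* The guild stage assumes one guild per OTU; mixed-guild annotations must
  be resolved upstream.
* The gated t-test's log remedy requires positive data; rate variables that
  can be negative need the explicit offset.
* BIOM support is TSV-dialect only (no HDF5), and no sequence processing of
  any kind is included — the pipeline starts from OTU tables.
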