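# Methods

## Data model

A co-IP LC-MS/MS acquisition is reduced to one cell per (protein,
experiment, antibody, treatment): the total peptide count (spectral
count, a relative-abundance proxy) and the distinct peptide number
(unique sequences supporting the identification). Cells that were never
measured are a first-class *not measured* marker, distinct from a true
`0(0)` cell: zeros participate in classification (a protein can drop to
zero under treatment), absences cannot. The packaged reference tables
transcribe the published counts of the 19 proteins reproducibly
detected in three independent anti-CESA pull-downs; the pre-immune
control counts of the original study were never deposited, so control
behaviour is exercised only through the synthetic generator.

All file I/O is tab-separated UTF-8 with mandatory headers and `.`
decimals; writers emit deterministic column order so reruns are
byte-identical.

## Enhancement statistic and Group I/II rule

Per experiment, enhancement is `100 (T − B) / B` on total counts
(and, in parallel, on distinct counts), computed in exact rational
arithmetic and rounded **half-up** (ties toward +∞) to an integer
percent. The three-experiment average is taken over the *rounded*
per-experiment values and rounded half-up again. This order of
operations reproduces every published average exactly; rounding the
unrounded means does not. The source tables round one cell
inconsistently (112 where exact arithmetic gives 112.9), so validation
allows ±1 point on per-experiment values while averages are held exact.
A zero blank count leaves the percent undefined (reported as such,
never as infinity); negative enhancement is reported, not clamped.

Group I requires the treated **total** strictly above the blank total in
every experiment. The distinct-peptide series is reported but does not
gate: one published Group-I protein has a decreasing distinct count in
one experiment, so a totals-only rule is the only one consistent with
all 19 published assignments. With integer rounding the percent is
non-decreasing (not strictly increasing) in the treated count; the
underlying exact ratio is strict.

## Specificity classes

The presence rule keeps proteins with ≥1 total peptide in at least one
treatment cell of every required experiment (default 3) under the
target antibody. For retained proteins the fold is the ratio of total
peptide counts summed over all experiments and both treatments, target
antibody over pre-immune serum — the simplest per-protein aggregation
consistent with a per-protein fold statement; sums over means is a
deliberate choice, and the threshold is inclusive (≥ 2.0) because the
background class is defined as *less than* 2-fold. Control sum zero
with nonzero target is its own class (*specific, absent from control*);
zero under both sera is an error, since such a protein cannot have
passed the presence rule.

## Glucan assay arithmetic

The in vitro reaction incorporates ¹⁴C-UDP-glucose; products are
resolved by sequential digestion (β-1,3-glucanases release callose; of
the remaining β-1,4-glucan, β-1,4-glucanases release the
non-crystalline ~90% and the resistant pellet is crystalline
cellulose). Two routes give the nmol-per-cpm factor:

* **Analytic**: label nmol = activity (µCi → Bq) / specific activity
  (GBq mmol⁻¹ → Bq nmol⁻¹); label cpm = activity × 2.22×10⁶ dpm µCi⁻¹ ×
  counting efficiency; factor = isotope-dilution ratio × nmol/cpm.
  With the study constants (0.05 µCi, 11.174 GBq mmol⁻¹, 7551:1,
  efficiency 1) this gives ≈ 0.01126 nmol cpm⁻¹.
* **Calibrated**: through-origin least squares of nmol on cpm,
  `Σxy/Σx²`, from paired observations. The published paired columns
  imply ≈ 0.00878 nmol cpm⁻¹ with < 1.5% spread across the four strata.

The two disagree by ~28%; the stated reaction constants are mutually
inconsistent with the published nmol values under any counting
efficiency ≤ 1, and the source of the discrepancy cannot be resolved
from the publication. The pipeline therefore treats calibration from
data as the default pathway and the analytic derivation as a documented
alternative (an explicit `factor_override` bypasses both). Counting
efficiency defaults to 1.0 (none is stated).

Method-comparison ratios are rounded half-up to two decimals.
Replicate comparisons use the pooled-variance two-sample t-test on
`n₁+n₂−2` degrees of freedom; zero-variance degenerate input resolves
to (0, 1) for equal means and (±∞, 0) otherwise. p-values are raw — the
experimental design tests a handful of planned contrasts, and no
multiple-testing correction is applied.

## Co-expression grouping

Spearman's ρ (average ranks for ties, via scipy) over tissues; ρ is
undefined for constant profiles and reported as such. Significance uses
the t-transform `t = ρ√((n−2)/(1−ρ²))` on n−2 df, adequate at the
64-tissue compendium scale; a seeded permutation p-value is provided
for small panels. |ρ| = 1 is reported as p = 0 with a warning.

Clustering is agglomerative with **average linkage on 1 − ρ** — the
linkage and distance are not dictated by the original analysis, and
this choice matches the correlation statistic used everywhere else.
Genes are processed in lexicographic order and cluster labels
renumbered by first appearance, so results are independent of row
order. Association labels use a majority vote: a candidate is
CESA-associated when ρ > 0 and p < α (default 0.05) against more than
half of the CESA reference genes, likewise for the callose-synthase
references; *majority* operationalizes an otherwise unquantified
"correlates with the reference set". A candidate never votes for
itself.

## Synthetic data

The generators emulate the statistical structure the classifiers
assume, not the instrumentation:

* **IP-MS counts**: totals are Poisson per cell (optionally
  Gamma-Poisson with an overdispersion parameter; at typical co-IP
  depths Poisson is adequate for testing a deterministic classifier).
  Distinct peptides are the occupancy of `total` draws over an
  equiprobable pool of `peptide_pool_size` peptides (expected occupancy
  `p(1−(1−1/p)ⁿ)`), which guarantees distinct ≤ min(total, pool).
  Defaults: baseline mean 15 (a mid-table spectral count), enhancement
  multiplier 2.5 (inside the 2–4-fold count enrichment and 1.5–3.6-fold
  product increases the treatment produces), control binding fraction
  0.2 for specific preys (true fold 5), full baseline for background
  binders, 3 experiments, 30 proteins. Role assignment is deterministic
  from the configured fractions; only counts are random. Enhanced preys
  are planted inside the specific set, as in the real complex.
* **Expression**: module genes are `3 × latent + N(0,1)` around a
  module latent profile (within-module Pearson 0.9), background genes
  pure noise, 64 tissues. Real compendia have correlated tissues,
  batch structure and heavier tails; recovery rates here therefore
  bound what the method does under its own assumptions, not on arrays.
* **Assay**: cpm = true nmol / factor with multiplicative Gaussian
  noise (CV 0.05, triplicates), truncated at zero.

All randomness flows from a single explicit seed per generator; global
random state is never touched. Under the null (multiplier 1) the
strict-increase rule fires at rate `P(T > B)³ < 0.5³`; with tie
probability ≈ 0.073 at mean 15 the realized rate is ≈ 0.10.

## Validation problem sizes

The recovery checks use 200 simulated datasets of 30 proteins for the
enhancement/specificity stages (and 200 more for the null rate), 100
seeded replicates of two 10-gene modules for clustering recovery, and
1,000 random inputs for each oracle-equivalence check (Spearman vs
explicit rank-then-Pearson; enhancement vs pure-integer half-up
arithmetic) — sizes at which the Monte-Carlo margins are comfortably
inside the asserted bounds.

## Known limitations

* No probabilistic scoring of interactions (no SAINT-style model) and
  no contaminant-repository filtering; the classes are deterministic
  rules on counts, as in the original design.
* Protein inference from shared peptides, raw spectra handling and
  search-engine score filtering are out of scope: input rows are
  assumed to be already-filtered identifications.
* The co-expression stage assumes homolog mapping has already happened;
  gene identifiers are opaque strings.
* The fold aggregation for specificity (sums across experiments) is one
  of several defensible conventions; per-experiment folds with a voting
  rule would behave differently near the threshold.
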