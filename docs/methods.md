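# Methods

This note documents the statistical model behind `secretodiff`, the
choices made where the analysis was genuinely open, and what the
synthetic data generator does and does not emulate.

## Data model

LFQ intensities from MaxQuant's `proteinGroups.txt` are treated as
lognormal: all modelling happens on the log2 scale.  A reported
intensity of 0 means "not measured" and is represented as an explicitly
masked cell, distinct from any numeric value; no stage other than
imputation may fill a masked cell, and imputation is the only stage
whose output depends on a random seed.  Flag columns follow the
MaxQuant convention that the literal `+` marks a row; anything else is
false.

Missingness in such data is predominantly left-censored (missing not at
random): proteins drop out when their abundance falls near the
detection limit.  Every downstream choice — the presence filter, the
down-shifted imputation, the per-column centering over observed values
only — assumes this mechanism.

## Filter cascade

Order: QC flags → sample exclusions → log2 → replicate-presence filter
(per batch) → batch merge → secreted-protein restriction → median
centering.  Points that needed a decision:

- **Flag priority.** A row carrying several QC flags is counted once in
  the filter report, with priority contaminant > reverse > site-only,
  so report counts always sum to the input row count.
- **Presence filter.** "Measured in at least 50% of the replicates of
  at least one condition" is evaluated with exact rational arithmetic,
  so 2 of 4 passes at τ = 0.5.  Groups are the (batch, condition) cells
  of the design *after* exclusions; excluded samples never contribute
  to presence fractions.
- **Exclusions.** Samples are excluded by (donor, condition) rule
  before any statistics are computed.  The rule exists because a sample
  with >95% unmeasured entries would make its column median (and any
  per-column imputation statistics) meaningless.
- **Secreted restriction** matches GOCC terms case-insensitively after
  whitespace normalization.  Annotations may come from an embedded
  `GOCC names` column or a separate long-format table; the separate
  table wins per protein on conflict, since embedded columns depend on
  the MaxQuant configuration and are often stale.
- **Median centering** subtracts each sample column's median over its
  *observed* values — the only defensible choice under MNAR, since the
  unobserved tail is below the detection limit by assumption.  The
  operation is idempotent to floating-point precision.

## Imputation

Missing cells are drawn from normal distributions shifted below the
observed intensities, with the branch chosen per (protein, condition):

- **major branch** (≥ 50% of the condition's replicates measured — the
  value was probably near the detection limit): `N(μ − 0.5σ, (0.3σ)²)`;
- **minor branch** (protein essentially absent from the condition):
  `N(μ − 1.8σ, (0.3σ)²)`.

Ties at exactly the presence cut go to the major branch, matching the
"≥" of the presence filter.  The reference scope for (μ, σ) is
configurable: the default `per_sample` computes them per sample column
over that column's observed values, which reconciles per-sample
imputation with the condition-level branch logic; `per_condition` and
`global` scopes are available for sensitivity analysis, since the exact
scoping convention differs between published workflows.  A column that
needs draws but has zero or undefined observed SD is a hard error.

Each cell's draw comes from a dedicated RNG stream seeded from
(seed, CRC32(protein id), CRC32(sample id)), so imputation results are
independent across cells and invariant to row/column ordering — a
property the test suite asserts.

## Differential testing

Each treatment is compared with the untreated group of the same batch
by Welch's unequal-variance t-test with Welch–Satterthwaite degrees of
freedom (delegated to `scipy.stats.ttest_ind(equal_var=False)`), on the
imputed matrix, so the test and the reported log2 fold change (mean
difference of log2 values) use exactly the same data.  Degenerate
cases: two zero-variance groups with identical means give p = 1 by
convention; zero variance with different means is computed with a
machine-epsilon variance floor to preserve the sign of the effect.

P-values are Benjamini–Hochberg adjusted (statsmodels `fdr_bh`; the
suite checks it against a brute-force step-up enumeration).  The family
is all proteins of one (batch, treatment) contrast by default — the
per-treatment phrasing of the hit definition — with a pooled-per-batch
option, since the two conventions give different hit counts and the
right one is not always recorded.  Hits are strict on the FDR
(q < 0.1) and inclusive on the effect (|log2FC| ≥ 1).

## Clustering

Rows are z-scored with the sample SD (constant rows map to zeros,
logged).  Rows and columns are clustered agglomeratively; the distance
and linkage used for published heatmaps are rarely recorded, so the
default is the common choice for such figures — Euclidean distance with
average linkage — and both are configurable (correlation, complete,
Ward).  Only the qualitative property is asserted in tests: with a
batch offset of at least twice the within-batch SD, the top column
split partitions samples exactly by batch.

## Targeted assays

Multiplex/ELISA readouts: technical duplicates are averaged first;
`value = raw_signal / tissue_protein`; per-donor fold change is value
over the batch's mean untreated value (so the untreated group's mean FC
is exactly 1), and the condition FC is the donor mean.  Computing FCs
on group means instead is supported (`per_donor=False`) because both
orders appear in practice.  Group comparisons use the two-sided
equal-variance Student's t-test (configurable to Welch), flagged
significant at p < 0.05 and notable at 0.05 ≤ p < 0.09.

qPCR: `dCt = Ct_gene − mean(Ct_PPIA, Ct_ACTB)`, relative expression
`2^−dCt`, optionally normalized to the untreated group's mean and
reported as log2FC.  The method is invariant to a constant shift
applied to all Ct values of a sample, and only to such shifts — both
directions are asserted.

## Synthetic data generator

The generator emulates the *statistical structure* the analysis
assumes, not mass spectrometry:

- 1400 proteins per batch (default), baseline log2 intensity
  ~ N(25, 2²) shared between batches;
- two batches with an additive offset of 2 log2 units on the second;
- four conditions (untreated + three treatments), n = 4 biological
  replicates (n = 5 for untreated in the second batch), replicate noise
  SD 0.5;
- sparse planted effects: 2% of secreted proteins per (batch,
  treatment), log2FC drawn from {−2, −1.5, 1.5, 2} — chosen to mirror
  the ~1–2% differential fraction typical of such exposures;
- left-censored missingness, P(missing | x) = logistic((c − x)/w) with
  detection midpoint c = 22 and width w = 1, giving ~5% dropout at the
  baseline mean and steeply more below it (a MCAR contrast mode is
  available by moving c);
- 2% decoy, 2% contaminant and 2% site-only junk rows; 20%
  non-secreted proteins annotated with non-secretory GOCC terms;
- two degenerate untreated samples in the second batch with 97% forced
  missingness, named after donors 14 and 16 so the exclusion rule has a
  target;
- raw-scale intensities rounded to 6 significant figures when written,
  to exercise parser tolerance.

Not emulated: protein–protein correlation, peptide-level inference,
shared-peptide ambiguity, and intensity-dependent variance.  Passing
recovery tests therefore demonstrates correctness of the pipeline's
arithmetic and its operating characteristics *under the stated model*,
not performance on any particular real dataset.

## Problem sizes and tolerances in the test suite

Distributional checks on the imputation pool 10⁴ draws per branch
(moments within ±0.01 of the shifted-normal values).  Null uniformity
of Welch p-values uses 10⁴ simulated 4-vs-4 comparisons and a KS test
at α = 0.01.  Recovery runs 20 replicates of the full design for the
bias check (planted log2FC of 2 recovered within ±0.1 on fully observed
proteins) and 50 replicates at 5% affected proteins for the empirical
FDR check (pooled FDR ≤ 0.15, i.e. the nominal 0.1 plus Monte-Carlo
slack).  Batch separation is checked over 50 seeds at 300 proteins with
the offset set to exactly twice the replicate SD.  The acceptance
script uses 10–25 replicates per quantity; all of these sizes keep the
whole suite in well under half an hour on one CPU while leaving
Monte-Carlo error far below the asserted tolerances.

## Known limitations

- The imputation reference scope actually used by any given published
  analysis may differ; results for proteins with heavy missingness are
  sensitive to this choice (hence the config switch).
- Welch's test with n = 4 per group has limited power at |log2FC| = 1.5
  once FDR correction over ~1100 proteins is applied; the recovery
  report makes this visible (recall well below 1) rather than hiding it.
- Median centering removes only location-type batch effects; no
  variance harmonisation or empirical-Bayes correction is attempted.
- Hit counts are stochastic through imputation: two analyses of the
  same data with different seeds can differ for borderline proteins.
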