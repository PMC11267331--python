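# secretodiff

Differential secretion analysis for label-free quantitative (LFQ)
secretomics, built for studies that ask how a treatment changes the set
of proteins a tissue releases into its culture medium — for example,
placental explants exposed to engineered nanoparticles, where the
conditioned medium (the secretome) is profiled by LC-MS/MS and
quantified with MaxQuant.

## What it does

The package implements the complete analysis path from a MaxQuant
`proteinGroups.txt` table to a list of differentially secreted proteins:

1. **QC filtering** — contaminants, reversed-decoy matches, and proteins
   identified only by modification sites are removed.
2. **Sample exclusions** — samples with degenerate coverage (e.g. >95%
   unmeasured entries) are dropped by (donor, condition) rule.
3. **Replicate-presence filter** — a protein is kept if it was measured
   in ≥ 50% of the biological replicates of at least one condition.
4. **log2 transform and batch merge** — LFQ value 0 encodes
   "not measured" and becomes a masked cell, never log2(0).
5. **Secreted-protein restriction** — proteins are kept when annotated
   with one of six GOCC terms (secretory granule [lumen/membrane],
   extracellular vesicle/space/exosome).
6. **Median centering** — each sample column is shifted so that the
   median of its observed values is 0, removing depth differences and
   discrete batch offsets.
7. **MNAR imputation** — missing intensities are drawn from normals
   shifted *below* the observed values: shift 0.5·SD when ≥ 50% of a
   condition's replicates were measured, 1.8·SD when the protein was
   essentially absent from the condition; width 0.3·SD in both cases.
8. **Welch + BH testing** — each treatment vs. untreated within batch,
   Welch's t-test with Benjamini–Hochberg FDR per contrast family;
   *hits* satisfy q < 0.1 and |log2FC| ≥ 1.
9. **Clustering** — row-z-scored matrix, hierarchical clustering of
   rows and columns (Euclidean/average by default) with an exportable
   column dendrogram.

It also ships the targeted-assay arithmetic used alongside discovery
secretomics (multiplex/ELISA signals normalized to tissue protein
content with fold changes vs. untreated and Student-t significance
flags; qPCR relative expression by the 2^-dCt method against PPIA and
ACTB), plus a synthetic-data generator that emulates the LFQ data
structure — two batches, four conditions, 4–5 biological replicates,
left-censored missingness, junk rows, planted effects — with a ground
truth table, so the whole pipeline is testable without any downloads.

The core stages are scikit-learn style estimators (`QCFilter`,
`PresenceFilter`, `SecretedFilter`, `MedianCenterer`,
`DownShiftImputer`, `WelchDifferentialTester`, `HierarchicalClusterer`)
operating on a proteins × samples `LogIntensityMatrix`; plain functions
(`presence_filter`, `impute`, `fit_contrasts`, ...) wrap them.

## Worked example

The packaged 12-protein miniature table contains one contaminant, one
decoy, one site-only identification, two proteins failing the presence
filter, two nuclear (non-secreted) proteins, and five analyzable
secreted proteins:

```python
import secretodiff as sd

design = sd.read_design("tests/data/toy_design.tsv")
table  = sd.read_protein_groups("tests/data/toy_proteinGroups.txt", design)
gocc   = sd.read_gocc("tests/data/toy_gocc.tsv")
res    = sd.run_tables({"term": table}, design, gocc, sd.RunConfig(seed=42))
print(res.report.to_frame().to_string(index=False))
print(res.results.round(4).to_string(index=False))
```

prints

```
batch  input_rows  retained  contaminant  reverse  site_only  presence  non_secreted
 term          12         5            1        1          1         2             2

protein_id   contrast  log2fc  t_stat     df      p      q   hit
       P01 TiO2_vs_UT   1.725  6.7337 3.6699 0.0034 0.0172  True
       P02 TiO2_vs_UT  -1.275 -3.7496 3.8750 0.0211 0.0528  True
       P03 TiO2_vs_UT  -0.275 -1.1326 3.0000 0.3397 0.4111 False
       P04 TiO2_vs_UT  -0.175 -0.8866 5.6987 0.4111 0.4111 False
       P05 TiO2_vs_UT  -0.275 -1.0735 3.6699 0.3485 0.4111 False
```

The filter report is conserving (12 = 5 + 1 + 1 + 1 + 2 + 2).  P01 is
secreted roughly 3.3-fold more under TiO2 exposure (log2FC 1.73 after
median centering) and passes both hit thresholds (q = 0.017 < 0.1,
|log2FC| ≥ 1); P02 drops ~2.4-fold and also qualifies; the remaining
proteins are unchanged.

The same pipeline runs from the shell:

```bash
secretodiff simulate --seed 7 --out sim/        # synthetic dataset + truth
secretodiff run --config run.yaml --out out/    # full analysis bundle
secretodiff recover --n-rep 20 --seed 1         # recovery vs planted truth
secretodiff qpcr --table ct.csv                 # 2^-dCt relative expression
```

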