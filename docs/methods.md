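# Methods

## The consensus-scoring model

`mirpanel` prioritizes microRNAs by how broadly and how credibly they target a
fixed panel of genes. The panel shipped with the package is the set of seven
clinically validated atherosclerosis drug targets — PCSK9, HMGCR, MTTP, APOC3,
LPA, CETP, APOB (G = 7) — but every function is parametric in the panel.

Evidence comes in two kinds:

* **Validated interactions**: rows exported from curated databases of
  experimentally supported miRNA–target pairs (TarBase-class,
  miRTarBase-class). Databases vote as a union: a gene counts once for a miRNA
  no matter how many validated databases list the pair.
* **Predicted interactions**: one export per computational prediction tool
  (seed-match / thermodynamics predictors), drawn from a registry of D tools
  (default D = 30). Each tool contributes at most one vote per (miRNA, gene)
  pair; votes across tools accumulate.

Per miRNA the scores are

    V = |{panel genes with validated evidence}|          0 ≤ V ≤ G
    P = Σ_genes (number of tools confirming the pair)    0 ≤ P ≤ D·G
    C = P / (D·G) + V / G                                0 ≤ C ≤ 2

C reaches its bound of 2 exactly when all D tools confirm every panel gene and
validated evidence covers the whole panel. The denominator uses the panel size
G, not the per-miRNA count of targeted genes: under the per-miRNA reading a
miRNA validated on all of its own targets would saturate at C ≥ 1 regardless
of breadth, defeating the purpose of rewarding multi-gene coverage.

A *multi-target filter* retains miRNAs with evidence (of either kind) on at
least `min_target_genes` panel genes; the default of 2 encodes "targets more
than one gene". Ranking is descending by C at full floating-point precision,
with deterministic tie-breaks: higher V, then higher P, then the miRNA
identifier alphabetically. C-Scores are rounded (default 2 decimals) only in
the reporting layer, never before ranking.

### Identifier handling

miRNA identifiers are matched case-insensitively and displayed in the
conventional `hsa-miR-124-3p` casing; arm suffixes (`-3p`/`-5p`) distinguish
mature miRNAs and are never stripped. Gene symbols are upper-cased and passed
through an alias map (`APOCIII → APOC3` by default) because apolipoprotein
C-III appears under both spellings across databases. Off-panel genes are kept
in the reader output with an `on_panel` flag so the same exports can be
re-scored against a different panel.

## PPI edge-list summary

STRING-style exports score each protein pair with a combined confidence in
[0, 1]; some dialects print 0–1000 integers, detected and divided by 1000
(idempotently). Tiers use the conventional inclusive cutoffs 0.15 (lowest),
0.4 (medium), 0.7 (high), 0.9 (highest); "lowest" is the conventional
low-confidence default, chosen because the tier is otherwise only defined as
"below 0.4". Edge counts are therefore monotone non-increasing as the tier
rises. The summary (nodes, edges, degrees) is computed on the simple
undirected graph of surviving edges, optionally padding isolated panel genes.
Database-side quantities — the enrichment p-value, the live tier counts of any
particular STRING release — are out of scope; the shipped
`ppi_athero_synthetic.tsv` is a synthetic edge list constructed only to
demonstrate a 20/14/8 medium/high/highest profile over the 7-gene panel.

## Relative expression (2^−ΔΔCT)

Technical replicates are averaged on the Ct scale (arithmetic mean, no outlier
rejection). Per biological replicate, ΔCt = Ct(target) − Ct(reference)
(GAPDH for mRNA, SNORD47 for miRNA assays); ΔΔCt subtracts the control-group
mean ΔCt; fold = 2^−ΔΔCt. Reported fold change and SD are the mean and SD of
per-replicate folds — i.e. on the fold scale, matching how such results are
reported ("fold change relative to control ± SD") — while inference runs on
ΔCt values, which are approximately normal: one-way ANOVA followed by Tukey
HSD contrasts versus the control, plus a Lilliefors-corrected
Kolmogorov–Smirnov normality check (n ≥ 4, non-constant). Significance tiers
map p < 0.05 → `*`, p < 0.01 → `**`. Amplification-efficiency correction
(Pfaffl) and absolute quantification are intentionally out of scope.

The ΔΔCT construction is invariant under adding a constant to every Ct of one
sample (input-amount effects cancel in ΔCt), and the control's fold against
itself is exactly 1 in the noiseless limit; both are property-tested.

## MTT viability

Per well, signal = A570 − A630 (background-corrected formazan absorbance);
viability% = 100 · mean(treated signal) / mean(control signal) at the matching
timepoint. Wells with negative corrected signal are kept but counted in
`n_flagged`; a non-positive control mean raises a normalization error rather
than producing a nonsense percentage.

## Synthetic-data generator

Because no raw database exports or wet-lab tables accompany the study design,
every input is generated with planted ground truth:

* **Evidence exports** — for each (miRNA, gene) with planted count k, exactly
  k distinct tools (sampled without replacement; *which* tools is immaterial
  to every score) list the pair; each validated pair appears under one or two
  source databases. By construction the pipeline's V/P/C equal the planted
  scores exactly, which is the central oracle test (also cross-checked by an
  independent csv-level recount).
* **Ct tables** — Ct(reference) ~ 16 + N(0, σ); Ct(target) = 16 + 8 −
  log2(fold) + N(0, σ), with 3 biological × 3 technical replicates and
  σ = 0.1 cycles by default (reactions in triplicate and ~0.1-cycle technical
  noise are field-typical; base Ct 16 and ΔCt 8 are ordinary qPCR magnitudes
  and cancel from every fold). Noiseless tables recover planted folds exactly.
* **MTT plates** — A630 background ≈ 0.05 AU, full-viability signal 0.6 AU,
  6 wells per condition, 2% relative well noise; planted fractions are
  recovered within a few percentage points.

What the generator does *not* emulate: amplification-efficiency differences
between assays, plate-position effects, miRNA–mRNA sequence binding, or
correlated biological variation between genes. Passing recovery tests
therefore show the estimators are correct under idealized noise, not that any
particular wet-lab figure is reproducible; published fold-change panels are
bundled as *emulation scenarios* (planted means), never as recomputable
outputs.

## Numerical and design choices

* Integer scores use exact integer arithmetic; no tolerance anywhere in the
  evidence path.
* Deterministic outputs: generators take explicit seeds (same seed →
  byte-identical files); CLI tables are sorted and serialized at fixed
  precision so identical runs are byte-identical.
* A miRNA present in only one evidence kind still receives a C-Score (the
  formula handles V = 0 or P = 0); the multi-target filter uses the union of
  evidence kinds.
* Degenerate inputs fail loudly: empty panels, unknown tiers, counts above D,
  missing reference assays, constant samples, and non-positive control signals
  raise typed exceptions rather than propagating NaNs.

## Problem sizes used in the test suite

Stochastic checks run at 100 random export sets for the pipeline-vs-recount
oracle, 200 seeds per planted fold for ΔΔCT recovery, 1000 null replicates
for the ANOVA type-I rate, and 50 seeds per distribution for the normality
check; the whole suite completes in about a minute on one core.

## Known limitations

* Gene-symbol reconciliation is a static alias map, not a full HGNC resolver.
* The prediction registry is configuration; the package does not know which
  30 tools a given study used, only how many.
* Tukey p-values on noiseless synthetic data degenerate to 0 (infinite test
  statistic); real data is never noiseless.
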