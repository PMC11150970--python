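# myosig

Cluster-restricted gene signatures for myogenic cell populations: derive
them from clustered single-cell RNA-seq counts, score them in bulk
transcriptomes, evaluate them as cell-identity classifiers, and test
whether their association with an external measurement beats random gene
sets.

## The problem

Satellite cells — the PAX7⁺ resident stem cells of skeletal muscle — and
their myoblast/myocyte progeny are a small fraction of the cells in a
muscle biopsy, so their activity is hard to read out of bulk RNA-seq:
most "myogenesis" gene sets are also expressed in fibers, immune cells or
fibro-adipogenic precursors. The remedy is a signature of genes whose
expression is *restricted* to the population of interest, derived from
large single-cell atlases and applied as a simple per-sample score to
bulk data. This package implements that machinery end to end, for anyone
who wants to build such signatures from their own clustered single-cell
data or apply the published myogenic ones (satellite cell, 10 genes;
myoblast/myocyte, 25; myonuclear, 66 — bundled as a GMT fixture).

## The method

Genes are kept as markers of a target population T when, with strict
inequalities,

- Wilcoxon rank-sum q-value (Bonferroni) `< 0.05` for T vs all other cells,
- fold change `(mean_T + c)/(mean_rest + c) > f_min` on library-size
  normalized expression (pseudocount `c = 0.01`),
- detected (count > 0) in `< d_glob` of all non-target cells and in
  `< d_clus` of the cells of every single other cluster.

A 3 × 3 × 3 grid over `(f_min, d_glob, d_clus)` — fold change
{1.5, 1.75, 2}, global detection {5, 10, 15 %}, per-cluster detection
{20, 30, 40 %} — yields 27 candidate lists; lists under 10 genes are
dropped and the winner is the list whose score best classifies the target
population in an independent validation dataset by ROC AUC.

Scores are sums of log-normalized expression of the signature genes
(DESeq2-style median-of-ratios + log2 for bulk; per-10k + ln for single
cell), reported after subtracting the control-group mean. The association
test draws 1000 random gene sets of matched size, correlates each with the
external measurement (Spearman), and reports the add-one empirical p-value
`(k+1)/(n+1)` — exactly 1/1001 (< 0.001) when no random set out-performs
the signature.

## Worked example

Everything below runs on the bundled synthetic-data generators — no
downloads.

```python
import myosig as ms

# clustered single-cell data with 12 planted satellite-like markers
m, ann, truth = ms.generate_single_cell(ms.default_sc_config(seed=1))
vm, vann, _   = ms.generate_single_cell(ms.default_sc_config(seed=2))

res = ms.SignatureDerivation(m, ann).fit(vm, vann.target_mask(),
                                         name="satellite_synthetic")
print(res.summary())
```

```
Signature derivation results
============================================================
Target clusters:      ['cluster_0']
Grid points:          27
Candidates >= 10 genes: 27
Selected signature:   satellite_synthetic (12 genes)
Winning thresholds:   fold change > 1.5, global detection < 0.05, cluster detection < 0.2
Validation AUC:       1.0000
------------------------------------------------------------
Genes (by descending fold change):
gene_00001, gene_00008, gene_00003, gene_00004, gene_00009, gene_00005, ...
```

All 27 grid points pass the 10-gene minimum here, the selected list is
exactly the 12 planted markers, and it classifies the held-out target
cluster perfectly (AUC 1.0 — on real cross-species validation one expects
values above 0.9 rather than 1).

```python
# bulk cohorts mixed from cell-type profiles; disease groups carry
# 3x / 6x the control satellite fraction
cfg, bulk_truth = ms.default_bulk_config(seed=3)
bm, meta, histology, props = ms.generate_bulk_cohort(cfg)

logm = ms.log_normalize(bm, mode="bulk_median_of_ratios")
score = ms.score_signature(logm, bulk_truth["satellite"])
centered = ms.center_scores(score, list(meta.index[meta.group == "control"]))
print(centered.scores.groupby(meta.group).mean().round(2))
```

```
group
control           0.00
disease_mild      4.54
disease_severe    9.65
```

The centered score rises monotonically with the planted satellite
fraction — the property that lets a 10-gene sum report on a ~1 % cell
population from whole-tissue RNA.

```python
null = ms.RandomSetNull(logm, bulk_truth["satellite"],
                        histology.to_numpy(), n_resamples=1000).fit(seed=4)
print(null.summary())
```

```
Random-gene-set resampling null
==================================================
Signature:          satellite_truth
Observed Spearman:  0.9087
Resamples:          1000 sets (universe of 2000 genes, seed 4)
Null rho range:     [-0.7183, 0.9000]
Sets out-performing the signature: 0
Empirical p:        0.000999 (p < 0.001)
```

The signature's correlation with the simulated PAX7⁺-per-fiber histology
(ρ = 0.91) exceeds all 1000 random sets, so the association is reported as
p < 0.001 — the smallest value the add-one estimator can produce at 1000
resamples.

The same stages are available from the shell
(`myosig simulate | derive | score | evaluate | associate | compare`), and
`myosig run --outdir out --seed 1` executes the whole chain, writing
`signature.gmt`, `scores.tsv`, `roc.tsv`, `assoc.json` and a
`provenance.json` that records the exact configuration and seeds.

The published human signatures are available directly:

```python
sigs = ms.load_reference_signatures()   # SatelliteCell (10), MyoblastMyocyte (25), Myonuclear (66)
```

## Layout

- `src/myosig/io.py` — count-matrix (TSV / MatrixMarket), GMT and ortholog-table I/O; core types
- `src/myosig/derivation.py` — marker statistics, threshold grid, ROC-based selection (`SignatureDerivation`)
- `src/myosig/scoring.py` — normalization, signature scores, control centering
- `src/myosig/evaluation.py` — ROC / AUC
- `src/myosig/association.py` — Spearman, random-gene-set null (`RandomSetNull`), group tests
- `src/myosig/simulate.py` — synthetic single-cell and bulk-cohort generators
- `src/myosig/cli.py` — command-line interface
- `docs/methods.md` — models, parameter choices, numerical details, limitations
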