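# Methods

`myosig` implements a pipeline for deriving cell-type-restricted gene
signatures from clustered single-cell RNA-seq counts, scoring them in bulk
transcriptomes, evaluating them as cell-identity classifiers, and testing
score–phenotype associations against a resampling null. This note records
the models, the parameters that matter, the numerical choices, and what the
bundled synthetic data does and does not establish.

## Signature derivation

Given a raw count matrix with per-cell cluster labels and a designated
target population (a set of clusters), each gene g receives:

- **fold change** `FC_g = (mean_target + c) / (mean_rest + c)` on linear
  library-size-normalized expression (per-10k scaling), pseudocount
  `c = 0.01` in numerator and denominator. The pseudocount guards the ratio
  for genes near zero; it is exposed as a parameter because published
  workflows differ on both the scale (log vs linear) and the offset.
- **detection fractions**: the fraction of cells with a nonzero raw count,
  computed over the target population, over all non-target cells pooled
  (global), and within each single non-target cluster (the maximum over
  clusters is retained). "Expressed" means raw count > 0, the standard
  single-cell convention. The global fraction is a cell-weighted mean of
  the per-cluster fractions and therefore always lies between their min
  and max.
- **DE q-value**: two-sided Wilcoxon rank-sum of target vs all other
  cells on normalized expression, Bonferroni-adjusted. Bonferroni (rather
  than an FDR procedure) is the marker-test convention of the Seurat
  lineage this workflow descends from, and family-wise control is the
  right scale here: a handful of genes is being certified, not a gene set
  being screened. With an FDR adjustment, a few overwhelming true markers
  relax the threshold enough to admit sporadic chance markers.
  `fdr_bh` is available as an option, and the prefilter can be disabled.

A gene enters a candidate list when it passes **all** filters strictly:
`q < α` (default 0.05), `FC > f_min`, global detection `< d_glob`,
per-cluster detection `< d_clus`. Strict inequalities match the filter as
published ("greater than" / "less than"). Candidates are ordered by
descending fold change.

The threshold grid defaults to fold change {1.5, 1.75, 2.0} × global
detection {5, 10, 15 %} × per-cluster detection {20, 30, 40 %} — 27
combinations. Candidates with fewer than `min_size` genes (default 10) are
discarded; the survivors are scored on an independent validation dataset
and the list with the highest ROC AUC against the validation labels wins.
AUC ties are broken by smaller gene count, then lexicographic gene order,
making selection deterministic and invariant to candidate order. AUCs are
rounded to 12 decimals before comparison so floating-point accumulation
noise cannot split a genuine tie (without this, two lists with true AUC
exactly 1 can differ by one ulp and the larger one can win). A
`thresholds=` argument skips the grid and applies one fixed combination —
the mode used when a signature inherits thresholds optimized for another
population rather than being re-optimized (the published myoblast/myocyte
and myonuclear signatures reused the satellite-optimal thresholds because
validation data for their populations was insufficient).

## Normalization and scoring

A signature score is the **sum** (not mean) of log-normalized expression of
the signature's genes in one observation. Sums match the published
definition; the consequence — score scale grows with signature size and
with the dataset's depth — is why scores are only compared within a
dataset and are reported after subtracting a control-group mean
(`center_scores`). Genes absent from a dataset are dropped for that
analysis; the retained fraction is recorded as coverage and a warning is
logged below 75 % (analyses proceed, since the published work once
proceeded at 3/10 genes).

Two normalization conventions:

- **Single-cell**: `ln(count / library_size × 10,000 + 1)`.
- **Bulk, median-of-ratios**: size factors are computed by the
  median-of-ratios construction, with one deliberate modification. The
  textbook version (reference = per-gene geometric mean of raw counts
  across samples) is *not* exactly invariant to rescaling one sample's
  counts: the reference couples the samples, and every normalized value
  picks up a factor `c^(1/m)`. We instead take the ratios on
  composition-normalized counts (each sample divided by its mean count per
  gene, `N_j/G`) and re-attach the library scale:

      sf_j = (N_j / G) · median_g( C_gj / geomean_i(C_gi) ),  C = counts·G/N

  computed over the genes nonzero in every sample, with the median taken
  in log space. Because the reference now depends only on compositions,
  scaling one sample's counts scales exactly that sample's size factor and
  leaves every normalized value in the matrix untouched — the contract the
  scoring layer relies on. The factors remain *exactly* proportional to
  the classical DESeq2 factors (constant `geomean(N)/G`, verified against
  pydeseq2 to 1e-12 in the test suite), so all within-dataset comparisons
  are identical to the DESeq2 convention. Values are `log2(x + 1)`; the
  base is configurable and irrelevant to rank-based downstream statistics.

## ROC evaluation

Scores are evaluated as binary classifiers with higher score = positive
class, never auto-flipped: a failed signature should surface as AUC < 0.5.
Ties contribute half a pair, so AUC equals the normalized Mann–Whitney
statistic `U/(n₁n₀)`; the test suite verifies this identity against an
O(n²) pairwise oracle to 1e-12 and checks invariance under monotone score
transforms and complementation under label swap. AUC is clipped into
[0, 1] (trapezoid accumulation can stray an ulp outside).

## Association and the resampling null

`spearman` is the Pearson correlation of mid-ranks. Its two-sided p-value
uses the t approximation for n > 10 and a permutation computation for
n ≤ 10 (full enumeration up to n = 7, seeded Monte Carlo above).

`resampling_null` asks whether a curated signature's correlation with an
external per-sample measurement beats size-matched random gene sets: for
each of `n_resamples` (default 1000) draws, `sig_size` genes are sampled
uniformly without replacement from the gene universe (default: genes with
nonzero expression in at least one sample — a constant score has no
defined rank correlation), scored identically, and correlated with the
measurement. "Out-performed" is read one-sided on ρ (the claim is a
positive association); a two-sided |ρ| option exists. The empirical
p-value is the add-one estimator `(k + 1)/(n + 1)` with
`k = #{null ρ ≥ observed ρ}`; it can never be 0, and with 1000 resamples
and no out-performing set it is exactly 1/1001, reported as p < 0.001.

Group comparisons dispatch as in the published figures: Wilcoxon rank-sum
(unpaired) or signed-rank (paired, with an explicit sample→pair map and an
error listing incomplete pairs); for ≥ 3 groups, one-way ANOVA with
Tukey's HSD when every group passes Shapiro–Wilk at α = 0.05 (or
`normality_ok=True`), otherwise Kruskal–Wallis with Dunn's post-hoc
(pooled mid-ranks, tie-corrected variance, unadjusted two-sided normal
p-values; implemented in-house as no installed package provides Dunn).
Stars: * < 0.05, ** < 0.01, *** < 0.001, **** < 0.0001.

## Synthetic data

The generators emulate the statistical structure the pipeline assumes,
not any particular tissue.

**Single cell** (`generate_single_cell`): negative-binomial counts,
per-gene baseline means lognormal(log 0.3, 1.0), dispersion r = 2 —
overdispersed and sparse enough to mimic droplet data. Default scale is 4
clusters × 500 cells × 2,000 genes, a desk-scale stand-in for a
hundreds-of-thousands-of-cells atlas. Planted markers are calibrated
analytically from the NB zero probability, `P[X>0] = 1 − (r/(r+μ))^r`:
the target-cluster mean is set so the detection fraction hits the
requested value (default 0.8) and the background mean likewise (default
0.02); the requested fold change (default 4) acts as a floor on the mean
ratio, raised only if the detection-implied ratio is smaller. Calibrating
means from detections rather than tuning empirically keeps realized
detection fractions within ±0.05 of specification by construction.
Feasibility requires target detection > background detection.

**Bulk** (`generate_bulk_cohort`): expected expression is a
proportion-weighted mixture of per-cell-type profiles, scaled to the
library size (default 10⁶), counts NB with dispersion 20 (mild
biological + technical noise). The default design has four types
(satellite, myoblast, myonucleus, interstitial) with 10 exclusive markers
each at 50× a leaky 2 % background, and groups control / mild / severe
with satellite fractions 1 / 3 / 6 % (myoblast in parallel) — healthy
muscle satellite content is of order 1 % of nuclei, and regenerating
dystrophic muscle several-fold that. Pseudo-histology links PAX7⁺ cells
per fiber to the satellite fraction linearly (slope 6, Gaussian noise
sd 0.02, floored at 0): 1 % satellite content maps to ≈ 0.06 PAX7⁺ per
fiber, a realistic order of magnitude. A gradient helper spreads
satellite fractions over 0.5–10 % for dose-response designs, and a
time-course option replaces groups with eight post-injury timepoints
(0–48 h) in which the satellite fraction dips by 8 h, the myoblast
fraction rises from 16 h, and myonuclear content dips near 20 h and
recovers by 48 h.

**What passing tests show, and what they do not.** The synthetic data have
independent genes (no co-expression modules), no batch effects, doublets,
or ambient RNA, exactly known cluster labels, and markers that are
cleanly restricted by construction. Recovery, AUC, monotonicity and
calibration results on these data certify the *machinery* — filters,
selection, scoring algebra, null construction — under the stated
generative model; they do not certify performance on real tissue, where
marker bleed-through, annotation error and correlated genes can only
degrade the clear-separation behaviour.

## Problem sizes and determinism

The test suite and the acceptance script run the derivation at the default
4 × 500 × 2,000 scale over 20 seed pairs, the calibration study at 200
replicates × 200 resamples on 1,000-gene, 24-sample null cohorts, and the
association analyses on 24-sample gradient cohorts with 1,000 resamples —
sizes chosen to exercise every code path at single-workstation cost. All
randomness flows through `numpy.random.default_rng` seeds; the CLI's `run`
command derives per-stage child seeds from one master seed via
`SeedSequence`, so identical configurations reproduce identical outputs.

## Known limitations

- Bulk size factors differ from classical DESeq2 by the dataset constant
  `geomean(N)/G`; absolute log-normalized values are therefore not
  interchangeable with DESeq2 output, though all within-dataset contrasts
  are.
- Dunn's post-hoc reports unadjusted pairwise p-values; apply a
  multiplicity correction externally if many pairs are compared.
- The DE prefilter treats cells as independent replicates
  (pseudoreplication is not addressed), as do the marker tests it mirrors.
- Ortholog mapping is table-driven and one-to-one; many-to-one collisions
  keep the first occurrence with a warning.
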