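# Methods

This note documents the models and procedures implemented in `ggnpipe`,
the defaults they run with, and the design decisions taken where the
underlying analysis convention was genuinely open.

## Cohort model and synthetic data

The synthetic generator (`ggnpipe.synthetic`) emulates a three-stage
cohort — normal lung (nLung, stage 0), adenocarcinoma in situ (AIS, stage
1) and invasive adenocarcinoma (IAC, stage 2) — with 5/3/4 samples per
group by default and a fixed cluster mix per sample (epithelial 30%,
immune 25%, stromal 10%, three T-cell clusters 35%).

Counts are negative binomial via the gamma–Poisson construction with
gene-specific baseline means (lognormal, mean 0.5 counts, σ = 1) and one
shared dispersion θ = 10. All planted structure acts multiplicatively on
the NB mean, parameterised on the log2 scale:

* **CNV segments.** A configurable fraction (default 40%) of AIS/IAC
  epithelial cells multiplies the means of a contiguous gene block by
  2^shift (default +1 over most of chromosome 1).
* **Stage modules.** Five gene modules follow per-stage mean levels —
  ascending-linear (0, ½, 1), ascending-step (0, 1, 1), biphasic
  (0, 1, ¼), descending (1, ½, 0), flat (0, 0, 0) — scaled by an effect
  size (default 1.5 log2) in epithelial cells, plus one latent Gaussian
  factor per module per cell (sd 1.2 log2, hub gene loading 2×) that
  induces the within-module co-expression the network analysis recovers.
  Module genes are drawn at expressed-gene abundance (lognormal mean 3
  counts) so this correlation (~0.5–0.6 at the cell level) survives count
  noise, as it does for real stage-filtered genes.
* **T-cell programs.** Naive/cytotoxic/exhaustion gene panels are elevated
  (default +1.5 log2) in their designated T cluster with per-cell activity
  spread (sd 0.8); panels are drawn with tighter abundance spread (σ = 0.5,
  mean 2 counts) because curated marker panels are reliably expressed. The
  cytotoxic program additionally drops 1 log2 in AIS/IAC cells, emulating
  the cytotoxicity loss along disease progression and providing planted
  positives for the dysfunction-gene selection.
* **TCR.** Clone sizes per T cluster follow a truncated geometric law
  (stop probability 0.90/0.45/0.65 for naive/cytotoxic/exhausted, caps
  20/50/50), reproducing a long-tailed clone-size distribution with two
  parameters; each clonotype carries random V/J genes and CDR3 sequences,
  emitted as one TRA and one TRB contig per cell.

What the generator does **not** emulate: doublets, ambient RNA, batch
effects, cell-type-specific library sizes, realistic gene-length or
GC effects, spatial structure, BCR. Passing recovery benchmarks therefore
demonstrates correctness of the statistics under the stated noise model,
not robustness to every artefact of real droplet data. One real-data
effect the generator does reproduce is compositional: strongly ascending
modules inflate library size in later stages, which can push a truly flat
module's normalised trajectory slightly downward.

## QC and composition

A cell is excluded when **any** of the four rules fires, with strict
inequalities (a cell at exactly 50,000 counts, exactly 200 detected genes
or exactly 20% mitochondrial fraction is kept): counts > 50,000, detected
genes > 6,000, detected genes < 200, mitochondrial fraction > 20%.
Mitochondrial genes are recognised by the feature-name prefix `MT-`
(configurable). Filtering is idempotent.

Composition tables report per-sample cluster fractions (absent clusters
as 0) and group differences use a two-sided unpaired Wilcoxon rank-sum
test on per-sample fractions with **exact conditional enumeration** when
both groups have ≤ 10 samples: mid-ranks are assigned to the pooled
values and the permutation distribution of the Mann–Whitney U statistic
is enumerated exhaustively, so ties are handled exactly and the 5-vs-4
design reproduces the characteristic p-ladder (minimum 2/126 ≈ 0.016).
Larger groups fall back to the tie-corrected normal approximation with
continuity correction. No multiplicity correction is applied across
clusters, matching per-cluster reporting conventions.

## CNV inference and malignancy score

Profiles are computed for query (epithelial AIS/IAC) cells against a
reference of immune and stromal cells:

1. library-size normalisation (counts per 10k);
2. log2 relative expression versus the reference per-gene mean,
   `log2(x+1) − log2(ref_mean+1)`;
3. clipping to ±3 log2;
4. a centred moving average of 101 genes within each chromosome
   (truncated windows at chromosome edges; chromosomes with < 3 genes
   pass through unsmoothed with a warning);
5. subtraction of the per-gene reference mean of the smoothed values, so
   reference profiles centre at exactly 0.

Window 101 and clip ±3 mirror the documented defaults of the standard
expression-CNV tool. Genes without genomic positions are dropped
(at most 10% may be missing); chromosomes sort naturally (1..22, X, Y).

The **mean-square statistic** of a cell is the mean of its squared profile
values. The reference pattern is the per-gene mean profile of the
ceil(0.05·n) cells with the largest mean square (ties broken by cell
order, so the top set is deterministic); the **CNV score** is each cell's
Pearson correlation with this pattern. A cell in the top set is scored
against a pattern that includes itself — excluding it changes scores
negligibly once n ≫ 20. Zero-variance profiles score 0 (with a warning), a
conservative non-malignant default. `classify_malignant` applies a strict
threshold (default 0.3) and reports the malignant percentage to one
decimal place.

The random-split check re-tests the called partition: per gene a rank-sum
test on log-normalised expression with BH correction, a DEG requiring
|logFC| ≥ 0.25 and adjusted p < 0.05; the same is run on random
label permutations preserving class sizes, which should (and in the
benchmarks does) yield a median of zero DEGs.

## Stage filter, metacells and modules

**Stage association.** Per gene, log-normalised expression is modelled as
`expr ~ intercept + stage` with a random intercept per sample, stage
entering as an ordinal 0/1/2 covariate (a categorical variant was
considered; ordinal was chosen as the simplest model matching a staged
progression). The stage term is tested by likelihood ratio against the
stage-free null and genes pass at BH-FDR < 0.001. The fit is a profiled
maximum likelihood written for this purpose: with variance ratio
λ = σ²_between/σ²_within fixed, the GLS solution and profile likelihood
have closed forms per sample block, and λ is optimised on a bounded
interval that includes 0. This makes boundary fits (pure-noise genes,
where λ̂ = 0) exact and fast rather than a numerical failure mode;
general-purpose mixed-model optimisers are fragile exactly there.
Degenerate genes get p = 1 with a flag instead of an exception. On
pure-noise cohorts the filter passes ~0% of genes at FDR 0.001.

**Metacells.** Within each stage independently: PCA (top 20 PCs) of
log-normalised expression, then greedy aggregation — seed at the
lowest-index unused cell, pool it with its k−1 nearest unused neighbours
(default k = 10); a final remainder of ≥ k_min (default 5) cells forms one
smaller metacell, smaller remainders are discarded; a stage with < k
cells yields no metacells. Metacell expression is the member mean of
log-normalised expression. These defaults give mean metacell sizes of
~7–10 cells, the magnitude typical of published metacell analyses.

**Soft threshold.** For each candidate power β, adjacency
`|cor|^β` (signed-hybrid available), connectivity k_i = Σ_j a_ij, and the
scale-free fit R² of log10 p(k) vs log10 k over 10 equal-width
connectivity bins, signed by the slope (a positive slope counts as a
failure). β is the smallest candidate reaching R² ≥ 0.8, else the argmax.

**Modules.** TOM from the adjacency; average-linkage hierarchical
clustering of 1 − TOM with a **static cut** at height 0.99 (the dynamic
hybrid tree cut is a deliberate deviation: the static cut is deterministic
and sufficient for planted-module recovery at these sizes); clusters below
30 genes go to grey. Module eigengenes are the first principal component
of the gene-standardised metacell submatrix (unit norm, sign fixed so the
mean member kME is positive); modules whose eigengenes correlate above
0.75 are merged. Modules are named with the classic colour palette in
decreasing-size order. kME is the correlation of a gene's metacell
profile with an eigengene; hub genes are the top 25 by own-module kME,
ties broken by gene id.

**Trajectories.** Per module, the eigengene's per-stage means m₀, m₁, m₂
with δ = 0.25·(max − min): descending iff m₀ ≥ m₁ ≥ m₂ and m₀ − m₂ > δ;
biphasic iff m₁ > max(m₀, m₂) + δ; ascending-step iff m₁ and m₂ both
exceed m₀ + δ with |m₂ − m₁| ≤ δ; else ascending-linear iff m₀ < m₁ < m₂;
else flat. A module whose stage spread is within noise (2× the largest
per-stage standard error of the eigengene) is called flat up front; a
module missing a stage is undetermined.

## Gene-program scores and dysfunction genes

Scores re-implement the binned-control scheme: genes are placed into 24
equal-frequency bins by average log-normalised expression (gene-name
tie-breaks keep the result independent of column order); each set gene
contributes 100 control genes sampled from its bin — set genes excluded
as candidates, sampling without replacement when the bin allows, seeded —
and the score is mean(set) − mean(controls) per cell. The bin and control
counts are the documented defaults of the reference implementation of
this scheme.

Dysfunction-gene selection intersects three per-gene criteria computed on
the scored cells: |Pearson r| ≥ 0.3 against the cytotoxic score
(zero-variance genes get r = 0), |logFC| ≥ 0.3 and BH-adjusted rank-sum
p < 0.05 between nLung and AIS/IAC. logFC is the difference of group
means of natural-log normalised expression (configurable to log2). The
|r| convention with explicit directional classes (`pos_corr_down`,
`neg_corr_up`) was chosen over signed r ≥ 0.3 so both reported directions
of dysfunction are selectable.

## TCR repertoire

Clonotype identity concatenates CDR3 (nucleotide when available, else
amino acid), V and J gene of the TRA and the TRB chain. Cells are
retained iff exactly one productive (and, for 10x input,
high-confidence) contig per chain remains; retention is reported as a
percentage to two decimals. Clone sizes are counted globally by default,
with a per-sample scope option (expansion within a repertoire). Occupancy
bins are **rank** bins: clonotypes sorted by descending clone size (ties
by clonotype id) and cut at ranks 10 / 100 / 1,000 / 10,000; each bin's
value is the member-clone cell total over the stratum's cells, so rows
sum to 1. Overlap between clusters defaults to the overlap coefficient
(shared clonotypes over the smaller repertoire, in percent, diagonal
100); the Jaccard variant is available because the field uses both and
"overlap rate" is not standardised. V–J usage is cell-weighted and
normalised per group.

## Numerical choices and problem sizes

All randomness flows through `numpy.random.default_rng` seeds; every
simulation and sampling step is deterministic under a fixed seed. The
validation suite and the reproduction script use cohorts of roughly
2,000–3,600 cells and 800–6,000 genes — sizes at which every planted
effect is comfortably detectable in seconds-to-minutes on one CPU —
with 10–20 seed replicates where a rate is measured.

## Known limitations

* The CNV score measures agreement with the dominant aberrant profile; in
  cohorts where strong non-CNV expression programs (e.g. large stage
  modules) span many genes, those programs leak into the smoothed
  profiles and inflate scores of non-malignant epithelial cells. The
  random-split DEG check is the guard for this failure mode.
* The mixed-model stage filter assumes a single random intercept per
  sample; sample-specific stage slopes are not modelled.
* The static tree cut trades the sensitivity of the dynamic hybrid
  algorithm for determinism; very close or nested modules may merge.
* Exact rank-sum enumeration is limited to groups of ≤ 10 samples
  (C(20,10) ≈ 1.8×10⁵ assignments); beyond that the normal approximation
  is used.
* Clonotype identity is exact sequence matching; no allowance for
  sequencing error or convergent CDR3s.
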