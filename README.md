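# ggnpipe

Single-cell RNA + TCR analysis of early-stage lung adenocarcinoma cohorts
presenting as ground-glass nodules (GGN). The package re-implements, as a
tested and reusable library, the bespoke computations of a three-stage
cohort design — matched normal lung (nLung), adenocarcinoma in situ (AIS)
and invasive adenocarcinoma (IAC):

* **QC and composition** — the four cell-level filters (UMI > 50,000,
  genes > 6,000, genes < 200, mitochondrial fraction > 20% each exclude a
  cell) and per-sample cell-type composition compared between groups with
  an exact two-sided unpaired Wilcoxon rank-sum test on per-sample
  fractions.
* **CNV-based malignancy calling** — per-cell copy-number profiles inferred
  from expression along genomic coordinates (clipped log2 relative
  expression vs an immune/stromal reference, per-chromosome moving
  average). Cells are sorted by the mean square (MS) of their CNV values;
  the **CNV score** of a cell is the Pearson correlation *r* of its profile
  with the mean profile of the top 5% of cells by MS, and cells with
  *r* > 0.3 are called malignant. A random-split differential-expression
  check verifies that the resulting partition carries signal that arbitrary
  splits do not.
* **Stage-trajectory co-expression modules** — genes associated with the
  ordinal stage (0/1/2) via a linear mixed model (random intercept per
  sample, likelihood-ratio test, BH-FDR < 0.001), cells aggregated into
  per-stage metacells, then the WGCNA core: soft-threshold power β chosen
  by scale-free fit, adjacency `a_ij = |cor(g_i, g_j)|^β`, topological
  overlap `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,
  average-linkage clustering, module eigengenes and kME connectivity, and a
  trajectory class per module (ascending-linear, ascending-step, biphasic,
  descending, flat).
* **Gene-program scoring** — binned-control scores (mean expression of a
  gene set minus expression-matched sampled controls) for naive, cytotoxic
  and exhaustion programs, and the dysfunction-gene selection: genes with
  |Pearson r| ≥ 0.3 versus the cytotoxic score **and** |logFC| ≥ 0.3 with
  BH-adjusted rank-sum p < 0.05 between nLung and AIS/IAC.
* **TCR repertoire statistics** — clonotypes as unique paired TRA–TRB
  receptors (CDR3 + V + J per chain; only cells with exactly one productive
  TRA and one TRB are retained), clonal fractions (clone size ≥ 2),
  clone-space occupancy over clonotype-rank bins (cutoffs 10 / 100 / 1,000 /
  10,000), clonotype overlap between clusters (overlap coefficient or
  Jaccard) and V–J gene-pair usage.
* **Synthetic cohorts with ground truth** — a generator that emulates the
  cohort design (5 + 3 + 4 samples, negative-binomial counts) and plants a
  malignant subpopulation with chromosome-scale shifts, five trajectory
  modules, three T-cell programs and clonally expanded repertoires, so
  every stage of the pipeline can be validated end to end with no external
  data.

## Worked example

```python
import ggnpipe as gp
from ggnpipe import benchmarks

cfg = gp.SimConfig(seed=1)                       # 12-sample, 3-stage cohort
adata, contigs, truth = gp.simulate_dataset(cfg)

filtered, report = gp.filter_cells(adata)        # QC (all synthetic cells pass)

# TCR repertoire
table, rep = gp.assign_clonotypes(contigs, metadata=adata.obs.rename_axis("barcode"))
print(rep["n_retained"], rep["retention_pct"], rep["n_clonotypes"])
# 1260 100.0 864
print(gp.clonal_fraction(table, by="cluster").set_index("cluster")["fraction"].round(3).to_dict())
# {'T_cytotoxic': 0.824, 'T_exhausted': 0.58, 'T_naive': 0.185}

# malignancy calling and module recovery on dedicated benchmark cohorts
print(benchmarks.cnv_recovery(seed=1))
# {'sensitivity': 1.0, 'specificity': 0.9955..., 'n_query': 371, 'n_cells': 2040}
print(benchmarks.module_recovery(seed=1))
# {'ari': 0.9577..., 'n_detected': 5, 'n_trajectory_correct': 5, 'n_metacells': 91}
```

The clonal fractions mirror the planted clone-size laws (expanded cytotoxic
cells, mostly-singleton naive cells); the CNV benchmark recovers the
planted malignant population at the default score threshold of 0.3; the
module benchmark recovers all five planted modules (adjusted Rand index
0.96) with their trajectory classes.

A thin CLI mirrors the library: `ggn simulate`, `ggn qc`, `ggn cnv`,
`ggn modules`, `ggn score`, `ggn tcr` (see `ggn --help`).

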