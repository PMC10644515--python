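"""Cell-level quality control and per-sample cell-type composition.

QC removes a cell when any of the study's four rules fires (strict
inequalities): total UMI counts > 50,000, detected genes > 6,000, detected
genes < 200, or mitochondrial fraction > 20%. Composition summarises the
per-sample cluster make-up and compares groups with an exact two-sided
unpaired Wilcoxon rank-sum test on per-sample fractions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from ._stats import rank_sum_test

__all__ = ["QCThresholds", "filter_cells", "composition", "compare_composition"]


@dataclass
class QCThresholds:
    max_counts: float = 50_000
    max_genes: float = 6_000
    min_genes: float = 200
    max_mito_fraction: float = 0.20
    mito_gene_prefix: str = "MT-"

    def __post_init__(self):
        if not self.min_genes < self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")


def filter_cells(adata, thresholds: QCThresholds | None = None):
    """Apply the QC rules; return (filtered AnnData, per-cell report).

    A cell is removed iff counts > max_counts OR detected genes > max_genes
    OR detected genes < min_genes OR mito fraction > max_mito_fraction; the
    report records which rule(s) fired for every input cell. Raises if no
    cell survives.
    """
    thr = thresholds or QCThresholds()
    X = adata.X
    if sparse.issparse(X):
        counts = np.asarray(X.sum(axis=1)).ravel()
        n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    else:
        X = np.asarray(X)
        counts = X.sum(axis=1)
        n_genes = (X > 0).sum(axis=1)
    mito_mask = adata.var_names.str.startswith(thr.mito_gene_prefix)
    if mito_mask.any():
        sub = X[:, np.flatnonzero(mito_mask)]
        mito = np.asarray(sub.sum(axis=1)).ravel()
    else:
        mito = np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore"):
        mito_frac = np.divide(mito, counts, out=np.zeros_like(mito, dtype=float),
                              where=counts > 0)

    report = pd.DataFrame(
        {
            "total_counts": counts,
            "n_genes": n_genes,
            "mito_fraction": mito_frac,
            "fail_max_counts": counts > thr.max_counts,
            "fail_max_genes": n_genes > thr.max_genes,
            "fail_min_genes": n_genes < thr.min_genes,
            "fail_mito": mito_frac > thr.max_mito_fraction,
        },
        index=adata.obs_names,
    )
    report["keep"] = ~report[
        ["fail_max_counts", "fail_max_genes", "fail_min_genes", "fail_mito"]
    ].any(axis=1)
    if not report["keep"].any():
        raise ValueError("QC removed every cell: empty dataset")
    return adata[report["keep"].to_numpy()].copy(), report


def composition(metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-sample cluster composition.

    `metadata` needs `sample`, `group`, `cluster` columns (one row per
    cell). Returns one row per (sample, cluster) — including fraction-0 rows
    for clusters absent from a sample — with the cell count and the fraction
    of that sample's cells.
    """
    required = {"sample", "group", "cluster"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if metadata[list(required)].isna().any().any():
        raise ValueError("metadata contains missing sample/group/cluster labels")
    counts = (
        metadata.groupby(["sample", "cluster"], observed=True, sort=True)
        .size()
        .unstack(fill_value=0)
    )
    group_of = metadata.drop_duplicates("sample").set_index("sample")["group"]
    frac = counts.div(counts.sum(axis=1), axis=0)
    long = (
        frac.stack()
        .rename("fraction")
        .to_frame()
        .join(counts.stack().rename("n_cells"))
        .reset_index()
    )
    long.insert(1, "group", long["sample"].map(group_of).to_numpy())
    return long[["sample", "group", "cluster", "n_cells", "fraction"]]


def compare_composition(table: pd.DataFrame, group_a: str, group_b: str) -> pd.Series:
    """Per-cluster two-sided Wilcoxon rank-sum p-values on per-sample
    fractions between two groups (exact enumeration for small groups)."""
    for g in (group_a, group_b):
        if (table["group"] == g).sum() == 0:
            raise ValueError(f"group {g!r} has no samples")
    out = {}
    for cluster, sub in table.groupby("cluster", observed=True):
        a = sub.loc[sub["group"] == group_a, "fraction"].to_numpy()
        b = sub.loc[sub["group"] == group_b, "fraction"].to_numpy()
        out[cluster] = rank_sum_test(a, b)
    return pd.Series(out, name="pvalue")
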