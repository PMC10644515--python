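"""Binned-control gene-set scoring and dysfunction-gene selection.

A cell's score for a gene program (naive, cytotoxic, exhaustion) is the
mean log-normalised expression of the program genes minus the mean of
expression-matched control genes: all genes are binned by average
expression and each program gene contributes controls drawn from its own
bin. Scores therefore centre near 0 for a program behaving like background.

Dysfunction-gene selection intersects two criteria on CD8 T cells: Pearson
correlation of a gene with the per-cell cytotoxic score (|r| >= 0.3) and
differential expression between nLung and AIS/IAC cells (|logFC| >= 0.3,
BH-adjusted rank-sum p < 0.05), then splits the hits into the two
directional classes: positively correlated genes that fall in AIS/IAC
(lost effector program) and negatively correlated genes that rise.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._stats import bh_adjust, log_normalize, ranksum_genes

__all__ = [
    "DEFAULT_GENE_SETS",
    "module_score",
    "score_table",
    "score_summaries",
    "select_dysfunction_genes",
]

DEFAULT_GENE_SETS = {
    "exhaustion": ["LAG3", "TIGIT", "PDCD1", "CTLA4", "HAVCR2"],
    "naive": ["CCR7", "TCF7", "LEF1", "SELL"],
    "cytotoxic": [
        "PRF1", "IFNG", "GNLY", "NKG7", "GZMB", "GZMA", "GZMH",
        "KLRK1", "KLRB1", "KLRD1", "CTSW", "CST7",
    ],
}


def module_score(
    adata,
    gene_set,
    n_bins: int = 24,
    n_ctrl: int | None = 100,
    seed: int = 0,
    set_name: str = "gene_set",
    normalize: bool = True,
) -> pd.Series:
    """Per-cell binned-control score of a gene set.

    Genes are placed into `n_bins` equal-frequency bins by their average
    log-normalised expression across cells. For each set gene, `n_ctrl`
    control genes are sampled from its bin (set genes excluded as
    candidates; without replacement when the bin is large enough, else with
    replacement; ``n_ctrl=None`` takes every candidate once). The score is
    mean(set genes) - mean(sampled controls) per cell. Deterministic under
    `seed`. Set genes absent from the matrix are dropped with a warning;
    raises if none remain. With ``normalize=False`` the matrix is used as
    provided (for data that is already log-normalised).
    """
    present = [g for g in gene_set if g in adata.var_names]
    missing = [g for g in gene_set if g not in adata.var_names]
    if not present:
        raise ValueError(f"no genes of set {set_name!r} found in the matrix")
    if missing:
        warnings.warn(f"{set_name}: dropping {len(missing)} absent gene(s)")

    if normalize:
        X = log_normalize(adata.X)
    else:
        X = adata.X
        X = X.toarray() if hasattr(X, "toarray") else np.asarray(X, dtype=float)
    avg = X.mean(axis=0)
    # equal-frequency binning on average expression; gene-name tie-break so
    # the result does not depend on matrix column order
    names = np.asarray(adata.var_names, dtype=object)
    order = np.lexsort((names, avg))
    bins = np.empty(adata.n_vars, dtype=int)
    bins[order] = (np.arange(adata.n_vars) * n_bins) // adata.n_vars

    var_index = pd.Index(adata.var_names)
    set_pos = var_index.get_indexer(sorted(present))
    set_set = set(set_pos.tolist())
    rng = np.random.default_rng(seed)
    ctrl_pos: list[int] = []
    for gpos in set_pos:
        candidates = [c for c in np.flatnonzero(bins == bins[gpos])
                      if c not in set_set]
        candidates = np.array(sorted(candidates, key=lambda c: names[c]))
        if candidates.size == 0:
            continue
        if n_ctrl is None:
            ctrl_pos.extend(candidates.tolist())
        else:
            replace = candidates.size < n_ctrl
            ctrl_pos.extend(rng.choice(candidates, size=n_ctrl, replace=replace).tolist())
    score = X[:, set_pos].mean(axis=1)
    if ctrl_pos:
        score = score - X[:, ctrl_pos].mean(axis=1)
    return pd.Series(score, index=adata.obs_names, name=set_name)


def score_table(adata, gene_sets: dict | None = None, n_bins: int = 24,
                n_ctrl: int | None = 100, seed: int = 0) -> pd.DataFrame:
    """Score every set of `gene_sets` (defaults to the naive / cytotoxic /
    exhaustion programs); returns per-cell scores joined with cluster and
    group labels."""
    gene_sets = gene_sets or DEFAULT_GENE_SETS
    out = pd.DataFrame(index=adata.obs_names)
    for i, (name, genes) in enumerate(gene_sets.items()):
        out[name] = module_score(
            adata, genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + i, set_name=name
        )
    for col in ("cluster", "group", "sample"):
        if col in adata.obs:
            out[col] = adata.obs[col].to_numpy()
    return out


def score_summaries(scores: pd.DataFrame, by="cluster") -> pd.DataFrame:
    """Stratified score summaries.

    For each score column, mean / median / sd / n per stratum and the
    stratum's rank by descending mean (ties keep stable label order).
    """
    by = [by] if isinstance(by, str) else list(by)
    for col in by:
        if col not in scores.columns:
            raise ValueError(f"missing stratification column {col!r}")
    value_cols = [c for c in scores.columns
                  if c not in ("cluster", "group", "sample")]
    rows = []
    for name in value_cols:
        g = scores.groupby(by, observed=True)[name]
        summary = g.agg(["mean", "median", "std", "count"]).reset_index()
        summary = summary.sort_values(
            ["mean", *by], ascending=[False] + [True] * len(by), kind="stable"
        )
        summary.insert(0, "set", name)
        summary["rank"] = summary["mean"].rank(ascending=False, method="min").astype(int)
        rows.append(summary)
    return pd.concat(rows, ignore_index=True)


def select_dysfunction_genes(
    adata,
    cytotoxic_scores,
    group_labels,
    r_min: float = 0.3,
    logfc_min: float = 0.3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Genes tracking the cytotoxic score and shifting between stages.

    `group_labels` marks each scored cell as "nLung" or anything else
    (treated as AIS/IAC). Per gene: Pearson r of log-normalised expression
    with the score across cells (zero-variance genes get r = 0); rank-sum
    test AIS/IAC vs nLung with BH correction; logFC = mean(AIS/IAC) -
    mean(nLung) of log-normalised expression. Selected iff |r| >= r_min and
    |logFC| >= logfc_min and adjusted p < alpha, with directional classes
    `pos_corr_down` (r > 0, falls in AIS/IAC) and `neg_corr_up`.
    """
    s = np.asarray(cytotoxic_scores, dtype=float)
    groups = np.asarray(group_labels)
    is_nlung = groups == "nLung"
    if is_nlung.all() or not is_nlung.any():
        raise ValueError("need both nLung and AIS/IAC cells among scored cells")
    X = log_normalize(adata.X)

    sc = s - s.mean()
    Xc = X - X.mean(axis=0)
    sd_x = X.std(axis=0)
    denom = sd_x * sc.std() * len(s)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Xc.T @ sc / denom, 0.0)

    p = ranksum_genes(X, ~is_nlung, is_nlung)
    adj = bh_adjust(p)
    logfc = X[~is_nlung].mean(axis=0) - X[is_nlung].mean(axis=0)
    selected = (np.abs(r) >= r_min) & (np.abs(logfc) >= logfc_min) & (adj < alpha)
    klass = np.where(
        (r > 0) & (logfc < 0), "pos_corr_down",
        np.where((r < 0) & (logfc > 0), "neg_corr_up", "concordant"),
    )
    return pd.DataFrame(
        {"r": r, "logfc": logfc, "pvalue": p, "adj_p": adj,
         "selected": selected, "class": klass},
        index=adata.var_names,
    )
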