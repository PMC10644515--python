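"""Expression-based CNV inference and malignant-cell classification.

Large-scale copy-number changes leave a footprint in expression averaged
over neighbouring genes along the genome. The profile for each cell is the
clipped log2 relative expression versus the mean of designated reference
(immune/stromal) cells, smoothed with a centred moving average within each
chromosome, then re-centred so the reference population sits at 0.

A cell's CNV score is the Pearson correlation of its profile with the mean
profile of the cells with the largest mean-square CNV (top 5% by default);
cells scoring above 0.3 are called malignant. A random-split differential
expression check verifies that the malignant/normal partition carries real
signal while arbitrary partitions do not.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bh_adjust, log_normalize, percent, ranksum_genes

__all__ = [
    "CNVProfile",
    "CNVScoreResult",
    "infer_cnv_profiles",
    "cnv_score",
    "classify_malignant",
    "validate_split_deg",
]


def _chrom_key(chrom: str):
    c = re.sub("^chr", "", str(chrom))
    if c.isdigit():
        return (int(c), "")
    return ({"X": 23, "Y": 24}.get(c, 25), c)


@dataclass
class CNVProfile:
    """Smoothed relative-expression matrix in genomic gene order."""

    matrix: np.ndarray  # (query + reference cells) x genes, log2 units
    cells: pd.Index
    genes: pd.Index
    chrom: np.ndarray  # per-gene chromosome, aligned with `genes`
    query_cells: list
    reference_cells: list
    window: int

    @property
    def query_matrix(self) -> np.ndarray:
        pos = self.cells.get_indexer(self.query_cells)
        return self.matrix[pos]


@dataclass
class CNVScoreResult:
    scores: pd.DataFrame  # barcode-indexed: ms, cnv_score [, malignant]
    top_fraction: float
    threshold: float | None = None
    summary: dict = field(default_factory=dict)


def _moving_average(block: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average along axis 1 with truncated edge windows."""
    n = block.shape[1]
    half = window // 2
    cs = np.cumsum(block, axis=1)
    cs = np.concatenate([np.zeros((block.shape[0], 1)), cs], axis=1)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (cs[:, hi] - cs[:, lo]) / (hi - lo)


def infer_cnv_profiles(
    adata,
    query_cells,
    reference_cells,
    window: int = 101,
    clip: float = 3.0,
) -> CNVProfile:
    """Infer smoothed CNV profiles for query cells against a reference.

    Pipeline: library-size normalise -> log2 relative expression versus the
    reference-cell mean -> clip to +/-`clip` -> per-chromosome centred
    moving average over `window` genes (truncated at chromosome edges) ->
    subtract the per-gene reference mean so reference profiles centre at 0.
    Genes without genomic positions are dropped (at most 10% may be
    missing). Chromosomes with fewer than 3 genes are passed through
    unsmoothed with a warning.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd gene count")
    query_cells = list(query_cells)
    reference_cells = list(reference_cells)
    if not reference_cells:
        raise ValueError("no reference cells")
    if set(query_cells) & set(reference_cells):
        raise ValueError("query and reference cells must be disjoint")

    var = adata.var
    has_pos = var["chrom"].notna() & var["start"].notna()
    if has_pos.mean() < 0.9:
        raise ValueError("gene positions available for < 90% of genes")
    order = sorted(
        np.flatnonzero(has_pos.to_numpy()),
        key=lambda i: (_chrom_key(var["chrom"].iloc[i]), var["start"].iloc[i]),
    )
    genes = adata.var_names[order]
    chrom = var["chrom"].to_numpy()[order].astype(str)

    cells = pd.Index(query_cells + reference_cells)
    sub = adata[cells, genes]
    # library-size normalised expression (counts per 10k, linear scale)
    norm = np.expm1(log_normalize(sub.X))
    n_ref = len(reference_cells)
    ref_mean = norm[-n_ref:].mean(axis=0)
    rel = np.log2(norm + 1.0) - np.log2(ref_mean + 1.0)
    np.clip(rel, -clip, clip, out=rel)

    smoothed = np.empty_like(rel)
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        if idx.size < 3:
            warnings.warn(
                f"chromosome {c} has {idx.size} genes; passed through unsmoothed"
            )
            smoothed[:, idx] = rel[:, idx]
        else:
            smoothed[:, idx] = _moving_average(rel[:, idx], window)
    smoothed -= smoothed[-n_ref:].mean(axis=0)

    return CNVProfile(
        matrix=smoothed,
        cells=cells,
        genes=pd.Index(genes),
        chrom=chrom,
        query_cells=query_cells,
        reference_cells=reference_cells,
        window=window,
    )


def cnv_score(profile: CNVProfile, top_fraction: float = 0.05) -> CNVScoreResult:
    """Mean-square CNV and CNV score (Pearson r vs the top-MS mean profile).

    Query cells are sorted by the mean square of their CNV values; the
    reference pattern is the per-gene mean over the ceil(top_fraction * n)
    cells with the largest mean square (a cell in the top set is scored
    against a pattern that includes itself). Zero-variance profiles score 0.
    """
    M = profile.query_matrix
    n = M.shape[0]
    need = int(np.ceil(1.0 / top_fraction))
    if n < need:
        raise ValueError(f"need at least {need} query cells for top_fraction={top_fraction}")
    ms = (M**2).mean(axis=1)
    m = int(np.ceil(top_fraction * n))
    top = np.argsort(-ms, kind="stable")[:m]  # MS ties broken by cell order
    R = M[top].mean(axis=0)

    Rc = R - R.mean()
    r_sd = Rc.std()
    Mc = M - M.mean(axis=1, keepdims=True)
    m_sd = Mc.std(axis=1)
    scores = np.zeros(n)
    if r_sd > 0:
        ok = m_sd > 0
        scores[ok] = (Mc[ok] @ Rc) / (M.shape[1] * m_sd[ok] * r_sd)
    if r_sd == 0 or (m_sd == 0).any():
        warnings.warn("zero-variance CNV profile(s); affected scores set to 0")

    df = pd.DataFrame(
        {"ms": ms, "cnv_score": scores}, index=pd.Index(profile.query_cells, name="barcode")
    )
    return CNVScoreResult(scores=df, top_fraction=top_fraction)


def classify_malignant(result: CNVScoreResult, threshold: float = 0.3) -> CNVScoreResult:
    """Call cells malignant at `cnv_score > threshold` (strict).

    Adds a `malignant` column and a summary with n_malignant, n_total and
    the malignant percentage rounded to 1 decimal place.
    """
    df = result.scores.copy()
    df["malignant"] = df["cnv_score"] > threshold
    n_mal = int(df["malignant"].sum())
    n_tot = int(len(df))
    summary = {
        "n_malignant": n_mal,
        "n_total": n_tot,
        "percent": percent(n_mal, n_tot, 1),
    }
    return CNVScoreResult(
        scores=df, top_fraction=result.top_fraction, threshold=threshold, summary=summary
    )


def validate_split_deg(
    adata,
    labels,
    n_random_splits: int = 3,
    logfc_min: float = 0.25,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """DEG counts for the malignant/normal split versus random splits.

    Per gene: Wilcoxon rank-sum on log-normalised expression between the two
    label classes; a DEG has |logFC| >= logfc_min and BH-adjusted p < alpha.
    The same test is repeated for `n_random_splits` random permutations of
    the labels preserving class sizes. Real structure shows up as many DEGs
    for the observed labels and none for the random splits.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.sum() < 3 or (~labels).sum() < 3:
        raise ValueError("each label class needs at least 3 cells")
    X = log_normalize(adata.X)
    rng = np.random.default_rng(seed)

    def count_degs(lab):
        p = ranksum_genes(X, lab, ~lab)
        logfc = X[lab].mean(axis=0) - X[~lab].mean(axis=0)
        adj = bh_adjust(p)
        sig = (np.abs(logfc) >= logfc_min) & (adj < alpha)
        return int(sig.sum()), int((sig & (logfc > 0)).sum()), sig

    rows = []
    n_obs, n_up, obs_sig = count_degs(labels)
    rows.append(("observed", n_obs, n_up, n_obs - n_up))
    for i in range(n_random_splits):
        perm = rng.permutation(labels)
        n, up, _ = count_degs(perm)
        rows.append((f"random_{i + 1}", n, up, n - up))
    out = pd.DataFrame(rows, columns=["split", "n_deg", "n_up", "n_down"])
    out.attrs["observed_deg_mask"] = obs_sig
    return out
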