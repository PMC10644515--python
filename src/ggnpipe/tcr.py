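"""TCR repertoire statistics from single-cell contig tables.

A clonotype is a unique paired TRA-TRB receptor: CDR3 sequence plus V and J
gene of each chain. Only cells with exactly one productive TRA and one
productive TRB contig are retained. On top of the clonotype table the
module computes clonal fractions (share of cells in clones observed >= 2
times), clone-space occupancy over clonotype-rank bins, clonotype overlap
between clusters, V-J gene-pair usage, and the clone-size distribution.

Accepts the 10x `filtered_contig_annotations.csv` dialect or AIRR
rearrangement TSV columns.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._stats import percent, rank_sum_test

__all__ = [
    "assign_clonotypes",
    "clonal_fraction",
    "compare_clonal_fraction",
    "clone_space_occupancy",
    "clonotype_overlap",
    "vj_usage",
    "clone_size_distribution",
]

_AIRR_MAP = {
    "cell_id": "barcode",
    "locus": "chain",
    "v_call": "v_gene",
    "j_call": "j_gene",
    "junction_aa": "cdr3",
    "junction": "cdr3_nt",
}

_TRUTHY = {"true", "t", "1", "yes", "y"}


def _as_bool(col: pd.Series) -> np.ndarray:
    if col.dtype == bool:
        return col.to_numpy()
    return col.astype(str).str.strip().str.lower().isin(_TRUTHY).to_numpy()


def _normalise_contigs(contigs: pd.DataFrame) -> pd.DataFrame:
    df = contigs.rename(columns={k: v for k, v in _AIRR_MAP.items()
                                 if k in contigs.columns and v not in contigs.columns})
    required = {"barcode", "chain", "v_gene", "j_gene", "cdr3", "productive"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"contig table missing columns: {sorted(missing)}")
    return df


def assign_clonotypes(
    contigs: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    require_productive: bool = True,
    require_high_confidence: bool = True,
    clone_scope: str = "global",
):
    """Build the clonotype table from raw contigs.

    Contigs failing the productive / high-confidence flags or carrying a
    chain label other than TRA/TRB are removed (counted in the report); a
    cell is retained iff exactly one TRA and one TRB contig remain. The
    clonotype key concatenates CDR3 (nucleotide sequence when a `cdr3_nt`
    column is present, else amino acid) with V and J gene names of both
    chains. Clone sizes are counted within `clone_scope`: "global" or
    "sample" (per-sample expansion; needs `metadata` with a sample column).

    Returns (table, report): `table` is indexed by barcode with chain
    annotations, clonotype id, clone size and a clonal flag (size >= 2),
    joined with sample/group/cluster labels when `metadata` (indexed by
    barcode or with a barcode column) is given. `report` records retention
    arithmetic: retained / total cells with the percentage to 2 d.p.
    """
    df = _normalise_contigs(contigs)
    n_rows_in = len(df)
    n_cells_in = df["barcode"].nunique()

    chain_ok = df["chain"].isin(["TRA", "TRB"])
    n_bad_chain = int((~chain_ok).sum())
    df = df[chain_ok]
    if require_productive:
        df = df[_as_bool(df["productive"])]
    if require_high_confidence and "high_confidence" in df.columns:
        df = df[_as_bool(df["high_confidence"])]

    cdr3_col = "cdr3_nt" if "cdr3_nt" in df.columns else "cdr3"
    counts = df.groupby(["barcode", "chain"], observed=True).size().unstack(fill_value=0)
    for ch in ("TRA", "TRB"):
        if ch not in counts.columns:
            counts[ch] = 0
    keep = counts.index[(counts["TRA"] == 1) & (counts["TRB"] == 1)]

    sub = df[df["barcode"].isin(keep)]
    tra = sub[sub["chain"] == "TRA"].set_index("barcode")
    trb = sub[sub["chain"] == "TRB"].set_index("barcode")
    table = pd.DataFrame(
        {
            "tra_v": tra["v_gene"], "tra_j": tra["j_gene"],
            "tra_cdr3": tra["cdr3"],
            "trb_v": trb.loc[tra.index, "v_gene"],
            "trb_j": trb.loc[tra.index, "j_gene"],
            "trb_cdr3": trb.loc[tra.index, "cdr3"],
        }
    )
    table["clonotype_id"] = (
        tra[cdr3_col].astype(str) + ":" + tra["v_gene"].astype(str) + ":"
        + tra["j_gene"].astype(str) + "|" + trb.loc[tra.index, cdr3_col].astype(str)
        + ":" + trb.loc[tra.index, "v_gene"].astype(str) + ":"
        + trb.loc[tra.index, "j_gene"].astype(str)
    )
    table.index.name = "barcode"
    table = table.sort_index()

    if metadata is not None:
        meta = metadata if metadata.index.name == "barcode" or "barcode" not in metadata.columns \
            else metadata.set_index("barcode")
        table = table.join(meta[[c for c in ("sample", "group", "cluster")
                                 if c in meta.columns]], how="left")

    if clone_scope == "sample":
        if "sample" not in table.columns:
            raise ValueError("clone_scope='sample' needs metadata with a sample column")
        sizes = table.groupby(["sample", "clonotype_id"], observed=True)["clonotype_id"] \
                     .transform("size")
    elif clone_scope == "global":
        sizes = table.groupby("clonotype_id", observed=True)["clonotype_id"].transform("size")
    else:
        raise ValueError("clone_scope must be 'global' or 'sample'")
    table["clone_size"] = sizes.astype(int)
    table["clonal"] = table["clone_size"] >= 2

    n_retained = len(table)
    report = {
        "n_cells_total": int(n_cells_in),
        "n_contig_rows": int(n_rows_in),
        "n_rejected_chain_rows": n_bad_chain,
        "n_retained": int(n_retained),
        "retention_pct": percent(n_retained, n_cells_in, 2) if n_cells_in else 0.0,
        "n_clonotypes": int(table["clonotype_id"].nunique()),
    }
    return table, report


def clonal_fraction(table: pd.DataFrame, by=("cluster", "group")) -> pd.DataFrame:
    """Fraction of clonal cells (clone size >= 2) per stratum."""
    by = [by] if isinstance(by, str) else list(by)
    g = table.groupby(by, observed=True)["clonal"]
    out = g.agg(n_cells="size", n_clonal="sum").reset_index()
    out["fraction"] = out["n_clonal"] / out["n_cells"]
    return out


def compare_clonal_fraction(table: pd.DataFrame, group_a: str, group_b: str) -> pd.Series:
    """Per-cluster rank-sum p-values on per-sample clonal fractions."""
    per_sample = clonal_fraction(table, by=("cluster", "group", "sample"))
    out = {}
    for cluster, sub in per_sample.groupby("cluster", observed=True):
        a = sub.loc[sub["group"] == group_a, "fraction"].to_numpy()
        b = sub.loc[sub["group"] == group_b, "fraction"].to_numpy()
        if a.size and b.size:
            out[cluster] = rank_sum_test(a, b)
        else:
            out[cluster] = np.nan
    return pd.Series(out, name="pvalue")


def clone_space_occupancy(
    table: pd.DataFrame, cutoffs=(10, 100, 1000, 10000), by: str = "group"
) -> pd.DataFrame:
    """Share of each stratum's cells held by clonotype-rank bins.

    Clonotypes are ranked within the stratum by descending clone size (ties
    by clonotype id); rank bins are delimited by `cutoffs`. Bin value = sum
    of member-clone sizes in the bin divided by the stratum's cell count,
    so each row sums to 1.
    """
    edges = [0, *cutoffs, np.inf]
    labels = [
        f"{int(lo) + 1}-{int(hi)}" if np.isfinite(hi) else f">{int(lo)}"
        for lo, hi in zip(edges[:-1], edges[1:])
    ]
    rows = {}
    for stratum, sub in table.groupby(by, observed=True):
        sizes = (
            sub.groupby("clonotype_id", observed=True).size()
            .rename("size").reset_index()
            .sort_values(["size", "clonotype_id"], ascending=[False, True], kind="stable")
        )
        rank = np.arange(1, len(sizes) + 1)
        which = np.digitize(rank, [c + 0.5 for c in cutoffs])
        total = sizes["size"].sum()
        rows[stratum] = [
            sizes["size"].to_numpy()[which == b].sum() / total for b in range(len(labels))
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=labels)


def clonotype_overlap(
    table: pd.DataFrame, by: str = "cluster", mode: str = "min"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise clonotype-set overlap between strata, in percent.

    mode="min" (overlap coefficient, 100*|A&B|/min(|A|,|B|)) or
    mode="jaccard" (100*|A&B|/|A|B|union). Returns (percent matrix with
    diagonal 100, shared-count matrix). Strata with zero clonotypes get
    overlap 0 with a warning.
    """
    if mode not in ("min", "jaccard"):
        raise ValueError("mode must be 'min' or 'jaccard'")
    sets = {s: set(sub["clonotype_id"]) for s, sub in table.groupby(by, observed=True)}
    strata = sorted(sets)
    if any(len(v) == 0 for v in sets.values()):
        warnings.warn("stratum with zero clonotypes; overlap set to 0")
    pct = pd.DataFrame(0.0, index=strata, columns=strata)
    shared = pd.DataFrame(0, index=strata, columns=strata)
    for i, a in enumerate(strata):
        for b in strata[i:]:
            inter = len(sets[a] & sets[b])
            if a == b:
                val = 100.0 if sets[a] else 0.0
            else:
                denom = (min(len(sets[a]), len(sets[b])) if mode == "min"
                         else len(sets[a] | sets[b]))
                val = 100.0 * inter / denom if denom else 0.0
            pct.loc[a, b] = pct.loc[b, a] = val
            shared.loc[a, b] = shared.loc[b, a] = inter
    return pct, shared


def vj_usage(table: pd.DataFrame, chain: str = "TRB", by: str = "group") -> pd.DataFrame:
    """Cell-weighted V-J gene-pair usage frequencies per stratum.

    Returns a long DataFrame (stratum, v_gene, j_gene, n_cells, frequency);
    frequencies sum to 1 within each stratum.
    """
    if chain not in ("TRA", "TRB"):
        raise ValueError("chain must be 'TRA' or 'TRB'")
    v, j = (f"{chain.lower()}_v", f"{chain.lower()}_j")
    counts = (
        table.groupby([by, v, j], observed=True).size().rename("n_cells").reset_index()
    )
    counts["frequency"] = counts.groupby(by, observed=True)["n_cells"].transform(
        lambda s: s / s.sum()
    )
    return counts.rename(columns={v: "v_gene", j: "j_gene"})


def clone_size_distribution(table: pd.DataFrame, by: str = "group") -> pd.DataFrame:
    """Number of clonotypes at each observed clone size, per stratum."""
    per_clone = (
        table.groupby([by, "clonotype_id"], observed=True).size().rename("clone_size")
    )
    out = (
        per_clone.reset_index()
        .groupby([by, "clone_size"], observed=True).size()
        .rename("n_clonotypes").reset_index()
    )
    return out
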