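"""Stage-associated co-expression modules on metacells (WGCNA core).

The trajectory from normal lung through adenocarcinoma in situ (AIS) to
invasive adenocarcinoma (IAC) is treated as an ordinal stage 0/1/2. Genes
whose expression tracks stage are selected with a random-intercept linear
mixed model (cells nested in samples), cells are aggregated into per-stage
metacells to de-noise correlations, and the metacell expression of the
stage-associated genes is organised into co-expression modules via the
classic weighted-network pipeline: soft-thresholded adjacency, topological
overlap, average-linkage clustering with a static cut, module eigengenes
and kME connectivity. Each module's eigengene trajectory across the three
stages is classified as ascending-linear, ascending-step, biphasic,
descending or flat.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from ._stats import bh_adjust, log_normalize, stage_lrt

__all__ = [
    "STAGE_ORDER",
    "MetacellMatrix",
    "ModuleAssignment",
    "stage_association_filter",
    "build_metacells",
    "pick_soft_threshold",
    "tom_similarity",
    "detect_modules",
    "module_trajectories",
    "classify_trajectory",
    "hub_genes",
]

STAGE_ORDER = ("nLung", "AIS", "IAC")

# classic WGCNA module colour order, assigned to modules by decreasing size
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
]


# ---------------------------------------------------------------------------
# stage-associated gene filter
# ---------------------------------------------------------------------------

def stage_association_filter(adata, fdr_max: float = 0.001) -> pd.DataFrame:
    """Per-gene mixed-model test for an ordinal stage effect.

    Fits log-normalised expression ~ stage (fixed, ordinal 0/1/2) with a
    random intercept per sample, tests the stage term with a likelihood
    ratio against the stage-free null, and applies Benjamini-Hochberg
    correction across genes. Returns a DataFrame indexed by gene with
    `coef`, `pvalue`, `fdr`, `ok` and `pass` (fdr < fdr_max) columns.
    Degenerate genes (zero variance, failed fits) get p = 1 with ok=False.
    """
    groups_present = [g for g in STAGE_ORDER if (adata.obs["group"] == g).any()]
    if len(groups_present) < 2:
        raise ValueError("need at least 2 stages present")
    if adata.obs["sample"].nunique() < 2:
        raise ValueError("need at least 2 samples")
    stage = adata.obs["group"].map(dict(zip(STAGE_ORDER, range(3)))).to_numpy(float)
    sample = adata.obs["sample"].to_numpy()
    X = log_normalize(adata.X)
    coefs = np.zeros(adata.n_vars)
    pvals = np.ones(adata.n_vars)
    ok = np.zeros(adata.n_vars, dtype=bool)
    for g in range(adata.n_vars):
        coefs[g], pvals[g], ok[g] = stage_lrt(X[:, g], stage, sample)
    fdr = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "coef": coefs,
            "pvalue": pvals,
            "fdr": fdr,
            "ok": ok,
            "pass": fdr < fdr_max,
        },
        index=adata.var_names,
    )


# ---------------------------------------------------------------------------
# metacells
# ---------------------------------------------------------------------------

@dataclass
class MetacellMatrix:
    expr: pd.DataFrame  # metacell x gene mean log-normalised expression
    stage: pd.Series  # metacell -> group label
    sizes: pd.Series  # metacell -> member-cell count
    members: dict = field(default_factory=dict)  # metacell -> barcodes


def build_metacells(adata, k: int = 10, k_min: int = 5, n_pcs: int = 20) -> MetacellMatrix:
    """Aggregate transcriptionally neighbouring cells into metacells,
    independently within each stage.

    Within a stage: PCA on log-normalised expression, then greedy
    aggregation — repeatedly seed at the lowest-index unused cell and pool
    it with its k-1 nearest unused neighbours in PC space. A final
    remainder of >= k_min cells forms one smaller metacell; smaller
    remainders are discarded. A stage with fewer than k cells yields no
    metacells (warning). Metacell expression is the member mean of
    log-normalised expression.
    """
    rows, stages, sizes, members = [], [], [], {}
    X_all = log_normalize(adata.X)
    obs_stage = adata.obs["group"].to_numpy()
    barcodes = np.asarray(adata.obs_names)
    for group in [g for g in STAGE_ORDER if (obs_stage == g).any()]:
        idx = np.flatnonzero(obs_stage == group)
        n = idx.size
        if n < k:
            warnings.warn(f"stage {group} has {n} < k cells; zero metacells")
            continue
        Xs = X_all[idx]
        n_comp = min(n_pcs, n - 1, Xs.shape[1])
        pcs = PCA(n_components=n_comp, svd_solver="full", random_state=0).fit_transform(Xs)
        order = (
            NearestNeighbors(n_neighbors=n - 1).fit(pcs)
            .kneighbors(return_distance=False)
        )
        # self is not included by kneighbors; prepend it
        order = np.concatenate([np.arange(n)[:, None], order], axis=1)
        used = np.zeros(n, dtype=bool)
        groups_members = []
        while (~used).sum() >= k:
            seed = int(np.flatnonzero(~used)[0])
            ranked = order[seed][~used[order[seed]]]
            chosen = ranked[:k]
            used[chosen] = True
            groups_members.append(chosen)
        rest = np.flatnonzero(~used)
        if rest.size >= k_min:
            groups_members.append(rest)
        for j, mem in enumerate(groups_members):
            mc_id = f"{group}_mc{j + 1}"
            rows.append(Xs[mem].mean(axis=0))
            stages.append(group)
            sizes.append(mem.size)
            members[mc_id] = [str(b) for b in barcodes[idx[mem]]]
    if not rows:
        raise ValueError("no metacells could be built")
    index = pd.Index(list(members), name="metacell")
    expr = pd.DataFrame(np.vstack(rows), index=index, columns=adata.var_names)
    return MetacellMatrix(
        expr=expr,
        stage=pd.Series(stages, index=index, name="stage"),
        sizes=pd.Series(sizes, index=index, name="n_cells"),
        members=members,
    )


# ---------------------------------------------------------------------------
# soft threshold and topological overlap
# ---------------------------------------------------------------------------

def _adjacency(corr: np.ndarray, beta: float, signed_hybrid: bool) -> np.ndarray:
    if signed_hybrid:
        a = np.where(corr > 0, corr, 0.0) ** beta
    else:
        a = np.abs(corr) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def _scale_free_fit(connectivity: np.ndarray, n_bins: int = 10):
    """Signed R^2 of log10 p(k) vs log10 k over equal-width k bins."""
    k = connectivity
    if np.ptp(k) == 0:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(k[mask].mean())
        ys.append(mask.mean())
    xs, ys = np.asarray(xs), np.asarray(ys)
    keep = (xs > 0) & (ys > 0)
    if keep.sum() < 3:
        return 0.0, 0.0
    res = stats.linregress(np.log10(xs[keep]), np.log10(ys[keep]))
    return float(-np.sign(res.slope) * res.rvalue**2), float(res.slope)


def pick_soft_threshold(
    metacells: MetacellMatrix,
    candidate_powers=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    r2_min: float = 0.8,
    signed_hybrid: bool = False,
):
    """Choose the soft-threshold power for scale-free topology.

    Returns (beta, diagnostics DataFrame with power / signed R^2 / slope /
    mean connectivity). Beta is the smallest candidate whose signed
    scale-free fit R^2 reaches `r2_min`, else the candidate maximising it.
    """
    expr = metacells.expr.loc[:, metacells.expr.std(axis=0) > 0]
    if metacells.expr.shape[0] < 30:
        warnings.warn("fewer than 30 metacells; soft-threshold fit is unstable")
    corr = np.corrcoef(expr.to_numpy().T)
    rows = []
    for power in candidate_powers:
        a = _adjacency(corr, power, signed_hybrid)
        k = a.sum(axis=1)
        r2, slope = _scale_free_fit(k)
        rows.append((power, r2, slope, k.mean()))
    table = pd.DataFrame(rows, columns=["power", "r2", "slope", "mean_k"])
    hits = table.loc[table["r2"] >= r2_min, "power"]
    beta = int(hits.iloc[0]) if len(hits) else int(table.loc[table["r2"].idxmax(), "power"])
    return beta, table


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with
    TOM_ii = 1; `adjacency` must have a zero diagonal.
    """
    a = adjacency
    k = a.sum(axis=1)
    num = a @ a + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = num / denom
    np.fill_diagonal(tom, 1.0)
    return tom


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------

@dataclass
class ModuleAssignment:
    modules: pd.Series  # gene -> module colour ("grey" = unassigned)
    power: float
    eigengenes: pd.DataFrame  # metacell x module, unit-norm columns
    kme: pd.DataFrame  # gene x module correlation with each eigengene
    own_kme: pd.Series  # gene -> kME with its own module's eigengene

    def module_sizes(self) -> pd.Series:
        return self.modules.value_counts()


def _eigengene(sub: np.ndarray) -> np.ndarray:
    """First principal component (unit norm over metacells) of a
    gene-standardised submatrix; sign fixed so mean gene loading > 0."""
    Z = (sub - sub.mean(axis=0)) / np.where(sub.std(axis=0) > 0, sub.std(axis=0), 1.0)
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    e = U[:, 0]
    if np.corrcoef(np.c_[e, Z].T)[0, 1:].mean() < 0:
        e = -e
    return e


def detect_modules(
    metacells: MetacellMatrix,
    beta: float,
    min_module_size: int = 30,
    merge_height: float = 0.25,
    cut_height: float = 0.99,
    signed_hybrid: bool = False,
) -> ModuleAssignment:
    """Cluster genes into co-expression modules from metacell expression.

    Average-linkage hierarchical clustering of 1 - TOM with a static cut at
    `cut_height`; candidate clusters below `min_module_size` go to grey;
    module eigengenes whose correlation exceeds 1 - merge_height are
    merged. Modules are named with the classic colour palette in
    decreasing-size order; constant genes are assigned grey.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    expr = metacells.expr
    variable = expr.columns[expr.std(axis=0).to_numpy() > 0]
    labels = pd.Series("grey", index=expr.columns, name="module")
    if len(variable) < min_module_size:
        return _finalise(labels, expr, beta)
    E = expr[variable].to_numpy()
    corr = np.corrcoef(E.T)
    a = _adjacency(corr, beta, signed_hybrid)
    tom = tom_similarity(a)
    dist = np.maximum(1.0 - tom, 0.0)  # guard fp overshoot at TOM ~ 1
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    Z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")

    ids, counts = np.unique(raw, return_counts=True)
    keep = ids[counts >= min_module_size]
    order = keep[np.argsort(-counts[counts >= min_module_size], kind="stable")]
    for rank, cid in enumerate(order):
        colour = MODULE_COLORS[rank % len(MODULE_COLORS)]
        labels.loc[variable[raw == cid]] = colour

    labels = _merge_close_modules(labels, expr, merge_height)
    return _finalise(labels, expr, beta)


def _module_eigengenes(labels: pd.Series, expr: pd.DataFrame) -> pd.DataFrame:
    cols = {}
    for colour in [c for c in labels.unique() if c != "grey"]:
        genes = labels.index[labels == colour]
        cols[colour] = _eigengene(expr[genes].to_numpy())
    return pd.DataFrame(cols, index=expr.index)


def _merge_close_modules(labels: pd.Series, expr: pd.DataFrame, merge_height: float):
    while True:
        colours = [c for c in labels.unique() if c != "grey"]
        if len(colours) < 2:
            break
        eig = _module_eigengenes(labels, expr)
        C = eig.corr().to_numpy()
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if C[i, j] <= 1.0 - merge_height:
            break
        a, b = eig.columns[i], eig.columns[j]
        big, small = (a, b) if (labels == a).sum() >= (labels == b).sum() else (b, a)
        labels = labels.replace(small, big)
    # re-rank colour names by size so naming stays canonical after merges
    sizes = labels[labels != "grey"].value_counts()
    rename = {c: MODULE_COLORS[r % len(MODULE_COLORS)] for r, c in enumerate(sizes.index)}
    return labels.map(lambda c: rename.get(c, "grey"))


def _finalise(labels: pd.Series, expr: pd.DataFrame, beta: float) -> ModuleAssignment:
    eig = _module_eigengenes(labels, expr)
    E = expr.to_numpy()
    Ec = E - E.mean(axis=0)
    sd = E.std(axis=0)
    kme = {}
    for colour in eig.columns:
        e = eig[colour].to_numpy()
        ec = e - e.mean()
        denom = sd * ec.std() * len(e)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, Ec.T @ ec / denom, 0.0)
        kme[colour] = r
    kme = pd.DataFrame(kme, index=expr.columns)
    own = pd.Series(0.0, index=expr.columns, name="kME")
    for colour in eig.columns:
        genes = labels.index[labels == colour]
        own.loc[genes] = kme.loc[genes, colour]
    return ModuleAssignment(modules=labels, power=beta, eigengenes=eig, kme=kme, own_kme=own)


# ---------------------------------------------------------------------------
# trajectory classification and hubs
# ---------------------------------------------------------------------------

def classify_trajectory(stage_means, delta: float, noise_gate: float = 0.0) -> str:
    """Classify a (nLung, AIS, IAC) mean triple into a trajectory class."""
    if any(m is None or (isinstance(m, float) and np.isnan(m)) for m in stage_means):
        return "undetermined"
    m0, m1, m2 = stage_means
    spread = max(stage_means) - min(stage_means)
    if spread <= noise_gate:
        return "flat"
    if m0 >= m1 >= m2 and (m0 - m2) > delta:
        return "descending"
    if m1 > max(m0, m2) + delta:
        return "biphasic"
    if m1 > m0 + delta and m2 > m0 + delta and abs(m2 - m1) <= delta:
        return "ascending-step"
    if m0 < m1 < m2:
        return "ascending-linear"
    return "flat"


def module_trajectories(
    assignment: ModuleAssignment,
    metacells: MetacellMatrix,
    delta_fraction: float = 0.25,
) -> pd.DataFrame:
    """Per-module stage means of the eigengene and trajectory class.

    delta = delta_fraction * (max stage mean - min stage mean) per module;
    a module whose stage spread is within noise (2x the largest per-stage
    standard error) is called flat; a module missing a stage is
    undetermined.
    """
    stage = metacells.stage
    rows = []
    for colour in assignment.eigengenes.columns:
        e = assignment.eigengenes[colour]
        means, sems = [], []
        for g in STAGE_ORDER:
            vals = e[stage == g]
            if len(vals) == 0:
                means.append(np.nan)
                sems.append(np.nan)
            else:
                means.append(float(vals.mean()))
                sems.append(float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0)
        if any(np.isnan(means)):
            klass = "undetermined"
        else:
            spread = max(means) - min(means)
            klass = classify_trajectory(
                means, delta=delta_fraction * spread, noise_gate=2.0 * np.nanmax(sems)
            )
        rows.append((colour, *means, klass))
    return pd.DataFrame(
        rows, columns=["module", *[f"mean_{g}" for g in STAGE_ORDER], "trajectory"]
    ).set_index("module")


def hub_genes(assignment: ModuleAssignment, n: int = 25) -> dict:
    """Top-n genes per module by own-module kME (ties broken by gene id)."""
    out = {}
    for colour in assignment.eigengenes.columns:
        genes = assignment.modules.index[assignment.modules == colour]
        # round so numerically tied kME values fall back to gene-id order
        ranked = sorted(genes, key=lambda g: (-round(assignment.own_kme[g], 10), g))
        out[colour] = ranked[:n]
    return out
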