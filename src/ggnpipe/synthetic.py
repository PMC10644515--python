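"""Synthetic GGN-LUAD cohort generator.

Emulates a multi-sample single-cell RNA + TCR cohort with three disease
stages (nLung -> AIS -> IAC), a malignant epithelial subpopulation carrying
chromosome-scale expression shifts, planted stage-trajectory co-expression
modules, three T-cell functional programs (naive / cytotoxic / exhaustion),
and clonally expanded TCR repertoires — together with the ground truth every
downstream stage is benchmarked against.

Counts are negative binomial (gamma-Poisson) around per-gene baselines;
all planted structure acts multiplicatively on the NB mean (log2 scale):

* CNV segments multiply segment-gene means by 2**shift in malignant cells;
* module genes follow a per-stage mean trajectory plus one shared latent
  Gaussian factor per module per cell (the co-expression WGCNA recovers);
* program genes are elevated in their designated T-cell cluster.

Everything is deterministic under a fixed seed.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ConfigError",
    "TRAJECTORY_LEVELS",
    "GROUPS",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
    "truncated_geometric_pmf",
    "expected_clonal_fraction",
]

GROUPS = ("nLung", "AIS", "IAC")
STAGE_OF_GROUP = {"nLung": 0, "AIS": 1, "IAC": 2}

# per-stage mean levels (nLung, AIS, IAC), scaled by the module effect size
TRAJECTORY_LEVELS = {
    "ascending-linear": (0.0, 0.5, 1.0),
    "ascending-step": (0.0, 1.0, 1.0),
    "biphasic": (0.0, 1.0, 0.25),
    "descending": (1.0, 0.5, 0.0),
    "flat": (0.0, 0.0, 0.0),
}

T_CLUSTERS = ("T_naive", "T_cytotoxic", "T_exhausted")

_AA = "ACDEFGHIKLMNPQRSTVWY"


class ConfigError(ValueError):
    """Invalid simulation configuration (overlapping gene roles etc.)."""


@dataclass
class SimConfig:
    """Cohort layout and effect sizes for :func:`simulate_dataset`.

    Defaults emulate the study cohort: 5 normal-lung, 3 AIS and 4 IAC
    samples; modest per-sample cell numbers keep the default simulation
    quick while leaving every planted effect detectable.
    """

    n_samples_per_group: dict = field(
        default_factory=lambda: {"nLung": 5, "AIS": 3, "IAC": 4}
    )
    n_cells_per_sample: int = 300
    n_genes: int = 2000
    n_chromosomes: int = 10
    n_mito_genes: int = 10
    # (chromosome, start gene index, end gene index, log2 shift); half-open
    # global gene indices that must fall inside the chromosome's gene range.
    # None plants one +1 log2 segment covering most of chromosome 1
    cnv_segments: list | None = None
    malignant_fraction: float = 0.4
    # (size, trajectory class, log2 effect per unit trajectory level)
    module_specs: list = field(
        default_factory=lambda: [
            (120, "ascending-linear", 1.5),
            (80, "ascending-step", 1.5),
            (60, "biphasic", 1.5),
            (50, "descending", 1.5),
            (40, "flat", 1.5),
        ]
    )
    module_factor_sd: float = 1.2
    module_hub_loading: float = 2.0
    # planted-role genes are drawn at expressed-gene abundance so the
    # within-module correlation the latent factor induces (~0.6) survives
    # count noise, as for real stage-filtered genes
    module_baseline_mean: float = 3.0
    program_baseline_mean: float = 2.0
    program_sizes: dict = field(
        default_factory=lambda: {"naive": 10, "cytotoxic": 12, "exhaustion": 8}
    )
    program_effect: float = 1.5
    # per-cell spread of program activity within the designated cluster
    program_activity_sd: float = 0.8
    # stage-linked log2 shift of a program inside its cluster (AIS/IAC vs
    # nLung); cytotoxicity falls with disease progression
    program_stage_log2fc: dict = field(default_factory=lambda: {"cytotoxic": -1.0})
    cluster_fractions: dict = field(
        default_factory=lambda: {
            "Epithelial": 0.30,
            "Immune": 0.25,
            "Stromal": 0.10,
            "T_naive": 0.15,
            "T_cytotoxic": 0.12,
            "T_exhausted": 0.08,
        }
    )
    # per-T-cluster truncated-geometric clone-size law: (stop prob, cap)
    clone_size_distribution: dict = field(
        default_factory=lambda: {
            "T_naive": (0.90, 20),
            "T_cytotoxic": (0.45, 50),
            "T_exhausted": (0.65, 50),
        }
    )
    baseline_mean: float = 0.5
    baseline_sigma: float = 1.0
    dispersion: float = 10.0
    seed: int = 0


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort."""

    malignant_cells: list
    cnv_segment_genes: list
    module_genes: dict  # module name -> gene names
    module_classes: dict  # module name -> trajectory class
    hub_genes: dict  # module name -> hub gene name
    program_genes: dict  # program -> gene names
    program_cluster: dict  # program -> cluster it is elevated in
    program_activity: dict  # program -> {barcode: true log2 activity}
    clonotype_of: dict  # barcode -> clonotype key
    expected_clonal_fraction: dict  # cluster -> analytic P(cell is clonal)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# clone-size law
# ---------------------------------------------------------------------------

def truncated_geometric_pmf(p: float, cap: int) -> np.ndarray:
    """pmf over clone sizes 1..cap of a geometric(p) truncated at cap."""
    if not (0 < p <= 1) or cap < 1:
        raise ConfigError("clone-size law needs 0 < p <= 1 and cap >= 1")
    s = np.arange(1, cap + 1)
    pmf = p * (1 - p) ** (s - 1)
    return pmf / pmf.sum()


def expected_clonal_fraction(p: float, cap: int) -> float:
    """Analytic fraction of cells belonging to clones of size >= 2."""
    pmf = truncated_geometric_pmf(p, cap)
    s = np.arange(1, cap + 1)
    return float((s[1:] * pmf[1:]).sum() / (s * pmf).sum())


# ---------------------------------------------------------------------------
# layout helpers
# ---------------------------------------------------------------------------

def _gene_positions(cfg: SimConfig) -> pd.DataFrame:
    n = cfg.n_genes
    per = n // cfg.n_chromosomes
    chroms = np.array(
        [str(min(i // per, cfg.n_chromosomes - 1) + 1) for i in range(n)]
    )
    rank = np.zeros(n, dtype=int)
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        rank[idx] = np.arange(idx.size)
    start = rank * 10_000
    return pd.DataFrame({"chrom": chroms, "start": start, "end": start + 1_000})


def _assign_roles(cfg: SimConfig) -> dict:
    """Deterministic, disjoint gene-role layout; raises on overlap."""
    n = cfg.n_genes
    mito = list(range(n - cfg.n_mito_genes, n))
    used: set[int] = set(mito)

    def take(block: list[int], what: str):
        if min(block) < 0 or max(block) >= n:
            raise ConfigError(f"{what} gene indices outside [0, n_genes)")
        if used & set(block):
            raise ConfigError(f"overlapping gene-role assignment for {what}")
        used.update(block)

    seg_genes: list[int] = []
    positions = _gene_positions(cfg)
    for chrom, lo, hi, _shift in cfg.cnv_segments:
        if hi <= lo:
            raise ConfigError("empty CNV segment")
        block = list(range(lo, hi))
        on_chrom = positions["chrom"].iloc[lo:hi] == str(chrom)
        if not bool(on_chrom.all()):
            raise ConfigError("CNV segment outside its chromosome's gene range")
        take(block, f"CNV segment {chrom}:{lo}-{hi}")
        seg_genes.extend(block)

    cursor = 0

    def next_block(size: int) -> list[int]:
        nonlocal cursor
        block: list[int] = []
        while len(block) < size:
            if cursor >= n:
                raise ConfigError("not enough genes for the requested roles")
            if cursor not in used:
                block.append(cursor)
            cursor += 1
        return block

    modules = {}
    for i, (size, klass, effect) in enumerate(cfg.module_specs):
        if klass not in TRAJECTORY_LEVELS:
            raise ConfigError(f"unknown trajectory class {klass!r}")
        block = next_block(size)
        take(block, f"module {i}")
        modules[f"M{i + 1}"] = (block, klass, float(effect))

    programs = {}
    for name, size in cfg.program_sizes.items():
        block = next_block(size)
        take(block, f"program {name}")
        programs[name] = block

    return {"mito": mito, "cnv": seg_genes, "modules": modules, "programs": programs}


# ---------------------------------------------------------------------------
# main simulation
# ---------------------------------------------------------------------------

def _validate(cfg: SimConfig):
    if not 0.0 <= cfg.malignant_fraction <= 1.0:
        raise ConfigError("malignant_fraction must lie in [0, 1]")
    if set(cfg.n_samples_per_group) != set(GROUPS):
        raise ConfigError(f"n_samples_per_group must have keys {GROUPS}")
    for cl, (p, cap) in cfg.clone_size_distribution.items():
        truncated_geometric_pmf(p, cap)  # validates parameters
    if abs(sum(cfg.cluster_fractions.values()) - 1.0) > 1e-6:
        raise ConfigError("cluster_fractions must sum to 1")


def simulate_dataset(cfg: SimConfig):
    """Generate (expression AnnData, TCR contig table, GroundTruth).

    The AnnData holds raw counts (cells x genes, sparse) with per-cell
    ``sample``/``group``/``cluster`` labels and per-gene genomic positions
    in ``.var``.
    """
    if cfg.cnv_segments is None:
        per_chrom = cfg.n_genes // cfg.n_chromosomes
        cfg = dataclasses.replace(
            cfg, cnv_segments=[("1", 0, min(150, int(per_chrom * 0.75)), 1.0)]
        )
    _validate(cfg)
    rng = np.random.default_rng(cfg.seed)
    roles = _assign_roles(cfg)
    positions = _gene_positions(cfg)

    gene_names = np.array([f"GENE{i:04d}" for i in range(cfg.n_genes)], dtype=object)
    for j, gi in enumerate(roles["mito"]):
        gene_names[gi] = f"MT-G{j + 1}"

    baseline = rng.lognormal(
        mean=np.log(cfg.baseline_mean) - cfg.baseline_sigma**2 / 2,
        sigma=cfg.baseline_sigma,
        size=cfg.n_genes,
    )
    for name, (genes, _k, _e) in roles["modules"].items():
        baseline[genes] = rng.lognormal(
            mean=np.log(cfg.module_baseline_mean) - cfg.baseline_sigma**2 / 2,
            sigma=cfg.baseline_sigma, size=len(genes),
        )
    for prog, genes in roles["programs"].items():
        # curated marker panels are reliably expressed: tighter spread
        baseline[genes] = rng.lognormal(
            mean=np.log(cfg.program_baseline_mean) - 0.5**2 / 2,
            sigma=0.5, size=len(genes),
        )
    # mitochondrial transcripts are high-abundance; target ~8-10% of counts
    nonmito = np.setdiff1d(np.arange(cfg.n_genes), roles["mito"])
    baseline[roles["mito"]] = 0.1 * baseline[nonmito].sum() / max(cfg.n_mito_genes, 1)

    # ---- cell sheet -------------------------------------------------------
    clusters = list(cfg.cluster_fractions)
    sizes = np.array([cfg.cluster_fractions[c] for c in clusters])
    per_cluster = np.floor(sizes * cfg.n_cells_per_sample).astype(int)
    per_cluster[0] += cfg.n_cells_per_sample - per_cluster.sum()

    rows = []
    for group in GROUPS:
        for s in range(cfg.n_samples_per_group[group]):
            sample = f"{group}_{s + 1}"
            for cl, k in zip(clusters, per_cluster):
                for i in range(k):
                    rows.append((sample, group, cl))
    obs = pd.DataFrame(rows, columns=["sample", "group", "cluster"])
    obs.index = [
        f"{r.sample}_CELL{i:05d}" for i, r in enumerate(obs.itertuples())
    ]
    n_cells = len(obs)
    stage = obs["group"].map(STAGE_OF_GROUP).to_numpy()

    # ---- malignant subpopulation -----------------------------------------
    malignant = np.zeros(n_cells, dtype=bool)
    for sample in obs["sample"].unique():
        sel = np.flatnonzero(
            (obs["sample"] == sample).to_numpy()
            & (obs["cluster"] == "Epithelial").to_numpy()
            & (obs["group"] != "nLung").to_numpy()
        )
        k = int(round(cfg.malignant_fraction * sel.size))
        malignant[rng.choice(sel, size=k, replace=False)] = True

    # ---- log2 effect matrix ----------------------------------------------
    log2fx = np.zeros((n_cells, cfg.n_genes), dtype=np.float32)
    for chrom, lo, hi, shift in cfg.cnv_segments:
        log2fx[np.ix_(malignant, np.arange(lo, hi))] += shift

    epithelial = (obs["cluster"] == "Epithelial").to_numpy()
    for name, (genes, klass, effect) in roles["modules"].items():
        levels = np.array(TRAJECTORY_LEVELS[klass])
        loading = np.ones(len(genes), dtype=np.float32)
        loading[0] = cfg.module_hub_loading  # first gene is the planted hub
        cell_val = np.zeros(n_cells, dtype=np.float32)
        cell_val[epithelial] = effect * levels[stage[epithelial]]
        cell_val[epithelial] += rng.normal(
            0.0, cfg.module_factor_sd, size=int(epithelial.sum())
        )
        log2fx[:, genes] += np.outer(cell_val, loading)

    program_cluster = {"naive": "T_naive", "cytotoxic": "T_cytotoxic",
                       "exhaustion": "T_exhausted"}
    program_activity: dict[str, dict[str, float]] = {}
    for prog, genes in roles["programs"].items():
        in_cluster = (obs["cluster"] == program_cluster[prog]).to_numpy()
        activity = np.zeros(n_cells, dtype=np.float32)
        activity[in_cluster] = cfg.program_effect + rng.normal(
            0.0, cfg.program_activity_sd, size=int(in_cluster.sum())
        )
        shift = cfg.program_stage_log2fc.get(prog, 0.0)
        if shift:
            activity[in_cluster & (stage > 0)] += shift
        log2fx[:, genes] += activity[:, None]
        program_activity[prog] = {
            str(b): float(a)
            for b, a in zip(obs.index[in_cluster], activity[in_cluster])
        }

    # ---- counts -----------------------------------------------------------
    mu = baseline[None, :] * np.exp2(log2fx)
    lam = rng.gamma(shape=cfg.dispersion, scale=mu / cfg.dispersion)
    counts = rng.poisson(lam).astype(np.int32)
    X = sparse.csr_matrix(counts)

    var = positions.copy()
    var.index = gene_names
    adata = ad.AnnData(X=X, obs=obs, var=var)

    # ---- TCR contigs ------------------------------------------------------
    contig_rows = []
    clonotype_of: dict[str, str] = {}
    barcodes = np.asarray(adata.obs_names)
    for sample in obs["sample"].unique():
        for cl in T_CLUSTERS:
            cells = barcodes[
                (obs["sample"] == sample).to_numpy()
                & (obs["cluster"] == cl).to_numpy()
            ]
            p, cap = cfg.clone_size_distribution[cl]
            pmf = truncated_geometric_pmf(p, cap)
            pos = 0
            clone_idx = 0
            while pos < cells.size:
                size = int(rng.choice(np.arange(1, cap + 1), p=pmf))
                size = min(size, cells.size - pos)
                clone_idx += 1
                tra_v = f"TRAV{rng.integers(1, 21)}"
                tra_j = f"TRAJ{rng.integers(1, 21)}"
                trb_v = f"TRBV{rng.integers(1, 21)}"
                trb_j = f"TRBJ{rng.integers(1, 3)}-{rng.integers(1, 8)}"
                tra_cdr3 = "C" + "".join(rng.choice(list(_AA), size=10)) + "F"
                trb_cdr3 = "C" + "".join(rng.choice(list(_AA), size=12)) + "F"
                key = f"{tra_cdr3}:{tra_v}:{tra_j}|{trb_cdr3}:{trb_v}:{trb_j}"
                for bc in cells[pos : pos + size]:
                    clonotype_of[str(bc)] = key
                    contig_rows.append(
                        (bc, "TRA", tra_v, tra_j, tra_cdr3, True, True)
                    )
                    contig_rows.append(
                        (bc, "TRB", trb_v, trb_j, trb_cdr3, True, True)
                    )
                pos += size
    contigs = pd.DataFrame(
        contig_rows,
        columns=[
            "barcode", "chain", "v_gene", "j_gene", "cdr3",
            "productive", "high_confidence",
        ],
    )

    gt = GroundTruth(
        malignant_cells=[str(b) for b in barcodes[malignant]],
        cnv_segment_genes=[str(g) for g in gene_names[roles["cnv"]]],
        module_genes={
            m: [str(g) for g in gene_names[genes]]
            for m, (genes, _k, _e) in roles["modules"].items()
        },
        module_classes={m: k for m, (_g, k, _e) in roles["modules"].items()},
        hub_genes={
            m: str(gene_names[genes[0]])
            for m, (genes, _k, _e) in roles["modules"].items()
        },
        program_genes={
            p: [str(g) for g in gene_names[genes]]
            for p, genes in roles["programs"].items()
        },
        program_cluster=program_cluster,
        program_activity=program_activity,
        clonotype_of=clonotype_of,
        expected_clonal_fraction={
            cl: expected_clonal_fraction(*cfg.clone_size_distribution[cl])
            for cl in T_CLUSTERS
        },
    )
    return adata, contigs, gt


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

def write_dataset(adata, contigs, ground_truth, out_dir):
    """Write the cohort as plain-text files.

    MTX counts follow the 10x genes-x-cells convention with barcode and
    feature TSVs; per-cell metadata is a TSV; gene positions a BED4
    (0-based half-open); TCR contigs the 10x filtered_contig_annotations
    CSV dialect; program gene sets and ground truth JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(out / "matrix.mtx", sparse.csr_matrix(adata.X).T.astype(int))
    pd.Series(adata.obs_names).to_csv(out / "barcodes.tsv", index=False, header=False)
    pd.DataFrame(
        {"id": adata.var_names, "name": adata.var_names, "type": "Gene Expression"}
    ).to_csv(out / "features.tsv", sep="\t", index=False, header=False)
    meta = adata.obs[["sample", "group", "cluster"]].copy()
    meta.insert(0, "barcode", adata.obs_names)
    meta.to_csv(out / "metadata.tsv", sep="\t", index=False)
    bed = adata.var[["chrom", "start", "end"]].copy()
    bed["name"] = adata.var_names
    bed.to_csv(out / "genes.bed", sep="\t", index=False, header=False)
    contigs.to_csv(out / "contigs.csv", index=False)
    if ground_truth is not None:
        (out / "gene_sets.json").write_text(
            json.dumps(ground_truth.program_genes, indent=1, sort_keys=True)
        )
        (out / "ground_truth.json").write_text(ground_truth.to_json())
    return sorted(p.name for p in out.iterdir())


def read_dataset(in_dir):
    """Read a cohort written by :func:`write_dataset`.

    Returns (AnnData, contig DataFrame, gene-set dict or None,
    ground-truth dict or None).
    """
    d = Path(in_dir)
    X = sparse.csr_matrix(mmread(d / "matrix.mtx").T)
    barcodes = pd.read_csv(d / "barcodes.tsv", header=None)[0].astype(str)
    features = pd.read_csv(d / "features.tsv", sep="\t", header=None)
    meta = pd.read_csv(d / "metadata.tsv", sep="\t").set_index("barcode")
    bed = pd.read_csv(
        d / "genes.bed", sep="\t", header=None,
        names=["chrom", "start", "end", "name"], dtype={"chrom": str},
    ).set_index("name")
    var = bed.loc[features[0].astype(str)]
    var.index = features[0].astype(str)
    adata = ad.AnnData(X=X, obs=meta.loc[barcodes], var=var)
    contigs = pd.read_csv(d / "contigs.csv")
    sets_path = d / "gene_sets.json"
    gt_path = d / "ground_truth.json"
    gene_sets = json.loads(sets_path.read_text()) if sets_path.exists() else None
    gt = json.loads(gt_path.read_text()) if gt_path.exists() else None
    return adata, contigs, gene_sets, gt
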