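"""End-to-end recovery benchmarks on synthetic cohorts.

Each benchmark simulates a cohort with known planted structure, runs the
relevant pipeline stage at its default settings and measures recovery
against the ground truth. They back both the validation test-suite and the
reproduction script; problem sizes are chosen to make every planted effect
measurable on one CPU in seconds-to-minutes.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import cnv as _cnv
from . import scoring as _scoring
from . import stagemods as _mods
from .synthetic import SimConfig, simulate_dataset

__all__ = [
    "cnv_recovery",
    "module_recovery",
    "cytotoxic_rank_rate",
    "dysfunction_selection_metrics",
    "stage_filter_type1_rate",
]


def _epithelial_split(adata):
    obs = adata.obs
    query = adata.obs_names[(obs["cluster"] == "Epithelial") & (obs["group"] != "nLung")]
    reference = adata.obs_names[obs["cluster"].isin(["Immune", "Stromal"])]
    return list(query), list(reference)


def cnv_recovery(seed: int = 0) -> dict:
    """Malignant-cell classification on a ~2,000-cell, 6,000-gene cohort
    with one +1 log2 segment of 300 genes in 40% of AIS/IAC epithelium.

    Returns sensitivity/specificity of `classify_malignant` at defaults
    against the planted malignant set.
    """
    cfg = SimConfig(
        seed=seed,
        n_genes=6000,
        n_cells_per_sample=170,
        cnv_segments=[("1", 100, 400, 1.0)],
        malignant_fraction=0.4,
        module_specs=[],
        program_sizes={},
    )
    adata, _, gt = simulate_dataset(cfg)
    query, reference = _epithelial_split(adata)
    profile = _cnv.infer_cnv_profiles(adata, query, reference)
    result = _cnv.classify_malignant(_cnv.cnv_score(profile))
    truth = result.scores.index.isin(gt.malignant_cells)
    call = result.scores["malignant"].to_numpy()
    return {
        "sensitivity": float((call & truth).sum() / truth.sum()),
        "specificity": float((~call & ~truth).sum() / (~truth).sum()),
        "n_query": int(len(query)),
        "n_cells": int(adata.n_obs),
    }


def module_recovery(seed: int = 0) -> dict:
    """WGCNA-core recovery of the five planted stage-trajectory modules.

    Runs metacell construction, soft-threshold selection, module detection
    and trajectory classification on the planted-module genes of the
    epithelial compartment; reports the adjusted Rand index versus the
    planted gene->module partition and how many detected modules carry
    their planted trajectory class.
    """
    cfg = SimConfig(seed=seed, n_genes=800, n_cells_per_sample=250, cnv_segments=[])
    adata, _, gt = simulate_dataset(cfg)
    epi = adata[adata.obs["cluster"] == "Epithelial"].copy()
    module_genes = [g for gs in gt.module_genes.values() for g in gs]
    sub = epi[:, module_genes].copy()
    metacells = _mods.build_metacells(sub, k=10)
    beta, _ = _mods.pick_soft_threshold(metacells)
    assignment = _mods.detect_modules(metacells, beta)
    truth = pd.Series({g: m for m, gs in gt.module_genes.items() for g in gs})
    ari = adjusted_rand_score(truth[assignment.modules.index], assignment.modules)
    trajectories = _mods.module_trajectories(assignment, metacells)
    correct = 0
    for colour in assignment.eigengenes.columns:
        planted = truth[assignment.modules.index[assignment.modules == colour]].mode()[0]
        correct += trajectories.loc[colour, "trajectory"] == gt.module_classes[planted]
    return {
        "ari": float(ari),
        "n_detected": int(len(assignment.eigengenes.columns)),
        "n_trajectory_correct": int(correct),
        "n_metacells": int(metacells.expr.shape[0]),
    }


def cytotoxic_rank_rate(seed: int = 0, n_seeds: int = 20) -> float:
    """Fraction of simulations where the planted cytotoxic cluster has the
    highest mean cytotoxic module score."""
    wins = 0
    for i in range(n_seeds):
        cfg = SimConfig(seed=seed + i, n_genes=1000, n_cells_per_sample=100,
                        cnv_segments=[], module_specs=[])
        adata, _, gt = simulate_dataset(cfg)
        scores = _scoring.score_table(adata, gt.program_genes, seed=seed + i)
        summary = _scoring.score_summaries(scores, by="cluster")
        top = summary[(summary["set"] == "cytotoxic") & (summary["rank"] == 1)]
        wins += top["cluster"].iloc[0] == "T_cytotoxic"
    return wins / n_seeds


def dysfunction_selection_metrics(seed: int = 0, n_seeds: int = 3) -> dict:
    """Recall on the planted cytotoxic-program genes and false-positive
    rate on background genes for the dysfunction-gene selection, averaged
    over `n_seeds` cohorts."""
    recalls, fprs = [], []
    for i in range(n_seeds):
        cfg = SimConfig(seed=seed + i, n_genes=1000, n_cells_per_sample=250,
                        cnv_segments=[], module_specs=[])
        adata, _, gt = simulate_dataset(cfg)
        tcells = adata[adata.obs["cluster"] == "T_cytotoxic"].copy()
        score = _scoring.module_score(
            tcells, gt.program_genes["cytotoxic"], seed=seed + i
        )
        selection = _scoring.select_dysfunction_genes(
            tcells, score, tcells.obs["group"].to_numpy()
        )
        planted = set(gt.program_genes["cytotoxic"])
        hits = set(selection.index[selection["selected"]])
        recalls.append(len(hits & planted) / len(planted))
        fprs.append(len(hits - planted) / (len(selection) - len(planted)))
    return {"recall": float(np.mean(recalls)), "null_fpr": float(np.mean(fprs))}


def stage_filter_type1_rate(seed: int = 0, n_genes: int = 1000) -> float:
    """Fraction of pure-noise genes passing the stage-association filter at
    FDR < 0.001 (3 stages x 4 samples x ~50 epithelial cells each)."""
    cfg = SimConfig(
        seed=seed,
        n_samples_per_group={"nLung": 4, "AIS": 4, "IAC": 4},
        n_cells_per_sample=170,
        n_genes=n_genes,
        cnv_segments=[],
        module_specs=[],
        program_sizes={},
    )
    adata, _, _ = simulate_dataset(cfg)
    epi = adata[adata.obs["cluster"] == "Epithelial"].copy()
    assoc = _mods.stage_association_filter(epi)
    return float(assoc["pass"].mean())
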