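import anndata as ad
import numpy as np
import pandas as pd
import pytest

import ggnpipe as gp


@pytest.fixture(scope="session")
def small_cohort():
    """Small full-featured cohort: CNV segment, five modules, programs, TCR."""
    cfg = gp.SimConfig(
        seed=42,
        n_genes=800,
        n_cells_per_sample=100,
        cnv_segments=[("1", 0, 60, 1.0)],
    )
    adata, contigs, gt = gp.simulate_dataset(cfg)
    return cfg, adata, contigs, gt


@pytest.fixture(scope="session")
def plain_cohort():
    """Cohort with no planted structure at all (pure NB noise + programs off)."""
    cfg = gp.SimConfig(
        seed=7,
        n_genes=400,
        n_cells_per_sample=80,
        cnv_segments=[],
        module_specs=[],
        program_sizes={},
    )
    adata, contigs, gt = gp.simulate_dataset(cfg)
    return cfg, adata, contigs, gt


def make_adata(counts, genes=None, chrom=None, start=None, **obs_cols):
    """Hand-built AnnData helper for toy matrices."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    genes = genes if genes is not None else [f"G{i}" for i in range(n_genes)]
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    var["chrom"] = chrom if chrom is not None else "1"
    var["start"] = start if start is not None else np.arange(n_genes) * 1000
    var["end"] = var["start"] + 100
    obs = pd.DataFrame(index=pd.Index([f"C{i}" for i in range(n_cells)], name="cell"))
    for k, v in obs_cols.items():
        obs[k] = v
    return ad.AnnData(X=counts.astype(np.float64), obs=obs, var=var)
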