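"""Per-nucleus and per-gene quality control.

Nuclei are removed if they have fewer than 1000 UMIs, more than 2.5%
mitochondrial transcripts, or lie outside +/-3 median absolute deviations
(MADs) of the per-sample median UMI or detected-gene count.  Genes detected
in fewer than 10 nuclei are removed.  The MAD is unscaled
(median(|x - median(x)|), no 1.4826 consistency factor) and is computed on
raw per-sample counts; nuclei above the upper UMI fence double as putative
doublets, so no separate doublet detector is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["QCThresholds", "compute_qc", "filter_nuclei", "filter_genes",
           "apply_qc", "mito_genes"]


@dataclass
class QCThresholds:
    min_umi: int = 1000
    max_mito: float = 0.025
    n_mads: float = 3.0
    min_cells_per_gene: int = 10


def mito_genes(adata: ad.AnnData, prefix: str = "mt-") -> list:
    """Mitochondrial genes identified by name prefix (default ``mt-``)."""
    return [g for g in adata.var_names if g.startswith(prefix)]


def compute_qc(adata: ad.AnnData, mito_gene_set=None) -> pd.DataFrame:
    """Per-nucleus totals: UMIs, detected genes, mitochondrial fraction.

    The mitochondrial fraction of an all-zero nucleus is defined as 0.
    """
    if mito_gene_set is None:
        mito_gene_set = mito_genes(adata)
    mito_gene_set = list(mito_gene_set)
    unknown = sorted(set(mito_gene_set) - set(adata.var_names))
    if unknown:
        raise ValueError(f"mitochondrial genes not in matrix: {unknown}")
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    total = np.asarray(X.sum(axis=1)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    mito_mask = adata.var_names.isin(mito_gene_set)
    mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    out = pd.DataFrame({
        "total_umis": total.astype(np.int64),
        "n_genes": n_genes.astype(np.int64),
        "mito_fraction": mito_frac,
    }, index=adata.obs_names)
    if "sample" in adata.obs:
        out["sample"] = adata.obs["sample"].to_numpy()
    else:
        out["sample"] = "S1"
    return out


def _mad_keep(x: np.ndarray, n_mads: float) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    return np.abs(x - med) <= n_mads * mad


def filter_nuclei(qc: pd.DataFrame, thr: QCThresholds | None = None) -> np.ndarray:
    """Boolean keep-mask over nuclei.

    Fixed cuts (UMIs >= min_umi, mito <= max_mito) are applied first; the
    per-sample +/- n_mads MAD fences on UMIs and detected genes are then
    computed within each sample on the raw values of all its nuclei.
    """
    thr = thr or QCThresholds()
    keep = (qc["total_umis"].to_numpy() >= thr.min_umi) & \
           (qc["mito_fraction"].to_numpy() <= thr.max_mito)
    for s, grp in qc.groupby("sample", observed=True):
        idx = qc.index.get_indexer(grp.index)
        if len(grp) < 2:
            warnings.warn(f"sample {s!r} has a single nucleus; MAD undefined, kept")
            continue
        in_fence = (_mad_keep(grp["total_umis"].to_numpy(float), thr.n_mads)
                    & _mad_keep(grp["n_genes"].to_numpy(float), thr.n_mads))
        keep[idx] &= in_fence
    return keep


def filter_genes(adata: ad.AnnData, min_cells: int = 10) -> np.ndarray:
    """Boolean keep-mask over genes: nonzero in at least ``min_cells`` nuclei."""
    X = adata.X
    if sp.issparse(X):
        n_cells = np.asarray((X > 0).sum(axis=0)).ravel()
    else:
        n_cells = (X > 0).sum(axis=0)
    return n_cells >= min_cells


def apply_qc(adata: ad.AnnData, thr: QCThresholds | None = None,
             mito_gene_set=None) -> ad.AnnData:
    """Full QC pass: compute metrics, filter nuclei then genes.

    The per-nucleus metrics are stored in ``.obs`` of the returned object.
    """
    thr = thr or QCThresholds()
    qc = compute_qc(adata, mito_gene_set)
    keep_n = filter_nuclei(qc, thr)
    out = adata[keep_n].copy()
    keep_g = filter_genes(out, thr.min_cells_per_gene)
    out = out[:, keep_g].copy()
    for col in ("total_umis", "n_genes", "mito_fraction"):
        out.obs[col] = qc.loc[out.obs_names, col]
    return out
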