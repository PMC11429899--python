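"""Normalization, variable genes, PCA with the find_pc rule, batch
alignment, and graph clustering.

The workflow mirrors the standard single-cell recipe: log normalization per
10,000 counts (natural log), top-2000 variable genes by variance-stabilized
ranking, PCA, a principled choice of the number of components (``find_pc``),
k-nearest-neighbor graph construction and Leiden community detection at a
given resolution.  Batch alignment is a pluggable contract; the default is
a mutual-nearest-neighbor shift correction in PC space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

__all__ = ["lognormalize", "select_variable_genes", "find_pc", "FindPCResult",
           "run_pca", "align_batches", "cluster_nuclei", "embed_umap",
           "cluster_pipeline"]


def lognormalize(adata: ad.AnnData, target_sum: float = 1e4,
                 base: float | None = None, layer: str | None = None) -> ad.AnnData:
    """Return a copy with ``X = log(1 + target_sum * c / total)``.

    Natural log by default (``base`` rescales).  Raw counts are preserved in
    ``layers["counts"]``.  A zero-total nucleus is an error: it should have
    been removed by QC.
    """
    out = adata.copy()
    X = out.layers[layer] if layer else out.X
    X = sp.csr_matrix(X, dtype=np.float64) if not sp.issparse(X) else X.astype(np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        bad = int((totals <= 0).sum())
        raise ValueError(f"{bad} nuclei have zero total counts; run QC first")
    out.layers["counts"] = adata.X.copy() if layer is None else adata.layers[layer].copy()
    X = X.multiply(target_sum / totals[:, None]).tocsr()
    X.data = np.log1p(X.data)
    if base is not None:
        X.data /= np.log(base)
    out.X = X
    return out


def select_variable_genes(adata: ad.AnnData, n_top_genes: int = 2000,
                          layer: str = "counts", span: float = 0.3) -> list:
    """Top variable genes by variance-stabilized ranking.

    On raw counts, a lowess trend of log10(variance) on log10(mean) predicts
    each gene's expected standard deviation; counts are standardized against
    the trend, clipped at sqrt(N), and genes are ranked by the variance of
    the clipped standardized values.  Constant genes rank last.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    X = adata.layers[layer] if layer in adata.layers else adata.X
    X = sp.csc_matrix(X, dtype=np.float64)
    n_obs, n_genes = X.shape
    if n_top_genes >= n_genes:
        return list(adata.var_names)
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = X.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.mean(axis=0)).ravel()
    var = (ex2 - mean ** 2) * n_obs / max(n_obs - 1, 1)

    expressed = (mean > 0) & (var > 0)
    fit = lowess(np.log10(var[expressed]), np.log10(mean[expressed]),
                 frac=span, return_sorted=False)
    reg_sd = np.ones(n_genes)
    reg_sd[expressed] = np.sqrt(10.0 ** fit)

    clip = np.sqrt(n_obs)
    std_var = np.zeros(n_genes)
    indptr, data = X.indptr, X.data
    for g in np.flatnonzero(expressed):
        vals = data[indptr[g]:indptr[g + 1]]
        z = np.minimum((vals - mean[g]) / reg_sd[g], clip)
        z0 = -mean[g] / reg_sd[g]  # zero entries, never above the clip
        nnz = vals.size
        s1 = z.sum() + (n_obs - nnz) * z0
        s2 = (z ** 2).sum() + (n_obs - nnz) * z0 ** 2
        std_var[g] = (s2 - s1 ** 2 / n_obs) / max(n_obs - 1, 1)

    order = np.argsort(-std_var, kind="stable")
    return [adata.var_names[i] for i in order[:n_top_genes]]


@dataclass
class FindPCResult:
    n_pcs: int
    criterion_a: int
    criterion_b: int


def find_pc(percent_variances, return_details: bool = False):
    """Number of principal components to retain.

    Two criteria on the per-component percent variance explained (descending):

    * A — first component k at which the cumulative percentage exceeds 90
      and the component's own percentage is below 5;
    * B — one past the last component whose drop to the next component
      exceeds 0.1 percentage points.

    The smaller of the two is returned.  If A is never satisfied the full
    length is used with a warning.
    """
    pv = np.asarray(percent_variances, dtype=float)
    if pv.size == 0:
        raise ValueError("empty variance vector")
    cum = np.cumsum(pv)
    a_hits = np.flatnonzero((cum > 90.0) & (pv < 5.0))
    if a_hits.size:
        a = int(a_hits[0]) + 1
    else:
        warnings.warn("cumulative-variance criterion never satisfied; "
                      "using all components")
        a = pv.size
    if pv.size >= 2:
        gaps = pv[:-1] - pv[1:]
        big = np.flatnonzero(gaps > 0.1)
        b = int(big[-1]) + 2 if big.size else 1
    else:
        b = 1
    n = min(a, b)
    if return_details:
        return FindPCResult(n, a, b)
    return n


def run_pca(adata: ad.AnnData, genes=None, n_comps: int = 50,
            seed: int = 0) -> np.ndarray:
    """Scale the selected genes and run PCA; stores ``obsm['X_pca']`` and the
    percent variance per component in ``uns['pct_variance']``.

    Returns the percent-variance vector (descending).
    """
    genes = list(genes) if genes is not None else list(adata.var_names)
    n_comps = min(n_comps, len(genes) - 1, adata.n_obs - 1)
    sub = adata[:, genes].copy()
    sc.pp.scale(sub, max_value=10)
    sc.tl.pca(sub, n_comps=n_comps, svd_solver="arpack", random_state=seed)
    adata.obsm["X_pca"] = sub.obsm["X_pca"]
    pct = sub.uns["pca"]["variance_ratio"] * 100.0
    adata.uns["pct_variance"] = pct
    return pct


def align_batches(adata: ad.AnnData, sample_key: str = "sample",
                  reference: str | None = None, use_rep: str = "X_pca",
                  k: int = 20, key_added: str = "X_pca_aligned") -> np.ndarray:
    """Mutual-nearest-neighbor shift correction in PC space.

    Each non-reference sample is translated by the mean displacement of its
    mutual nearest neighbors in the reference sample.  With fewer than two
    samples the representation passes through unchanged.  This is the
    default implementation of a pluggable batch-alignment contract: aligned
    replicates of one condition should intermix at least as well as the
    unaligned representation.
    """
    rep = np.asarray(adata.obsm[use_rep], dtype=float).copy()
    labels = adata.obs[sample_key].astype(str).to_numpy()
    samples = pd.unique(labels)
    if len(samples) < 2:
        adata.obsm[key_added] = rep
        return rep
    if reference is None:
        # largest sample anchors the correction
        reference = max(samples, key=lambda s: (labels == s).sum())
    ref_idx = np.flatnonzero(labels == reference)
    ref = rep[ref_idx]
    nn_ref = NearestNeighbors(n_neighbors=min(k, len(ref_idx))).fit(ref)
    for s in samples:
        if s == reference:
            continue
        idx = np.flatnonzero(labels == s)
        qry = rep[idx]
        kq = min(k, len(idx))
        _, to_ref = nn_ref.kneighbors(qry)
        nn_qry = NearestNeighbors(n_neighbors=kq).fit(qry)
        _, to_qry = nn_qry.kneighbors(ref)
        # mutual pairs: q's neighbor r also lists q among its neighbors
        pairs = []
        back = [set(row) for row in to_qry]
        for qi, row in enumerate(to_ref):
            for ri in row:
                if qi in back[ri]:
                    pairs.append((qi, ri))
        if pairs:
            qi, ri = np.array(pairs).T
            shift = (ref[ri] - qry[qi]).mean(axis=0)
            rep[idx] += shift
    adata.obsm[key_added] = rep
    return rep


def cluster_nuclei(adata: ad.AnnData, resolution: float = 0.24,
                   n_pcs: int | None = None, n_neighbors: int = 20,
                   seed: int = 0, use_rep: str = "X_pca",
                   key_added: str = "cluster") -> np.ndarray:
    """Leiden community detection on the k-NN graph in PC space.

    The graph is the symmetrized k-nearest-neighbor graph over the first
    ``n_pcs`` components (``find_pc`` of the stored variance profile when
    not given).  Labels are contiguous integers from 0, ordered by
    decreasing cluster size, stored in ``obs[key_added]``; deterministic
    for a fixed seed.
    """
    import igraph
    import leidenalg

    if n_pcs is None:
        n_pcs = find_pc(adata.uns["pct_variance"]) if "pct_variance" in adata.uns \
            else adata.obsm[use_rep].shape[1]
    n_pcs = min(n_pcs, adata.obsm[use_rep].shape[1])
    rep = np.asarray(adata.obsm[use_rep])[:, :n_pcs]
    n = rep.shape[0]
    k = min(n_neighbors, n - 1)
    from sklearn.neighbors import kneighbors_graph
    A = kneighbors_graph(rep, k, mode="connectivity", include_self=False)
    A = A.maximum(A.T).tocoo()
    mask = A.row < A.col
    g = igraph.Graph(n=n, edges=list(zip(A.row[mask], A.col[mask])),
                     directed=False)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=int(seed), n_iterations=2)
    raw = np.asarray(part.membership)
    # relabel by decreasing size for stable, contiguous ids
    order = pd.Series(raw).value_counts().index.to_numpy()
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[r] for r in raw])
    adata.obs[key_added] = pd.Categorical(labels)
    return labels


def embed_umap(adata: ad.AnnData, seed: int = 0, use_rep: str = "X_pca",
               n_neighbors: int = 20, n_pcs: int | None = None) -> np.ndarray:
    """2-D UMAP embedding (builds the scanpy neighbor graph if absent)."""
    if "neighbors" not in adata.uns:
        if n_pcs is None and "pct_variance" in adata.uns:
            n_pcs = find_pc(adata.uns["pct_variance"])
        sc.pp.neighbors(adata, n_neighbors=n_neighbors, n_pcs=n_pcs,
                        use_rep=use_rep, random_state=seed)
    sc.tl.umap(adata, random_state=seed)
    return adata.obsm["X_umap"]


def cluster_pipeline(adata: ad.AnnData, resolution: float = 0.24,
                     n_top_genes: int = 2000, n_comps: int = 50,
                     seed: int = 0, align: bool = False,
                     sample_key: str = "sample", reference: str | None = None,
                     umap: bool = False, key_added: str = "cluster") -> ad.AnnData:
    """Convenience wrapper: lognormalize -> variable genes -> PCA(find_pc)
    -> (optional batch alignment) -> neighbors -> Leiden (-> optional UMAP).

    Returns a new AnnData; raw counts stay in ``layers['counts']``.
    """
    norm = lognormalize(adata)
    hvg = select_variable_genes(norm, n_top_genes=n_top_genes)
    run_pca(norm, genes=hvg, n_comps=n_comps, seed=seed)
    rep = "X_pca"
    if align and sample_key in norm.obs and norm.obs[sample_key].nunique() > 1:
        align_batches(norm, sample_key=sample_key, reference=reference)
        rep = "X_pca_aligned"
    cluster_nuclei(adata=norm, resolution=resolution, seed=seed,
                   use_rep=rep, key_added=key_added)
    if umap:
        embed_umap(norm, seed=seed)
    return norm
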