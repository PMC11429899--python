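"""Negative and positive selection of V1 interneuron nuclei.

Enriched single-nucleus preparations still carry contaminating
oligodendrocytes, astrocytes, microglia and non-V1 neurons.  Negative
selection repeatedly clusters the data, scores every cluster against
contaminant marker panels, and removes flagged clusters until none remain.
Positive selection then transfers class labels from an annotated reference
(an embryonic whole-spinal-cord dataset in the original study) and keeps
nuclei whose V1 prediction score clears a threshold.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from . import preprocess
from .qc import QCThresholds

__all__ = ["DEFAULT_NEGATIVE_PANELS", "score_panels", "negative_selection",
           "transfer_labels", "select_v1", "select_v1_pipeline"]

#: Default contaminant marker panels (field-standard cell-class markers;
#: user-supplied panels override these).
DEFAULT_NEGATIVE_PANELS = {
    "oligodendrocyte": ["Plp1", "Mbp", "Mog", "Sox10"],
    "astrocyte": ["Aqp4", "Gfap", "Slc1a3"],
    "microglia": ["C1qa", "C1qb", "Cx3cr1"],
    "non_v1_neuron": ["Chat", "Isl1", "Vsx2", "Slc17a6"],
}


def score_panels(norm: ad.AnnData, clusters, panels: dict) -> pd.DataFrame:
    """Per-cluster panel z-scores.

    For each panel, the mean log-normalized expression of its genes is
    averaged within each cluster and z-scored across clusters (ddof=1).
    Panel genes missing from the matrix are dropped with a warning; a panel
    with no genes present is an error.  Returns clusters x panels.
    """
    clusters = np.asarray(clusters)
    uniq = np.unique(clusters)
    means = {}
    for name, genes in panels.items():
        present = [g for g in genes if g in norm.var_names]
        missing = sorted(set(genes) - set(present))
        if not present:
            raise ValueError(f"panel {name!r} has no genes in the matrix")
        if missing:
            warnings.warn(f"panel {name!r}: missing genes dropped: {missing}")
        vals = np.asarray(norm[:, present].X.mean(axis=1)).ravel()
        means[name] = np.array([vals[clusters == c].mean() for c in uniq])
    df = pd.DataFrame(means, index=pd.Index(uniq, name="cluster"))
    mu = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1).replace(0.0, 1.0)
    return (df - mu) / sd


def _flag_clusters(norm: ad.AnnData, clusters, panels: dict,
                   z_threshold: float, min_mean: float,
                   qc_thresholds: QCThresholds) -> pd.DataFrame:
    """One round of annotation: which clusters breach a panel or QC rule."""
    z = score_panels(norm, clusters, panels)
    uniq = z.index.to_numpy()
    # absolute expression guard: a panel only flags clusters where it is
    # actually expressed, not merely relatively enriched noise
    raw_means = {}
    for name, genes in panels.items():
        present = [g for g in genes if g in norm.var_names]
        vals = np.asarray(norm[:, present].X.mean(axis=1)).ravel()
        raw_means[name] = np.array([vals[np.asarray(clusters) == c].mean()
                                    for c in uniq])
    records = []
    for ci, c in enumerate(uniq):
        mask = np.asarray(clusters) == c
        for name in panels:
            if z.loc[c, name] > z_threshold and raw_means[name][ci] > min_mean:
                records.append((c, int(mask.sum()), "panel", name,
                                float(z.loc[c, name])))
        if "total_umis" in norm.obs and "mito_fraction" in norm.obs:
            med_umi = float(np.median(norm.obs.loc[mask, "total_umis"]))
            med_mito = float(np.median(norm.obs.loc[mask, "mito_fraction"]))
            if med_umi < qc_thresholds.min_umi:
                records.append((c, int(mask.sum()), "qc", "median_umi", med_umi))
            if med_mito > qc_thresholds.max_mito:
                records.append((c, int(mask.sum()), "qc", "median_mito", med_mito))
    return pd.DataFrame(records,
                        columns=["cluster", "n_nuclei", "rule", "trigger", "value"])


def negative_selection(adata: ad.AnnData, panels: dict | None = None,
                       z_threshold: float = 2.0, min_mean: float = 0.1,
                       max_rounds: int = 10, resolution: float = 1.0,
                       n_top_genes: int = 2000, seed: int = 0,
                       qc_thresholds: QCThresholds | None = None) -> tuple:
    """Iterative removal of contaminant clusters.

    Each round: log-normalize, reduce, cluster at ``resolution``, flag
    clusters whose panel z-score exceeds ``z_threshold`` (with the panel
    expressed above ``min_mean``) or whose median QC metrics breach the QC
    fences, and remove the flagged nuclei.  Stops when a round flags nothing
    or after ``max_rounds``.  Returns ``(keep_mask, log)`` where the log
    records every removal with its triggering rule.
    """
    panels = panels or DEFAULT_NEGATIVE_PANELS
    qc_thresholds = qc_thresholds or QCThresholds()
    keep = np.ones(adata.n_obs, dtype=bool)
    logs = []
    for rnd in range(1, max_rounds + 1):
        current = adata[keep]
        norm = preprocess.cluster_pipeline(
            current, resolution=resolution, n_top_genes=n_top_genes,
            seed=seed + rnd)
        clusters = norm.obs["cluster"].to_numpy()
        flags = _flag_clusters(norm, clusters, panels, z_threshold,
                               min_mean, qc_thresholds)
        flags.insert(0, "round", rnd)
        logs.append(flags)
        if flags.empty:
            break
        bad_clusters = set(flags["cluster"])
        drop_local = np.isin(clusters, list(bad_clusters))
        keep_idx = np.flatnonzero(keep)
        keep[keep_idx[drop_local]] = False
        if not keep.any():
            raise RuntimeError("negative selection removed every nucleus")
    logs = [f for f in logs if not f.empty]
    if logs:
        log = pd.concat(logs, ignore_index=True)
    else:
        log = pd.DataFrame(columns=["round", "cluster", "n_nuclei", "rule",
                                    "trigger", "value"])
    return keep, log


def transfer_labels(query: ad.AnnData, reference: ad.AnnData,
                    label_key: str = "class_label", k: int = 30,
                    n_top_genes: int = 2000, n_comps: int = 50,
                    min_shared_genes: int = 100, seed: int = 0) -> pd.DataFrame:
    """Reference-based label transfer with kernel-weighted k-NN scoring.

    The reference (raw counts) is log-normalized, scaled, and reduced by
    PCA over its variable genes; the query is projected into the same PC
    space using the reference's gene means/scales and loadings.  Each query
    nucleus receives per-label scores: the Gaussian-kernel-weighted fraction
    of each label among its ``k`` nearest reference cells (bandwidth = mean
    neighbor distance; exact matches at distance zero take all the weight).
    Scores form an exact probability vector; the argmax label (lexicographic
    tie-break) is stored in the ``predicted`` column.
    """
    shared = [g for g in reference.var_names if g in set(query.var_names)]
    if not shared:
        raise ValueError("query and reference share no genes")
    if len(shared) < min_shared_genes:
        raise ValueError(
            f"only {len(shared)} shared genes (< {min_shared_genes})")

    ref = preprocess.lognormalize(reference[:, shared].copy())
    hvg = preprocess.select_variable_genes(ref, n_top_genes=n_top_genes)
    ref = ref[:, hvg]
    Xr = np.asarray(ref.X.todense() if hasattr(ref.X, "todense") else ref.X)
    mu = Xr.mean(axis=0)
    sd = Xr.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Zr = np.clip((Xr - mu) / sd, -10, 10)
    n_comps = min(n_comps, Zr.shape[1] - 1, Zr.shape[0] - 1)
    from sklearn.decomposition import PCA
    pca = PCA(n_components=n_comps, svd_solver="arpack", random_state=seed)
    ref_pcs = pca.fit_transform(Zr)

    qnorm = query if query.X.max() < 50 and "counts" in query.layers else \
        preprocess.lognormalize(query)
    Xq = qnorm[:, hvg].X
    Xq = np.asarray(Xq.todense() if hasattr(Xq, "todense") else Xq)
    Zq = np.clip((Xq - mu) / sd, -10, 10)
    qry_pcs = (Zq - pca.mean_) @ pca.components_.T

    labels = reference.obs[label_key].astype(str).to_numpy()
    label_set = sorted(set(labels))
    k = min(k, ref_pcs.shape[0])
    nn = NearestNeighbors(n_neighbors=k).fit(ref_pcs)
    dist, idx = nn.kneighbors(qry_pcs)
    sigma = dist.mean(axis=1, keepdims=True)
    sigma[sigma == 0] = 1.0
    w = np.exp(-0.5 * (dist / sigma) ** 2)
    exact = dist == 0
    has_exact = exact.any(axis=1)
    w[has_exact] = exact[has_exact].astype(float)
    w /= w.sum(axis=1, keepdims=True)

    scores = np.zeros((qry_pcs.shape[0], len(label_set)))
    lab_idx = {l: i for i, l in enumerate(label_set)}
    neigh_labels = np.vectorize(lab_idx.get)(labels[idx])
    for li in range(len(label_set)):
        scores[:, li] = np.where(neigh_labels == li, w, 0.0).sum(axis=1)
    scores /= scores.sum(axis=1, keepdims=True)
    out = pd.DataFrame(scores, columns=label_set, index=query.obs_names)
    out["predicted"] = [label_set[i] for i in np.argmax(scores, axis=1)]
    return out


def select_v1(pred: pd.DataFrame, threshold: float = 0.5,
              v1_label: str = "V1") -> np.ndarray:
    """Keep nuclei whose argmax label is V1 with score >= threshold."""
    if v1_label not in pred.columns:
        raise ValueError(f"no {v1_label!r} column in prediction scores")
    return ((pred["predicted"] == v1_label)
            & (pred[v1_label] >= threshold)).to_numpy()


def select_v1_pipeline(adata: ad.AnnData, reference: ad.AnnData,
                       panels: dict | None = None, seed: int = 0,
                       threshold: float = 0.5, **neg_kwargs) -> tuple:
    """Negative selection followed by positive selection.

    Returns ``(keep_mask, negative_log, prediction_scores)`` over the input
    nuclei; the mask combines both stages.
    """
    neg_keep, log = negative_selection(adata, panels=panels, seed=seed,
                                       **neg_kwargs)
    surv = adata[neg_keep]
    pred = transfer_labels(surv, reference, seed=seed)
    pos_keep = select_v1(pred, threshold=threshold)
    keep = np.zeros(adata.n_obs, dtype=bool)
    keep[np.flatnonzero(neg_keep)[pos_keep]] = True
    return keep, log, pred
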