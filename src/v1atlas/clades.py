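"""Clade assignment for V1 interneuron clusters.

Postnatal V1 interneurons segregate into five largely mutually exclusive
clades marked by Foxp2, Sp8, Pou6f2, MafA/Calbindin (Chrna2 serves as the
assignment-time proxy for MafA) and Rnf220.  A nucleus is marker-positive
when its log-normalized expression strictly exceeds the marker's threshold
(Foxp2 2.8, Sp8 0.8, Pou6f2 2.6, Chrna2 1.1).  Clusters are assigned to the
marker with the highest positive cross-cluster z-score of mean expression;
clusters with no positive primary z fall to the Rnf220 clade when Rnf220's
z is positive, otherwise remain unassigned.

Per-nucleus thresholds are applied on the merged log-normalized matrix, not
on batch-corrected values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

__all__ = ["CladeThresholds", "call_marker_positive", "cluster_clade_zscores",
           "assign_clades", "count_coexpressing", "clade_proportions",
           "MARKER_TO_CLADE"]

MARKER_TO_CLADE = {
    "Foxp2": "Foxp2",
    "Sp8": "Sp8",
    "Pou6f2": "Pou6f2",
    "Chrna2": "MafA/Calb",
    "Rnf220": "Rnf220",
}

PRIMARY_MARKERS = ("Foxp2", "Sp8", "Pou6f2", "Chrna2")


@dataclass
class CladeThresholds:
    """Log-normalized expression cutoffs for per-nucleus marker positivity."""

    thresholds: dict = field(default_factory=lambda: {
        "Foxp2": 2.8, "Sp8": 0.8, "Pou6f2": 2.6, "Chrna2": 1.1})
    rnf220: float | None = None

    def as_dict(self) -> dict:
        out = dict(self.thresholds)
        if self.rnf220 is not None:
            out["Rnf220"] = self.rnf220
        return out


def _expr(norm: ad.AnnData, gene: str) -> np.ndarray:
    if gene not in norm.var_names:
        raise ValueError(f"marker gene {gene!r} missing from matrix")
    x = norm[:, gene].X
    return np.asarray(x.todense() if hasattr(x, "todense") else x).ravel()


def call_marker_positive(norm: ad.AnnData,
                         thresholds: CladeThresholds | None = None) -> pd.DataFrame:
    """Per-nucleus marker-positivity booleans (strict > threshold)."""
    thresholds = thresholds or CladeThresholds()
    out = {}
    for gene, cut in thresholds.as_dict().items():
        out[gene] = _expr(norm, gene) > cut
    return pd.DataFrame(out, index=norm.obs_names)


def cluster_clade_zscores(norm: ad.AnnData, clusters,
                          markers=PRIMARY_MARKERS) -> pd.DataFrame:
    """Cross-cluster z-scores of per-cluster mean marker expression.

    For each marker, the mean log-normalized expression per cluster is
    z-scored across clusters (mean 0, sd 1 with ddof=1).  A single cluster
    leaves the z-score undefined and is an error.
    """
    clusters = np.asarray(clusters)
    uniq = np.unique(clusters)
    if uniq.size < 2:
        raise ValueError("z-scores require at least two clusters")
    rows = {}
    for gene in markers:
        vals = _expr(norm, gene)
        rows[gene] = np.array([vals[clusters == c].mean() for c in uniq])
    df = pd.DataFrame(rows, index=pd.Index(uniq, name="cluster"))
    mu = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1).replace(0.0, 1.0)
    return (df - mu) / sd


def assign_clades(z: pd.DataFrame, rnf220_z: pd.Series | None = None) -> pd.Series:
    """Clade label per cluster from the primary-marker z matrix.

    The cluster is assigned to the marker with the highest positive z
    (covers the multi-positive tie rule); with no positive primary z it is
    assigned Rnf220 when ``rnf220_z`` is positive, else ``unassigned``.
    """
    labels = {}
    for cluster, row in z.iterrows():
        primary = row[[m for m in PRIMARY_MARKERS if m in row.index]]
        positive = primary[primary > 0]
        if len(positive):
            labels[cluster] = MARKER_TO_CLADE[positive.idxmax()]
        elif rnf220_z is not None and rnf220_z.get(cluster, 0.0) > 0:
            labels[cluster] = "Rnf220"
        else:
            labels[cluster] = "unassigned"
    return pd.Series(labels, name="clade").rename_axis("cluster")


def count_coexpressing(calls: pd.DataFrame,
                       markers=PRIMARY_MARKERS) -> int:
    """Number of nuclei positive for two or more clade markers."""
    cols = [m for m in markers if m in calls.columns]
    return int((calls[cols].sum(axis=1) >= 2).sum())


def clade_proportions(clusters, clade_map: pd.Series | dict,
                      replicates=None) -> pd.DataFrame:
    """Fraction of nuclei per clade, per replicate, with mean +/- SEM.

    ``clade_map`` maps cluster label -> clade.  Fractions within a replicate
    sum to 1 exactly (unassigned clusters included under ``unassigned``).
    Returns a DataFrame indexed by clade with one column per replicate plus
    ``mean`` and ``sem``.
    """
    clusters = np.asarray(clusters)
    clade_map = pd.Series(clade_map)
    if replicates is None:
        replicates = np.zeros(clusters.size, dtype=int)
    replicates = np.asarray(replicates)
    clades = clade_map.reindex(clusters).fillna("unassigned").to_numpy()
    df = pd.DataFrame({"clade": clades, "replicate": replicates})
    table = (df.groupby(["clade", "replicate"], observed=True).size()
             .unstack(fill_value=0))
    fractions = table / table.sum(axis=0)
    out = fractions.copy()
    out["mean"] = fractions.mean(axis=1)
    n_rep = fractions.shape[1]
    out["sem"] = fractions.std(axis=1, ddof=1) / np.sqrt(n_rep) if n_rep > 1 else 0.0
    return out
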