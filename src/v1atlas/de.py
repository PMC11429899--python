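"""Differential expression and cluster-relationship analysis.

Marker and age comparisons use the two-sided Wilcoxon rank-sum test on
log-normalized expression: exact enumeration of the rank-sum null when the
smaller group has at most 8 observations, a tie-corrected normal
approximation otherwise.  P values are Bonferroni-adjusted over the genes
tested; significance additionally requires |log2FC| strictly above 0.25,
with log2FC = log2((mean(expm1 a) + 1) / (mean(expm1 b) + 1)).

Pseudo-bulk profiles are exact raw-count sums per sample; pseudo-bulk DE is
a minimal count-based contract: median-of-ratios size factors, per-gene
method-of-moments negative-binomial dispersion, an NB GLM Wald test on the
condition coefficient, and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from itertools import combinations

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.cluster import hierarchy

__all__ = ["rank_sum_test", "wilcoxon_de", "find_markers", "age_degs",
           "pseudobulk", "pseudobulk_de", "cluster_tree",
           "cluster_correlation", "tree_to_newick", "LOG2FC_THRESHOLD"]

LOG2FC_THRESHOLD = 0.25
EXACT_MAX_N = 8


def rank_sum_test(a, b) -> tuple:
    """Two-sided Wilcoxon rank-sum test; returns (rank sum of a, p value).

    Exact when min(len(a), len(b)) <= 8: the p value is the fraction of all
    C(n, n_a) rank assignments whose rank sum lies at least as far from the
    null mean as the observed one (midranks for ties).  Otherwise a normal
    approximation with tie correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    if min(n1, n2) <= EXACT_MAX_N:
        sums = np.array([ranks[list(c)].sum()
                         for c in combinations(range(n1 + n2), n1)])
        p = float(np.mean(np.abs(sums - mu) >= np.abs(w - mu) - 1e-12))
    else:
        n = n1 + n2
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if sigma2 <= 0:
            return float(w), 1.0
        z = (w - mu) / np.sqrt(sigma2)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return float(w), min(p, 1.0)


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)


def _log2fc(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """log2FC on the natural-log-normalized scale with the expm1-mean + 1
    pseudocount convention."""
    return np.log2((np.expm1(a).mean(axis=0) + 1.0)
                   / (np.expm1(b).mean(axis=0) + 1.0))


def _ranksum_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Vectorized tie-corrected normal-approximation p values per column."""
    n1, n2 = A.shape[0], B.shape[0]
    n = n1 + n2
    pooled = np.vstack([A, B])
    ranks = stats.rankdata(pooled, axis=0)
    w = ranks[:n1].sum(axis=0)
    mu = n1 * (n + 1) / 2.0
    srt = np.sort(pooled, axis=0)
    new = np.vstack([np.ones((1, pooled.shape[1]), bool),
                     np.diff(srt, axis=0) != 0])
    tie_term = np.zeros(pooled.shape[1])
    for j in range(pooled.shape[1]):
        counts = np.diff(np.append(np.flatnonzero(new[:, j]), n))
        tie_term[j] = (counts ** 3 - counts).sum() / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    sigma2 = np.maximum(sigma2, 1e-300)
    z = (w - mu) / np.sqrt(sigma2)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[sigma2 <= 1e-299] = 1.0
    return np.minimum(p, 1.0)


def wilcoxon_de(norm: ad.AnnData, group_a, group_b,
                genes=None, n_total_genes: int | None = None) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum DE between two nucleus sets.

    ``group_a``/``group_b`` are boolean masks or index arrays over nuclei.
    Bonferroni adjustment uses ``n_total_genes`` (default: genes tested).
    """
    genes = list(genes) if genes is not None else list(norm.var_names)
    missing = sorted(set(genes) - set(norm.var_names))
    if missing:
        raise ValueError(f"genes absent from matrix: {missing}")
    A = _dense(norm[group_a][:, genes].X)
    B = _dense(norm[group_b][:, genes].X)
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("both groups must be nonempty")
    n_tests = n_total_genes if n_total_genes is not None else len(genes)
    if min(A.shape[0], B.shape[0]) <= EXACT_MAX_N:
        stats_p = np.array([rank_sum_test(A[:, j], B[:, j])
                            for j in range(len(genes))])
        stat, p = stats_p[:, 0], stats_p[:, 1]
    else:
        p = _ranksum_matrix(A, B)
        stat = stats.rankdata(np.vstack([A, B]), axis=0)[:A.shape[0]].sum(axis=0)
    lfc = _log2fc(A, B)
    padj = np.minimum(p * n_tests, 1.0)
    out = pd.DataFrame({
        "stat": stat, "pval": p, "padj": padj, "log2fc": lfc,
        "direction": np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none")),
        "significant": (padj < 0.05) & (np.abs(lfc) > LOG2FC_THRESHOLD),
    }, index=pd.Index(genes, name="gene"))
    return out


def find_markers(norm: ad.AnnData, clusters, mode: str = "one-vs-rest",
                 genes=None) -> dict:
    """Per-cluster marker tables, significant genes ranked by log2FC.

    ``mode`` is ``"one-vs-rest"`` (each cluster against all others) or
    ``"pairwise"`` (every ordered cluster pair, keyed ``(a, b)``).
    """
    clusters = np.asarray(clusters)
    uniq = np.unique(clusters)
    if uniq.size < 2:
        raise ValueError("marker finding requires at least two clusters")
    out = {}
    if mode == "one-vs-rest":
        for c in uniq:
            res = wilcoxon_de(norm, clusters == c, clusters != c, genes=genes)
            out[c] = res[res["significant"]].sort_values(
                "log2fc", ascending=False)
    elif mode == "pairwise":
        for c1, c2 in combinations(uniq, 2):
            res = wilcoxon_de(norm, clusters == c1, clusters == c2, genes=genes)
            out[(c1, c2)] = res[res["significant"]].sort_values(
                "log2fc", ascending=False)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def age_degs(norm: ad.AnnData, ages=None, groupings=None,
             alpha: float = 0.05) -> dict:
    """Positively enriched genes per age grouping.

    Default groupings follow the developmental contrasts of interest:
    ``P0`` vs all other ages, and ``P28`` + ``P56`` combined vs the rest.
    Returns grouping name -> DataFrame filtered to adjusted p < alpha and
    log2FC > 0, ranked by log2FC.
    """
    if ages is None:
        ages = norm.obs["age"]
    ages = np.asarray(ages).astype(str)
    if groupings is None:
        groupings = {"P0": ["P0"], "P28+P56": ["P28", "P56"]}
    out = {}
    for name, members in groupings.items():
        mask = np.isin(ages, members)
        if not mask.any() or mask.all():
            out[name] = pd.DataFrame()
            continue
        res = wilcoxon_de(norm, mask, ~mask)
        hits = res[(res["padj"] < alpha) & (res["log2fc"] > 0)]
        out[name] = hits.sort_values("log2fc", ascending=False)
    return out


def pseudobulk(adata: ad.AnnData, grouping) -> ad.AnnData:
    """Sum raw counts over nuclei per group; exact integer conservation.

    ``grouping`` is a per-nucleus label array or an ``obs`` column name.
    Returns an AnnData of groups x genes.
    """
    if isinstance(grouping, str):
        grouping = adata.obs[grouping]
    labels = np.asarray(grouping).astype(str)
    if adata.n_obs == 0 or labels.size == 0:
        raise ValueError("empty group: no nuclei to aggregate")
    uniq = list(pd.unique(labels))
    X = adata.layers["counts"] if "counts" in adata.layers else adata.X
    X = sp.csr_matrix(X)
    rows = []
    for g in uniq:
        mask = labels == g
        if not mask.any():
            raise ValueError(f"group {g!r} is empty")
        rows.append(np.asarray(X[mask].sum(axis=0)).ravel())
    agg = ad.AnnData(X=np.vstack(rows),
                     obs=pd.DataFrame(index=uniq),
                     var=adata.var.copy())
    return agg


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (samples x genes input)."""
    counts = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    usable = np.all(np.isfinite(logc), axis=0)
    if not usable.any():
        raise ValueError("no gene is expressed in every sample")
    log_geo = logc[:, usable].mean(axis=0)
    return np.exp(np.median(logc[:, usable] - log_geo, axis=1))


def pseudobulk_de(agg: ad.AnnData, condition, alpha_floor: float = 1e-8) -> pd.DataFrame:
    """Count-based DE on pseudo-bulk profiles.

    Median-of-ratios size factors, method-of-moments NB dispersion per gene
    (floored), NB GLM with a condition coefficient tested by Wald z, and
    Benjamini-Hochberg adjustment.  Requires at least two samples per
    condition (dispersion is inestimable otherwise).
    """
    import statsmodels.api as sm
    from statsmodels.stats.multitest import multipletests

    if isinstance(condition, str):
        condition = agg.obs[condition]
    cond = np.asarray(condition).astype(str)
    levels = sorted(pd.unique(cond))
    if len(levels) != 2:
        raise ValueError(f"exactly two conditions required, got {levels}")
    counts = np.asarray(agg.X, dtype=float)
    for lv in levels:
        if (cond == lv).sum() < 2:
            raise ValueError(f"condition {lv!r} has a single replicate; "
                             "dispersion cannot be estimated")
    sf = size_factors(counts)
    normed = counts / sf[:, None]
    x = (cond == levels[1]).astype(float)
    design = sm.add_constant(x)
    offset = np.log(sf)

    # method-of-moments dispersion on normalized counts, pooled within groups
    disp = np.full(counts.shape[1], alpha_floor)
    for j in range(counts.shape[1]):
        resid_var, mean_sum = 0.0, 0.0
        df = 0
        for lv in levels:
            grp = normed[cond == lv, j]
            resid_var += grp.var(ddof=1) * (grp.size - 1)
            mean_sum += grp.mean() * grp.size
            df += grp.size - 1
        mu = mean_sum / counts.shape[0]
        if mu > 0 and df > 0:
            v = resid_var / df
            disp[j] = max((v - mu) / mu ** 2, alpha_floor)

    records = []
    for j in range(counts.shape[1]):
        y = counts[:, j]
        if y.sum() == 0:
            records.append((0.0, 1.0, 0.0))
            continue
        try:
            fam = sm.families.NegativeBinomial(alpha=disp[j])
            fit = sm.GLM(y, design, family=fam, offset=offset).fit()
            coef = fit.params[1]
            se = fit.bse[1]
            zval = coef / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(zval))
            records.append((coef / np.log(2.0), p, zval))
        except Exception:
            records.append((0.0, 1.0, 0.0))
    lfc, pvals, zs = map(np.array, zip(*records))
    padj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "log2fc": lfc, "stat": zs, "pval": pvals, "padj": padj,
        "size_factor_min": sf.min(), "size_factor_max": sf.max(),
    }, index=agg.var_names)


# ---------------------------------------------------------------------------
# cluster relationships
# ---------------------------------------------------------------------------

def _cluster_means(values: np.ndarray, clusters: np.ndarray) -> tuple:
    uniq = np.unique(clusters)
    means = np.vstack([values[clusters == c].mean(axis=0) for c in uniq])
    return uniq, means


def cluster_tree(profiles: pd.DataFrame) -> np.ndarray:
    """Average-linkage agglomeration of cluster mean profiles (Euclidean).

    ``profiles`` is clusters x features (typically PC-space means).
    Returns the scipy linkage matrix; leaves follow the row order.
    """
    if profiles.shape[0] < 2:
        raise ValueError("need at least two clusters")
    return hierarchy.linkage(profiles.to_numpy(), method="average",
                             metric="euclidean")


def cluster_correlation(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between cluster mean expression profiles."""
    corr = np.corrcoef(profiles.to_numpy())
    return pd.DataFrame(corr, index=profiles.index, columns=profiles.index)


def tree_to_newick(linkage: np.ndarray, labels) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(linkage)
    labels = list(labels)

    def rec(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
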