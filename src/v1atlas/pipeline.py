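"""End-to-end pipeline orchestration.

``run_pipeline`` executes the stages of the atlas workflow in order —
simulate (or load), QC, negative+positive selection, clustering, clade
assignment, and (when two genotypes are present) compositional testing —
writing per-stage outputs and a manifest that records parameter values,
per-stage nucleus counts and the seed derivation, the audit trail for the
selection process.

Every stochastic stage draws its seed deterministically from the single
top-level seed via a CRC32 hash of the stage name (kept below 2**31), so
two runs with the same configuration are identical wherever determinism is
claimed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clades as clades_mod
from . import composition as comp_mod
from . import io as io_mod
from . import preprocess, qc, select, simulate

__all__ = ["RunConfig", "stage_seed", "run_pipeline"]


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2**31)."""
    return (int(base_seed) ^ zlib.crc32(stage.encode())) % (2 ** 31 - 1)


@dataclass
class RunConfig:
    outdir: str = "v1atlas_run"
    seed: int = 0
    counts_path: str | None = None   # None -> simulate
    reference_path: str | None = None
    n_nuclei: int = 20_000
    n_genes: int = 3_000
    resolution: float = 0.24
    n_top_genes: int = 2000
    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    clade_thresholds: clades_mod.CladeThresholds = field(
        default_factory=clades_mod.CladeThresholds)
    selection_threshold: float = 0.5
    fdr: float = 0.05
    dm_draws: int = 2000
    umap: bool = False


def run_pipeline(config: RunConfig) -> dict:
    """Run the full workflow; returns the manifest dict (also written to
    ``outdir/manifest.json``)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": {}, "parameters": {
        "resolution": config.resolution,
        "min_umi": config.qc_thresholds.min_umi,
        "max_mito": config.qc_thresholds.max_mito,
        "n_mads": config.qc_thresholds.n_mads,
        "min_cells_per_gene": config.qc_thresholds.min_cells_per_gene,
        "clade_thresholds": config.clade_thresholds.as_dict(),
        "selection_threshold": config.selection_threshold,
        "fdr": config.fdr,
    }}

    # ------------------------------------------------------------------ input
    truth = None
    if config.counts_path is None:
        cfg = simulate.default_config(n_nuclei=config.n_nuclei,
                                      n_genes=config.n_genes,
                                      seed=stage_seed(config.seed, "simulate"))
        adata, truth = simulate.simulate_counts(cfg)
        manifest["stages"]["simulate"] = {"n_nuclei": adata.n_obs,
                                          "n_genes": adata.n_vars}
    else:
        if not Path(config.counts_path).exists():
            raise FileNotFoundError(config.counts_path)
        adata = io_mod.read_counts(config.counts_path)
        manifest["stages"]["load"] = {"n_nuclei": adata.n_obs,
                                      "n_genes": adata.n_vars}

    # --------------------------------------------------------------------- qc
    adata = qc.apply_qc(adata, config.qc_thresholds)
    manifest["stages"]["qc"] = {"n_nuclei": adata.n_obs,
                                "n_genes": adata.n_vars}

    # -------------------------------------------------------------- selection
    if config.reference_path is None:
        reference = simulate.simulate_reference(
            n_genes=config.n_genes, seed=stage_seed(config.seed, "reference"))
    else:
        reference = io_mod.read_counts(config.reference_path)
    keep, neg_log, pred = select.select_v1_pipeline(
        adata, reference, seed=stage_seed(config.seed, "selection"),
        threshold=config.selection_threshold)
    neg_log.to_csv(out / "negative_selection_log.tsv", sep="\t", index=False)
    pd.Series(adata.obs_names[keep]).to_csv(out / "v1_barcodes.txt",
                                            index=False, header=False)
    manifest["stages"]["selection"] = {
        "n_input": adata.n_obs,
        "n_removed_negative": int(adata.n_obs - len(pred)),
        "n_retained": int(keep.sum()),
    }
    v1 = adata[keep].copy()

    # ------------------------------------------------------------- clustering
    norm = preprocess.cluster_pipeline(
        v1, resolution=config.resolution, n_top_genes=config.n_top_genes,
        seed=stage_seed(config.seed, "cluster"), umap=config.umap)
    clusters = norm.obs["cluster"].to_numpy()
    manifest["stages"]["cluster"] = {
        "n_clusters": int(len(np.unique(clusters))),
        "resolution": config.resolution,
    }
    emb_cols = {}
    if config.umap:
        emb_cols = {"umap1": norm.obsm["X_umap"][:, 0],
                    "umap2": norm.obsm["X_umap"][:, 1]}
    pd.DataFrame({"nucleus": norm.obs_names, "cluster": clusters, **emb_cols}) \
        .to_csv(out / "clusters.tsv", sep="\t", index=False)

    # ----------------------------------------------------------------- clades
    calls = clades_mod.call_marker_positive(norm, config.clade_thresholds)
    z = clades_mod.cluster_clade_zscores(norm, clusters)
    rnf_z = clades_mod.cluster_clade_zscores(norm, clusters,
                                             markers=("Rnf220",))["Rnf220"]
    clade_map = clades_mod.assign_clades(z, rnf_z)
    props = clades_mod.clade_proportions(
        clusters, clade_map, norm.obs.get("replicate"))
    z.join(clade_map).to_csv(out / "clades.tsv", sep="\t")
    props.to_csv(out / "clade_proportions.tsv", sep="\t")
    manifest["stages"]["clades"] = {
        "n_coexpressing": clades_mod.count_coexpressing(calls),
        "proportions": {str(k): float(v) for k, v in props["mean"].items()},
    }

    # ------------------------------------------------------------ composition
    if "genotype" in norm.obs and norm.obs["genotype"].nunique() == 2:
        comp = pd.crosstab(pd.Series(clusters, name="cluster"),
                           norm.obs["sample"].to_numpy())
        genotypes = norm.obs.groupby("sample", observed=True)["genotype"] \
            .first().astype(str)
        fit = comp_mod.dm_test(comp, genotypes, fdr=config.fdr,
                               n_draws=config.dm_draws,
                               seed=stage_seed(config.seed, "dm"))
        fit.table.to_csv(out / "dm_effects.tsv", sep="\t")
        manifest["stages"]["composition"] = {
            "reference_cluster": str(fit.reference),
            "credible_clusters": [str(c) for c in fit.credible_clusters()],
            "rhat": fit.rhat,
        }

    if truth is not None:
        # selection is scored on its own input (post-QC nuclei); true V1
        # singlets are the positive class, doublets count as negatives
        pool = truth.nuclei.loc[adata.obs_names]
        target = (pool["is_v1"] & ~pool["doublet"]).to_numpy()
        kept = np.zeros(adata.n_obs, dtype=bool)
        kept[adata.obs_names.get_indexer(v1.obs_names)] = True
        tp = int((kept & target).sum())
        manifest["stages"]["ground_truth"] = {
            "v1_precision": tp / max(int(kept.sum()), 1),
            "v1_recall": tp / max(int(target.sum()), 1),
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
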