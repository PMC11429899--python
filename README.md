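# v1atlas

A tested, reusable implementation of a single-nucleus RNA-seq analysis
pipeline for spinal V1 interneurons — the inhibitory interneuron class
defined by developmental expression of the transcription factor En1.
The pipeline covers the full path from raw UMI count matrices to
biological read-outs:

1. **Quality control** — per-nucleus filtering (≥ 1000 UMIs, ≤ 2.5%
   mitochondrial transcripts, within ±3 median absolute deviations of the
   per-sample median UMI and gene counts) and removal of genes detected in
   fewer than 10 nuclei.
2. **Dimensionality reduction and clustering** — log normalization per
   10,000 counts, top-2000 variable genes by a variance-stabilized
   mean–variance trend, PCA with a two-criterion rule (`find_pc`) for the
   number of components, k-NN graph construction and Leiden community
   detection; optional mutual-nearest-neighbor batch alignment and UMAP.
3. **Negative and positive selection** — iterative removal of contaminant
   clusters (oligodendrocytes, astrocytes, microglia, non-V1 neurons)
   flagged by marker-panel z-scores, then retention of nuclei classified
   as V1 by reference-based label transfer with a prediction score.
4. **Clade assignment** — V1 interneurons partition into five largely
   mutually exclusive clades (Foxp2, Sp8, Pou6f2, MafA/Calbindin, Rnf220).
   Per-nucleus marker positivity uses strict log-normalized cutoffs
   (Foxp2 > 2.8, Sp8 > 0.8, Pou6f2 > 2.6, Chrna2 > 1.1 as the MafA proxy);
   clusters are assigned to the marker with the highest positive
   cross-cluster z-score of mean expression.
5. **Compositional analysis** — iLISI mixing scores, normalized
   genotype ratios, and a Bayesian hierarchical Dirichlet-multinomial
   model with spike-and-slab genotype effects and a zero-effect reference
   cluster, testing for credible changes in cluster abundance at a chosen
   expected false discovery rate.
6. **Differential expression** — Wilcoxon rank-sum tests (exact for small
   groups), Bonferroni correction, |log2FC| > 0.25 significance rule;
   pseudo-bulk aggregation with a size-factor + negative-binomial Wald
   contract; cluster dendrograms and correlation structure.
7. **Spatial statistics** — standardized spinal hemisection coordinates
   (650 µm lateral, 400 µm ventral from the central canal), kernel density
   maps, and the Fasano–Franceschini two-dimensional Kolmogorov–Smirnov
   test with a permutation p value.
8. **Physiology** — fictive-locomotion frequency from ventral-root
   recordings (1-s moving mean, periodogram argmax) and joint-angle
   kinematics from nine tracked limb landmarks.

A first-class synthetic-data generator (`v1atlas.simulate`) produces all
inputs with known ground truth — cluster-structured negative-binomial
counts with planted clade markers, contaminant populations, ambient-RNA
admixture, doublets, a genotype-specific cluster depletion, spatial point
sets, rhythmic traces and landmark tracks — so every stage has a
parameter-recovery test surface.

## The compositional model

For sample $s$ with cluster counts $n_s$ and genotype indicator $x_s$:

$$n_s \sim \mathrm{DirichletMultinomial}(\alpha_s), \qquad
\log \alpha_{sk} = \gamma_k + I_k\,\beta_k\,x_s,$$

with $\beta_{\text{ref}} \equiv 0$ for the reference cluster,
$I_k \sim \mathrm{Bernoulli}(\pi)$ spike-and-slab indicators and
$\beta_k \sim \mathcal N(0, \sigma^2)$ slabs. Posterior inference is by
Metropolis-within-Gibbs (exact Gibbs for $I_k$, random-walk Metropolis for
$\gamma, \beta$, a joint concentration-scale move, split-$\hat R$
diagnostics). The credible set at expected FDR $q$ is the largest set of
clusters, in decreasing posterior inclusion probability, whose mean
$(1 - \text{inclusion})$ stays ≤ $q$. Effects are reported as log2 fold
changes.

## Worked example

```python
from v1atlas import qc, select, preprocess, clades
from v1atlas.simulate import default_config, simulate_counts, simulate_reference

adata, truth = simulate_counts(default_config(n_nuclei=4000, n_genes=2000, seed=0))
post = qc.apply_qc(adata)                       # 4000 -> 3577 nuclei
reference = simulate_reference(n_nuclei=3000, n_genes=2000, seed=7)
keep, log, pred = select.select_v1_pipeline(post, reference, seed=0)
print(log[["round", "cluster", "rule", "trigger"]].to_string(index=False))
norm = preprocess.cluster_pipeline(post[keep].copy(), resolution=0.24, seed=0)
z = clades.cluster_clade_zscores(norm, norm.obs["cluster"])
print(clades.assign_clades(z).to_string())
```

prints the negative-selection audit log — each contaminant cluster with
the panel that flagged it —

```
 round cluster  rule         trigger
     1       9 panel oligodendrocyte
     1      10 panel       astrocyte
     1      11 panel   non_v1_neuron
     1      12 panel       microglia
```

and the clade label assigned to every remaining cluster
(`0 Foxp2`, `1 Sp8`, `2 Rnf220`, `3 Pou6f2`, `5 MafA/Calb`, …); clusters
with no positive primary marker z-score and no Rnf220 enrichment stay
`unassigned`. On this fixture the retained set recovers true V1 nuclei
with precision 0.97 and recall 1.00 against the generator's ground truth.

A command-line interface mirrors the library
(`v1atlas simulate|qc|cluster|select|clades|composition|de|spatial|physio|run`);
`v1atlas run` executes the whole pipeline and writes per-stage outputs
plus a `manifest.json` recording parameters, seeds and nucleus counts.

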