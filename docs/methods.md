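# Methods

This note documents the models, parameter choices and numerical
conventions behind `v1atlas`, and what the synthetic-data tests do and do
not demonstrate about real data.

## Synthetic data generator

The generator (`v1atlas.simulate`) emulates a droplet-based single-nucleus
RNA-seq experiment enriched for spinal V1 interneurons.

**Counts.** Each population (six V1 clusters, one per clade, plus four
contaminant classes) has a relative expression profile built from a shared
lognormal baseline with a population-specific "module" of ~12% of genes
perturbed by lognormal factors (σ = 1.8). Counts are negative binomial
(gamma–Poisson) with gene-level dispersion 0.3 — matching the
overdispersion assumed by the downstream Dirichlet-multinomial and NB
tests — and per-nucleus depth drawn lognormally (median ≈ 6,000 UMIs,
σ = 0.5 on the log scale, matching the depth reported for this kind of
experiment), scaled per sample. Marker genes use a lower dispersion
(0.05) so that planted log-normalized means sit reliably above the clade
thresholds; e.g. a Foxp2 mean of 3.5 puts ≥ 90% of that cluster's nuclei
above the 2.8 call threshold.

**Biology vs. sampling.** Profiles are seeded by `profile_seed`,
independent of the sampling seed, so a query dataset and its reference
describe the same underlying cell types while being independent draws —
the property that makes label transfer meaningful.

**Artifacts.** Ambient RNA is binomial thinning of each nucleus's counts
(default 2%, a post-ambient-correction residual level) replaced by draws
from the pooled profile. Doublets (default 5%) add a second random
nucleus's counts to a barcode and are flagged in the ground truth.
A genotype-specific depletion multiplies one cluster's sampling
probability by 2^log2FC (default −log2 3 for the knockout experiment).

**Defaults are the study conditions**: 20,000 nuclei over 8 samples
(2 replicates × P0/P14/P28/P56), 10% contaminants, clade fractions
40/20/12/5/15/8%; for the genotype comparison, 4 samples × 2,000 nuclei,
2 per genotype. The gene count (3,000) is a desk-scale choice: it keeps
every planted structure (markers, modules, mitochondrial mass) while the
full pipeline runs in minutes on one CPU.

**What passing tests do not show.** The generator has no gene–gene
correlation beyond cluster means, no read-level error model, no realistic
batch nonlinearity, and cluster separations are cleaner than real
development-spanning data; recovery rates here are upper bounds on what
the same pipeline achieves on real tissue.

## Quality control

Fixed cuts first (UMIs ≥ 1000, mitochondrial fraction ≤ 0.025), then
per-sample ±3 MAD fences on raw UMI and detected-gene counts. The MAD is
unscaled (no 1.4826 factor) — the fences are conventions, both the scale
and `n_mads` are configurable. The upper UMI fence doubles as the doublet
handler; no separate doublet detector is used. Genes in fewer than 10
nuclei are dropped. The all-zero nucleus has mitochondrial fraction 0 by
convention (removed by the UMI cut regardless). Note the MAD fence is not
idempotent under re-application: trimming a sample narrows its recomputed
fence. Metrics always refer to the matrix they were computed from.

## Normalization, PCA, clustering

Log normalization is ln(1 + 10⁴·c/total) (natural log; base
configurable). Variable genes are ranked by variance-stabilized
standardized variance: a lowess trend of log10 variance on log10 mean
predicts each gene's expected sd; standardized counts are clipped at √N
and re-variance'd. `find_pc` combines two criteria on the percent
variance per component: (A) first k with cumulative > 90% and own < 5%;
(B) one past the last drop > 0.1 points; the smaller wins and both values
are reported. Clustering is Leiden (RBConfiguration, seeded, 2
iterations) on the symmetrized k = 20 nearest-neighbor graph over the
`find_pc` components. Batch alignment is a pluggable contract — aligned
replicates must intermix at least as well as unaligned — with a
mutual-nearest-neighbor mean-shift correction in PC space as default; it
removes translation-like batch effects and is not a substitute for
anchor-based integration of strongly nonlinear batches.

## Selection

Negative selection iterates: normalize → reduce → cluster (resolution 1.0
so contaminant populations stay split) → flag clusters with any panel
z-score > 2 across clusters *and* panel mean expression > 0.1 (the
absolute guard keeps relative enrichment of an unexpressed panel from
flagging anything) or with median QC metrics breaching the fences →
remove. It stops when nothing is flagged (≤ 10 rounds) and logs every
removal with its trigger. Positive selection projects the query into the
reference's PCA (reference gene means/scales and loadings), scores each
nucleus by Gaussian-kernel-weighted label fractions among k = 30 nearest
reference cells (bandwidth = mean neighbor distance; exact matches take
all weight; ties broken lexicographically), and keeps nuclei whose argmax
label is V1 with score ≥ 0.5. Scores are exactly normalized probability
vectors.

## Clades

Per-nucleus positivity is a strict inequality on merged (not
batch-corrected) log-normalized expression: Foxp2 > 2.8, Sp8 > 0.8,
Pou6f2 > 2.6, Chrna2 > 1.1 (Chrna2 proxies the MafA/Calbindin clade;
Calb1 is a display marker only). Cluster assignment z-scores the
per-cluster mean of each marker across clusters (sd with ddof = 1) and
takes the highest positive z; clusters with none fall to Rnf220 when its
z is positive, else `unassigned` — in the default synthetic data the
Nr5a2 cluster lands there by construction, since Nr5a2 is not a primary
clade marker. Proportions are per replicate and sum to 1 exactly.

## Compositional model

Counts per sample are Dirichlet-multinomial; log α is a cluster intercept
plus a genotype effect gated by a Bernoulli spike-and-slab indicator
(prior inclusion 0.1, slab sd 2 on the natural-log scale, intercept sd
10); the reference cluster's effect is fixed at zero. The reference is
chosen among clusters at or above median abundance by smallest
between-genotype change, then least dispersion, then lowest id. Inference
is Metropolis-within-Gibbs: random-walk updates for intercepts and active
effects (step sizes adapted only during burn-in), a joint shift of all
intercepts (the overall concentration is weakly identified and mixes
slowly coordinate-wise), exact Gibbs for the indicators with excluded
effects refreshed from the slab prior. Defaults: 4 chains × 2000 draws
after 1000 burn-in; split-R̂ over the log posterior and reference
intercept must be ≤ 1.05 or the fit errors. The credible set at expected
FDR q is the largest inclusion-ordered prefix with mean
(1 − inclusion) ≤ q. Effects are posterior means of indicator × effect on
the log2 scale, with 95% intervals over included draws.

## Differential expression

The rank-sum test enumerates all C(n, n₁) rank assignments (midranks for
ties) when the smaller group has ≤ 8 observations — the two-sided p is
the fraction of assignments at least as far from the null mean as
observed — and otherwise uses the tie-corrected normal approximation
without continuity correction. log2FC = log2((mean(expm1 a)+1) /
(mean(expm1 b)+1)); significance needs Bonferroni-adjusted p < 0.05 and
|log2FC| strictly > 0.25. No min-expression prefilter is applied by
default. Age contrasts are P0 vs rest and P28+P56 vs rest, keeping
positively enriched genes. Pseudo-bulk sums raw counts exactly;
pseudo-bulk DE is deliberately minimal: median-of-ratios size factors,
per-gene method-of-moments NB dispersion floored at 1e-8, NB GLM Wald
test, Benjamini–Hochberg — a count-based contract, not a port of a full
bulk pipeline (no dispersion shrinkage, so it is noisier at 2 vs 2
replicates). Cluster trees are average-linkage on Euclidean distances
between cluster means in PC space; correlations are Pearson on full
log-normalized cluster means.

## Spatial statistics

Positions are standardized per section: x′ = x·650/L, y′ = y·400/V (µm
from the central canal; the single ventral factor V also scales dorsal
points, which have no standardized bound of their own). Densities are
Gaussian KDE with Scott's rule. The two-sample comparison is the
Fasano–Franceschini statistic — with each sample's points as origins, the
maximum over open quadrants of the absolute difference in empirical
fractions, averaged over the two per-sample maxima — with a seeded
label-permutation p, p = (1 + #{D ≥ D_obs})/(n_perm + 1), default
n_perm = 1000. Sections are pooled by default.

**Conservatism.** Quadrant fractions are multiples of 1/n, so D is
discrete; permutations tied with the observed value must count as extreme
for the p to be valid, and that atom mass makes the test conservative at
small n (measured null rejection ≈ 0.026–0.030 at α = 0.05 with n = 50
per sample). The test never over-rejects; users should expect slightly
sub-nominal size rather than exact uniformity.

## Physiology

Traces are smoothed with a centered moving mean of 10,000 points (1 s at
10 kHz), truncated to valid support; the locomotor frequency is the
argmax of the plain (untapered) periodogram excluding the zero bin, with
resolution fs/n (1/60 Hz for 60-s records). Joint angles are the arccos
of the normalized dot product of the two arm vectors at the vertex
(ankle: hindpaw/knee; knee: ankle/groin; wrist: forepaw/elbow; elbow:
wrist/armpit), invariant to rigid transforms and uniform scaling; frames
with coincident landmarks are NaN-flagged. Frame selection requires all
nine landmark confidences ≥ 0.9 and no overlap with user-supplied
exclusion intervals (the stand-in for manual annotation of turning or
flipping). Summaries are per-animal means, then group mean ± SEM across
animals.

## Orchestration and determinism

`run_pipeline` executes simulate/load → QC → selection → clustering →
clades → (composition when two genotypes are present), writing per-stage
TSVs and a JSON manifest with parameters and per-stage nucleus counts.
Every stochastic stage derives its seed from the top-level seed XOR'd
with a CRC32 of the stage name (kept below 2³¹), so equal configurations
reproduce bit-identical results wherever determinism is claimed (MCMC
reproduces exactly for a fixed seed; doubling draws leaves the credible
set unchanged on the recovery fixture).

## Problem sizes used in tests

Unit tests run on 4,000-nucleus fixtures; the acceptance tests use the
full default conditions (20,000 nuclei for selection and clades, 100
calibration replicates for the compositional null, 500 for the 2-D KS
null, 50 for frequency recovery). These sizes were chosen so the entire
suite completes in well under half an hour on a single CPU while keeping
every statistical check at the scale its tolerance assumes.
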