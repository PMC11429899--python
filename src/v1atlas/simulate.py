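"""Synthetic data generation with known ground truth.

Every downstream stage of the pipeline (QC, clustering, negative/positive
selection, clade calling, compositional testing, spatial statistics,
physiology) is exercised against data produced here, where the true cluster,
clade, contamination status and composition of every nucleus are known by
construction.

The count generator emulates the statistical structure of a droplet-based
single-nucleus RNA-seq experiment enriched for spinal V1 interneurons:

* cluster-structured negative-binomial UMI counts with per-nucleus depth
  variation and per-sample depth scaling,
* planted clade-marker genes (Foxp2, Sp8, Pou6f2, Chrna2, Rnf220, Nr5a2)
  whose log-normalized means sit above the clade-calling thresholds,
* contaminant populations (oligodendrocytes, astrocytes, microglia,
  non-V1 neurons) carrying their own marker panels,
* ambient-RNA admixture from the pooled profile, doublets as sums of two
  nucleus profiles, and an optional genotype-specific depletion of one
  cluster (the En1-knockout phenotype).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ClusterSpec",
    "SampleSpec",
    "ContaminantSpec",
    "DepletionSpec",
    "SimConfig",
    "GroundTruth",
    "default_config",
    "en1_experiment_config",
    "simulate_counts",
    "simulate_composition",
    "simulate_reference",
    "simulate_positions",
    "simulate_root_trace",
    "simulate_landmarks",
    "HEMISECTION_LATERAL_UM",
    "HEMISECTION_VENTRAL_UM",
    "LANDMARKS",
]

# Standardized hemisection bounds (um from the central canal).
HEMISECTION_LATERAL_UM = 650.0
HEMISECTION_VENTRAL_UM = 400.0

LANDMARKS = (
    "forepaw", "wrist", "elbow", "armpit",
    "hindpaw", "ankle", "knee", "groin", "anus",
)

#: marker gene -> (clade, planted log-normalized mean in expressing clusters)
CLADE_MARKER_MAP = {
    "Foxp2": ("Foxp2", 3.5),
    "Sp8": ("Sp8", 1.5),
    "Pou6f2": ("Pou6f2", 3.2),
    "Chrna2": ("MafA/Calb", 1.8),
    "Rnf220": ("Rnf220", 2.5),
    "Nr5a2": ("Nr5a2", 2.5),
}

#: contaminant panel name -> marker genes (illustrative panels; the field's
#: canonical cell-class markers, not a published table)
CONTAMINANT_PANELS = {
    "oligodendrocyte": ["Plp1", "Mbp", "Mog", "Sox10"],
    "astrocyte": ["Aqp4", "Gfap", "Slc1a3"],
    "microglia": ["C1qa", "C1qb", "Cx3cr1"],
    "non_v1_neuron": ["Chat", "Isl1", "Vsx2", "Slc17a6"],
}

MITO_GENES = ["mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp6",
              "mt-Co3", "mt-Nd4", "mt-Cytb"]


@dataclass
class ClusterSpec:
    """One planted V1 cluster: its clade and its share of the V1 pool."""

    name: str
    fraction: float
    clade: str


@dataclass
class SampleSpec:
    name: str
    age: str
    genotype: str = "WT"
    replicate: int = 1
    depth_scale: float = 1.0


@dataclass
class ContaminantSpec:
    panel: str
    genes: list
    fraction: float


@dataclass
class DepletionSpec:
    """Multiply one cluster's sampling probability by 2**log2fc in a genotype."""

    cluster: str
    genotype: str
    log2fc: float


@dataclass
class SimConfig:
    n_nuclei: int = 20_000
    n_genes: int = 3_000
    clusters: list = field(default_factory=list)
    contaminants: list = field(default_factory=list)
    samples: list = field(default_factory=list)
    depletion: DepletionSpec | None = None
    ambient_fraction: float = 0.02
    doublet_rate: float = 0.05
    mean_depth: float = 6_000.0
    dispersion: float = 0.3
    marker_dispersion: float = 0.05
    mito_fraction: float = 0.01
    seed: int = 0
    #: seeds the cell-type expression profiles themselves; shared between a
    #: query and its reference so both describe the same underlying biology
    profile_seed: int = 0

    def validate(self) -> None:
        v1_frac = sum(c.fraction for c in self.clusters)
        cont_frac = sum(c.fraction for c in self.contaminants)
        if not self.clusters:
            raise ValueError("at least one V1 cluster is required")
        if not math.isclose(v1_frac, 1.0, abs_tol=1e-6):
            raise ValueError(f"V1 cluster fractions must sum to 1, got {v1_frac}")
        if cont_frac >= 1.0:
            raise ValueError(f"contaminant fractions must sum to < 1, got {cont_frac}")
        if not 0 <= self.ambient_fraction < 1:
            raise ValueError("ambient_fraction must be in [0, 1)")
        if not 0 <= self.doublet_rate < 1:
            raise ValueError("doublet_rate must be in [0, 1)")
        for s in self.samples:
            if s.depth_scale <= 0:
                raise ValueError("depth_scale must be > 0")


@dataclass
class GroundTruth:
    """Per-nucleus true labels and realized composition.

    ``nuclei`` has one row per barcode: population (cluster or contaminant
    panel), clade (NA for contaminants), sample, contaminant and doublet
    flags.  ``composition`` is the realized cluster x sample count table;
    its column sums equal the per-sample nucleus counts exactly because
    labels are assigned, not inferred.
    """

    nuclei: pd.DataFrame
    composition: pd.DataFrame


def _default_clusters() -> list:
    # One cluster per clade; fractions follow the clade proportions measured
    # in the postnatal V1 atlas (Foxp2 largest, MafA/Calb smallest).
    return [
        ClusterSpec("V1_Foxp2", 0.40, "Foxp2"),
        ClusterSpec("V1_Sp8", 0.20, "Sp8"),
        ClusterSpec("V1_Pou6f2", 0.12, "Pou6f2"),
        ClusterSpec("V1_MafA", 0.05, "MafA/Calb"),
        ClusterSpec("V1_Rnf220", 0.15, "Rnf220"),
        ClusterSpec("V1_Nr5a2", 0.08, "Nr5a2"),
    ]


def _default_contaminants(total: float = 0.10) -> list:
    weights = {"oligodendrocyte": 0.4, "astrocyte": 0.3,
               "microglia": 0.15, "non_v1_neuron": 0.15}
    return [ContaminantSpec(p, CONTAMINANT_PANELS[p], total * w)
            for p, w in weights.items()]


def _default_samples() -> list:
    out = []
    for age in ("P0", "P14", "P28", "P56"):
        for rep in (1, 2):
            out.append(SampleSpec(f"{age}R{rep}", age, "WT", rep, 1.0))
    return out


def default_config(n_nuclei: int = 20_000, n_genes: int = 3_000,
                   contaminant_fraction: float = 0.10,
                   doublet_rate: float = 0.05, seed: int = 0,
                   **kwargs) -> SimConfig:
    """The postnatal-atlas study conditions: 8 samples (2 replicates at each
    of P0/P14/P28/P56), six planted V1 clusters, 10% contaminants."""
    return SimConfig(
        n_nuclei=n_nuclei,
        n_genes=n_genes,
        clusters=_default_clusters(),
        contaminants=_default_contaminants(contaminant_fraction),
        samples=_default_samples(),
        doublet_rate=doublet_rate,
        seed=seed,
        **kwargs,
    )


def en1_experiment_config(n_per_sample: int = 2_000, n_genes: int = 3_000,
                          log2fc: float = -math.log2(3.0), seed: int = 0,
                          depleted_cluster: str = "V1_Nr5a2",
                          **kwargs) -> SimConfig:
    """Genotype-comparison conditions: 4 P0 samples (2 Het, 2 KO), one small
    cluster depleted in the KO genotype (default 3-fold)."""
    samples = [
        SampleSpec("HetR1", "P0", "Het", 1, 1.0),
        SampleSpec("HetR2", "P0", "Het", 2, 1.0),
        SampleSpec("KoR1", "P0", "KO", 1, 1.0),
        SampleSpec("KoR2", "P0", "KO", 2, 1.0),
    ]
    depletion = None
    if log2fc != 0:
        depletion = DepletionSpec(depleted_cluster, "KO", log2fc)
    return SimConfig(
        n_nuclei=n_per_sample * len(samples),
        n_genes=n_genes,
        clusters=_default_clusters(),
        contaminants=[],
        samples=samples,
        depletion=depletion,
        doublet_rate=0.0,
        ambient_fraction=0.0,
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def _gene_names(config: SimConfig) -> list:
    special = (list(CLADE_MARKER_MAP) + ["Calb1"]
               + [g for p in config.contaminants for g in p.genes]
               + MITO_GENES)
    # preserve order, drop duplicates
    special = list(dict.fromkeys(special))
    n_filler = config.n_genes - len(special)
    if n_filler < 0:
        raise ValueError("n_genes too small to hold the marker genes")
    filler = [f"Gene{i:04d}" for i in range(n_filler)]
    return special + filler


def _population_profiles(config: SimConfig, genes: list,
                         rng: np.random.Generator) -> dict:
    """Relative expression profile (sums to 1) per population.

    A shared baseline profile is perturbed per population by lognormal
    factors on a random subset of "module" genes, then the population's
    marker genes are planted at relative abundances chosen so the expected
    log-normalized expression hits the configured target.
    """
    n_genes = len(genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    baseline = rng.lognormal(mean=0.0, sigma=1.6, size=n_genes)
    # markers start near zero everywhere; planted only where intended
    special = set(CLADE_MARKER_MAP) | {"Calb1"} | {
        g for p in CONTAMINANT_PANELS.values() for g in p}
    for g in special:
        if g in gene_idx:
            baseline[gene_idx[g]] = 1e-3
    mito_idx = [gene_idx[g] for g in MITO_GENES if g in gene_idx]

    profiles = {}

    def _finalize(prof, planted):
        prof = prof / prof.sum()
        # mitochondrial mass fixed to the configured fraction
        prof[mito_idx] = 0.0
        prof *= (1.0 - config.mito_fraction) / prof.sum()
        prof[mito_idx] = config.mito_fraction / max(len(mito_idx), 1)
        # plant markers last so their relative abundance is exact
        for g, target in planted.items():
            rel = (math.expm1(target)) / 1e4
            i = gene_idx[g]
            other = 1.0 - prof[i]
            prof *= (1.0 - rel) / other
            prof[i] = rel
        return prof / prof.sum()

    for cl in config.clusters:
        n_module = max(100, n_genes // 8)
        module = rng.choice(n_genes, size=n_module, replace=False)
        prof = baseline.copy()
        prof[module] *= rng.lognormal(mean=0.0, sigma=1.8, size=n_module)
        planted = {}
        for marker, (clade, level) in CLADE_MARKER_MAP.items():
            if clade == cl.clade:
                planted[marker] = level
        if cl.clade == "MafA/Calb" and "Calb1" in gene_idx:
            planted["Calb1"] = 2.0  # display proxy marker
        profiles[cl.name] = _finalize(prof, planted)

    for cont in config.contaminants:
        n_module = max(100, n_genes // 8)
        module = rng.choice(n_genes, size=n_module, replace=False)
        prof = baseline.copy()
        prof[module] *= rng.lognormal(mean=0.0, sigma=1.8, size=n_module)
        planted = {g: 3.0 for g in cont.genes if g in gene_idx}
        profiles[cont.panel] = _finalize(prof, planted)

    return profiles


def _nb_counts(mu: np.ndarray, dispersion: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu**2."""
    r = 1.0 / np.maximum(dispersion, 1e-12)
    lam = rng.gamma(shape=r, scale=mu / r)
    return rng.poisson(lam)



def _assign_labels(config: SimConfig, samples, rng) -> tuple:
    """Assign each nucleus a sample and a true population label."""
    n = config.n_nuclei
    sample_of = np.repeat(np.arange(len(samples)), n // len(samples))
    if sample_of.size < n:
        sample_of = np.concatenate(
            [sample_of, rng.integers(0, len(samples), n - sample_of.size)])

    pop_names = [c.name for c in config.clusters] + \
                [c.panel for c in config.contaminants]
    cont_total = sum(c.fraction for c in config.contaminants)
    base_probs = np.array(
        [c.fraction * (1 - cont_total) for c in config.clusters]
        + [c.fraction for c in config.contaminants])

    pop_of = np.empty(n, dtype=int)
    for si, s in enumerate(samples):
        probs = base_probs.copy()
        if config.depletion is not None and s.genotype == config.depletion.genotype:
            di = pop_names.index(config.depletion.cluster)
            probs[di] *= 2.0 ** config.depletion.log2fc
        probs /= probs.sum()
        mask = sample_of == si
        pop_of[mask] = rng.choice(len(pop_names), size=mask.sum(), p=probs)
    return sample_of, pop_of, pop_names


def simulate_composition(config: SimConfig) -> pd.DataFrame:
    """Draw only the cluster x sample composition table (no gene counts).

    Uses the same label-assignment law as :func:`simulate_counts`; useful
    for calibration studies of the compositional test where the expression
    matrix is irrelevant.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = config.samples or [SampleSpec("S1", "P0")]
    sample_of, pop_of, pop_names = _assign_labels(config, samples, rng)
    df = pd.DataFrame({
        "population": pd.Categorical([pop_names[i] for i in pop_of],
                                     categories=pop_names),
        "sample": pd.Categorical([samples[i].name for i in sample_of],
                                 categories=[s.name for s in samples]),
    })
    return (df.groupby(["population", "sample"], observed=False)
            .size().unstack(fill_value=0))


def simulate_counts(config: SimConfig) -> tuple:
    """Simulate a raw UMI count matrix with ground truth.

    Returns an :class:`anndata.AnnData` (nuclei x genes, sparse integer
    counts, per-nucleus sample/age/genotype/replicate metadata) and a
    :class:`GroundTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config)
    profiles = _population_profiles(
        config, genes, np.random.default_rng(config.profile_seed))

    samples = config.samples or [SampleSpec("S1", "P0")]
    sample_of, pop_of, pop_names = _assign_labels(config, samples, rng)
    n = config.n_nuclei

    depth_scale = np.array([s.depth_scale for s in samples])[sample_of]
    depths = rng.lognormal(mean=np.log(config.mean_depth) - 0.125,
                           sigma=0.5, size=n) * depth_scale

    gene_idx = {g: i for i, g in enumerate(genes)}
    marker_cols = np.array(sorted(
        gene_idx[g] for g in
        set(CLADE_MARKER_MAP) | {"Calb1"} |
        {g for p in config.contaminants for g in p.genes if g in gene_idx}))
    disp = np.full(len(genes), config.dispersion)
    if marker_cols.size:
        disp[marker_cols] = config.marker_dispersion

    X = np.zeros((n, len(genes)), dtype=np.int64)
    chunk = 2_000
    for pi, pname in enumerate(pop_names):
        idx = np.flatnonzero(pop_of == pi)
        prof = profiles[pname]
        for start in range(0, idx.size, chunk):
            rows = idx[start:start + chunk]
            mu = depths[rows, None] * prof[None, :]
            X[rows] = _nb_counts(mu, disp[None, :], rng)

    # ambient admixture: binomial thinning + pooled-profile replacement
    if config.ambient_fraction > 0:
        pooled = X.sum(axis=0).astype(float)
        pooled /= pooled.sum()
        removed = X - rng.binomial(X, 1.0 - config.ambient_fraction)
        X -= removed
        add_tot = removed.sum(axis=1)
        for start in range(0, n, chunk):
            sl = slice(start, min(start + chunk, n))
            X[sl] += rng.multinomial(add_tot[sl], pooled)

    # doublets: a fraction of barcodes receive a second nucleus's counts
    doublet = np.zeros(n, dtype=bool)
    if config.doublet_rate > 0:
        n_dbl = int(round(config.doublet_rate * n))
        hosts = rng.choice(n, size=n_dbl, replace=False)
        partners = rng.integers(0, n, size=n_dbl)
        X[hosts] += X[partners]
        doublet[hosts] = True

    obs = pd.DataFrame({
        "sample": pd.Categorical([samples[i].name for i in sample_of]),
        "age": pd.Categorical([samples[i].age for i in sample_of]),
        "genotype": pd.Categorical([samples[i].genotype for i in sample_of]),
        "replicate": [samples[i].replicate for i in sample_of],
    }, index=[f"nucleus_{i:06d}" for i in range(n)])

    adata = ad.AnnData(X=sp.csr_matrix(X), obs=obs,
                       var=pd.DataFrame(index=genes))

    clade_of = {c.name: c.clade for c in config.clusters}
    truth_df = pd.DataFrame({
        "population": [pop_names[i] for i in pop_of],
        "clade": [clade_of.get(pop_names[i], pd.NA) for i in pop_of],
        "sample": obs["sample"].to_numpy(),
        "contaminant": pop_of >= len(config.clusters),
        "doublet": doublet,
    }, index=obs.index)
    truth_df["is_v1"] = ~truth_df["contaminant"]

    composition = (truth_df.groupby(["population", "sample"], observed=False)
                   .size().unstack(fill_value=0))
    return adata, GroundTruth(nuclei=truth_df, composition=composition)


def simulate_reference(n_nuclei: int = 4_000, n_genes: int = 3_000,
                       v1_fraction: float = 0.35, seed: int = 0) -> ad.AnnData:
    """A synthetic stand-in for the embryonic whole-spinal-cord reference
    used for positive selection (label transfer).

    V1 nuclei are generated from the same clade-structured profiles as the
    query generator; the remaining classes reuse the contaminant profiles
    under neuronal/glial class labels.  Returns an AnnData with an
    ``obs["class_label"]`` column in which the target class is ``"V1"``.
    """
    cfg = default_config(n_nuclei=n_nuclei, n_genes=n_genes,
                         contaminant_fraction=1.0 - v1_fraction,
                         doublet_rate=0.0, seed=seed,
                         ambient_fraction=0.0)
    cfg.samples = [SampleSpec("E13", "E13", "WT", 1, 1.0)]
    adata, truth = simulate_counts(cfg)
    label = np.where(truth.nuclei["contaminant"], truth.nuclei["population"], "V1")
    adata.obs["class_label"] = pd.Categorical(label)
    return adata


# ---------------------------------------------------------------------------
# spatial positions
# ---------------------------------------------------------------------------

def simulate_positions(clade_fractions: dict, density_params: dict,
                       n: int, seed: int = 0,
                       dorsal_bound: float = HEMISECTION_VENTRAL_UM) -> pd.DataFrame:
    """Sample per-neuron (x, y) positions in the standardized hemisection.

    ``density_params[clade]`` is a list of Gaussian-mixture components
    ``(weight, (mx, my), (sx, sy))``; points are rejection-sampled into
    x in [0, 650], y in [-400, dorsal_bound] um.  Returns a DataFrame with
    columns x_um, y_um, clade.
    """
    rng = np.random.default_rng(seed)
    clades = list(clade_fractions)
    fracs = np.array([clade_fractions[c] for c in clades], dtype=float)
    if n == 0:
        return pd.DataFrame(columns=["x_um", "y_um", "clade"])
    fracs = fracs / fracs.sum()
    labels = rng.choice(len(clades), size=n, p=fracs)
    xs = np.empty(n)
    ys = np.empty(n)
    for i, li in enumerate(labels):
        comps = density_params[clades[li]]
        w = np.array([c[0] for c in comps], dtype=float)
        w /= w.sum()
        for _ in range(10_000):
            ci = rng.choice(len(comps), p=w)
            _, (mx, my), (sx, sy) = comps[ci]
            x = mx + sx * rng.standard_normal()
            y = my + sy * rng.standard_normal()
            if 0 <= x <= HEMISECTION_LATERAL_UM and -HEMISECTION_VENTRAL_UM <= y <= dorsal_bound:
                xs[i], ys[i] = x, y
                break
        else:  # pragma: no cover - pathological component far outside bounds
            raise RuntimeError("rejection sampling failed; component outside hemisection")
    return pd.DataFrame({"x_um": xs, "y_um": ys,
                         "clade": [clades[i] for i in labels]})


# ---------------------------------------------------------------------------
# ventral-root traces
# ---------------------------------------------------------------------------

def simulate_root_trace(freq_hz: float, fs_hz: float = 10_000.0,
                        duration_s: float = 60.0, burst_shape: str = "burst",
                        noise_sd: float = 0.5, seed: int = 0) -> pd.DataFrame:
    """Rhythmic ventral-root-like trace: periodic bursting envelope at
    ``freq_hz`` plus broadband Gaussian noise.

    ``burst_shape`` is ``"sinusoid"`` (pure tone) or ``"burst"`` (sharpened
    raised-cosine envelope, closer to rectified electroneurogram bursts).
    Returns a DataFrame with columns time_s, value.
    """
    if freq_hz <= 0 or freq_hz >= fs_hz / 2:
        raise ValueError(f"freq_hz must lie in (0, Nyquist={fs_hz / 2})")
    n = int(round(fs_hz * duration_s))
    t = np.arange(n) / fs_hz
    if burst_shape == "sinusoid":
        signal = np.sin(2 * np.pi * freq_hz * t)
    elif burst_shape == "burst":
        envelope = (0.5 * (1 + np.cos(2 * np.pi * freq_hz * t))) ** 3
        signal = envelope
    else:
        raise ValueError(f"unknown burst_shape {burst_shape!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + noise_sd * rng.standard_normal(n)
    return pd.DataFrame({"time_s": t, "value": signal})


# ---------------------------------------------------------------------------
# limb landmarks
# ---------------------------------------------------------------------------

def _rot(v: np.ndarray, theta: np.ndarray) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.stack([c * v[..., 0] - s * v[..., 1],
                     c * v[..., 1] + s * v[..., 0]], axis=-1)


def simulate_landmarks(angles_deg: dict, segment_lengths: dict | None = None,
                       noise_sd: float = 0.0, seed: int = 0,
                       frame_rate: float = 200.0) -> pd.DataFrame:
    """Place the nine tracked landmarks per frame by forward kinematics.

    ``angles_deg`` maps joints ({'knee', 'ankle', 'elbow', 'wrist'}) to
    per-frame interior-angle series in (0, 180) degrees.  The hindlimb chain
    groin -> knee -> ankle -> hindpaw and forelimb chain armpit -> elbow ->
    wrist -> forepaw are built so that the recomputed joint angles equal the
    planted series exactly before noise.  Returns a long DataFrame with
    columns frame, landmark, x, y, confidence.
    """
    lengths = {"thigh": 10.0, "shank": 9.0, "foot": 5.0,
               "upper_arm": 8.0, "forearm": 7.0, "hand": 4.0}
    if segment_lengths:
        lengths.update(segment_lengths)
    for k, v in lengths.items():
        if v <= 0:
            raise ValueError(f"segment length {k!r} must be > 0")

    series = {j: np.atleast_1d(np.asarray(a, dtype=float))
              for j, a in angles_deg.items()}
    n_frames = max(len(a) for a in series.values())
    for j, a in series.items():
        if len(a) == 1:
            series[j] = np.full(n_frames, a[0])
        elif len(a) != n_frames:
            raise ValueError("angle series lengths differ")
        if np.any((series[j] <= 0) | (series[j] >= 180)):
            raise ValueError(f"{j} angles must lie in (0, 180) degrees")

    def chain(root, seg1, seg2, seg3, joint_a, joint_b, start_dir_deg):
        """root -> A (planted angle joint_a) -> B (planted angle joint_b) -> tip."""
        a = np.deg2rad(series.get(joint_a, np.full(n_frames, 150.0)))
        b = np.deg2rad(series.get(joint_b, np.full(n_frames, 150.0)))
        d0 = np.deg2rad(start_dir_deg)
        dir1 = np.stack([np.full(n_frames, np.cos(d0)),
                         np.full(n_frames, np.sin(d0))], axis=-1)
        p_root = np.broadcast_to(np.asarray(root, dtype=float), (n_frames, 2))
        p1 = p_root + lengths[seg1] * dir1
        # interior angle alpha at a joint: outgoing = incoming rotated by pi - alpha
        dir2 = _rot(dir1, np.pi - a)
        p2 = p1 + lengths[seg2] * dir2
        dir3 = _rot(dir2, np.pi - b)
        p3 = p2 + lengths[seg3] * dir3
        return p_root, p1, p2, p3

    groin, knee, ankle, hindpaw = chain(
        (0.0, 0.0), "thigh", "shank", "foot", "knee", "ankle", -60.0)
    armpit, elbow, wrist, forepaw = chain(
        (0.0, 30.0), "upper_arm", "forearm", "hand", "elbow", "wrist", -120.0)
    anus = np.broadcast_to(np.array([-5.0, -2.0]), (n_frames, 2))

    coords = {"groin": groin, "knee": knee, "ankle": ankle, "hindpaw": hindpaw,
              "armpit": armpit, "elbow": elbow, "wrist": wrist,
              "forepaw": forepaw, "anus": anus}
    rng = np.random.default_rng(seed)
    rows = []
    for name in LANDMARKS:
        xy = np.array(coords[name], dtype=float)
        if noise_sd > 0:
            xy = xy + noise_sd * rng.standard_normal(xy.shape)
        rows.append(pd.DataFrame({
            "frame": np.arange(n_frames),
            "landmark": name,
            "x": xy[:, 0], "y": xy[:, 1],
            "confidence": 1.0,
        }))
    out = pd.concat(rows, ignore_index=True)
    out.attrs["frame_rate"] = frame_rate
    return out
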