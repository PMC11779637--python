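"""Synthetic cohorts with known ground truth for every pipeline stage.

Every generator draws from a dedicated RNG stream derived from one global
seed (see :mod:`locusevo._rng`), so a fixed seed yields bitwise-identical
output and adding a generator never perturbs the others.  Ground truth is
returned alongside the data and serializes losslessly to JSON.

The generators emulate the input shapes of a multi-cohort Barrett's
esophagus / esophageal adenocarcinoma study: somatic variant + copy-number +
purity tables with planted clonal structure, progression cohorts with
genotype-dependent odds, bulk count matrices with TF-driven modules chained
to a binary loss-of-function marker, survival tables with group-specific
hazards, and segmented-cell tables with planted phenotype fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ._rng import child_rng
from .clonality import expected_vaf
from .phenotype import DEFAULT_PRIORITY

# hg38-like coordinates of the 9p21 panel plus TP53
DEFAULT_GENE_PANEL = (
    {"gene": "KLHL9", "chrom": "chr9", "start": 21_331_510, "end": 21_335_932},
    {"gene": "IFNE", "chrom": "chr9", "start": 21_480_839, "end": 21_482_314},
    {"gene": "MTAP", "chrom": "chr9", "start": 21_802_635, "end": 21_937_651},
    {"gene": "CDKN2A", "chrom": "chr9", "start": 21_967_752, "end": 21_995_043},
    {"gene": "CDKN2B", "chrom": "chr9", "start": 22_002_903, "end": 22_009_313},
    {"gene": "DMRTA1", "chrom": "chr9", "start": 22_446_839, "end": 22_452_472},
    {"gene": "TP53", "chrom": "chr17", "start": 7_668_421, "end": 7_687_490},
)

# intended per-gene damage-class frequencies; free parameters of the stated
# world (the study prints no per-class counts), chosen once as plausible for
# an EAC-like cohort where CDKN2A loss is common
DEFAULT_DAMAGE_PROBS = {
    "CDKN2A": {"hom_del": 0.25, "damaging_mutation": 0.15, "double_hit": 0.10,
               "het_del": 0.10, "wild_type": 0.40},
    "TP53": {"damaging_mutation": 0.50, "double_hit": 0.10, "hom_del": 0.05,
             "wild_type": 0.35},
    "MTAP": {"hom_del": 0.20, "het_del": 0.10, "wild_type": 0.70},
    "CDKN2B": {"hom_del": 0.20, "het_del": 0.10, "wild_type": 0.70},
    "KLHL9": {"hom_del": 0.10, "wild_type": 0.90},
    "IFNE": {"hom_del": 0.10, "wild_type": 0.90},
    "DMRTA1": {"hom_del": 0.10, "wild_type": 0.90},
}


@dataclass
class SimConfig:
    """Stated world of the tumor-genome generator."""

    seed: int = 0
    n_samples: int = 50
    depth_mean: float = 100.0
    purity_range: tuple = (0.5, 0.95)
    gene_panel: tuple = DEFAULT_GENE_PANEL
    damage_probs: dict = field(default_factory=lambda: {
        g: dict(v) for g, v in DEFAULT_DAMAGE_PROBS.items()})
    mutation_ccfs: dict = field(default_factory=dict)  # gene -> true CCF, default 1.0
    ploidy: float = 2.0

    def __post_init__(self):
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError(f"purity_range must lie in (0, 1], got {self.purity_range}")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")
        if self.n_samples < 0:
            raise ValueError("n_samples must be non-negative")


def _draw_class(rng, probs: dict) -> str:
    names = sorted(probs)
    p = np.array([probs[k] for k in names], dtype=float)
    return names[rng.choice(len(names), p=p / p.sum())]


def simulate_tumor_genomes(config: SimConfig):
    """Variant, CNA-segment and purity/ploidy tables with planted damage
    classes and clonal structure.

    Each planted mutation's alt-read count is Binomial(depth, E[VAF]) at its
    true CCF given the sample's purity and the local copy number; CNA
    segments cover the full span of deleted/amplified genes.  Returns
    (variants, segments, purity_table, truth).
    """
    rng = child_rng(config.seed, "tumor_genomes")
    variants, segments, purities = [], [], []
    truth = {"mutations": [], "damage": {}, "config_seed": config.seed}

    for i in range(config.n_samples):
        sample = f"S{i + 1:04d}"
        purity = float(rng.uniform(*config.purity_range))
        purities.append({"sample": sample, "purity": purity, "ploidy": config.ploidy})
        truth["damage"][sample] = {}
        for gene in config.gene_panel:
            name = gene["gene"]
            probs = config.damage_probs.get(name, {"wild_type": 1.0})
            klass = _draw_class(rng, probs)
            truth["damage"][sample][name] = klass

            if klass in ("hom_del", "het_del", "double_hit", "amplified"):
                cn = {"hom_del": 0, "het_del": 1, "double_hit": 1,
                      "amplified": int(2 * config.ploidy) + 1}[klass]
                segments.append({"sample": sample, "chrom": gene["chrom"],
                                 "start": gene["start"], "end": gene["end"],
                                 "total_cn": cn})
            if klass in ("damaging_mutation", "double_hit"):
                ccf = float(config.mutation_ccfs.get(name, 1.0))
                tumor_cn = 1 if klass == "double_hit" else 2
                vaf = expected_vaf(ccf, purity, tumor_cn, 2, 1)
                depth = max(1, int(rng.poisson(config.depth_mean)))
                alt = int(rng.binomial(depth, vaf))
                consequence = ("frameshift", "stopgain", "missense")[int(rng.integers(3))]
                support = int(rng.integers(7, 11)) if consequence == "missense" else 0
                pos = int(rng.integers(gene["start"], gene["end"] + 1))
                variants.append({
                    "sample": sample, "gene": name, "chrom": gene["chrom"],
                    "pos": pos, "consequence": consequence,
                    "predictor_support": support, "alt_reads": alt,
                    "total_reads": depth, "tumor_cn": tumor_cn,
                })
                truth["mutations"].append({
                    "sample": sample, "gene": name, "true_ccf": ccf,
                    "tumor_cn": tumor_cn, "purity": purity})

    cols_v = ["sample", "gene", "chrom", "pos", "consequence",
              "predictor_support", "alt_reads", "total_reads", "tumor_cn"]
    cols_s = ["sample", "chrom", "start", "end", "total_cn"]
    return (pd.DataFrame(variants, columns=cols_v),
            pd.DataFrame(segments, columns=cols_s),
            pd.DataFrame(purities, columns=["sample", "purity", "ploidy"]),
            truth)


def simulate_mutation_reads(n_mutations: int, true_ccf: float, depth_mean: float,
                            purity: float = 1.0, tumor_cn: int = 2,
                            multiplicity: int = 1, seed: int = 0) -> pd.DataFrame:
    """Read counts for ``n_mutations`` i.i.d. mutations at one true CCF —
    the minimal input of the clonality stage."""
    rng = child_rng(seed, "tumor_genomes")
    depth = np.maximum(rng.poisson(depth_mean, size=n_mutations), 1)
    vaf = expected_vaf(true_ccf, purity, tumor_cn, 2, multiplicity)
    alt = rng.binomial(depth, vaf)
    return pd.DataFrame({
        "alt_reads": alt, "total_reads": depth, "purity": purity,
        "tumor_cn": tumor_cn, "true_ccf": true_ccf})


def simulate_progression_cohort(n: int, beta0: float, beta_tp53: float,
                                beta_cdkn2a: float,
                                genotype_freqs=(0.35, 0.25, 0.30, 0.10),
                                seed: int = 0):
    """Progression cohort: genotypes over (TP53 LoF, CDKN2A LoF) drawn from
    ``genotype_freqs`` = (wt/wt, TP53-only, CDKN2A-only, both), progression ~
    Bernoulli(logit^-1(beta0 + beta_tp53*x1 + beta_cdkn2a*x2)).

    The default frequencies make CDKN2A LoF common and double LoF depleted;
    they are free parameters (no published per-genotype counts exist).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    freqs = np.asarray(genotype_freqs, dtype=float)
    if freqs.shape != (4,) or abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("genotype_freqs must be a 4-vector summing to 1")
    rng = child_rng(seed, "progression_cohort")
    geno = rng.choice(4, size=n, p=freqs)
    tp53 = np.isin(geno, (1, 3)).astype(int)
    cdkn2a = np.isin(geno, (2, 3)).astype(int)
    p = expit(beta0 + beta_tp53 * tp53 + beta_cdkn2a * cdkn2a)
    prog = rng.binomial(1, p) if n else np.array([], dtype=int)
    cohort = pd.DataFrame({
        "sample": [f"BE{i + 1:05d}" for i in range(n)],
        "tp53_lof": tp53, "cdkn2a_lof": cdkn2a, "progressed": prog})
    truth = {"beta": {"intercept": beta0, "tp53_lof": beta_tp53,
                      "cdkn2a_lof": beta_cdkn2a},
             "genotype_freqs": freqs.tolist()}
    return cohort, truth


def simulate_expression_cohort(n_samples: int, n_genes: int, n_modules: int,
                               marker_effect: float, tf_names: list[str] | None = None,
                               seed: int = 0, module_size: int = 20,
                               dispersion: float = 0.1, base_log2_mean: float = 9.0,
                               tf_target_slope: float = 0.9, noise_sd: float = 1.0,
                               noise_gene_sd: float = 0.4, module_cofactor_sd: float = 0.5,
                               marker_fraction: float = 0.5):
    """Negative-binomial count matrix with planted TF-driven modules chained
    to a binary marker (marker -> TF -> targets).

    Each module's TF carries the marker effect (log2FC = ``marker_effect``
    between marker groups) on top of a latent factor of sd ``noise_sd``; its
    targets follow the TF with slope ``tf_target_slope``.  Remaining genes
    are exchangeable low-variability background (sd ``noise_gene_sd``, the
    typical quiet-transcriptome regime against which a co-expressed module
    stands out).  Returns (counts genes x samples, marker Series, truth).
    """
    if n_modules * module_size > n_genes:
        raise ValueError("n_modules * module_size must not exceed n_genes")
    if tf_names is None:
        tf_names = [f"TF{j + 1}" for j in range(n_modules)]
    if len(tf_names) < n_modules:
        raise ValueError("need one TF name per module")
    rng = child_rng(seed, "expression_cohort")
    samples = [f"R{i + 1:04d}" for i in range(n_samples)]
    marker = rng.binomial(1, marker_fraction, size=n_samples)
    if n_samples and (marker.sum() == 0 or marker.sum() == n_samples):
        warnings.warn("marker vector is degenerate (all one class); "
                      "effects are unidentifiable", RuntimeWarning, stacklevel=2)

    r = 1.0 / dispersion

    def draw_counts(log2_mean: np.ndarray) -> np.ndarray:
        mu = np.exp2(log2_mean)
        return rng.negative_binomial(r, r / (r + mu))

    gene_names, rows = [], []
    membership, tf_targets = {}, {}
    for j in range(n_modules):
        tf = tf_names[j]
        tf_latent = marker_effect * marker + rng.normal(0, noise_sd, n_samples)
        tf_counts = draw_counts(base_log2_mean + tf_latent)
        gene_names.append(tf)
        rows.append(tf_counts)
        membership[tf] = f"module{j + 1}"
        # targets respond to the TF's realized expression (the observable
        # mediates), so the marker -> TF -> target chain holds on observables
        tf_obs = np.log2(tf_counts + 1.0)
        # shared co-regulation independent of the TF: real modules answer to
        # several inputs, so the eigengene is not a noise-free copy of the TF
        cofactor = rng.normal(0, module_cofactor_sd, n_samples)
        targets = []
        for t in range(module_size - 1):
            g = f"M{j + 1}G{t + 1}"
            targets.append(g)
            gene_names.append(g)
            rows.append(draw_counts(base_log2_mean
                                    + tf_target_slope * (tf_obs - base_log2_mean)
                                    + cofactor + rng.normal(0, 0.2, n_samples)))
            membership[g] = f"module{j + 1}"
        tf_targets[tf] = targets
    for t in range(n_genes - n_modules * module_size):
        g = f"NOISE{t + 1}"
        gene_names.append(g)
        rows.append(draw_counts(base_log2_mean + rng.normal(0, noise_gene_sd, n_samples)))

    counts = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, n_samples)),
                          index=gene_names, columns=samples)
    marker = pd.Series(marker, index=samples, name="marker")
    truth = {"module_membership": membership, "tf_targets": tf_targets,
             "marker_effect": marker_effect, "dispersion": dispersion}
    return counts, marker, truth


def simulate_survival_cohort(group_sizes: dict, hazard_ratios: dict,
                             censor_rate: float = 0.2, seed: int = 0,
                             baseline_hazard: float = 0.01) -> pd.DataFrame:
    """Exponential survival times scaled by per-group hazard ratios with
    independent exponential censoring calibrated so a fraction
    ``censor_rate`` of records is censored in expectation."""
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must be in [0, 1)")
    for g, hr in hazard_ratios.items():
        if hr <= 0:
            raise ValueError(f"hazard ratio for group {g!r} must be positive")
    rng = child_rng(seed, "survival_cohort")
    rows = []
    i = 0
    for group in sorted(group_sizes):
        n = group_sizes[group]
        lam = baseline_hazard * hazard_ratios.get(group, 1.0)
        t_event = rng.exponential(1 / lam, size=n)
        if censor_rate > 0:
            lam_c = lam * censor_rate / (1 - censor_rate)
            t_cens = rng.exponential(1 / lam_c, size=n)
        else:
            t_cens = np.full(n, np.inf)
        for te, tc in zip(t_event, t_cens):
            i += 1
            rows.append({"sample": f"P{i:05d}", "group": group,
                         "time": float(min(te, tc)), "event": bool(te <= tc)})
    return pd.DataFrame(rows, columns=["sample", "group", "time", "event"])


def simulate_cell_table(n_cells: int, phenotype_fractions: dict,
                        overlap_noise: float = 0.05, seed: int = 0,
                        n_samples: int = 1) -> pd.DataFrame:
    """Segmented-cell table with planted phenotypes.

    Each cell's mask-overlap fractions peak at 0.6 on its true phenotype and
    are half-normal background noise elsewhere; marker intensity is high
    (N(5,1)) for the true phenotype's marker and low (N(1,0.5)) otherwise.
    Fractions must sum to <= 1; the remainder stays truly unassigned.
    """
    unknown = sorted(set(phenotype_fractions) - set(DEFAULT_PRIORITY))
    if unknown:
        raise ValueError(f"unknown phenotypes {unknown}; "
                         f"valid names: {list(DEFAULT_PRIORITY)}")
    fr = np.array([phenotype_fractions.get(p, 0.0) for p in DEFAULT_PRIORITY])
    if fr.sum() > 1 + 1e-12:
        raise ValueError("phenotype fractions must sum to <= 1")
    rng = child_rng(seed, "cell_table")
    labels = list(DEFAULT_PRIORITY) + ["unassigned"]
    p = np.append(fr, 1 - fr.sum())
    idx = rng.choice(len(labels), size=n_cells, p=p)
    used = [ph for ph in DEFAULT_PRIORITY if phenotype_fractions.get(ph, 0) > 0]
    rows = []
    for i in range(n_cells):
        true_ph = labels[idx[i]]
        row = {"cell": f"C{i + 1:06d}",
               "sample": f"IMC{1 + i % n_samples:02d}",
               "true_phenotype": true_ph}
        for ph in used:
            if ph == true_ph:
                ov = 0.6 + rng.normal(0, overlap_noise)
            else:
                ov = abs(rng.normal(0, overlap_noise)) if overlap_noise > 0 else 0.0
            row[f"overlap_{ph}"] = float(np.clip(ov, 0.0, 1.0))
            hi = ph == true_ph
            row[f"marker_{ph}"] = float(max(rng.normal(5, 1) if hi else rng.normal(1, 0.5), 0.0))
        rows.append(row)
    return pd.DataFrame(rows)
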