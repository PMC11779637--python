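"""Three-step causal regulatory protocol linking a binary loss-of-function
marker to transcriptional modules through transcription factors (TFs).

Step 1 — module discovery: the top-50% most variable genes are grouped into
k = round(nAG * nBpG / nGpB) modules (nBpG = max modules per gene, default 2;
nGpB = mean module size, default 30) by a seeded local search maximizing a
composite of member co-expression, optional protein-interaction density and
TF-target enrichment.  Modules are filtered on eigengene quality (PC1
permutation FDR and variance explained), enrichment in a keratinization gene
set and in the targets of at least one TF correlated with the eigengene.

Step 2 — edge orienting: for each (marker M, TF A, module eigengene B)
triple, five path models (causal M->A->B, reactive M->B->A, confounded
A<-M->B, collider M->A<-B, independence) are fitted by maximum likelihood on
the standardized three-variable system; each model's probability is the
chi-squared goodness-of-fit p-value of its implied correlation structure.
The single-marker score is log10 P(causal) - log10 P(next-best alternative);
models are significant when the causal model fits best and the score is at
least 0.5.

Step 3 — significant models are retained only if their TF is differentially
expressed (FDR < 0.1) in the marker-only group versus locus-wild-type
samples, positively correlated (Spearman R > 0.5, FDR < 0.1) with the target
signature's enrichment score, and present in at least 30% of the significant
models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_rng
from .stats import bh_adjust, fisher_exact_2x2

logger = logging.getLogger(__name__)

CAUSAL_MODELS = ("causal", "reactive", "confounded", "collider", "independent")
_LOG10_FLOOR = 1e-300


@dataclass
class GeneModule:
    module_id: str
    members: list
    eigengene: np.ndarray = None
    variance_explained: float = np.nan
    pc1_p: float = np.nan
    pc1_fdr: float = np.nan
    keratinization_fisher_p: float = np.nan
    tf_enrichment: dict = field(default_factory=dict)
    tf_eigengene_correlation: dict = field(default_factory=dict)
    candidate_tfs: list = field(default_factory=list)


@dataclass
class CausalModelResult:
    marker: str
    tf: str
    module: str
    model_logp: dict
    neo_score: float
    best_model: str
    significant: bool


# ---------------------------------------------------------------------------
# Step 0: gene selection and k
# ---------------------------------------------------------------------------

def select_variable_genes(expression: pd.DataFrame) -> list[str]:
    """Top 50% most variably expressed genes (rows); at the median-variance
    boundary, ties resolve lexicographically by gene name."""
    if expression.shape[1] < 2:
        raise ValueError("need at least 2 samples to rank variances")
    var = expression.var(axis=1, ddof=1)
    if np.allclose(var, 0):
        logger.info("all genes have equal (zero) variance; tie rule applies")
    order = var.iloc[np.lexsort((var.index, -var.to_numpy()))]
    k = (len(order) + 1) // 2
    return sorted(order.index[:k])


def compute_k(n_analyzed_genes: int, n_modules_per_gene: int = 2,
              genes_per_module: int = 30) -> int:
    """Module count k = round(nAG * nBpG / nGpB), floored at 1."""
    if genes_per_module <= 0:
        raise ValueError("genes_per_module must be positive")
    return max(1, round(n_analyzed_genes * n_modules_per_gene / genes_per_module))


# ---------------------------------------------------------------------------
# Mutual-information TF network
# ---------------------------------------------------------------------------

def _rank_bin(x: np.ndarray, n_bins: int) -> np.ndarray:
    order = stats.rankdata(x, method="average")
    return np.minimum(((order - 1) / len(x) * n_bins).astype(int), n_bins - 1)


def _binned_mi(a: np.ndarray, b: np.ndarray, n_bins: int) -> float:
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (a, b), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (pa * pb))
    return float(np.nansum(terms))


def infer_tf_network(expression: pd.DataFrame, tfs: list[str],
                     mi_pvalue: float = 1e-8, dpi_tolerance: float = 0.0,
                     seed: int = 0, n_null: int = 2000) -> pd.DataFrame:
    """TF-target pairs by rank-binned mutual information.

    MI is estimated on equal-frequency rank bins; the retention threshold is
    calibrated by fitting a gamma distribution to a permutation null of MI
    values and taking its upper ``mi_pvalue`` quantile.  Indirect edges are
    pruned by the data-processing inequality: within every TF-TF-target
    triangle the weakest edge is removed (within ``dpi_tolerance``).
    """
    tfs = [t for t in tfs if t in expression.index]
    if not tfs:
        raise ValueError("no TF present in the expression matrix")
    n = expression.shape[1]
    if n < 20:
        warnings.warn("fewer than 20 samples: MI estimates are unstable",
                      RuntimeWarning, stacklevel=2)
    n_bins = max(2, int(np.sqrt(n / 5)))
    binned = {g: _rank_bin(expression.loc[g].to_numpy(dtype=float), n_bins)
              for g in expression.index}

    rng = child_rng(seed, "mi_null")
    ref = binned[tfs[0]].copy()
    null = np.empty(n_null)
    for b in range(n_null):
        perm = rng.permutation(n)
        null[b] = _binned_mi(ref, ref[perm], n_bins)
    # gamma tail fit extrapolates far beyond the permutation count
    a_fit, loc_fit, scale_fit = stats.gamma.fit(null + 1e-12, floc=0)
    threshold = float(stats.gamma.isf(mi_pvalue, a_fit, loc=loc_fit, scale=scale_fit))

    mi_of: dict[tuple[str, str], float] = {}
    edges = []
    targets = [g for g in expression.index]
    for tf in tfs:
        for g in targets:
            if g == tf:
                continue
            mi = _binned_mi(binned[tf], binned[g], n_bins)
            if mi >= threshold:
                mi_of[(tf, g)] = mi
                edges.append((tf, g, mi))

    # DPI over TF-TF-target triangles
    removed = set()
    for i, tf1 in enumerate(tfs):
        for tf2 in tfs[i + 1:]:
            m12 = mi_of.get((tf1, tf2), mi_of.get((tf2, tf1)))
            if m12 is None:
                continue
            for g in targets:
                if g in (tf1, tf2):
                    continue
                m1g, m2g = mi_of.get((tf1, g)), mi_of.get((tf2, g))
                if m1g is None or m2g is None:
                    continue
                trio = {(tf1, tf2): m12, (tf1, g): m1g, (tf2, g): m2g}
                weakest = min(trio, key=lambda e: trio[e])
                others = [v for e, v in trio.items() if e != weakest]
                if trio[weakest] < min(others) * (1 - dpi_tolerance) or dpi_tolerance == 0:
                    removed.add(weakest)
    kept = [(tf, g, mi) for tf, g, mi in edges if (tf, g) not in removed]
    return pd.DataFrame(kept, columns=["tf", "target", "mi"])


# ---------------------------------------------------------------------------
# Module detection and filtering
# ---------------------------------------------------------------------------

def _eigengene(z: np.ndarray):
    """PC1 scores and variance-explained of a members x samples z-matrix."""
    zc = z - z.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(zc, full_matrices=False)
    var_explained = float(s[0] ** 2 / np.sum(s ** 2)) if np.sum(s ** 2) > 0 else 0.0
    pc1 = vt[0]
    # orient so the mean member correlation with the eigengene is positive
    corr = np.array([np.corrcoef(row, pc1)[0, 1] for row in zc])
    if np.nanmean(corr) < 0:
        pc1 = -pc1
    return pc1, var_explained


def detect_modules(expression: pd.DataFrame, k: int, tf_network: pd.DataFrame | None = None,
                   ppin: pd.DataFrame | None = None, iterations: int = 2000,
                   seed: int = 123, ppin_weight: float = 0.0,
                   tf_weight: float = 0.2) -> list[GeneModule]:
    """Partition genes into k co-expression modules by seeded local search.

    Genes are z-scored per row and seeded into k groups by average-linkage
    clustering of the correlation distance (1 - r).  The seeding is then
    refined by iterated eigengene affinity: each round recomputes every
    module's eigengene (PC1) and reassigns each gene to the module whose
    eigengene it correlates with most, plus optional bonuses for sharing a
    TF with the module's members and for PPIN adjacency.  ``iterations``
    counts single-gene updates (one full pass = one update per gene); the
    procedure is deterministic for a fixed seed.
    """
    from sklearn.cluster import AgglomerativeClustering

    genes = list(expression.index)
    n_genes = len(genes)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_genes / 2:
        raise ValueError(f"k={k} exceeds n_genes/2={n_genes / 2:.0f}")
    z = ((expression.sub(expression.mean(axis=1), axis=0))
         .div(expression.std(axis=1, ddof=0).replace(0, 1.0), axis=0)).to_numpy()
    zc = z - z.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(zc, axis=1)
    norms[norms == 0] = 1.0

    agg = AgglomerativeClustering(n_clusters=min(k, n_genes), metric="precomputed",
                                  linkage="average")
    corr = np.corrcoef(z)
    np.fill_diagonal(corr, 0.0)
    labels = agg.fit_predict(1.0 - corr)

    tf_targets: dict[str, set] = {}
    if tf_network is not None and len(tf_network):
        for tf, grp in tf_network.groupby("tf"):
            tf_targets[tf] = set(grp["target"])
    is_target = {tf: np.array([genes[i] in t for i in range(n_genes)])
                 for tf, t in tf_targets.items()}
    neighbours = np.zeros((n_genes, n_genes))
    if ppin is not None and len(ppin):
        pos = {g: i for i, g in enumerate(genes)}
        for row in ppin.itertuples(index=False):
            if row.gene_a in pos and row.gene_b in pos:
                w = float(getattr(row, "weight", 1.0))
                neighbours[pos[row.gene_a], pos[row.gene_b]] = w
                neighbours[pos[row.gene_b], pos[row.gene_a]] = w

    n_passes = max(1, int(np.ceil(iterations / n_genes)))
    for _ in range(n_passes):
        affinity = np.zeros((n_genes, k))
        for m in range(k):
            idx = np.flatnonzero(labels == m)
            if idx.size == 0:
                affinity[:, m] = -np.inf
                continue
            pc1, _ = _eigengene(z[idx]) if idx.size > 1 else (zc[idx[0]], 1.0)
            pc1 = pc1 - pc1.mean()
            denom = np.linalg.norm(pc1)
            affinity[:, m] = np.abs(zc @ pc1) / (norms * max(denom, 1e-12))
            if tf_weight and tf_targets:
                member_names = {genes[i] for i in idx}
                for tf, mask in is_target.items():
                    frac = len(member_names & tf_targets[tf]) / idx.size
                    affinity[mask, m] += tf_weight * frac * mask[list(idx)].mean()
            if ppin_weight and ppin is not None:
                affinity[:, m] += ppin_weight * neighbours[:, idx].mean(axis=1)
        new_labels = np.argmax(affinity, axis=1)
        # keep every module at >= 2 members: pin its two highest-affinity genes
        for m in range(k):
            if np.sum(new_labels == m) < 2:
                keep = np.argsort(-affinity[:, m])[:2]
                new_labels[keep] = m
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels

    modules = []
    for m in range(k):
        idx = np.flatnonzero(labels == m)
        if idx.size < 2:
            continue
        names = sorted(genes[i] for i in idx)
        pc1, ve = _eigengene(z[idx])
        modules.append(GeneModule(module_id=f"M{m + 1}", members=names,
                                  eigengene=pc1, variance_explained=ve))
    return modules


def _pc1_permutation_p(z: np.ndarray, observed_ve: float, rng, n_perm: int = 200) -> float:
    null = np.empty(n_perm)
    zp = z.copy()
    for b in range(n_perm):
        for row in zp:
            rng.shuffle(row)
        null[b] = _eigengene(zp)[1]
    return (1 + int(np.sum(null >= observed_ve))) / (1 + n_perm)


def _overlap_fisher(set_a: set, set_b: set, universe: int) -> float:
    a_and_b = len(set_a & set_b)
    a_only = len(set_a) - a_and_b
    b_only = len(set_b) - a_and_b
    rest = universe - a_and_b - a_only - b_only
    return fisher_exact_2x2([[a_and_b, a_only], [b_only, max(rest, 0)]])


def filter_modules(modules: list[GeneModule], expression: pd.DataFrame,
                   keratinization_set: set, tf_network: pd.DataFrame,
                   var_explained_min: float = 0.32, pc1_fdr_max: float = 0.1,
                   fisher_p_max: float = 0.01, tf_corr_min: float = 0.5,
                   n_perm: int = 200, seed: int = 123) -> list[GeneModule]:
    """Step-1 module filters.

    A module survives when all hold: PC1 permutation FDR <= ``pc1_fdr_max``
    and variance explained >= ``var_explained_min`` (0.32 progressor-BE
    preset; 0.25 EAC preset); Fisher p <= ``fisher_p_max`` for overlap with
    the keratinization set; at least one TF whose targets are enriched among
    members (Fisher p <= ``fisher_p_max``) and whose expression correlates
    with the eigengene at |r| > ``tf_corr_min``.  Surviving modules carry
    their candidate TFs.
    """
    universe = expression.shape[0]
    rng = child_rng(seed, "pc1_permutation")
    z = ((expression.sub(expression.mean(axis=1), axis=0))
         .div(expression.std(axis=1, ddof=0).replace(0, 1.0), axis=0))
    tf_targets = {tf: set(grp["target"]) for tf, grp in tf_network.groupby("tf")} \
        if len(tf_network) else {}

    usable = []
    for mod in modules:
        present = [g for g in mod.members if g in expression.index]
        if len(present) < 3:
            logger.info("module %s smaller than 3 after expression "
                        "intersection; dropped", mod.module_id)
            continue
        usable.append(mod)
        zm = z.loc[present].to_numpy()
        mod.eigengene, mod.variance_explained = _eigengene(zm)
        mod.pc1_p = _pc1_permutation_p(zm, mod.variance_explained, rng, n_perm)
        mod.keratinization_fisher_p = _overlap_fisher(set(present),
                                                      set(keratinization_set), universe)
        mod.tf_enrichment = {
            tf: _overlap_fisher(set(present), targets, universe)
            for tf, targets in tf_targets.items()}
        mod.tf_eigengene_correlation = {
            tf: float(np.corrcoef(expression.loc[tf].to_numpy(dtype=float),
                                  mod.eigengene)[0, 1])
            for tf in tf_targets if tf in expression.index}

    fdrs = bh_adjust(np.array([m.pc1_p for m in usable])) if usable else []
    retained = []
    for mod, fdr in zip(usable, fdrs):
        mod.pc1_fdr = float(fdr)
        if mod.pc1_fdr > pc1_fdr_max or mod.variance_explained < var_explained_min:
            continue
        if mod.keratinization_fisher_p > fisher_p_max:
            continue
        mod.candidate_tfs = sorted(
            tf for tf, p in mod.tf_enrichment.items()
            if p <= fisher_p_max
            and abs(mod.tf_eigengene_correlation.get(tf, 0.0)) > tf_corr_min)
        if not mod.candidate_tfs:
            continue
        retained.append(mod)
    return retained


# ---------------------------------------------------------------------------
# NEO-style single-marker edge orienting
# ---------------------------------------------------------------------------

def _model_chi2(S: np.ndarray, n: int, model: str):
    """Chi-square GOF of one path model on the sample correlation matrix S of
    (M, A, B); MLEs of recursive path models are the DAG-factorized
    regressions."""
    r1, r2, r3 = S[0, 1], S[0, 2], S[1, 2]  # r_MA, r_MB, r_AB
    sigma = np.eye(3)
    if model == "causal":           # M -> A -> B
        sigma[0, 1] = r1; sigma[1, 2] = r3; sigma[0, 2] = r1 * r3
        df = 1
    elif model == "reactive":       # M -> B -> A
        sigma[0, 2] = r2; sigma[1, 2] = r3; sigma[0, 1] = r2 * r3
        df = 1
    elif model == "confounded":     # A <- M -> B
        sigma[0, 1] = r1; sigma[0, 2] = r2; sigma[1, 2] = r1 * r2
        df = 1
    elif model == "collider":       # M -> A <- B with M independent of B
        a = (r1 - r3 * r2) / (1 - r2 ** 2)
        c = (r3 - r1 * r2) / (1 - r2 ** 2)
        sigma[0, 1] = a; sigma[1, 2] = c; sigma[0, 2] = 0.0
        df = 1
    elif model == "independent":
        df = 3
    else:
        raise ValueError(model)
    sigma = np.triu(sigma) + np.triu(sigma, 1).T
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    if sign_m <= 0 or sign_s <= 0:
        return np.inf, df
    f_ml = logdet_m - logdet_s + float(np.trace(S @ np.linalg.inv(sigma))) - 3.0
    return max(f_ml, 0.0) * (n - 1), df


def neo_single_marker(marker, tf_expr, eigengene, marker_name: str = "marker",
                      tf_name: str = "TF", module_id: str = "module",
                      models: tuple = CAUSAL_MODELS) -> CausalModelResult:
    """Orient the marker -> TF -> module triple by likelihood-based edge
    orienting; see module docstring for the five models and the score."""
    m = np.asarray(marker, dtype=float)
    a = np.asarray(tf_expr, dtype=float)
    b = np.asarray(eigengene, dtype=float)
    if not (m.size == a.size == b.size):
        raise ValueError("marker, TF and eigengene must have equal lengths")
    if np.all(m == m[0]):
        raise ValueError("marker is degenerate (constant)")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("constant TF or eigengene: orientation undefined")
    X = np.column_stack([m, a, b])
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    S = np.corrcoef(X, rowvar=False)
    n = m.size

    logp = {}
    for model in models:
        t, df = _model_chi2(S, n, model)
        p = float(stats.chi2.sf(t, df)) if np.isfinite(t) else 0.0
        logp[model] = float(np.log10(max(p, _LOG10_FLOOR)))
    best = max(logp, key=lambda k: (logp[k], k != "causal"))
    alternatives = [v for k, v in logp.items() if k != "causal"]
    score = logp["causal"] - max(alternatives)
    significant = best == "causal" and score >= 0.5
    return CausalModelResult(marker=marker_name, tf=tf_name, module=module_id,
                             model_logp=logp, neo_score=float(score),
                             best_model=best, significant=significant)


def filter_causal_models(models: list[CausalModelResult], de_table: pd.DataFrame,
                         correlations: pd.DataFrame,
                         min_model_fraction: float = 0.30,
                         de_fdr_max: float = 0.1, corr_min: float = 0.5,
                         corr_fdr_max: float = 0.1):
    """Step-3 filters on significant causal models.

    ``de_table`` is indexed by TF with columns log2fc, fdr (marker-only group
    vs locus-wild-type); ``correlations`` is indexed by TF with columns rho,
    fdr (TF expression vs target-signature enrichment score).  A model is
    retained when its TF is differentially expressed (FDR < 0.1), positively
    correlated (R > 0.5 and FDR < 0.1 — strict inequality), and contributes
    to at least ``min_model_fraction`` of the significant models.
    Returns (retained TF list, retained models).
    """
    significant = [m for m in models if m.significant]
    if not significant:
        return [], []
    counts: dict[str, int] = {}
    for m in significant:
        counts[m.tf] = counts.get(m.tf, 0) + 1
    n_sig = len(significant)
    retained = []
    for m in significant:
        if m.tf not in de_table.index or m.tf not in correlations.index:
            continue
        if not de_table.loc[m.tf, "fdr"] < de_fdr_max:
            continue
        row = correlations.loc[m.tf]
        if not (row["rho"] > corr_min and row["fdr"] < corr_fdr_max):
            continue
        if counts[m.tf] / n_sig < min_model_fraction:
            continue
        retained.append(m)
    tf_list = sorted({m.tf for m in retained})
    return tf_list, retained


# ---------------------------------------------------------------------------
# End-to-end protocol
# ---------------------------------------------------------------------------

PRESETS = {"p-be": {"var_explained_min": 0.32}, "eac": {"var_explained_min": 0.25}}


def run_causal_protocol(counts: pd.DataFrame, marker: pd.Series, tfs: list[str],
                        keratinization_set: set, preset: str = "p-be",
                        seed: int = 123, iterations: int = 2000,
                        mi_pvalue: float = 1e-8, n_perm: int = 200) -> dict:
    """All three steps on a counts matrix (genes x samples) and a binary
    per-sample marker; returns the intermediate artifacts and the final TF
    list.  ``preset`` selects the variance-explained floor (0.32 'p-be',
    0.25 'eac')."""
    from .enrichment import (median_of_ratios_size_factors, ssgsea_scores)
    from .stats import wilcoxon_rank_sum

    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    marker = marker.reindex(counts.columns)
    norm = counts / median_of_ratios_size_factors(counts)
    log_expr = np.log2(norm + 1.0)

    variable = select_variable_genes(log_expr)
    analyzed = [g for g in variable if g not in tfs]
    k = min(compute_k(len(analyzed)), max(1, len(analyzed) // 2))
    net = infer_tf_network(log_expr.loc[sorted(set(analyzed) | set(t for t in tfs if t in log_expr.index))],
                           tfs, mi_pvalue=mi_pvalue, seed=seed)
    modules = detect_modules(log_expr.loc[analyzed], k, tf_network=net,
                             iterations=iterations, seed=seed)
    retained = filter_modules(modules, log_expr, keratinization_set, net,
                              var_explained_min=PRESETS[preset]["var_explained_min"],
                              n_perm=n_perm, seed=seed)

    models = []
    for mod in retained:
        for tf in mod.candidate_tfs:
            models.append(neo_single_marker(
                marker.to_numpy(), log_expr.loc[tf].to_numpy(), mod.eigengene,
                marker_name="marker", tf_name=tf, module_id=mod.module_id))

    # step-3 evidence: marker-group DE and TF-vs-target-signature correlation
    m1 = marker.index[marker == 1]
    m0 = marker.index[marker == 0]
    tf_rows, corr_rows = [], []
    present_tfs = [t for t in tfs if t in log_expr.index]
    tf_targets = {tf: list(grp["target"]) for tf, grp in net.groupby("tf")}
    nes = ssgsea_scores(log_expr, {tf: tg for tf, tg in tf_targets.items() if tg})
    for tf in present_tfs:
        x = log_expr.loc[tf, m1]
        y = log_expr.loc[tf, m0]
        p = wilcoxon_rank_sum(x, y) if len(m1) >= 2 and len(m0) >= 2 else 1.0
        tf_rows.append({"tf": tf, "log2fc": float(x.mean() - y.mean()), "p": p})
        if tf in nes.columns and not nes[tf].isna().all():
            rho = float(stats.spearmanr(log_expr.loc[tf], nes[tf]).statistic)
            pc = float(stats.spearmanr(log_expr.loc[tf], nes[tf]).pvalue)
        else:
            rho, pc = 0.0, 1.0
        corr_rows.append({"tf": tf, "rho": rho, "p": pc})
    de_table = pd.DataFrame(tf_rows).set_index("tf")
    de_table["fdr"] = bh_adjust(de_table["p"].to_numpy()) if len(de_table) else []
    correlations = pd.DataFrame(corr_rows).set_index("tf")
    correlations["fdr"] = bh_adjust(correlations["p"].to_numpy()) if len(correlations) else []

    final_tfs, final_models = filter_causal_models(models, de_table, correlations)
    return {"k": k, "network": net, "modules": modules, "retained_modules": retained,
            "causal_models": models, "de_table": de_table,
            "correlations": correlations, "final_tfs": final_tfs,
            "final_models": final_models}
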