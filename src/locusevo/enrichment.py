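"""Preranked gene-set enrichment, leading-edge redundancy pruning and
single-sample immune-signature scoring.

The enrichment score (ES) of a gene set along a ranked gene list is the
extremum of the weighted Kolmogorov-Smirnov running sum: walking down the
list, hits increment by |stat|^p / sum(|stat|^p over hits) and misses
decrement by 1/(N-K).  Significance is assessed by gene-label permutation;
NES normalizes ES by the mean |permuted ES| of matching sign, and the
leading edge collects the hits at or before the ES extremum (on the
extremum's side).

Redundant pathways are pruned pairwise on leading-edge overlap:
rule A — if one pathway's unique leading-edge genes outnumber the shared
plus the other's unique genes, the other is removed; rule B — if the shared
genes outnumber both unique sets, the member with the higher FDR is removed.
Pairs are visited in ascending-FDR order and the rules iterate to a
fixpoint, so the result is deterministic and idempotent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_rng
from .stats import bh_adjust, wilcoxon_rank_sum

logger = logging.getLogger(__name__)


@dataclass
class GSEAResult:
    name: str
    es: float
    nes: float
    p: float
    fdr: float
    leading_edge: list
    set_size: int


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def filter_expressed_genes(prob_expressed: dict, threshold: float = 0.9) -> set:
    """Genes whose probability of expression is at least ``threshold``
    (genes below 0.9 are filtered out; 0.9 itself is retained)."""
    bad = {g: p for g, p in prob_expressed.items() if not (0 <= p <= 1)}
    if bad:
        raise ValueError(f"probabilities outside [0,1]: {bad}")
    return {g for g, p in prob_expressed.items() if p >= threshold}


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors: per-sample median of count ratios to the
    geometric-mean pseudo-reference over genes expressed everywhere."""
    logc = np.log(counts.replace(0, np.nan))
    logmeans = logc.mean(axis=1)
    use = np.isfinite(logmeans)
    if not use.any():
        raise ValueError("no gene has nonzero counts in every sample")
    ratios = logc.loc[use].sub(logmeans[use], axis=0)
    return np.exp(ratios.median(axis=0))


def rank_genes_by_fc(counts: pd.DataFrame, group_a: list[str], group_b: list[str]) -> pd.Series:
    """Rank genes by log2 fold-change of group A over group B.

    Size-factor normalization (median of ratios), then
    log2((mean_A + 0.5) / (mean_B + 0.5)) on normalized counts; descending
    order, ties broken by gene name for determinism.  Genes with zero counts
    in every sample are dropped.
    """
    ga, gb = set(group_a), set(group_b)
    if not ga or not gb or ga & gb:
        raise ValueError("groups must be nonempty and disjoint")
    allzero = (counts.sum(axis=1) == 0)
    if allzero.any():
        logger.info("dropping %d genes with zero counts everywhere", int(allzero.sum()))
        counts = counts.loc[~allzero]
    sf = median_of_ratios_size_factors(counts)
    norm = counts / sf
    fc = np.log2((norm[list(group_a)].mean(axis=1) + 0.5)
                 / (norm[list(group_b)].mean(axis=1) + 0.5))
    fc = fc.iloc[np.lexsort((fc.index, -fc.to_numpy()))]
    return fc


# ---------------------------------------------------------------------------
# Preranked GSEA
# ---------------------------------------------------------------------------

def _es_walk(stat: np.ndarray, hit_mask: np.ndarray, p: float):
    """Weighted-KS running sum; returns (ES, extremum position index)."""
    n = stat.size
    k = int(hit_mask.sum())
    if k == 0 or k == n:
        raise ValueError("gene set must hit a strict subset of the ranked list")
    w = np.abs(stat) ** p
    hit_w = np.where(hit_mask, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit stats are zero: fall back to unweighted hits
        hit_w = hit_mask.astype(float)
        denom = hit_w.sum()
    steps = hit_w / denom - (~hit_mask) / (n - k)
    running = np.cumsum(steps)
    imax, imin = int(np.argmax(running)), int(np.argmin(running))
    # magnitude decides; an exact tie goes to the earlier extremum
    if abs(running[imax]) > abs(running[imin]) or (
            abs(running[imax]) == abs(running[imin]) and imax < imin):
        return float(running[imax]), imax
    return float(running[imin]), imin


def _leading_edge(genes: np.ndarray, hit_mask: np.ndarray, es: float, pos: int) -> list:
    if es >= 0:
        mask = hit_mask.copy()
        mask[pos + 1:] = False
    else:
        mask = hit_mask.copy()
        mask[:pos] = False
    return [str(g) for g in genes[mask]]


def gsea_preranked(ranked: pd.Series, gene_sets: dict[str, list], n_perm: int = 1000,
                   weight: float = 1.0, seed: int = 0, min_size: int = 10,
                   max_size: int = 500) -> list[GSEAResult]:
    """Preranked GSEA over a collection of gene sets.

    ``ranked`` maps gene -> ranking statistic (log2FC), descending.  Sets are
    restricted to 10-500 member genes present in the ranked list; p-values
    come from ``n_perm`` gene-label permutations (sign-matched), NES divides
    ES by the mean |permuted ES| of the same sign, and FDR is BH across sets.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes = ranked.index.to_numpy()
    stat = ranked.to_numpy(dtype=float)
    if len(set(genes)) != len(genes):
        raise ValueError("ranked list contains duplicate genes")
    rng = child_rng(seed, "gsea_permutation")
    gene_pos = {g: i for i, g in enumerate(genes)}

    results: list[GSEAResult] = []
    pvals = []
    for name, members in gene_sets.items():
        idx = sorted({gene_pos[g] for g in members if g in gene_pos})
        k = len(idx)
        if k == 0:
            warnings.warn(f"gene set {name!r} has no overlap with the ranked "
                          "list; excluded", RuntimeWarning, stacklevel=2)
            continue
        if not (min_size <= k <= max_size):
            continue
        hit = np.zeros(genes.size, dtype=bool)
        hit[idx] = True
        es, pos = _es_walk(stat, hit, weight)
        le = _leading_edge(genes, hit, es, pos)

        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            ph = np.zeros(genes.size, dtype=bool)
            ph[rng.choice(genes.size, size=k, replace=False)] = True
            perm_es[b] = _es_walk(stat, ph, weight)[0]
        same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
        if same_sign.size == 0:
            nes, p = 0.0, 1.0 / (n_perm + 1)
        else:
            nes = es / float(np.mean(np.abs(same_sign)))
            p = (1 + int(np.sum(np.abs(same_sign) >= abs(es)))) / (1 + same_sign.size)
        results.append(GSEAResult(name, es, nes, float(p), np.nan, le, k))
        pvals.append(p)

    if results:
        fdrs = bh_adjust(np.array(pvals))
        for r, f in zip(results, fdrs):
            r.fdr = float(f)
    return results


# ---------------------------------------------------------------------------
# Leading-edge redundancy pruning
# ---------------------------------------------------------------------------

def _pair_rule(le_p: set, le_q: set, fdr_p: float, fdr_q: float,
               strict_rule_a: bool = False):
    """Apply the two pruning rules to one ordered pair; return 'P'/'Q' to drop
    or None."""
    shared = len(le_p & le_q)
    u_p, u_q = len(le_p) - shared, len(le_q) - shared
    if strict_rule_a:
        a_pq = u_p > shared and u_p > u_q
        a_qp = u_q > shared and u_q > u_p
    else:
        a_pq = u_p > shared + u_q
        a_qp = u_q > shared + u_p
    if a_pq:
        return "Q"
    if a_qp:
        return "P"
    if shared > u_p and shared > u_q:
        return "Q" if fdr_q >= fdr_p else "P"
    return None


def prune_redundant_pathways(results: list[GSEAResult],
                             strict_rule_a: bool = False) -> list[GSEAResult]:
    """Remove redundant pathways by pairwise leading-edge overlap.

    Pairs are visited in ascending-FDR order and both rules are iterated to a
    fixpoint; the output is idempotent and no surviving pair violates either
    rule.  ``strict_rule_a`` switches rule A to the alternative reading
    u_P > shared AND u_P > u_Q.
    """
    names = [r.name for r in results]
    if len(set(names)) != len(names):
        raise ValueError("duplicate gene-set names")
    alive = sorted(results, key=lambda r: (r.fdr, r.name))
    changed = True
    while changed:
        changed = False
        for i in range(len(alive)):
            for j in range(i + 1, len(alive)):
                p, q = alive[i], alive[j]
                drop = _pair_rule(set(p.leading_edge), set(q.leading_edge),
                                  p.fdr, q.fdr, strict_rule_a)
                if drop is not None:
                    alive.remove(p if drop == "P" else q)
                    changed = True
                    break
            if changed:
                break
    order = {r.name: i for i, r in enumerate(results)}
    return sorted(alive, key=lambda r: order[r.name])


# ---------------------------------------------------------------------------
# Single-sample scoring and comparisons
# ---------------------------------------------------------------------------

def ssgsea_scores(expression: pd.DataFrame, signatures: dict[str, list],
                  weight: float = 0.25, znorm: bool = True) -> pd.DataFrame:
    """Single-sample enrichment scores (samples x signatures).

    Genes are rank-normalized within each sample; each signature's score is
    the weighted-KS enrichment statistic of its genes in that sample's
    ranking (exponent 0.25 by default), then z-normalized across samples per
    signature.  Signatures absent from the matrix yield NaN columns.
    """
    n_genes = expression.shape[0]
    ranks = expression.rank(axis=0, method="average") / n_genes
    out = pd.DataFrame(index=expression.columns, dtype=float)
    for name, members in signatures.items():
        present = [g for g in members if g in expression.index]
        if not present:
            warnings.warn(f"signature {name!r} fully absent from matrix",
                          RuntimeWarning, stacklevel=2)
            out[name] = np.nan
            continue
        scores = []
        for s in expression.columns:
            r = ranks[s]
            order = r.iloc[np.lexsort((r.index, -r.to_numpy()))]
            hit = order.index.isin(present)
            es, _ = _es_walk(order.to_numpy(), np.asarray(hit), weight)
            scores.append(es)
        col = np.asarray(scores, dtype=float)
        if znorm and col.std(ddof=0) > 0:
            col = (col - col.mean()) / col.std(ddof=0)
        out[name] = col
    return out


def compare_infiltration(scores: pd.DataFrame, groups: pd.Series, reference: str,
                         fdr_threshold: float = 0.1) -> pd.DataFrame:
    """Wilcoxon comparison of per-signature scores between each group and the
    reference group, BH-corrected across signatures within each group."""
    if (groups == reference).sum() == 0:
        raise ValueError(f"reference group {reference!r} is empty")
    ref_samples = groups.index[groups == reference]
    rows = []
    for g in sorted(set(groups) - {reference}):
        members = groups.index[groups == g]
        if len(members) < 2:
            warnings.warn(f"group {g!r} has <2 samples; excluded",
                          RuntimeWarning, stacklevel=2)
            continue
        ps, sigs = [], []
        for sig in scores.columns:
            x = scores.loc[members, sig].dropna()
            y = scores.loc[ref_samples, sig].dropna()
            if len(x) < 2 or len(y) < 2:
                continue
            ps.append(wilcoxon_rank_sum(x, y))
            sigs.append(sig)
        fdrs = bh_adjust(np.array(ps)) if ps else np.array([])
        for sig, p, f in zip(sigs, ps, fdrs):
            rows.append({"group": g, "signature": sig, "p": p, "fdr": f,
                         "significant": f < fdr_threshold})
    return pd.DataFrame(rows)


def leading_edge_overlap(res_a: GSEAResult, res_b: GSEAResult,
                         fc_a: pd.Series, fc_b: pd.Series) -> dict:
    """Shared leading-edge genes of two enrichments plus the Pearson
    correlation of the two cohorts' fold changes over the shared genes."""
    if not res_a.leading_edge or not res_b.leading_edge:
        raise ValueError("both leading edges must be nonempty")
    shared = sorted(set(res_a.leading_edge) & set(res_b.leading_edge))
    if len(shared) < 3:
        return {"shared": shared, "r": np.nan, "p": np.nan,
                "note": "fewer than 3 shared genes; correlation undefined"}
    r, p = stats.pearsonr(fc_a.loc[shared], fc_b.loc[shared])
    return {"shared": shared, "r": float(r), "p": float(p)}


def signature_tf_correlation(nes_per_sample, tf_expression) -> tuple[float, float]:
    """Spearman correlation between a per-sample signature score and a TF's
    expression; exact permutation p for n <= 9, t-approximation otherwise."""
    x = np.asarray(nes_per_sample, dtype=float)
    y = np.asarray(tf_expression, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan
    rho = float(stats.spearmanr(x, y).statistic)
    n = x.size
    if n <= 9:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        count = total = 0
        for perm in permutations(range(n)):
            r = stats.spearmanr(rx, ry[list(perm)]).statistic
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total
    p = float(stats.spearmanr(x, y).pvalue)
    return rho, p
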