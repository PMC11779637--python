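"""Cancer-cell-fraction (CCF) posteriors and mutation clonality.

For a somatic point mutation observed with ``alt`` of ``total`` reads in a
tumor sample of purity ``rho``, local tumor copy number ``n_t`` and normal
copy number ``n_n``, the expected variant allele frequency at cancer cell
fraction ``f`` carried on ``m`` chromosomal copies is

    E[VAF] = rho * m * f / (rho * n_t + (1 - rho) * n_n)

The CCF posterior is evaluated on the fixed grid {0.01, 0.02, ..., 1.00}
by scoring the binomial likelihood of the read counts at each grid point and
normalizing.  A mutation's clonal probability is the posterior mass on grid
points strictly above 0.95 (i.e. 0.96..1.00), and the mutation is called
clonal when that probability exceeds 0.5.

Clonality is defined for mutation records only; copy-number deletions are
never assigned CCFs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CCF_GRID = np.round(np.arange(1, 101) * 0.01, 2)
_CLONAL_MASK = CCF_GRID > 0.95  # strict: the 0.95 grid point is subclonal side


@dataclass(frozen=True)
class CCFPosterior:
    """Normalized CCF posterior for one mutation on the 100-point grid."""

    probs: np.ndarray
    clonal_probability: float = field(init=False)
    is_clonal: bool = field(init=False)
    grid: np.ndarray = field(default_factory=lambda: CCF_GRID.copy())

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (100,):
            raise ValueError("posterior must have exactly 100 grid points")
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("posterior probabilities must be non-negative and sum to 1")
        object.__setattr__(self, "probs", p)
        cp = float(p[_CLONAL_MASK].sum())
        object.__setattr__(self, "clonal_probability", cp)
        object.__setattr__(self, "is_clonal", cp > 0.5)

    @property
    def mode(self) -> float:
        return float(CCF_GRID[int(np.argmax(self.probs))])


def expected_vaf(ccf: float, purity: float, tumor_cn: int, normal_cn: int = 2,
                 multiplicity: int = 1) -> float:
    """Expected VAF of a mutation at cancer cell fraction ``ccf``."""
    if not (0 < purity <= 1):
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if tumor_cn < 1 or multiplicity < 1:
        raise ValueError("tumor_cn and multiplicity must be >= 1")
    if multiplicity > tumor_cn:
        raise ValueError("multiplicity cannot exceed tumor copy number")
    v = purity * multiplicity * ccf / (purity * tumor_cn + (1 - purity) * normal_cn)
    return float(min(max(v, 0.0), 1.0))


def _auto_multiplicity(alt: int, total: int, purity: float, tumor_cn: int,
                       normal_cn: int) -> int:
    """Point-estimate multiplicity: VAF/purity scaled by total local CN, rounded
    and clamped to [1, tumor_cn]."""
    vaf = alt / total
    m_hat = round(vaf / purity * (purity * tumor_cn + (1 - purity) * normal_cn))
    return int(min(max(m_hat, 1), tumor_cn))


def ccf_posterior(alt_reads: int, total_reads: int, purity: float, tumor_cn: int,
                  normal_cn: int = 2, multiplicity: int | str = "auto") -> CCFPosterior:
    """Posterior over the 100-point CCF grid for one mutation.

    ``multiplicity="auto"`` uses the standard point estimate
    ``clamp(round((alt/total)/purity * (purity*n_t + (1-purity)*n_n)), 1, n_t)``.
    """
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    if not (0 <= alt_reads <= total_reads):
        raise ValueError("alt_reads must be in [0, total_reads]")
    if multiplicity == "auto":
        multiplicity = _auto_multiplicity(alt_reads, total_reads, purity, tumor_cn, normal_cn)
    vafs = np.array([expected_vaf(f, purity, tumor_cn, normal_cn, multiplicity)
                     for f in CCF_GRID])
    lik = stats.binom.pmf(alt_reads, total_reads, vafs)
    tot = lik.sum()
    if tot <= 0 or not np.isfinite(tot):
        warnings.warn("all-zero binomial likelihood across the CCF grid; "
                      "returning a uniform posterior", RuntimeWarning, stacklevel=2)
        return CCFPosterior(np.full(100, 0.01))
    return CCFPosterior(lik / tot)


def clonality_call(posterior: CCFPosterior) -> str:
    """'clonal' iff the posterior mass on grid CCF > 0.95 exceeds 0.5."""
    return "clonal" if posterior.clonal_probability > 0.5 else "subclonal"


def _gene_fully_clonal(calls: list[str]) -> bool:
    # conservative: a gene is clonal only when every damaging mutation is clonal
    return len(calls) > 0 and all(c == "clonal" for c in calls)


def order_events(calls: pd.DataFrame, gene_a: str, gene_b: str) -> dict:
    """Order two genes' loss events across a cohort from per-mutation clonality.

    ``calls`` is a long table with columns sample, gene, call ('clonal' /
    'subclonal'), one row per damaging mutation.  A sample contributes to the
    ordering only if it has >=1 damaging mutation in both genes.  Within such
    a sample, gene A is called first when A is fully clonal and B is not, and
    vice versa; both-clonal and both-subclonal samples stay unordered.

    Also reports, over all samples carrying each gene, the fraction in which
    that gene is fully clonal.
    """
    required = {"sample", "gene", "call"}
    if not required.issubset(calls.columns):
        raise ValueError(f"calls table needs columns {sorted(required)}")
    per = {}
    for (sample, gene), grp in calls.groupby(["sample", "gene"], sort=True):
        per.setdefault(sample, {})[gene] = _gene_fully_clonal(list(grp["call"]))

    a_first = b_first = unordered = 0
    ordered_samples: dict[str, str] = {}
    for sample, genes in sorted(per.items()):
        if gene_a not in genes or gene_b not in genes:
            continue
        ca, cb = genes[gene_a], genes[gene_b]
        if ca and not cb:
            a_first += 1
            ordered_samples[sample] = f"{gene_a}-first"
        elif cb and not ca:
            b_first += 1
            ordered_samples[sample] = f"{gene_b}-first"
        else:
            unordered += 1
            ordered_samples[sample] = "unordered"

    n_with_a = sum(1 for g in per.values() if gene_a in g)
    n_with_b = sum(1 for g in per.values() if gene_b in g)
    return {
        "gene_a": gene_a,
        "gene_b": gene_b,
        "n_both": a_first + b_first + unordered,
        "a_first": a_first,
        "b_first": b_first,
        "unordered": unordered,
        "fraction_a_first": a_first / max(a_first + b_first + unordered, 1),
        "fraction_b_first": b_first / max(a_first + b_first + unordered, 1),
        "fully_clonal_fraction_a": (
            sum(1 for g in per.values() if g.get(gene_a)) / n_with_a if n_with_a else float("nan")),
        "fully_clonal_fraction_b": (
            sum(1 for g in per.values() if g.get(gene_b)) / n_with_b if n_with_b else float("nan")),
        "per_sample": ordered_samples,
    }


def posterior_table(inputs: pd.DataFrame) -> pd.DataFrame:
    """Vectorized convenience: per-mutation posteriors for a cohort table.

    Expects columns alt_reads, total_reads, purity, tumor_cn and optionally
    normal_cn, multiplicity; returns the input plus mode, clonal_probability
    and call columns.
    """
    out = inputs.copy()
    modes, cps, calls = [], [], []
    for row in inputs.itertuples(index=False):
        post = ccf_posterior(
            int(row.alt_reads), int(row.total_reads), float(row.purity),
            int(row.tumor_cn),
            int(getattr(row, "normal_cn", 2)),
            getattr(row, "multiplicity", "auto"),
        )
        modes.append(post.mode)
        cps.append(post.clonal_probability)
        calls.append(clonality_call(post))
    out["ccf_mode"] = modes
    out["clonal_probability"] = cps
    out["call"] = calls
    return out
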