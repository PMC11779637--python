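"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles (explicit
loops, lgamma-based combinatorics, naive optimizers) and never calls into
locusevo, so agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def binom_pmf(k: int, n: int, p: float) -> float:
    if p <= 0.0:
        return 1.0 if k == 0 else 0.0
    if p >= 1.0:
        return 1.0 if k == n else 0.0
    logc = math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
    return math.exp(logc + k * math.log(p) + (n - k) * math.log(1 - p))


def ccf_posterior_bruteforce(alt, total, purity, tumor_cn, normal_cn=2,
                             multiplicity=1):
    """100-point CCF posterior by direct likelihood evaluation."""
    probs = []
    for i in range(1, 101):
        ccf = i / 100.0
        vaf = purity * multiplicity * ccf / (purity * tumor_cn + (1 - purity) * normal_cn)
        vaf = min(max(vaf, 0.0), 1.0)
        probs.append(binom_pmf(alt, total, vaf))
    s = sum(probs)
    if s == 0.0:  # numerically impossible data; caller falls back to uniform
        return None
    return [x / s for x in probs]


def hypergeom_pmf(a, row1, row2, col1):
    """P(top-left cell = a) for fixed 2x2 margins."""
    n = row1 + row2
    logp = (math.lgamma(row1 + 1) - math.lgamma(a + 1) - math.lgamma(row1 - a + 1)
            + math.lgamma(row2 + 1) - math.lgamma(col1 - a + 1)
            - math.lgamma(row2 - (col1 - a) + 1)
            - (math.lgamma(n + 1) - math.lgamma(col1 + 1) - math.lgamma(n - col1 + 1)))
    return math.exp(logp)


def fisher_twosided_enumeration(table) -> float:
    """Two-sided Fisher p by summing hypergeometric masses <= observed
    (R probability-mass convention with 1+1e-7 slack)."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    lo, hi = max(0, col1 - row2), min(col1, row1)
    p_obs = hypergeom_pmf(a, row1, row2, col1)
    total = 0.0
    for x in range(lo, hi + 1):
        px = hypergeom_pmf(x, row1, row2, col1)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


def wilcoxon_exact_enumeration(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments
    (no ties assumed)."""
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    r_obs = sum(ranks[v] for v in x)
    u_obs = r_obs - n1 * (n1 + 1) / 2
    us = []
    for comb in combinations(range(n1 + n2), n1):
        r = sum(i + 1 for i in comb)
        us.append(r - n1 * (n1 + 1) / 2)
    us = np.array(us, dtype=float)
    lower = np.mean(us <= u_obs)
    upper = np.mean(us >= u_obs)
    return float(min(1.0, 2 * min(lower, upper)))


def gsea_running_sum(stats, hits, p=1.0):
    """Brute-force weighted-KS walk; returns (ES, extremum index)."""
    n = len(stats)
    k = sum(hits)
    wsum = sum(abs(s) ** p for s, h in zip(stats, hits) if h)
    run, best, pos = 0.0, 0.0, 0
    for i in range(n):
        if hits[i]:
            run += (abs(stats[i]) ** p) / wsum if wsum > 0 else 1.0 / k
        else:
            run -= 1.0 / (n - k)
        if abs(run) > abs(best):
            best, pos = run, i
    return best, pos


def prune_fixpoint(entries, strict_rule_a=False):
    """Redundancy-pruning oracle: entries = list of (name, fdr, leading-edge
    set).  Repeatedly scans pairs in ascending-(fdr, name) order and applies
    rule A / rule B until no removal fires; returns surviving names."""
    alive = sorted(entries, key=lambda e: (e[1], e[0]))
    while True:
        removal = None
        for i in range(len(alive)):
            for j in range(i + 1, len(alive)):
                (pn, pf, ple), (qn, qf, qle) = alive[i], alive[j]
                shared = len(ple & qle)
                up, uq = len(ple) - shared, len(qle) - shared
                if strict_rule_a:
                    a_pq = up > shared and up > uq
                    a_qp = uq > shared and uq > up
                else:
                    a_pq = up > shared + uq
                    a_qp = uq > shared + up
                if a_pq:
                    removal = j
                elif a_qp:
                    removal = i
                elif shared > up and shared > uq:
                    removal = j if qf >= pf else i
                if removal is not None:
                    break
            if removal is not None:
                break
        if removal is None:
            return {e[0] for e in alive}
        del alive[removal]


def firth_penalized_loglik(beta, X, y):
    eta = X @ beta
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    pi = 1.0 / (1.0 + np.exp(-eta))
    w = pi * (1 - pi)
    info = (X * w[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(info)
    return ll + 0.5 * logdet if sign > 0 else -np.inf


def firth_optimizer_oracle(X, y):
    """Independent maximizer of the Firth penalized likelihood."""
    from scipy.optimize import minimize

    res = minimize(lambda b: -firth_penalized_loglik(b, X, y),
                   np.zeros(X.shape[1]), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    return res.x


def logrank_two_group_oracle(times, events, groups):
    """Hand-rolled two-group log-rank chi-square: sum of observed-minus-
    expected group-1 events over distinct event times, squared over the
    hypergeometric variance."""
    data = sorted(zip(times, events, groups))
    labels = sorted(set(groups))
    assert len(labels) == 2
    o_minus_e, var = 0.0, 0.0
    for t in sorted({d[0] for d in data if d[1]}):
        at_risk = [d for d in data if d[0] >= t]
        n = len(at_risk)
        n1 = sum(1 for d in at_risk if d[2] == labels[0])
        d_t = sum(1 for d in data if d[0] == t and d[1])
        d1 = sum(1 for d in data if d[0] == t and d[1] and d[2] == labels[0])
        o_minus_e += d1 - d_t * n1 / n
        if n > 1:
            var += d_t * (n1 / n) * (1 - n1 / n) * (n - d_t) / (n - 1)
    return o_minus_e ** 2 / var if var > 0 else 0.0


def eigen_variance_explained_oracle(z):
    """PC1 variance-explained from an eigendecomposition of the member
    covariance (rows centered over samples)."""
    zc = z - z.mean(axis=1, keepdims=True)
    cov = zc @ zc.T
    vals = np.linalg.eigvalsh(cov)
    return float(vals[-1] / vals.sum())
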