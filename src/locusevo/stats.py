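"""Cohort statistics: Firth-penalized logistic regression with nested-model
comparison, exact 2x2 tests, Wilcoxon rank-sum, Kaplan-Meier / log-rank
survival screening and Benjamini-Hochberg correction.

The Firth model maximizes the penalized log-likelihood

    l*(beta) = l(beta) + 0.5 * log det I(beta)

(Jeffreys-prior penalty), which keeps estimates finite under complete
separation and reduces small-sample bias.  Nested models are compared by the
penalized-likelihood-ratio statistic against a chi-squared reference, the
analog of logistf's anova in R.  Progression odds are reported as e^beta.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FirthLogit", "FirthLogitResults", "fit_firth_logistic",
    "compare_nested_models", "fisher_exact_2x2", "wilcoxon_rank_sum",
    "bh_adjust", "compare_survival", "survival_screen_9p21",
]


# ---------------------------------------------------------------------------
# Firth-penalized logistic regression
# ---------------------------------------------------------------------------

class FirthLogit:
    """Logistic regression with Firth bias correction.

    Parameters
    ----------
    endog : (n,) binary response
    exog : (n, p) design matrix including the intercept column
    names : optional column names for reporting
    """

    def __init__(self, endog, exog, names=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog have incompatible shapes")
        if not set(np.unique(self.endog)) <= {0.0, 1.0}:
            raise ValueError("endog must be binary 0/1")
        n, p = self.exog.shape
        if n < p:
            raise ValueError("need at least as many observations as parameters")
        self.names = list(names) if names is not None else [f"x{j}" for j in range(p)]
        rank = np.linalg.matrix_rank(self.exog)
        if rank < p:
            raise ValueError(f"design matrix is collinear (rank {rank} < {p}); "
                             f"columns: {self.names}")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, covariates: list[str],
                       add_intercept: bool = True) -> "FirthLogit":
        X = data[covariates].to_numpy(dtype=float)
        names = list(covariates)
        if add_intercept:
            X = np.column_stack([np.ones(len(data)), X])
            names = ["intercept"] + names
        return cls(data[response].to_numpy(), X, names=names)

    # penalized log-likelihood l(beta) + 0.5*log det Xp'W Xp; the penalty
    # design Xp defaults to the model design but may be a larger design so
    # that restricted and full fits share a comparable penalty (the
    # profile-penalized-likelihood convention for nested-model tests)
    def _penalized_loglik(self, beta, penalty_exog=None):
        Xp = self.exog if penalty_exog is None else penalty_exog
        eta = self.exog @ beta
        ll = float(np.sum(self.endog * eta - np.logaddexp(0.0, eta)))
        pi = 1.0 / (1.0 + np.exp(-eta))
        w = pi * (1 - pi)
        info = (Xp * w[:, None]).T @ Xp
        sign, logdet = np.linalg.slogdet(info)
        if sign <= 0:
            return -np.inf
        return ll + 0.5 * logdet

    def fit(self, tol: float = 1e-8, maxiter: int = 100,
            penalty_exog=None) -> "FirthLogitResults":
        X, y = self.exog, self.endog
        Xp = X if penalty_exog is None else np.asarray(penalty_exog, dtype=float)
        n, p = X.shape
        beta = np.zeros(p)
        converged = False
        pll = self._penalized_loglik(beta, penalty_exog)
        it = 0
        for it in range(1, maxiter + 1):
            eta = X @ beta
            pi = 1.0 / (1.0 + np.exp(-eta))
            w = pi * (1 - pi)
            info_p = (Xp * w[:, None]).T @ Xp
            # hat diagonal of W^{1/2} Xp (Xp'W Xp)^{-1} Xp' W^{1/2}
            h = w * np.einsum("ij,jk,ik->i", Xp, np.linalg.inv(info_p), Xp)
            score = X.T @ (y - pi + h * (0.5 - pi))
            info = (X * w[:, None]).T @ X
            step = np.linalg.solve(info, score)
            # step-halving on the penalized likelihood
            new_beta = beta + step
            new_pll = self._penalized_loglik(new_beta, penalty_exog)
            halvings = 0
            while new_pll < pll and halvings < 25:
                step *= 0.5
                new_beta = beta + step
                new_pll = self._penalized_loglik(new_beta, penalty_exog)
                halvings += 1
            delta = np.max(np.abs(new_beta - beta))
            beta, pll = new_beta, new_pll
            if delta < tol:
                converged = True
                break
        eta = X @ beta
        pi = 1.0 / (1.0 + np.exp(-eta))
        w = pi * (1 - pi)
        info = (X * w[:, None]).T @ X
        se = np.sqrt(np.diag(np.linalg.inv(info)))
        return FirthLogitResults(self, beta, se, pll, pi, converged, it)


class FirthLogitResults:
    """Fit of a :class:`FirthLogit` model."""

    def __init__(self, model, beta, se, penalized_loglik, fitted_probs,
                 converged, iterations):
        self.model = model
        self.beta = beta
        self.se = se
        self.penalized_loglik = float(penalized_loglik)
        self.fitted_probs = fitted_probs
        self.converged = bool(converged)
        self.iterations = int(iterations)

    @property
    def odds(self) -> np.ndarray:
        """Per-coefficient odds, e^beta."""
        return np.exp(self.beta)

    def wald_pvalues(self) -> np.ndarray:
        z = self.beta / self.se
        return 2 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.beta,
            "se": self.se,
            "odds": self.odds,
            "p_wald": self.wald_pvalues(),
        }, index=self.model.names)

    def __repr__(self):
        status = "converged" if self.converged else "NOT converged"
        return (f"<FirthLogitResults {status} in {self.iterations} it, "
                f"pll={self.penalized_loglik:.4f}>")


def fit_firth_logistic(X, y, names=None, tol: float = 1e-8,
                       maxiter: int = 100) -> FirthLogitResults:
    """Functional wrapper around :class:`FirthLogit`."""
    return FirthLogit(y, X, names=names).fit(tol=tol, maxiter=maxiter)


def compare_nested_models(fit1: FirthLogitResults, fit2: FirthLogitResults) -> dict:
    """Penalized-likelihood-ratio test of nested Firth fits (model 1 in model 2).

    Returns the LR statistic, df, chi-squared p, per-coefficient odds of the
    larger model and expected progressor counts per genotype cell (sum of
    fitted probabilities over samples sharing a covariate pattern).
    """
    X1, X2 = fit1.model.exog, fit2.model.exog
    if X2.shape[1] <= X1.shape[1] or X1.shape[0] != X2.shape[0]:
        raise ValueError("model 1 must be strictly nested in model 2")
    # nesting check: every column of X1 must lie in the column space of X2
    resid = X1 - X2 @ np.linalg.lstsq(X2, X1, rcond=None)[0]
    if np.max(np.abs(resid)) > 1e-8:
        raise ValueError("designs are not nested")
    # refit the restricted model under the full-design penalty so both
    # penalized likelihoods are on the same scale (logistf PLR convention)
    restricted = FirthLogit(fit1.model.endog, X1, names=fit1.model.names)
    fit1 = restricted.fit(penalty_exog=X2)
    lr = 2.0 * (fit2.penalized_loglik - fit1.penalized_loglik)
    lr = max(lr, 0.0)
    df = X2.shape[1] - X1.shape[1]
    p = float(stats.chi2.sf(lr, df)) if lr > 0 else 1.0

    # genotype cells = distinct non-intercept covariate patterns of model 2
    patt = X2[:, 1:] if X2.shape[1] > 1 else X2
    cells = {}
    for i, row in enumerate(map(tuple, patt)):
        cells.setdefault(row, []).append(i)
    expected = {
        cell: {
            "n": len(idx),
            "expected_model1": float(np.sum(fit1.fitted_probs[idx])),
            "expected_model2": float(np.sum(fit2.fitted_probs[idx])),
            "observed": float(np.sum(fit2.model.endog[idx])),
        }
        for cell, idx in sorted(cells.items())
    }
    return {
        "statistic": float(lr),
        "df": int(df),
        "p": p,
        "odds": dict(zip(fit2.model.names, np.exp(fit2.beta))),
        "expected_counts": expected,
    }


def compare_progression_models(cohort: pd.DataFrame, interaction: bool = False) -> dict:
    """Firth comparison of the two nested models of cancer initiation:
    model 1 (TP53 LoF only) versus model 2 (TP53 + CDKN2A LoF, optionally
    with interaction).  ``cohort`` needs columns tp53_lof, cdkn2a_lof,
    progressed.  Returns the nested-model comparison plus both fits."""
    data = cohort.copy()
    fit1 = FirthLogit.from_dataframe(data, "progressed", ["tp53_lof"]).fit()
    covs = ["tp53_lof", "cdkn2a_lof"]
    if interaction:
        data["tp53_x_cdkn2a"] = data["tp53_lof"] * data["cdkn2a_lof"]
        covs.append("tp53_x_cdkn2a")
    fit2 = FirthLogit.from_dataframe(data, "progressed", covs).fit()
    out = compare_nested_models(fit1, fit2)
    out["fit1"], out["fit2"] = fit1, fit2
    return out


# ---------------------------------------------------------------------------
# Exact and rank tests
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table, probability-mass convention
    (sum of hypergeometric probabilities <= that of the observed table, with a
    1+1e-7 tolerance factor, as in R)."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative integer cells")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``mode='auto'`` uses the exact null distribution when min(n) <= 10 and
    there are no ties, otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    if mode == "auto":
        mode = "exact" if (min(x.size, y.size) <= 10 and not has_ties) else "normal"
    if mode == "exact":
        if has_ties:
            # exact enumeration with ties: permutation distribution of U
            res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method=stats.PermutationMethod())
            return float(res.pvalue)
        method = "exact"
    elif mode == "normal":
        method = "asymptotic"
    else:
        raise ValueError("mode must be 'auto', 'exact' or 'normal'")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def compare_survival(records: pd.DataFrame, groups: list[str] | None = None) -> dict:
    """Kaplan-Meier curves per group plus the log-rank test across groups.

    ``records`` has columns sample, time, event, group.  Returns the fitted
    KM curves, the log-rank chi-squared statistic, its df (groups-1) and p.
    """
    req = {"time", "event", "group"}
    if not req.issubset(records.columns):
        raise ValueError(f"records need columns {sorted(req)}")
    if np.any(records["time"].to_numpy(dtype=float) < 0):
        raise ValueError("times must be non-negative")
    if groups is not None:
        unknown = set(groups) - set(records["group"])
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        records = records[records["group"].isin(groups)]
    if int(records["event"].sum()) < 1:
        raise ValueError("no events in the data")
    labels = sorted(records["group"].unique())
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    curves = {}
    for g in labels:
        sub = records[records["group"] == g]
        km = KaplanMeierFitter(label=str(g))
        km.fit(sub["time"], event_observed=sub["event"])
        curves[g] = km
    lr = multivariate_logrank_test(records["time"], records["group"], records["event"])
    return {
        "curves": curves,
        "statistic": float(lr.test_statistic),
        "df": len(labels) - 1,
        "p": float(lr.p_value),
    }


def survival_screen_9p21(profiles: list[dict], reference_samples: list[str],
                         records: pd.DataFrame, fdr_threshold: float = 0.1,
                         min_events: int = 2) -> pd.DataFrame:
    """Screen each co-deletion profile group against the wild-type reference.

    Each group with at least ``min_events`` observed events is compared to the
    reference by log-rank; p-values are BH-adjusted across groups and flagged
    at FDR < ``fdr_threshold``.
    """
    if not reference_samples:
        raise ValueError("reference set is empty")
    recs = records.set_index("sample")
    ref = recs.loc[recs.index.intersection(reference_samples)].assign(group="reference")
    rows = []
    for i, prof in enumerate(profiles):
        members = recs.index.intersection(prof["samples"])
        grp = recs.loc[members].assign(group="group")
        label = prof.get("group_id", f"profile_{i}")
        if int(grp["event"].sum()) < min_events:
            rows.append({"group": label, "n": len(grp), "p": np.nan,
                         "skipped": True})
            continue
        both = pd.concat([grp, ref]).reset_index()
        res = compare_survival(both)
        rows.append({"group": label, "n": len(grp), "p": res["p"],
                     "skipped": False})
    out = pd.DataFrame(rows)
    tested = out[~out["skipped"]]
    out["fdr"] = np.nan
    if len(tested):
        out.loc[tested.index, "fdr"] = bh_adjust(tested["p"].to_numpy())
    out["significant"] = out["fdr"] < fdr_threshold
    return out
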