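"""Preranked GSEA, redundancy pruning, single-sample scoring, correlations."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from _oracles import gsea_running_sum, prune_fixpoint
from locusevo.enrichment import (GSEAResult, _es_walk, compare_infiltration,
                                 filter_expressed_genes, gsea_preranked,
                                 leading_edge_overlap, prune_redundant_pathways,
                                 rank_genes_by_fc, signature_tf_correlation,
                                 ssgsea_scores)


def test_filter_expressed_genes_boundary():
    probs = {"a": 0.9, "b": 0.89, "c": 1.0, "d": 0.0}
    assert filter_expressed_genes(probs) == {"a", "c"}
    assert filter_expressed_genes({}) == set()
    with pytest.raises(ValueError):
        filter_expressed_genes({"a": 1.2})


def test_rank_genes_by_fc_definition():
    idx = ["doubled"] + [f"flat{i}" for i in range(9)] + ["allzero"]
    counts = pd.DataFrame({
        "a1": [200] + [100] * 9 + [0], "a2": [210] + [110] * 9 + [0],
        "b1": [100] + [100] * 9 + [0], "b2": [110] + [110] * 9 + [0],
    }, index=idx)
    ranked = rank_genes_by_fc(counts, ["a1", "a2"], ["b1", "b2"])
    assert "allzero" not in ranked.index
    assert ranked.loc["doubled"] == pytest.approx(1.0, abs=0.1)
    assert ranked.loc["flat0"] == pytest.approx(0.0, abs=0.1)
    assert ranked.index[0] == "doubled"  # descending, ties by name
    assert list(ranked.index[1:]) == sorted(ranked.index[1:])
    with pytest.raises(ValueError):
        rank_genes_by_fc(counts, ["a1"], ["a1"])


def test_es_reaches_one_for_top_k_set():
    ranked = pd.Series(np.linspace(10, 1, 50), index=[f"g{i}" for i in range(50)])
    res = gsea_preranked(ranked, {"top": [f"g{i}" for i in range(12)]},
                         n_perm=100, seed=0)[0]
    assert res.es == pytest.approx(1.0)
    assert res.leading_edge == [f"g{i}" for i in range(12)]


def test_es_matches_bruteforce_walk():
    rng = np.random.default_rng(23)
    for _ in range(50):
        n = int(rng.integers(6, 60))
        stats_ = np.sort(rng.normal(size=n))[::-1]
        k = int(rng.integers(1, n))
        hits = np.zeros(n, dtype=bool)
        hits[rng.choice(n, size=k, replace=False)] = True
        if hits.all():
            hits[0] = False
        es, pos = _es_walk(stats_, hits, 1.0)
        o_es, o_pos = gsea_running_sum(list(stats_), list(hits), 1.0)
        assert es == pytest.approx(o_es, abs=1e-12)
        assert pos == o_pos


def test_small_worked_example():
    # 6-gene list, 2-gene set, stats (4,3,2,1,1,1)
    stats_ = np.array([4.0, 3.0, 2.0, 1.0, 1.0, 1.0])
    hits = np.array([True, False, True, False, False, False])
    es, _ = _es_walk(stats_, hits, 1.0)
    o_es, _ = gsea_running_sum(list(stats_), list(hits), 1.0)
    assert es == pytest.approx(o_es, abs=1e-12)


def test_es_invariant_to_monotone_rescale_at_p0():
    rng = np.random.default_rng(29)
    stats_ = np.sort(rng.normal(size=40))[::-1]
    hits = np.zeros(40, dtype=bool)
    hits[rng.choice(40, 8, replace=False)] = True
    es1, _ = _es_walk(stats_, hits, 0.0)
    es2, _ = _es_walk(stats_ * 7.5 + 0, hits, 0.0)  # positive scaling keeps order
    assert es1 == pytest.approx(es2, abs=1e-12)


def test_gsea_leading_edge_is_subset_and_signs_agree():
    rng = np.random.default_rng(31)
    genes = [f"g{i}" for i in range(120)]
    ranked = pd.Series(np.sort(rng.normal(size=120))[::-1], index=genes)
    sets = {f"s{j}": list(rng.choice(genes, 15, replace=False)) for j in range(5)}
    for r in gsea_preranked(ranked, sets, n_perm=150, seed=1):
        assert set(r.leading_edge) <= set(sets[r.name])
        assert abs(r.es) <= 1
        assert np.sign(r.nes) == np.sign(r.es) or r.es == 0
        assert 0 < r.p <= 1 and 0 < r.fdr <= 1


def test_gsea_input_validation():
    ranked = pd.Series([3.0, 2.0, 1.0], index=["a", "b", "c"])
    with pytest.raises(ValueError, match="n_perm"):
        gsea_preranked(ranked, {"s": ["a"]}, n_perm=10)
    with pytest.warns(RuntimeWarning, match="no overlap"):
        out = gsea_preranked(ranked, {"s": ["zzz"]}, n_perm=100, min_size=1)
    assert out == []


def _res(name, fdr, le):
    return GSEAResult(name, 0.5, 1.0, 0.01, fdr, list(le), len(le))


def test_prune_rule_b_removes_higher_fdr():
    p = _res("P", 0.01, [f"g{i}" for i in range(1, 11)])
    q = _res("Q", 0.05, [f"g{i}" for i in range(1, 7)] + ["g11", "g12"])
    kept = prune_redundant_pathways([p, q])
    assert [r.name for r in kept] == ["P"]


def test_prune_rule_a_ignores_fdr():
    # P has 9 unique vs shared(1) + unique_Q(1): Q removed though its FDR is lower
    p = _res("P", 0.05, [f"g{i}" for i in range(1, 11)])
    q = _res("Q", 0.001, ["g1", "g11"])
    kept = prune_redundant_pathways([p, q])
    assert [r.name for r in kept] == ["P"]


def test_prune_matches_fixpoint_oracle_and_idempotent():
    rng = np.random.default_rng(37)
    pool = [f"g{i}" for i in range(30)]
    for _ in range(10):
        results = []
        for j in range(int(rng.integers(3, 8))):
            le = list(rng.choice(pool, size=int(rng.integers(2, 12)), replace=False))
            results.append(_res(f"s{j}", float(rng.uniform(0, 0.2)), le))
        kept = prune_redundant_pathways(results)
        oracle = prune_fixpoint([(r.name, r.fdr, set(r.leading_edge)) for r in results])
        assert {r.name for r in kept} == oracle
        again = prune_redundant_pathways(kept)
        assert [r.name for r in again] == [r.name for r in kept]


def test_prune_duplicate_names_rejected():
    with pytest.raises(ValueError):
        prune_redundant_pathways([_res("P", 0.1, ["a"]), _res("P", 0.2, ["b"])])


def test_ssgsea_monotone_in_signature_rank():
    genes = [f"g{i}" for i in range(40)]
    sig = genes[:8]
    up = pd.Series(np.arange(40, 0, -1), index=genes, dtype=float)
    down = pd.Series(np.arange(1, 41), index=genes, dtype=float)
    expr = pd.DataFrame({"s": up, "t": down})
    scores = ssgsea_scores(expr, {"sig": sig}, znorm=False)
    assert scores.loc["s", "sig"] > scores.loc["t", "sig"]


def test_ssgsea_constant_matrix_equal_scores():
    expr = pd.DataFrame(np.ones((20, 4)), index=[f"g{i}" for i in range(20)],
                        columns=list("abcd"))
    scores = ssgsea_scores(expr, {"sig": ["g0", "g3", "g7"]}, znorm=False)
    assert scores["sig"].nunique() == 1


def test_ssgsea_absent_signature_is_nan():
    expr = pd.DataFrame(np.ones((5, 2)), index=[f"g{i}" for i in range(5)],
                        columns=["a", "b"])
    with pytest.warns(RuntimeWarning, match="absent"):
        scores = ssgsea_scores(expr, {"none": ["zz"]})
    assert scores["none"].isna().all()


def test_compare_infiltration_null_and_m1():
    rng = np.random.default_rng(41)
    scores = pd.DataFrame(rng.normal(size=(40, 3)), columns=["s1", "s2", "s3"],
                          index=[f"c{i}" for i in range(40)])
    groups = pd.Series(["ref"] * 20 + ["g"] * 20, index=scores.index)
    out = compare_infiltration(scores, groups, "ref")
    assert not out["significant"].any()
    single = compare_infiltration(scores[["s1"]], groups, "ref")
    assert single.loc[0, "fdr"] == pytest.approx(single.loc[0, "p"])


def test_leading_edge_overlap_correlations():
    a = _res("A", 0.01, ["g1", "g2", "g3", "g4"])
    b = _res("B", 0.01, ["g2", "g3", "g4", "g5"])
    fc = pd.Series({"g1": 1.0, "g2": 2.0, "g3": -1.0, "g4": 0.5, "g5": 3.0})
    res = leading_edge_overlap(a, b, fc, fc)
    assert res["shared"] == ["g2", "g3", "g4"] and res["r"] == pytest.approx(1.0)
    res = leading_edge_overlap(a, b, fc, -fc)
    assert res["r"] == pytest.approx(-1.0)
    tiny = _res("C", 0.01, ["g2"])
    out = leading_edge_overlap(a, tiny, fc, fc)
    assert np.isnan(out["r"])


def test_signature_tf_correlation_extremes_and_exact_p():
    x = np.arange(8.0)
    rho, p = signature_tf_correlation(x, x)
    assert rho == pytest.approx(1.0) and p == pytest.approx(2 / math.factorial(8) * 1)
    rho, _ = signature_tf_correlation(x, -x)
    assert rho == pytest.approx(-1.0)
    # exact p equals an independent enumeration for n=6
    rng = np.random.default_rng(43)
    a, b = rng.normal(size=6), rng.normal(size=6)
    rho, p = signature_tf_correlation(a, b)
    ra, rb = sps.rankdata(a), sps.rankdata(b)
    count = total = 0
    for perm in permutations(range(6)):
        r = sps.spearmanr(ra[list(perm)], rb).statistic
        total += 1
        count += abs(r) >= abs(rho) - 1e-12
    assert p == pytest.approx(count / total)
    # constant vector undefined
    rho, p = signature_tf_correlation(np.ones(5), np.arange(5))
    assert np.isnan(rho) and np.isnan(p)
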