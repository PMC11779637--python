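"""Causal TF-network protocol: gene selection, MI network, modules, NEO."""

import numpy as np
import pandas as pd
import pytest

from _oracles import eigen_variance_explained_oracle
from locusevo import simulate
from locusevo.network import (CAUSAL_MODELS, GeneModule, _eigengene, compute_k,
                              detect_modules, filter_causal_models, filter_modules,
                              infer_tf_network, neo_single_marker,
                              run_causal_protocol, select_variable_genes)


# ---------------------------------------------------------------------------
# gene selection and k
# ---------------------------------------------------------------------------

def test_select_variable_genes_counts_and_ties():
    pattern = np.sin(np.arange(20))
    expr = pd.DataFrame(pattern * np.arange(1, 101)[:, None],
                        index=[f"g{i:03d}" for i in range(100)])
    sel = select_variable_genes(expr)
    assert len(sel) == 50
    # the scaled construction makes the last 50 rows the most variable
    assert set(sel) == {f"g{i:03d}" for i in range(50, 100)}
    # all-equal variance: lexicographically first half wins
    flat = pd.DataFrame(np.tile(np.sin(np.arange(10)), (6, 1)),
                        index=list("fedcba"))
    assert select_variable_genes(flat) == ["a", "b", "c"]


@pytest.mark.parametrize("nag,expected", [(300, 20), (7500, 500), (10, 1)])
def test_compute_k_formula(nag, expected):
    assert compute_k(nag) == expected


def test_compute_k_rejects_zero_module_size():
    with pytest.raises(ValueError):
        compute_k(100, genes_per_module=0)


# ---------------------------------------------------------------------------
# eigengene
# ---------------------------------------------------------------------------

def test_eigengene_variance_explained_matches_svd_oracle():
    rng = np.random.default_rng(5)
    for _ in range(5):
        z = rng.normal(size=(12, 30))
        _, ve = _eigengene(z)
        assert ve == pytest.approx(eigen_variance_explained_oracle(z), abs=1e-10)


def test_eigengene_oriented_positively():
    rng = np.random.default_rng(6)
    base = rng.normal(size=50)
    z = np.vstack([base + rng.normal(0, 0.2, 50) for _ in range(8)])
    pc1, ve = _eigengene(z)
    corr = np.corrcoef(np.vstack([z.mean(axis=0), pc1]))[0, 1]
    assert corr > 0.9 and ve > 0.8


# ---------------------------------------------------------------------------
# MI network
# ---------------------------------------------------------------------------

def test_mi_network_keeps_copies_drops_noise():
    rng = np.random.default_rng(8)
    n = 300
    tf = rng.normal(size=n)
    expr = pd.DataFrame({
        "TF": tf,
        "copy": tf + rng.normal(0, 1e-6, n),
        "noise": rng.normal(size=n),
    }).T
    net = infer_tf_network(expr, ["TF"], seed=0)
    assert "copy" in set(net["target"])
    assert "noise" not in set(net["target"])


def test_mi_network_dpi_prunes_indirect_edge():
    rng = np.random.default_rng(9)
    hits = 0
    for rep in range(5):
        n = 300
        tf1 = rng.normal(size=n)
        tf2 = 0.95 * tf1 + rng.normal(0, 0.3, n)
        g = 0.95 * tf2 + rng.normal(0, 0.3, n)
        expr = pd.DataFrame({"TF1": tf1, "TF2": tf2, "g": g}).T
        net = infer_tf_network(expr, ["TF1", "TF2"], seed=rep)
        edges = set(zip(net["tf"], net["target"]))
        hits += ("TF1", "g") not in edges and ("TF2", "g") in edges
    assert hits >= 4


def test_mi_network_warns_few_samples():
    rng = np.random.default_rng(10)
    expr = pd.DataFrame(rng.normal(size=(3, 10)), index=["TF", "a", "b"])
    with pytest.warns(RuntimeWarning, match="unstable"):
        infer_tf_network(expr, ["TF"], seed=0)
    with pytest.raises(ValueError, match="TF"):
        infer_tf_network(expr, ["absent"], seed=0)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

def _two_module_matrix(seed=12, n=80):
    rng = np.random.default_rng(seed)
    f1, f2 = rng.normal(size=n), rng.normal(size=n)
    rows, names = [], []
    for i in range(15):
        rows.append(f1 + rng.normal(0, 0.4, n)); names.append(f"a{i:02d}")
    for i in range(15):
        rows.append(f2 + rng.normal(0, 0.4, n)); names.append(f"b{i:02d}")
    return pd.DataFrame(rows, index=names)


def test_detect_modules_recovers_planted_structure():
    expr = _two_module_matrix()
    mods = detect_modules(expr, 2, iterations=500, seed=123)
    assert len(mods) == 2
    for truth in ({f"a{i:02d}" for i in range(15)}, {f"b{i:02d}" for i in range(15)}):
        best = max(len(truth & set(m.members)) / len(truth | set(m.members))
                   for m in mods)
        assert best >= 0.8


def test_detect_modules_deterministic_and_bounded():
    expr = _two_module_matrix(seed=13)
    m1 = detect_modules(expr, 2, iterations=300, seed=123)
    m2 = detect_modules(expr, 2, iterations=300, seed=123)
    assert [m.members for m in m1] == [m.members for m in m2]
    with pytest.raises(ValueError, match="k"):
        detect_modules(expr, 20, seed=123)


def test_detect_modules_noise_has_low_coherence():
    rng = np.random.default_rng(14)
    expr = pd.DataFrame(rng.normal(size=(40, 60)),
                        index=[f"n{i:02d}" for i in range(40)])
    mods = detect_modules(expr, 3, iterations=300, seed=123)
    z = ((expr.sub(expr.mean(axis=1), axis=0))
         .div(expr.std(axis=1, ddof=0), axis=0))
    for m in mods:
        sub = np.corrcoef(z.loc[m.members].to_numpy())
        np.fill_diagonal(sub, np.nan)
        assert np.nanmean(sub) < 0.2


def test_filter_modules_thresholds():
    expr = _two_module_matrix(seed=15)
    mods = detect_modules(expr, 2, iterations=300, seed=123)
    net = pd.DataFrame({"tf": [], "target": [], "mi": []})
    # without any TF evidence nothing can survive
    kept = filter_modules(mods, expr, {"a00", "a01", "a02"}, net, n_perm=50)
    assert kept == []
    # attach a perfect TF to module 'a' and use an inclusive VE threshold
    amod = next(m for m in mods if sum(g.startswith("a") for g in m.members) > 7)
    tf_net = pd.DataFrame({"tf": ["a00"] * 10,
                           "target": [f"a{i:02d}" for i in range(1, 11)],
                           "mi": [1.0] * 10})
    kept = filter_modules(mods, expr, set(amod.members), tf_net,
                          var_explained_min=amod.variance_explained - 1e-9,
                          n_perm=50)
    assert [m.module_id for m in kept] == [amod.module_id]
    assert kept[0].candidate_tfs == ["a00"]
    # a stricter Fisher cutoff drops it
    kept = filter_modules(mods, expr, set(amod.members), tf_net,
                          var_explained_min=0.1, fisher_p_max=1e-30, n_perm=50)
    assert kept == []


# ---------------------------------------------------------------------------
# NEO single-marker orientation
# ---------------------------------------------------------------------------

def _chain(rng, n=500, a=0.7, b=0.7):
    m = rng.binomial(1, 0.5, n).astype(float)
    x = a * m + rng.normal(0, np.sqrt(1 - a**2 / 4), n)
    y = b * x + rng.normal(0, np.sqrt(max(1 - b**2, 0.1)), n)
    return m, x, y


def test_neo_orients_chain_as_causal():
    rng = np.random.default_rng(21)
    res = neo_single_marker(*_chain(rng))
    assert res.best_model == "causal"
    assert res.significant and res.neo_score >= 0.5
    assert set(res.model_logp) == set(CAUSAL_MODELS)


def test_neo_confounded_not_called_causal():
    rng = np.random.default_rng(22)
    n = 500
    m = rng.binomial(1, 0.5, n).astype(float)
    a = 0.7 * m + rng.normal(0, 0.7, n)
    b = 0.7 * m + rng.normal(0, 0.7, n)
    res = neo_single_marker(m, a, b)
    assert res.best_model == "confounded"
    assert not res.significant


def test_neo_independent_not_significant():
    rng = np.random.default_rng(23)
    fails = 0
    for _ in range(10):
        m = rng.binomial(1, 0.5, 300).astype(float)
        res = neo_single_marker(m, rng.normal(size=300), rng.normal(size=300))
        fails += res.significant
    assert fails <= 1


def test_neo_rejects_degenerate_inputs():
    with pytest.raises(ValueError, match="marker"):
        neo_single_marker(np.zeros(10), np.arange(10.0), np.arange(10.0))
    with pytest.raises(ValueError, match="constant"):
        neo_single_marker(np.r_[np.zeros(5), np.ones(5)], np.ones(10), np.arange(10.0))


# ---------------------------------------------------------------------------
# step-3 filters and the full protocol
# ---------------------------------------------------------------------------

def _model(tf, significant=True):
    from locusevo.network import CausalModelResult
    return CausalModelResult("marker", tf, "M1",
                             {m: -1.0 for m in CAUSAL_MODELS}, 1.0,
                             "causal" if significant else "reactive", significant)


def test_filter_causal_models_rules():
    # TFa carries 3 of 8 significant models (37.5% >= 30%); TFb only 1 (12.5%)
    models = [_model("TFa")] * 3 + [_model("TFb")] + [_model(f"x{i}") for i in range(4)]
    de = pd.DataFrame({"log2fc": [1, 1], "fdr": [0.01, 0.01]}, index=["TFa", "TFb"])
    corr = pd.DataFrame({"rho": [0.8, 0.8], "fdr": [0.01, 0.01]}, index=["TFa", "TFb"])
    tfs, kept = filter_causal_models(models, de, corr)
    assert tfs == ["TFa"] and len(kept) == 3
    # R exactly 0.5 fails the strict inequality
    corr.loc["TFa", "rho"] = 0.5
    tfs, kept = filter_causal_models(models, de, corr)
    assert tfs == []
    # non-significant input set yields empty output, not an error
    assert filter_causal_models([_model("TFa", significant=False)], de, corr) == ([], [])


def test_full_protocol_recovers_planted_mediator():
    counts, marker, truth = simulate.simulate_expression_cohort(
        n_samples=200, n_genes=200, n_modules=1, marker_effect=-1.0, seed=1)
    res = run_causal_protocol(counts, marker, ["TF1"],
                              set(truth["tf_targets"]["TF1"]), preset="p-be",
                              seed=123, iterations=1000, n_perm=100)
    assert res["final_tfs"] == ["TF1"]
    kept = res["retained_modules"][0]
    planted = set(truth["tf_targets"]["TF1"])
    jacc = len(planted & set(kept.members)) / len(planted | set(kept.members))
    assert jacc >= 0.6


def test_protocol_rejects_unknown_preset():
    counts, marker, _ = simulate.simulate_expression_cohort(
        n_samples=30, n_genes=40, n_modules=1, marker_effect=-1.0, seed=2)
    with pytest.raises(ValueError, match="preset"):
        run_causal_protocol(counts, marker, ["TF1"], set(), preset="zzz")
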