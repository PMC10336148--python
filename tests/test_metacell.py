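"""Metacell construction, stain correlation and preranked GSEA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stcem import SynthConfig, expression, metacell
from stcem.synthetic import generate_sc


@pytest.fixture(scope="module")
def sc_data():
    mat, bodipy, truth = generate_sc(SynthConfig(seed=0, n_cells_sc=600))
    return expression.normalize(mat), bodipy, truth


def test_k1_metacells_are_single_cells_and_correlation_matches(sc_data):
    norm, bodipy, _ = sc_data
    n = norm.n_cells
    mc = metacell.build_metacells(norm, bodipy, k=1, seed=0, n_seeds=n)
    assert all(len(m) == 1 for m in mc.members)
    order = np.concatenate(mc.members)
    np.testing.assert_array_equal(mc.expression.to_numpy(), norm.norm[order])
    # k=1 stain correlation equals the single-cell correlation exactly
    corr = metacell.stain_correlation(mc).set_index("gene")["pearson_r"]
    lb = np.log10(bodipy)[order]
    for g in list(norm.gene_names)[:15]:
        j = list(norm.gene_names).index(g)
        expected = stats.pearsonr(norm.norm[order, j], lb).statistic
        assert corr[g] == pytest.approx(expected, abs=1e-12)


def test_metacells_reduce_gene_variance(sc_data):
    norm, bodipy, _ = sc_data
    mc = metacell.build_metacells(norm, bodipy, k=20, seed=0, n_seeds=100)
    v_mc = mc.expression.to_numpy().var(axis=0)
    v_sc = norm.norm.var(axis=0)
    expressed = v_sc > 0
    assert np.median(v_mc[expressed] / v_sc[expressed]) < 0.5


def test_metacell_determinism_and_k_bounds(sc_data):
    norm, bodipy, _ = sc_data
    a = metacell.build_metacells(norm, bodipy, k=10, seed=5)
    b = metacell.build_metacells(norm, bodipy, k=10, seed=5)
    assert all(np.array_equal(x, y) for x, y in zip(a.members, b.members))
    with pytest.raises(ValueError, match="exceeds"):
        metacell.build_metacells(norm, bodipy, k=norm.n_cells + 1)


def test_max_shared_bounds_metacell_overlap(sc_data):
    norm, bodipy, _ = sc_data
    mc = metacell.build_metacells(norm, bodipy, k=20, seed=0, n_seeds=150, max_shared=5)
    sets = [set(m.tolist()) for m in mc.members]
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            assert len(sets[i] & sets[j]) <= 5


def test_gene_identical_to_stain_has_r_one(sc_data):
    norm, bodipy, _ = sc_data
    mod = norm.copy()
    mod.norm[:, 0] = np.log10(bodipy)
    mc = metacell.build_metacells(mod, bodipy, k=5, seed=1, n_seeds=80)
    corr = metacell.stain_correlation(mc).set_index("gene")["pearson_r"]
    assert corr[mod.gene_names[0]] == pytest.approx(1.0, abs=1e-12)


def test_planted_markers_occupy_ranking_extremes():
    tops, bots = [], []
    for seed in range(10):
        mat, bodipy, truth = generate_sc(SynthConfig(seed=seed, n_cells_sc=600))
        norm = expression.normalize(mat)
        mc = metacell.build_metacells(norm, bodipy, k=20, seed=seed, n_seeds=120)
        corr = metacell.stain_correlation(mc).dropna().reset_index(drop=True)
        rank = {g: i for i, g in enumerate(corr["gene"])}
        n = len(corr)
        foamy = truth.programs["foamy"] + truth.sc_programs["foamy"]
        homeo = truth.programs["homeostatic"] + truth.sc_programs["homeostatic"]
        tops.append(np.mean([rank[g] < n / 10 for g in foamy if g in rank]))
        bots.append(np.mean([rank[g] >= 9 * n / 10 for g in homeo if g in rank]))
    assert np.mean(tops) >= 0.8
    assert np.mean(bots) >= 0.8


def test_metacell_correlation_amplifies_planted_signal():
    stronger = 0
    for seed in range(10):
        mat, bodipy, truth = generate_sc(SynthConfig(seed=seed, n_cells_sc=500))
        norm = expression.normalize(mat)
        marker = truth.sc_programs["foamy"][0]
        j = list(norm.gene_names).index(marker)
        r_sc = abs(stats.pearsonr(norm.norm[:, j], np.log10(bodipy)).statistic)
        mc = metacell.build_metacells(norm, bodipy, k=20, seed=seed, n_seeds=100)
        r_mc = abs(
            metacell.stain_correlation(mc).set_index("gene")["pearson_r"][marker]
        )
        stronger += r_mc > r_sc
    assert stronger >= 8


# ---------------------------------------------------------------- GSEA

def _gsea_oracle_es(ranked_stats, in_set, weight):
    """Brute-force running-sum enrichment score."""
    hits = np.abs(ranked_stats) ** weight * in_set
    denom_hit = hits.sum()
    n_miss = (~in_set.astype(bool)).sum()
    run, best = 0.0, 0.0
    for i in range(len(ranked_stats)):
        if in_set[i]:
            run += hits[i] / denom_hit
        else:
            run -= 1.0 / n_miss
        if abs(run) > abs(best):
            best = run
    return best


def test_es_matches_brute_force_oracle_on_toy_lists():
    rng = np.random.default_rng(0)
    for trial in range(5):
        stats_vec = np.sort(rng.normal(size=20))[::-1]
        genes = [f"g{i}" for i in range(20)]
        members = list(rng.choice(genes, size=5, replace=False))
        ranks = pd.Series(stats_vec, index=genes)
        out = metacell.preranked_gsea(ranks, {"t": members}, weight=1.0, n_perm=50, seed=trial)
        in_set = np.isin(genes, members)
        oracle = _gsea_oracle_es(stats_vec, in_set, 1.0)
        assert out["ES"].iloc[0] == pytest.approx(oracle, abs=1e-12)


def test_set_at_top_of_ranking_has_maximal_es():
    genes = [f"g{i}" for i in range(100)]
    ranks = pd.Series(np.linspace(3, -3, 100), index=genes)
    sets = {"top": genes[:8], "mid": genes[40:48], "bottom": genes[-8:]}
    out = metacell.preranked_gsea(ranks, sets, n_perm=100, seed=0).set_index("term")
    assert out.loc["top", "ES"] > 0.9
    assert out.loc["top", "ES"] == out["ES"].max()
    assert out.loc["bottom", "ES"] < 0


def test_es_antisymmetric_under_rank_reversal_at_weight_zero():
    rng = np.random.default_rng(1)
    genes = [f"g{i}" for i in range(40)]
    vals = rng.normal(size=40)
    members = list(rng.choice(genes, size=8, replace=False))
    fwd = metacell.preranked_gsea(
        pd.Series(vals, index=genes), {"t": members}, weight=0.0, n_perm=20, seed=0
    )
    rev = metacell.preranked_gsea(
        pd.Series(-vals, index=genes), {"t": members}, weight=0.0, n_perm=20, seed=0
    )
    assert fwd["ES"].iloc[0] == pytest.approx(-rev["ES"].iloc[0], abs=1e-12)


def test_gsea_p_uniform_for_random_sets():
    rng = np.random.default_rng(2)
    genes = [f"g{i}" for i in range(200)]
    ps = []
    for i in range(300):
        ranks = pd.Series(rng.normal(size=200), index=genes)
        members = list(rng.choice(genes, size=15, replace=False))
        out = metacell.preranked_gsea(ranks, {"t": members}, n_perm=100, seed=i)
        ps.append(out["p"].iloc[0])
    assert stats.kstest(ps, "uniform", alternative="greater").pvalue > 0.01
    assert 0.3 < np.mean(ps) < 0.7


def test_small_sets_are_skipped():
    genes = [f"g{i}" for i in range(50)]
    ranks = pd.Series(np.arange(50.0), index=genes)
    out = metacell.preranked_gsea(ranks, {"tiny": genes[:2]}, n_perm=10, seed=0)
    assert len(out) == 0
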