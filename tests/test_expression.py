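"""QC, normalization, scoring, markers, clustering and transfer."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from stcem import CountsMatrix, GeneSignature, QcThresholds, expression
from stcem.types import new_cell_table


def _toy_counts(raw, genes=None, blanks=0):
    raw = np.asarray(raw)
    n, g = raw.shape
    if genes is None:
        genes = [f"g{j}" for j in range(g - blanks)] + [f"Blank-{j}" for j in range(blanks)]
    return CountsMatrix(
        cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
        gene_names=np.array(genes, dtype=object),
        raw=raw,
    )


def _toy_cells(counts, volume=100.0):
    n = counts.n_cells
    return new_cell_table(counts.cell_ids, np.arange(n), np.zeros(n), volume=volume)


# ----------------------------------------------------------------- QC

def test_qc_excludes_low_count_cell_and_keeps_boundary_cell():
    raw = np.zeros((2, 10), dtype=int)
    raw[0, :5] = 5  # 25 transcripts -> excluded
    raw[1, :5] = 6  # 30 transcripts, 5 genes -> retained
    counts = _toy_counts(raw)
    cells = _toy_cells(counts, volume=[100.0, 41.0])
    kept, _, report = expression.qc_filter(cells, counts, QcThresholds())
    assert list(kept["cell_id"]) == ["c1"]
    assert report["low_counts"] == 1


def test_qc_removes_exactly_planted_violators_and_is_idempotent(small_bundle):
    cells, counts = small_bundle.st_cells, small_bundle.st_counts
    planted = set(sum(small_bundle.truth.qc_violators.values(), []))
    kept, kept_counts, report = expression.qc_filter(cells, counts)
    assert set(report["removed_cell_ids"]) == planted
    kept2, _, report2 = expression.qc_filter(kept, kept_counts)
    assert report2["n_removed"] == 0
    pd.testing.assert_frame_equal(kept, kept2)


def test_qc_all_removed_raises():
    counts = _toy_counts(np.ones((3, 10), dtype=int))  # 10 transcripts each
    with pytest.raises(ValueError, match="empty after QC"):
        expression.qc_filter(_toy_cells(counts), counts)


# -------------------------------------------------------- normalization

def test_normalize_closed_form_and_zero_preservation():
    rng = np.random.default_rng(0)
    raw = rng.poisson(3.0, size=(20, 15))
    raw[:, 0] += 1  # avoid zero-total cells
    counts = _toy_counts(raw)
    norm = expression.normalize(counts)
    total = raw.sum(axis=1)
    expected = np.log1p(raw * (1e4 / total[:, None]))
    np.testing.assert_allclose(norm.norm, expected, atol=1e-12)
    assert ((norm.norm == 0) == (raw == 0)).all()


def test_normalize_single_expressed_gene_gives_ln2():
    raw = np.zeros((1, 2), dtype=int)
    raw[0, 0] = 10_000
    norm = expression.normalize(_toy_counts(raw))
    # the expressed gene maps to ln(1 + 1e4 * 10000/10000) ... at total 1e4
    assert norm.norm[0, 0] == pytest.approx(np.log(1 + 1e4), rel=1e-12)
    # a count of 1 in a cell with total 10000 gives exactly ln 2
    raw3 = np.zeros((1, 10_000), dtype=int)
    raw3[0] = 1
    norm3 = expression.normalize(_toy_counts(raw3, genes=[f"g{j}" for j in range(10_000)]))
    assert norm3.norm[0, 0] == pytest.approx(np.log(2), abs=1e-12)


def test_normalize_excludes_blanks_from_totals():
    raw = np.array([[5, 5, 90]])
    counts = _toy_counts(raw, genes=["g0", "g1", "Blank-1"])
    norm = expression.normalize(counts)
    assert list(norm.gene_names) == ["g0", "g1"]
    np.testing.assert_allclose(norm.norm[0], np.log1p(5 * 1e4 / 10), atol=1e-12)


def test_normalize_zero_total_cell_raises():
    counts = _toy_counts(np.zeros((1, 3), dtype=int))
    with pytest.raises(ValueError, match="zero total"):
        expression.normalize(counts)


# ------------------------------------------------------- module scores

def test_module_score_separates_planted_program(small_bundle):
    counts = expression.normalize(small_bundle.st_counts)
    sig = GeneSignature("foamy", small_bundle.truth.programs["foamy"])
    score = expression.module_score(counts, sig, seed=0)
    classes = small_bundle.truth.st_classes
    assert score[classes == "foamy"].mean() > score[classes == "homeostatic"].mean()


def test_module_score_duplicate_gene_listing_is_idempotent(small_bundle):
    counts = expression.normalize(small_bundle.st_counts)
    genes = small_bundle.truth.programs["foamy"]
    s1 = expression.module_score(counts, GeneSignature("a", genes), seed=1)
    s2 = expression.module_score(counts, GeneSignature("b", list(genes) * 3), seed=1)
    np.testing.assert_allclose(s1, s2)


def test_module_score_missing_genes_warn_and_all_missing_raise(small_bundle):
    counts = expression.normalize(small_bundle.st_counts)
    genes = small_bundle.truth.programs["foamy"]
    with pytest.warns(UserWarning, match="absent"):
        expression.module_score(counts, GeneSignature("a", list(genes) + ["nope"]), seed=0)
    with pytest.raises(ValueError, match="no signature gene"):
        expression.module_score(counts, GeneSignature("b", ["nope1", "nope2"]), seed=0)


# ----------------------------------------------------------- regression

def test_regress_all_zero_scores_is_noop(small_bundle):
    counts = expression.normalize(small_bundle.st_counts)
    out = expression.regress_signatures(counts, np.zeros(counts.n_cells))
    np.testing.assert_array_equal(out.norm, counts.norm)


def test_regress_residuals_orthogonal_and_kill_proportional_gene():
    rng = np.random.default_rng(0)
    n = 200
    score = rng.normal(size=n)
    norm = rng.normal(size=(n, 10))
    norm[:, 0] = 2.5 * score  # perfectly proportional gene
    counts = _toy_counts(np.ones((n, 10), dtype=int))
    counts.norm = norm
    out = expression.regress_signatures(counts, score)
    assert np.linalg.norm(out.norm[:, 0]) < 1e-8
    sc = score - score.mean()
    for j in range(10):
        r = out.norm[:, j]
        assert abs(np.dot(r - r.mean(), sc)) / n < 1e-10


def test_regress_drops_collinear_covariate():
    rng = np.random.default_rng(1)
    score = rng.normal(size=50)
    counts = _toy_counts(np.ones((50, 4), dtype=int))
    counts.norm = rng.normal(size=(50, 4))
    with pytest.warns(UserWarning, match="collinear"):
        out = expression.regress_signatures(counts, np.column_stack([score, 2 * score]))
    assert out.norm.shape == counts.norm.shape


# -------------------------------------------------------------- markers

def test_rank_sum_uniform_p_under_label_permutation():
    rng = np.random.default_rng(0)
    n_genes = 2000
    counts = _toy_counts(rng.poisson(5, size=(120, n_genes)) + 1,
                         genes=[f"g{j}" for j in range(n_genes)])
    counts = expression.normalize(counts)
    labels = rng.permutation(["a"] * 60 + ["b"] * 60)
    res = expression.rank_sum_markers(counts, labels, "a")
    frac = (res["p"] < 0.05).mean()
    assert 0.02 < frac < 0.08
    assert stats.kstest(res["p"], "uniform").pvalue > 0.01


def test_rank_sum_detects_planted_marker_and_handles_constant_gene():
    rng = np.random.default_rng(1)
    raw = rng.poisson(5, size=(400, 50)) + 1
    labels = np.array(["a"] * 200 + ["b"] * 200)
    raw[labels == "a", 0] = rng.poisson(5 * np.e**2, size=200) + 1  # logfc 2
    counts = expression.normalize(_toy_counts(raw, genes=[f"g{j}" for j in range(50)]))
    counts.norm[:, 1] = 0.7  # constant in the tested layer
    res = expression.rank_sum_markers(counts, labels, "a").set_index("gene")
    assert res.loc["g0", "adj_p"] < 0.01
    assert res.loc["g0", "logFC"] > 0
    assert res.loc["g1", "p"] == 1.0


def test_rank_sum_missing_group_raises(small_bundle):
    counts = expression.normalize(small_bundle.st_counts)
    with pytest.raises(ValueError):
        expression.rank_sum_markers(counts, small_bundle.truth.st_classes, "absent-class")


# ------------------------------------------------------------ clustering

def test_cluster_graph_recovers_separated_blobs():
    rng = np.random.default_rng(0)
    centers = np.array([[0, 0], [12, 0], [0, 12]], dtype=float)
    X = np.vstack([rng.normal(c, 1.0, size=(100, 2)) for c in centers])
    X = np.hstack([X, rng.normal(size=(300, 8)) * 0.2])
    truth = np.repeat([0, 1, 2], 100)
    labels = expression.cluster_graph(X, n_pcs=5, k_snn=15, resolution=0.2, seed=0)
    assert adjusted_rand_score(truth, labels) >= 0.95


def test_cluster_graph_duplicates_co_cluster_and_zero_resolution_merges():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(60, 5))
    X2 = np.vstack([X, X])
    labels = expression.cluster_graph(X2, n_pcs=4, k_snn=10, seed=0)
    assert (labels[:60] == labels[60:]).all()
    single = expression.cluster_graph(X, n_pcs=4, k_snn=10, resolution=0.0, seed=0)
    assert len(set(single)) == 1


# ------------------------------------------------- transfer / imputation

def test_transfer_identity_query_reproduces_labels(small_bundle):
    ref = expression.normalize(small_bundle.st_counts)
    labels, conf = expression.transfer_labels(ref, small_bundle.truth.st_classes, ref)
    assert (labels == small_bundle.truth.st_classes).all()
    np.testing.assert_allclose(conf, 1.0)


def test_transfer_recovers_planted_classes_sc_to_st(medium_bundle):
    ref = expression.normalize(medium_bundle.sc_counts)
    cells, counts, _ = expression.qc_filter(medium_bundle.st_cells, medium_bundle.st_counts)
    query = expression.normalize(counts)
    labels, conf = expression.transfer_labels(ref, medium_bundle.truth.sc_classes, query)
    acc = (labels == cells["class_label"].to_numpy(object)).mean()
    assert acc >= 0.9
    # noise query should be less confident than the matched query
    rng = np.random.default_rng(0)
    noise = query.copy()
    noise.norm = rng.uniform(0, noise.norm.max(), size=noise.norm.shape)
    _, conf_noise = expression.transfer_labels(ref, medium_bundle.truth.sc_classes, noise)
    assert stats.mannwhitneyu(conf_noise, conf, alternative="less").pvalue < 1e-6


def test_impute_gene_eligibility_filter_and_passthrough(medium_bundle):
    ref = expression.normalize(medium_bundle.sc_counts)
    cells, counts, _ = expression.qc_filter(medium_bundle.st_cells, medium_bundle.st_counts)
    query = expression.normalize(counts)
    # plant an ineligible reference gene: 9 counts total
    j = list(ref.gene_names).index(medium_bundle.truth.null_genes[-1])
    ref.raw[:, j] = 0
    ref.raw[:3, j] = 3
    out, prov = expression.impute_genes(ref, query)
    assert ref.gene_names[j] not in set(prov.loc[prov["provenance"] == "imputed", "gene"])
    # measured panel genes pass through unchanged
    panel = list(query.gene_names)
    np.testing.assert_array_equal(out.norm[:, : len(panel)], query.norm)
    # planted non-panel foamy marker imputes higher in foamy cells
    marker = medium_bundle.truth.sc_programs["foamy"][0]
    col = list(out.gene_names).index(marker)
    vals = out.norm[:, col]
    foamy = cells["class_label"].to_numpy(object) == "foamy"
    p = stats.mannwhitneyu(vals[foamy], vals[~foamy], alternative="greater").pvalue
    assert p < 0.01


def test_impute_no_overlap_raises():
    a = expression.normalize(_toy_counts(np.ones((25, 12), dtype=int), genes=[f"a{j}" for j in range(12)]))
    b = expression.normalize(_toy_counts(np.ones((25, 12), dtype=int), genes=[f"b{j}" for j in range(12)]))
    with pytest.raises(ValueError, match="overlap"):
        expression.impute_genes(a, b)
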