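"""Mask-derived morphometrics, structural clustering, expert-label matching."""

import numpy as np
import pandas as pd
import pytest
from math import comb
from sklearn.metrics import adjusted_rand_score

from stcem import ultrastructure as us
from stcem.ultrastructure import LabelMaskStack, extract_features

from conftest import make_cells


def _square_stack(px=1.0):
    """20×20 canvas: 10×10 cell with a 4×4 nucleus."""
    whole = np.zeros((20, 20), dtype=bool)
    whole[5:15, 5:15] = True
    nucleus = np.zeros_like(whole)
    nucleus[7:11, 7:11] = True
    return LabelMaskStack(whole_cell=whole, organelles={"nucleus": nucleus}, px_size_um=px)


def test_square_cell_pixel_arithmetic():
    row = extract_features(_square_stack())
    assert row["whole_cell_area"] == 100
    assert row["nucleus_area"] == 16
    assert row["empty_cytoplasm_area"] == 84
    assert row["nucleus_area__per__whole_cell_area"] == pytest.approx(0.16)


def test_pixel_conservation_is_exact():
    rng = np.random.default_rng(0)
    whole = np.zeros((40, 40), dtype=bool)
    whole[5:35, 5:35] = True
    # carve disjoint organelles out of the cell
    organelles = {}
    cols = np.array_split(np.arange(6, 34), 5)
    for key, cc in zip(["nucleus", "lysosome", "lipid_droplet", "mitochondria", "organellar_cytoplasm"], cols):
        m = np.zeros_like(whole)
        m[8:20, cc] = rng.random((12, len(cc))) > 0.4
        organelles[key] = m & whole
    stack = LabelMaskStack(whole_cell=whole, organelles=organelles, px_size_um=1.0)
    row = extract_features(stack)
    parts = (
        row["nucleus_area"] + row["lysosome_area"] + row["lipid_droplet_area"]
        + row["mitochondria_area"] + row["organellar_cytoplasm_area"]
    )
    assert parts + row["empty_cytoplasm_area"] == row["whole_cell_area"]


def test_features_invariant_to_mask_translation():
    s1 = _square_stack()
    whole = np.roll(s1.whole_cell, (3, 2), axis=(0, 1))
    nuc = np.roll(s1.organelles["nucleus"], (3, 2), axis=(0, 1))
    s2 = LabelMaskStack(whole_cell=whole, organelles={"nucleus": nuc}, px_size_um=1.0)
    r1, r2 = extract_features(s1), extract_features(s2)
    for k in us.BASE_FEATURES:
        assert r1[k] == r2[k]


def test_er_arc_length_for_straight_segment():
    whole = np.zeros((20, 60), dtype=bool)
    whole[2:18, 2:58] = True
    er = np.zeros_like(whole)
    er[10, 5:55] = True  # 50 px straight line
    stack = LabelMaskStack(whole_cell=whole, organelles={"er": er}, px_size_um=2.0)
    row = extract_features(stack)
    assert row["er_length"] == pytest.approx(49 * 2.0, abs=2.0)


def test_no_organelles_means_empty_cytoplasm_is_whole_cell():
    whole = np.zeros((12, 12), dtype=bool)
    whole[2:10, 2:10] = True
    row = extract_features(LabelMaskStack(whole_cell=whole))
    assert row["empty_cytoplasm_area"] == row["whole_cell_area"]


def test_organelle_outside_cell_raises():
    whole = np.zeros((12, 12), dtype=bool)
    whole[2:8, 2:8] = True
    nucleus = np.zeros_like(whole)
    nucleus[0:8, 0:8] = True
    with pytest.raises(ValueError, match="beyond the whole-cell"):
        extract_features(LabelMaskStack(whole_cell=whole, organelles={"nucleus": nucleus}))


def test_heterochromatin_outside_nucleus_raises():
    whole = np.zeros((16, 16), dtype=bool)
    whole[1:15, 1:15] = True
    nucleus = np.zeros_like(whole)
    nucleus[2:8, 2:8] = True
    het = np.zeros_like(whole)
    het[8:14, 8:14] = True
    with pytest.raises(ValueError, match="heterochromatin"):
        extract_features(
            LabelMaskStack(whole_cell=whole, organelles={"nucleus": nucleus, "heterochromatin": het})
        )


# ----------------------------------------------------------- clustering

def test_structural_clustering_recovers_planted_classes(medium_bundle):
    b = medium_bundle
    keep = np.isin(b.truth.em_classes, ["foamy", "T-cell", "IFN-responsive"])
    table = b.em_features[keep].drop(columns=["cell_id"]).reset_index(drop=True)
    feats = [c for c in table.columns if c not in ("x", "y")]
    labels = us.cluster_structural(table, resolution=0.5, features=feats)
    assert adjusted_rand_score(b.truth.em_classes[keep], labels) >= 0.8


def test_duplicated_rows_co_cluster_and_zero_resolution_merges(small_bundle):
    table = small_bundle.em_features.drop(columns=["cell_id"]).head(80)
    feats = [c for c in table.columns if c not in ("x", "y")]
    dup = pd.concat([table, table], ignore_index=True)
    labels = us.cluster_structural(dup, resolution=1.0, features=feats)
    assert (labels[:80] == labels[80:]).all()
    single = us.cluster_structural(table, resolution=0.0, features=feats)
    assert len(set(single)) == 1


# ------------------------------------------------------- label matching

def test_match_identity_and_jittered_coordinates():
    rng = np.random.default_rng(0)
    xy = rng.random((40, 2)) * 1000  # spacing >> jitter whp
    featured = make_cells(xy, ["x"] * 40)
    mapping = us.match_expert_labels(featured, featured)
    assert (mapping["featured_index"].to_numpy() == np.arange(40)).all()
    assert mapping["distance"].max() == 0.0
    ok = 0
    for seed in range(10):
        r2 = np.random.default_rng(seed)
        grid = np.column_stack([np.repeat(np.arange(8) * 25.0, 8), np.tile(np.arange(8) * 25.0, 8)])
        expert = make_cells(grid + r2.normal(0, 2.0, grid.shape), ["x"] * 64)
        m = us.match_expert_labels(expert, make_cells(grid, ["x"] * 64))
        ok += (m["featured_index"].to_numpy() == np.arange(64)).all()
    assert ok == 10


def test_many_to_one_match_is_flagged():
    featured = make_cells([(0, 0), (100, 100)], ["x", "x"])
    expert = make_cells([(1, 0), (0, 1), (100, 99)], ["x", "x", "x"])
    with pytest.warns(UserWarning, match="share"):
        m = us.match_expert_labels(expert, featured)
    assert m["shared_match"].tolist() == [True, True, False]


# ----------------------------------------------------------- Fisher test

def _fisher_greater_oracle(n11, n12, n21, n22):
    """Exact enumeration of P[overlap >= n11] under the hypergeometric null."""
    row1, col1, n = n11 + n12, n11 + n21, n11 + n12 + n21 + n22
    num = 0
    den = comb(n, col1)
    for k in range(n11, min(row1, col1) + 1):
        if col1 - k <= n - row1:
            num += comb(row1, k) * comb(n - row1, col1 - k)
    return num / den


def test_fisher_overlap_matches_exact_enumeration():
    rng = np.random.default_rng(1)
    for _ in range(5):
        n = int(rng.integers(20, 61))
        a = rng.choice(["a1", "a2"], size=n)
        b = rng.choice(["b1", "b2"], size=n)
        out = us.overlap_test(a, b)
        for _, row in out.iterrows():
            in_a = a == row["class_a"]
            in_b = b == row["class_b"]
            n11 = int((in_a & in_b).sum())
            n12 = int((in_a & ~in_b).sum())
            n21 = int((~in_a & in_b).sum())
            n22 = int((~in_a & ~in_b).sum())
            oracle = _fisher_greater_oracle(n11, n12, n21, n22)
            assert row["fisher_p"] == pytest.approx(oracle, abs=1e-12)


def test_fisher_perfectly_aligned_labels_are_significant():
    a = ["u"] * 20 + ["v"] * 20
    out = us.overlap_test(a, a).set_index(["class_a", "class_b"])
    assert out.loc[("u", "u"), "fisher_p"] < 1e-5
    assert out.loc[("u", "u"), "count"] == 20


def test_fisher_absent_overlap_gives_p_one():
    a = ["u"] * 10 + ["v"] * 10
    b = ["w"] * 10 + ["u"] * 10
    out = us.overlap_test(a, b).set_index(["class_a", "class_b"])
    assert out.loc[("u", "u"), "count"] == 0
    assert out.loc[("u", "u"), "fisher_p"] == 1.0


def test_fisher_p_uniform_under_independent_labels():
    from scipy import stats

    rng = np.random.default_rng(2)
    ps = []
    for _ in range(500):
        a = rng.choice(["a1", "a2"], size=40)
        b = rng.choice(["b1", "b2"], size=40)
        in_a, in_b = a == "a1", b == "b1"
        n11 = int((in_a & in_b).sum())
        out = us.overlap_test(a, b)
        ps.append(out.set_index(["class_a", "class_b"]).loc[("a1", "b1"), "fisher_p"])
    # discrete p-values are conservative; one-sided KS against sub-uniformity
    assert stats.kstest(ps, "uniform", alternative="greater").pvalue > 0.01
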