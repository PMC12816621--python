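"""Scoring, stratification, hypoxia/subtype/purity rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import glycostrat as g
from glycostrat.signatures import SCHEME_LABELS


def make_expr(values, genes, samples):
    return g.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def sv(scores, ids=None):
    ids = ids or [f"s{i}" for i in range(len(scores))]
    return g.ScoreVector(ids, np.asarray(scores, float), "t", [], [])


# ---------------------------------------------------------------------- types


def test_expression_matrix_rejects_duplicate_ids():
    df = pd.DataFrame(np.ones((2, 2)), index=["A", "A"], columns=["s1", "s2"])
    with pytest.raises(ValueError, match="duplicate gene"):
        g.ExpressionMatrix(df)


def test_gene_set_rejects_duplicates_after_aliasing():
    with pytest.raises(ValueError, match="duplicate"):
        g.GeneSet("x", ["PKM", "pkm2"])  # both canonicalize to PKM


def test_packaged_glycolytic_signature(glyco_sig):
    assert len(glyco_sig) == 14
    assert "PKM2" in glyco_sig.genes and "PKM" in glyco_sig.canonical()


# -------------------------------------------------------------- log_normalize


def test_log_normalize_hand_values():
    counts = pd.DataFrame({"s1": [30, 70]}, index=["g1", "g2"])
    em = g.log_normalize(counts, scale=100, log_base=2)
    np.testing.assert_allclose(em.values["s1"], [np.log2(31), np.log2(71)])


def test_log_normalize_single_gene_closed_form():
    counts = pd.DataFrame({"s1": [123.0]}, index=["g1"])
    em = g.log_normalize(counts, scale=50, log_base="e")
    assert em.values.iloc[0, 0] == pytest.approx(np.log(1 + 50))


def test_log_normalize_zero_column_names_sample():
    counts = pd.DataFrame({"ok": [1, 2], "empty": [0, 0]}, index=["g1", "g2"])
    with pytest.raises(ValueError, match="empty"):
        g.log_normalize(counts)


# ------------------------------------------------------------ signature_score


def test_score_constant_and_identity_and_mean(small_expr):
    # 3-gene signature on s1: mean(1, 2, 6) = 3
    full = g.GeneSet("all3", ["GA", "GB", "GC"])
    assert g.signature_score(small_expr, full).scores[0] == pytest.approx(3.0)
    # constant sample s2: all genes 2.0
    assert g.signature_score(small_expr, full).scores[1] == pytest.approx(2.0)
    # one-gene signature reproduces that gene's row
    one = g.GeneSet("one", ["GB"])
    np.testing.assert_allclose(
        g.signature_score(small_expr, one).scores, small_expr.values.loc["GB"]
    )


def test_score_invariant_to_gene_order_and_extraneous_genes(small_expr):
    sig = g.GeneSet("s", ["GA", "GC"])
    base = g.signature_score(small_expr, sig).scores
    shuffled = g.ExpressionMatrix(small_expr.values.iloc[[2, 0, 1]])
    np.testing.assert_allclose(g.signature_score(shuffled, sig).scores, base)
    extra = g.ExpressionMatrix(
        pd.concat([small_expr.values, small_expr.values.rename(index=lambda s: s + "X") * 9])
    )
    np.testing.assert_allclose(g.signature_score(extra, sig).scores, base)


def test_score_alias_matches_pkm2_to_pkm():
    em = make_expr([[5.0], [1.0]], ["PKM", "OTHER"], ["s1"])
    res = g.signature_score(em, g.GeneSet("sig", ["PKM2"]))
    assert res.scores[0] == pytest.approx(5.0)
    assert res.genes_used == ["PKM2"] and res.genes_missing == []


def test_score_missing_genes_warn_then_error():
    em = make_expr([[1.0], [3.0]], ["GA", "GB"], ["s1"])
    sig3 = g.GeneSet("sig", ["GA", "GB", "GZ"])
    with pytest.warns(UserWarning, match="missing"):
        res = g.signature_score(em, sig3)
    assert res.genes_missing == ["GZ"]
    assert res.scores[0] == pytest.approx(2.0)  # mean over present genes only
    with pytest.raises(g.SignatureCoverageError, match="GZ"):
        g.signature_score(em, sig3, min_fraction=0.9)


# ---------------------------------------------------------------- stratifiers


@pytest.mark.parametrize(
    "scores,expected_high",
    [
        ([1, 2, 3, 4], {"s2", "s3"}),  # median 2.5: strict exceedance
        ([1, 2, 3], {"s2"}),  # median 2: only 3 exceeds
        ([5, 5, 5, 5], set()),  # ties at the median go Low
    ],
)
def test_median_split_strict_exceedance(scores, expected_high):
    ga = g.stratify_by_median(sv(scores))
    high = {s for s, l in zip(ga.sample_ids, ga.labels) if l == "High"}
    assert high == expected_high


def test_median_split_needs_two_samples():
    with pytest.raises(ValueError):
        g.stratify_by_median(sv([1.0]))


def _tertile_oracle(scores):
    """Independent sort-and-interpolate cut, same boundary convention."""
    x = np.sort(np.asarray(scores, float))
    n = len(x)

    def quant(q):
        h = (n - 1) * q
        lo, hi = int(np.floor(h)), int(np.ceil(h))
        return x[lo] + (h - lo) * (x[hi] - x[lo])

    q1, q2 = quant(1 / 3), quant(2 / 3)
    return ["Low" if s <= q1 else ("Intermediate" if s <= q2 else "High") for s in scores]


def test_tertiles_balanced_and_oracle():
    nine = list(range(9))
    ga = g.stratify_by_tertiles(sv(nine))
    assert [ga.labels.count(l) for l in ("Low", "Intermediate", "High")] == [3, 3, 3]
    ten = list(range(1, 11))
    ga10 = g.stratify_by_tertiles(sv(ten))
    assert ga10.labels == _tertile_oracle(ten)


def test_tertiles_degenerate_all_equal():
    ga = g.stratify_by_tertiles(sv([2.0] * 6))
    assert set(ga.labels) == {"Low"}


@given(st.lists(st.integers(-1000, 1000), min_size=4, max_size=30, unique=True))
def test_stratifiers_are_rank_determined(scores):
    """Strictly monotone transforms (exact in floats) give identical labels."""
    scores = [float(s) for s in scores]
    cubed = [s**3 for s in scores]  # strictly monotone, exactly representable
    affine = [3 * s + 7 for s in scores]
    assert g.stratify_by_median(sv(scores)).labels == g.stratify_by_median(sv(cubed)).labels
    assert (
        g.stratify_by_tertiles(sv(scores)).labels
        == g.stratify_by_tertiles(sv(affine)).labels
    )


# ------------------------------------------------------- hypoxia and subtype


def test_build_hypoxia_signature_set_semantics():
    a = g.GeneSet("up", ["A", "B", "C"])
    b = g.GeneSet("hif", ["B", "C", "D"])
    inter = g.build_hypoxia_signature(a, b)
    assert set(inter.genes) == {"B", "C"}
    # commutative as a set, idempotent
    assert set(g.build_hypoxia_signature(b, a).genes) == {"B", "C"}
    assert set(g.build_hypoxia_signature(a, a).genes) == {"A", "B", "C"}
    with pytest.raises(ValueError, match="no overlap"):
        g.build_hypoxia_signature(a, g.GeneSet("other", ["X", "Y"]))


def test_hypoxia_score_median_conventions():
    em = make_expr([[1.0], [5.0], [9.0]], ["A", "B", "C"], ["s1"])
    assert g.hypoxia_score(em, g.GeneSet("h", ["A", "B", "C"])).scores[0] == 5.0
    em4 = make_expr([[1.0], [2.0], [8.0], [9.0]], list("ABCD"), ["s1"])
    assert g.hypoxia_score(em4, g.GeneSet("h", list("ABCD"))).scores[0] == 5.0


def test_hypoxia_score_matches_sort_and_pick_oracle():
    rng = np.random.default_rng(11)
    vals = rng.normal(size=(7, 5))
    genes = [f"G{i}" for i in range(7)]
    em = make_expr(vals, genes, [f"s{i}" for i in range(5)])
    res = g.hypoxia_score(em, g.GeneSet("h", genes))
    for j in range(5):
        col = np.sort(vals[:, j])
        assert res.scores[j] == pytest.approx(col[3])  # middle of 7


def test_call_subtype_argmax_tie_and_oracle():
    basal = g.GeneSet("basal", ["B1", "B2"])
    classical = g.GeneSet("classical", ["C1", "C2"])
    genes = ["B1", "B2", "C1", "C2"]
    em = make_expr([[2.0, 1.0], [2.0, 1.0], [1.0, 1.0], [1.0, 1.0]], genes, ["s1", "s2"])
    with pytest.warns(UserWarning, match="tied"):
        ga = g.call_subtype(em, basal, classical)
    assert ga.labels == ["Basal-like", "Classical"]  # s2 is an exact tie
    rng = np.random.default_rng(3)
    vals = rng.normal(size=(4, 20))
    emr = make_expr(vals, genes, [f"s{i}" for i in range(20)])
    gar = g.call_subtype(emr, basal, classical)
    expected = [
        "Basal-like" if vals[:2, j].mean() > vals[2:, j].mean() else "Classical"
        for j in range(20)
    ]
    assert gar.labels == expected


# -------------------------------------------------------------------- purity


def test_bin_purity_boundaries():
    ga = g.bin_purity(np.array([49.9, 50.0, 75.0, 75.1, 60.0]))
    assert ga.labels == ["low", "mid", "mid", "high", "mid"]


def test_bin_purity_range_guard():
    with pytest.raises(ValueError):
        g.bin_purity(np.array([101.0]))
    with pytest.raises(ValueError):
        g.bin_purity(np.array([-1.0]))


def test_group_assignment_vocabulary_enforced():
    with pytest.raises(ValueError, match="vocabulary"):
        g.GroupAssignment(["s1"], ["Medium"], "tertile_3group")
    for scheme, labels in SCHEME_LABELS.items():
        g.GroupAssignment(list(labels), list(labels), scheme)  # all vocab ok
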