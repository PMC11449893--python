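"""Consensus annotation, reference correlation, AUC set activity and the
majority/DEPA refinement rule — including exhaustive truth tables."""

from collections import Counter
from itertools import product

import numpy as np
import pandas as pd
import pytest

import scapa_atlas as sa
from scapa_atlas import celltyping as ct


TYPES = ["A", "B", "C", "D"]


def _consensus_oracle(votes):
    """Independent re-derivation: modal label iff unique mode with
    support >= 2."""
    votes = [v for v in votes if v is not None]
    if not votes:
        return ct.UNLABELED
    counts = Counter(votes)
    top = max(counts.values())
    if top < 2 or sum(1 for v in counts.values() if v == top) > 1:
        return ct.UNLABELED
    return counts.most_common(1)[0][0]


def test_consensus_truth_table_exhaustive_three_strategies():
    patterns = list(product(TYPES + [None], repeat=3))
    table = pd.DataFrame(patterns, columns=["s1", "s2", "s3"])
    table.index = [f"cell{i}" for i in range(len(table))]
    out = ct.consensus_labels(table)
    for i, votes in enumerate(patterns):
        assert out["consensus"].iloc[i] == _consensus_oracle(votes), votes


def test_consensus_examples_from_contract():
    table = pd.DataFrame(
        [["A", "A", "B", None], ["A", "B", "C", None], ["A", "A", "B", "B"]],
        columns=["s1", "s2", "s3", "s4"],
        index=["x", "y", "z"],
    )
    out = ct.consensus_labels(table)
    assert list(out["consensus"]) == ["A", ct.UNLABELED, ct.UNLABELED]


def test_consensus_requires_two_strategies():
    with pytest.raises(ValueError):
        ct.consensus_labels(pd.DataFrame({"s1": ["A"]}, index=["c"]))


def test_refine_truth_table_exhaustive():
    patterns = list(product(TYPES, repeat=3))
    gene = pd.Series([p[0] for p in patterns], index=range(len(patterns)))
    depa = pd.Series([p[1] for p in patterns], index=range(len(patterns)))
    apa = pd.Series([p[2] for p in patterns], index=range(len(patterns)))
    out = ct.refine_unlabeled(gene, depa, apa)
    for i, (g, d, a) in enumerate(patterns):
        votes = Counter([g, d, a])
        if votes.most_common(1)[0][1] >= 2:
            expect = votes.most_common(1)[0][0]
            assert out["final"].iloc[i] == expect
            assert out["provenance"].iloc[i] == "majority"
        else:
            assert out["final"].iloc[i] == d  # all distinct -> DEPA label
            assert out["provenance"].iloc[i] == "depa_tiebreak"


def test_refine_never_unlabeled_when_votes_present():
    patterns = list(product(TYPES, repeat=3))
    gene = pd.Series([p[0] for p in patterns])
    depa = pd.Series([p[1] for p in patterns])
    apa = pd.Series([p[2] for p in patterns])
    out = ct.refine_unlabeled(gene, depa, apa)
    assert (out["final"] != ct.UNLABELED).all()


def test_pcc_identifies_identical_and_rejects_negated_profiles():
    rng = np.random.default_rng(0)
    ref = pd.DataFrame(
        rng.normal(size=(50, 3)), columns=["A", "B", "C"],
        index=[f"g{i}" for i in range(50)],
    )
    expr = pd.DataFrame(
        {"cell1": ref["B"], "cell2": -ref["C"]}, index=ref.index
    )
    labels = ct.pcc_annotate(expr, ref)
    assert labels["cell1"] == "B"
    assert labels["cell2"] != "C"


def test_pcc_zero_variance_cell_gets_no_label():
    ref = pd.DataFrame(
        {"A": [1.0, 2.0, 3.0], "B": [3.0, 1.0, 2.0]}, index=["g0", "g1", "g2"]
    )
    expr = pd.DataFrame({"flat": [1.0, 1.0, 1.0]}, index=ref.index)
    assert ct.pcc_annotate(expr, ref)["flat"] is None


def test_pcc_empty_gene_intersection_raises():
    ref = pd.DataFrame({"A": [1.0], "B": [2.0]}, index=["gX"])
    expr = pd.DataFrame({"c": [1.0]}, index=["gY"])
    with pytest.raises(ValueError, match="shared"):
        ct.pcc_annotate(expr, ref)


def test_reference_shape_contract_and_constant_profile():
    expr = pd.DataFrame(
        np.ones((30, 12)) * 2.5,
        index=[f"g{i}" for i in range(30)],
        columns=[f"c{i}" for i in range(12)],
    )
    labels = pd.Series(["A"] * 6 + ["B"] * 6, index=expr.columns)
    ref = ct.build_reference(expr, labels, n_hvg=10)
    assert ref.shape == (10, 2)
    assert (ref.columns == ["A", "B"]).all()
    np.testing.assert_allclose(ref.to_numpy(), 2.5)


def _expr(values):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"f{i}" for i in range(values.shape[0])],
        columns=[f"c{i}" for i in range(values.shape[1])],
    )


def test_auc_boundary_scores():
    n = 40
    rng = np.random.default_rng(1)
    base = rng.permutation(n).astype(float)[:, None]
    expr = _expr(base)
    order = expr["c0"].sort_values(ascending=False).index
    top_set = list(order[:4])
    bottom_set = list(order[-4:])
    act = ct.auc_activity(expr, {"top": top_set, "bottom": bottom_set}, top_fraction=0.25)
    assert act.loc["top", "c0"] == pytest.approx(1.0)
    assert act.loc["bottom", "c0"] == 0.0


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(2)
    expr = _expr(rng.random((60, 5)) + 0.1)
    sets = {"s1": [f"f{i}" for i in range(0, 12, 2)], "s2": [f"f{i}" for i in range(30, 40)]}
    a = ct.auc_activity(expr, sets, top_fraction=0.2, seed=3)
    b = ct.auc_activity(np.exp(expr * 4), sets, top_fraction=0.2, seed=3)
    pd.testing.assert_frame_equal(a, b)


def test_auc_matches_direct_rank_enumeration():
    """Oracle: recompute one cell's activity by explicit ranking."""
    rng = np.random.default_rng(4)
    expr = _expr(rng.permutation(30).astype(float)[:, None])
    members = ["f3", "f11", "f20"]
    tf = 0.3
    act = ct.auc_activity(expr, {"s": members}, top_fraction=tf, seed=0).loc["s", "c0"]
    window = int(np.ceil(tf * 30))
    ranking = expr["c0"].sort_values(ascending=False).index[:window]
    hits = np.cumsum([f in members for f in ranking])
    max_area = np.minimum(np.arange(1, window + 1), min(len(members), window)).sum()
    assert act == pytest.approx(hits.sum() / max_area)


def test_empty_set_scores_zero():
    expr = _expr(np.arange(10, dtype=float)[:, None])
    act = ct.auc_activity(expr, {"ghost": ["nope"]}, top_fraction=0.5)
    assert act.loc["ghost", "c0"] == 0.0


def test_expression_filter_boundaries_and_fixed_point():
    rng = np.random.default_rng(5)
    counts = pd.DataFrame(
        rng.poisson(2.0, size=(300, 30)),
        index=[f"g{i}" for i in range(300)],
        columns=[f"c{i}" for i in range(30)],
    )
    counts.iloc[:, 0] = 0
    counts.iloc[200:, 0] = 1  # cell c0: exactly 100 expressed genes
    out = ct.filter_expression_matrix(
        counts, stage="per_batch", min_genes_per_cell=101, min_cells_per_gene=3
    )
    assert "c0" not in out.columns
    again = ct.filter_expression_matrix(
        out, stage="per_batch", min_genes_per_cell=101, min_cells_per_gene=3
    )
    pd.testing.assert_frame_equal(out, again)
    kept = ct.filter_expression_matrix(
        counts, stage="per_batch", min_genes_per_cell=100, min_cells_per_gene=3
    )
    assert "c0" in kept.columns  # boundary: >= is kept


def test_expression_filter_empty_result_raises():
    counts = pd.DataFrame(np.zeros((5, 5)), dtype=int)
    with pytest.raises(ValueError):
        ct.filter_expression_matrix(counts, stage="combined")


def test_relabel_low_support_quiescent_center_rule():
    # support for the target label is counted over every source column
    labels = pd.DataFrame(
        {
            "s1": ["QC", "stele", "cortex"],
            "s2": ["QC", "stele", "cortex"],
            "final": ["QC", "QC", "cortex"],
        },
        index=["c0", "c1", "c2"],
    )
    out = ct.relabel_low_support(labels, target="QC", fallback="SCN")
    assert list(out) == ["QC", "SCN", "cortex"]
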