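"""Discretization, mutual information, ranking, cutoff curve and selection."""

from __future__ import annotations

import math

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, strategies as st

import termrank as tr
from termrank.model import DiscretizedJoint, TermRankError

from helpers import brute_force_mi_from_table

# ---------------------------------------------------------------------------
# discretize


def test_discretize_constant_column_all_middle():
    assert (tr.discretize(np.full(7, 3.3)) == 1).all()


def test_discretize_hand_computed_thresholds():
    # mean 2, sample sd sqrt(20) ~ 4.472: only the 10 exceeds mean + sd
    states = tr.discretize(np.array([0.0, 0.0, 0.0, 0.0, 10.0]))
    assert list(states) == [1, 1, 1, 1, 2]


@given(
    st.lists(
        st.floats(0, 100, allow_nan=False, allow_infinity=False),
        min_size=2,
        max_size=40,
    )
)
def test_discretize_partition_is_definitional(values):
    col = np.array(values)
    states = tr.discretize(col)
    mu, sd = col.mean(), col.std(ddof=1)
    if sd == 0:
        assert (states == 1).all()
    else:
        np.testing.assert_array_equal(states == 2, col > mu + sd)
        np.testing.assert_array_equal(states == 0, col < mu - sd)


def test_discretize_k_multiplier_widens_middle_band():
    col = np.array([0.0, 0.0, 0.0, 0.0, 10.0])
    assert (tr.discretize(col, k=3.0) == 1).all()


# ---------------------------------------------------------------------------
# mutual information


def test_mi_zero_for_independent_table():
    joint = DiscretizedJoint(np.array([[10, 20, 10], [10, 20, 10]]))
    assert tr.mutual_information(joint) == pytest.approx(0.0, abs=1e-15)


def test_mi_one_bit_for_balanced_perfect_feature():
    joint = DiscretizedJoint(np.array([[50, 0, 0], [0, 50, 0]]))
    assert tr.mutual_information(joint) == pytest.approx(1.0, abs=1e-12)


def test_mi_frozen_value_four_cell_table():
    joint = DiscretizedJoint(np.array([[40, 10, 0], [10, 40, 0]]))
    assert tr.mutual_information(joint) == pytest.approx(0.278072, abs=5e-7)


def test_mi_base_conversion():
    joint = DiscretizedJoint(np.array([[40, 10, 0], [10, 40, 0]]))
    bits = tr.mutual_information(joint, base=2.0)
    nats = tr.mutual_information(joint, base=math.e)
    assert nats == pytest.approx(bits * math.log(2), rel=1e-12)


def test_mi_empty_table_rejected():
    with pytest.raises(TermRankError):
        tr.mutual_information(DiscretizedJoint(np.zeros((2, 3), dtype=int)))


@given(
    st.lists(st.integers(0, 50), min_size=6, max_size=6).filter(
        lambda c: sum(c) > 0
    )
)
def test_mi_matches_brute_force_and_entropy_bound(cells):
    counts = np.array(cells).reshape(2, 3)
    joint = DiscretizedJoint(counts)
    mi = tr.mutual_information(joint)
    assert mi == pytest.approx(brute_force_mi_from_table(counts), abs=1e-12)
    n = counts.sum()
    pc = counts.sum(axis=1) / n
    h_label = -sum(p * math.log2(p) for p in pc if p > 0)
    assert -1e-12 <= mi <= h_label + 1e-12


def test_mi_against_sklearn_contingency():
    from sklearn.metrics import mutual_info_score

    rng = np.random.default_rng(3)
    for _ in range(25):
        counts = rng.integers(0, 30, size=(2, 3))
        if counts.sum() == 0:
            continue
        ours = tr.mutual_information(DiscretizedJoint(counts), base=math.e)
        theirs = mutual_info_score(None, None, contingency=counts)
        assert ours == pytest.approx(theirs, abs=1e-12)


# ---------------------------------------------------------------------------
# ranking


def _ranking_problem():
    """Eight genes, three columns with MI order col0 > col2 > col1."""
    universe = [f"g{i}" for i in range(8)]
    labels = tr.LabeledGeneSet(universe, {"g0", "g1"})
    cat = tr.AnnotationCatalogue(
        [
            tr.Term("T0", "biological_process", frozenset(universe)),
            tr.Term("T1", "biological_process", frozenset(universe)),
            tr.Term("T2", "kegg_pathway", frozenset(universe)),
        ]
    )
    perfect = [5.0, 5.0, 0, 0, 0, 0, 0, 0]  # highs exactly on the positives
    flat = [1.0] * 8  # constant: MI 0
    partial = [5.0, 0, 0, 0, 0, 0, 0, 0]  # high on one positive only
    dense = np.column_stack([perfect, flat, partial]).astype(float)
    matrix = tr.FeatureMatrix(universe, cat.term_ids, sp.csr_matrix(dense))
    return matrix, labels, cat


def test_maxrel_rank_orders_by_mi_descending():
    matrix, labels, cat = _ranking_problem()
    mlist = tr.maxrel_rank(matrix, labels, cat)
    assert mlist.term_ids == ["T0", "T2", "T1"]
    assert [e.rank for e in mlist] == [1, 2, 3]
    # perfect column reaches the label entropy H(2/8) = 0.8112781 bits
    assert mlist[0].mi == pytest.approx(0.8112781244591328, abs=1e-12)
    assert mlist[2].mi == pytest.approx(0.0, abs=1e-15)


def test_maxrel_rank_tie_broken_by_catalogue_index():
    universe = [f"g{i}" for i in range(6)]
    labels = tr.LabeledGeneSet(universe, {"g0", "g1"})
    cat = tr.AnnotationCatalogue(
        [
            tr.Term("A", "biological_process", frozenset(universe)),
            tr.Term("B", "biological_process", frozenset(universe)),
        ]
    )
    col = np.array([9.0, 9.0, 0, 0, 0, 0])
    matrix = tr.FeatureMatrix(
        universe, cat.term_ids, sp.csr_matrix(np.column_stack([col, col]))
    )
    mlist = tr.maxrel_rank(matrix, labels, cat)
    assert mlist[0].mi == mlist[1].mi
    assert mlist.term_ids == ["A", "B"]


def test_maxrel_rank_dimension_mismatch_rejected():
    matrix, labels, cat = _ranking_problem()
    other = tr.LabeledGeneSet(["x", "y", "z"], {"x"})
    with pytest.raises(TermRankError):
        tr.maxrel_rank(matrix, other, cat)


def test_maxrel_rank_invariant_to_sample_permutation():
    matrix, labels, cat = _ranking_problem()
    base = tr.maxrel_rank(matrix, labels, cat)
    rng = np.random.default_rng(11)
    perm = rng.permutation(len(labels.universe))
    universe_p = [labels.universe[i] for i in perm]
    labels_p = tr.LabeledGeneSet(universe_p, labels.positives)
    matrix_p = tr.FeatureMatrix(
        universe_p, matrix.col_index, matrix.values[perm, :]
    )
    assert tr.maxrel_rank(matrix_p, labels_p, cat) == base


def test_planted_terms_dominate_ranking(default_dataset, default_run):
    top = set(default_run.ranking.top(10))
    assert set(default_dataset.truth.planted_term_ids) <= top


# ---------------------------------------------------------------------------
# cutoff curve and selection


def _mi_list(values):
    entries = [
        tr.MaxRelEntry(i + 1, f"T{i}", "biological_process", "", v)
        for i, v in enumerate(values)
    ]
    return tr.MaxRelList(entries)


def test_cutoff_curve_inclusive_rule():
    mlist = _mi_list([0.005, 0.003, 0.003, 0.001])
    curve = tr.cutoff_curve(mlist, [0.003])
    assert curve.n_selected(0.003) == 3


def test_cutoff_curve_extremes():
    mlist = _mi_list([0.005, 0.003, 0.003, 0.001])
    curve = tr.cutoff_curve(mlist, [0.0, 0.1])
    assert curve.n_selected(0.0) == 4
    assert curve.n_selected(0.1) == 0


def test_cutoff_curve_non_increasing(default_run):
    ns = [n for _, n in default_run.curve]
    assert all(a >= b for a, b in zip(ns, ns[1:]))


def test_select_consistent_with_curve(default_run):
    for cutoff in (0.0, 0.001, 0.003, 0.01):
        curve = tr.cutoff_curve(default_run.ranking, [cutoff])
        assert len(tr.select(default_run.ranking, cutoff)) == curve.n_selected(cutoff)


def test_select_prefix_and_edge_cases():
    mlist = _mi_list([0.005, 0.003, 0.003, 0.001])
    assert tr.select(mlist, 0.001).term_ids == mlist.term_ids  # min MI: full list
    assert tr.select(mlist, 0.002).term_ids == ["T0", "T1", "T2"]
    assert len(tr.select(mlist, 0.1)) == 0  # empty selection: warning, empty list


def test_maxrel_tsv_round_trip(tmp_path):
    mlist = _mi_list([0.0051234, 0.003, 0.003, 0.0011])
    tr.write_maxrel(mlist, tmp_path / "list.tsv")
    again = tr.read_maxrel(tmp_path / "list.tsv")
    assert again == mlist  # mi_exact column preserves full precision
    # displayed MI is rounded to 3 decimals while ranking stays unrounded
    lines = (tmp_path / "list.tsv").read_text().splitlines()
    assert lines[1].split("\t")[3] == "0.005"
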