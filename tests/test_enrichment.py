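"""Hypergeometric upper-tail probabilities and enrichment scores."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

import termrank as tr
from termrank.enrichment import SCORE_CAP, tail_scores
from termrank.model import EnrichmentCounts, TermRankError

from helpers import exact_upper_tail


@pytest.mark.parametrize(
    "N,M,n,m,expected",
    [
        (10, 3, 3, 0, 1.0),  # sum over the whole support
        (10, 3, 3, 3, 1 / 120),
        (10, 5, 4, 2, 155 / 210),
    ],
)
def test_upper_tail_frozen_values(N, M, n, m, expected):
    p = tr.upper_tail_p(EnrichmentCounts(N=N, M=M, n=n, m=m))
    assert p == pytest.approx(expected, rel=1e-12)


@st.composite
def count_tuples(draw, max_n=40):
    N = draw(st.integers(1, max_n))
    M = draw(st.integers(0, N))
    n = draw(st.integers(0, N))
    m = draw(st.integers(0, min(M, n)))
    return N, M, n, m


@given(count_tuples())
def test_upper_tail_matches_exact_rational_oracle(tup):
    N, M, n, m = tup
    p = tr.upper_tail_p(EnrichmentCounts(N=N, M=M, n=n, m=m))
    exact = float(exact_upper_tail(N, M, n, m))
    assert p == pytest.approx(exact, rel=1e-9, abs=1e-300)


@given(count_tuples(max_n=30))
def test_upper_tail_monotone_nonincreasing_in_m(tup):
    N, M, n, _ = tup
    tails = [
        tr.upper_tail_p(EnrichmentCounts(N=N, M=M, n=n, m=m))
        for m in range(min(M, n) + 1)
    ]
    assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))


def test_invalid_counts_rejected():
    with pytest.raises(TermRankError):
        EnrichmentCounts(N=10, M=11, n=3, m=1)  # M > N
    with pytest.raises(TermRankError):
        EnrichmentCounts(N=10, M=3, n=3, m=4)  # m > min(M, n)
    with pytest.raises(TermRankError):
        EnrichmentCounts(N=10, M=3, n=-1, m=0)


# ---------------------------------------------------------------------------
# enrichment_score


def _triangle_net():
    return tr.InteractionNetwork.from_edges(
        [("g", "A"), ("g", "B"), ("g", "C"), ("A", "B")]
    )


def test_score_full_overlap():
    term = tr.Term("T", "biological_process", frozenset({"A", "B", "C"}))
    score = tr.enrichment_score("g", term, _triangle_net(), n_background=10)
    assert score == pytest.approx(-np.log10(1 / 120), rel=1e-12)


def test_score_zero_iff_no_overlap():
    term = tr.Term("T", "biological_process", frozenset({"X"}))
    net = tr.InteractionNetwork.from_edges(
        [("g", "A"), ("g", "B"), ("g", "C"), ("X", "A")]
    )
    assert tr.enrichment_score("g", term, net, n_background=10) == 0.0


def test_score_zero_for_isolated_gene():
    net = tr.InteractionNetwork.from_edges([("g", "A")])
    # B has no neighbours besides nothing: make an isolated node explicitly
    net.graph.add_node("lonely")
    term = tr.Term("T", "biological_process", frozenset({"A"}))
    assert tr.enrichment_score("lonely", term, net, n_background=10) == 0.0


def test_neighbourhood_excludes_gene_itself():
    term = tr.Term("T", "biological_process", frozenset({"g", "A"}))
    net = tr.InteractionNetwork.from_edges([("g", "A")])
    # G2 = {A}; g itself in the term must not inflate the overlap
    counts_score = tr.enrichment_score("g", term, net, n_background=10)
    expected = tr.score_from_p(float(exact_upper_tail(10, 2, 1, 1)))
    assert counts_score == pytest.approx(expected, rel=1e-12)


def test_score_gene_not_in_network_raises():
    term = tr.Term("T", "biological_process", frozenset({"A"}))
    with pytest.raises(TermRankError):
        tr.enrichment_score("missing", term, _triangle_net(), n_background=10)


def test_score_term_emptied_by_universe_raises():
    term = tr.Term("T", "biological_process", frozenset({"X"}))
    with pytest.raises(TermRankError):
        tr.enrichment_score(
            "g", term, _triangle_net(), n_background=4, universe={"g", "A", "B", "C"}
        )


def test_score_capped_and_never_negative():
    assert tr.score_from_p(0.0) == SCORE_CAP
    assert tr.score_from_p(1.0) == 0.0
    assert tr.score_from_p(5e-324) <= SCORE_CAP
    assert tr.score_from_p(0.9999999) >= 0.0


def test_tail_scores_matches_scalar_path():
    rng = np.random.default_rng(0)
    N = 50
    M = rng.integers(1, N, size=200)
    n = rng.integers(1, N, size=200)
    m = np.array([rng.integers(0, min(a, b) + 1) for a, b in zip(M, n)])
    vec = tail_scores(m, N, M, n)
    for i in range(200):
        p = tr.upper_tail_p(EnrichmentCounts(N=N, M=int(M[i]), n=int(n[i]), m=int(m[i])))
        assert vec[i] == pytest.approx(tr.score_from_p(p), rel=1e-12, abs=1e-12)


def test_score_gene_is_elementwise_enrichment_score():
    net = _triangle_net()
    cat = tr.AnnotationCatalogue(
        [
            tr.Term("T1", "biological_process", frozenset({"X"})),
            tr.Term("T2", "cellular_component", frozenset({"A", "B"})),
            tr.Term("T3", "kegg_pathway", frozenset({"C"})),
        ]
    )
    net.graph.add_node("X")
    vec = tr.score_gene("g", cat, net, n_background=10)
    assert vec.shape == (3,)
    assert vec[0] == 0.0 and vec[1] > 0 and vec[2] > 0
    for j, term in enumerate(cat):
        assert vec[j] == tr.enrichment_score("g", term, net, n_background=10)
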