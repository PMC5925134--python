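"""Hypergeometric network-neighbourhood enrichment scores.

A gene ``g`` is related to a functional term by asking how surprising the
overlap is between the term's member set ``G1`` and ``g``'s strict network
neighbourhood ``G2``, against a background of ``N`` genes.  With ``M = |G1|``,
``n = |G2|`` and ``m = |G1 ∩ G2|``, the enrichment score is

    ES(g, term) = -log10 P(X >= m),   X ~ Hypergeometric(N, M, n)

i.e. the upper tail (inclusive of ``m``) of the hypergeometric distribution.
``m = 0`` gives ``P = 1`` and a score of exactly 0; a tail probability that
underflows to 0 in double precision is mapped to ``SCORE_CAP`` so scores stay
finite and comparable.

The tail is evaluated through :func:`scipy.stats.hypergeom.sf`, never by
naive floating-point summation of pmf terms.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom

from .model import (
    AnnotationCatalogue,
    EnrichmentCounts,
    InteractionNetwork,
    Term,
    TermRankError,
)

#: Upper bound on -log10(p); roughly -log10 of the smallest positive double.
SCORE_CAP = 350.0

#: Scores below this are treated as structural zeros in sparse storage.
ZERO_TOL = 1e-12


def upper_tail_p(counts: EnrichmentCounts) -> float:
    """Upper-tail probability P(X >= m) for X ~ Hypergeometric(N, M, n).

    The sum is inclusive of ``m`` (survival function at ``m - 1``).  Returns
    a value in [0, 1]; exact 0 only on double-precision underflow.
    """
    if counts.m == 0:
        return 1.0
    # scipy's convention: hypergeom(M=population, n=successes, N=draws)
    return float(hypergeom.sf(counts.m - 1, counts.N, counts.M, counts.n))


def score_from_p(p: float) -> float:
    """Map a tail probability to the capped -log10 enrichment score."""
    if p <= 0.0:
        return SCORE_CAP
    if p >= 1.0:
        return 0.0
    return min(-np.log10(p), SCORE_CAP)


def tail_scores(
    m: np.ndarray, N: int, M: np.ndarray, n: np.ndarray
) -> np.ndarray:
    """Vectorised enrichment scores for arrays of overlap counts.

    ``m``, ``M`` and ``n`` broadcast together; ``N`` is the scalar background
    size.  Used by the feature-matrix builder on the nonzero overlap pattern.
    """
    m = np.asarray(m, dtype=np.int64)
    with np.errstate(divide="ignore"):
        p = hypergeom.sf(m - 1, N, M, n)
        scores = np.where(p > 0.0, -np.log10(np.maximum(p, 5e-324)), SCORE_CAP)
    scores = np.clip(scores, 0.0, SCORE_CAP)
    scores[m == 0] = 0.0
    return scores


def _neighbour_counts(
    gene: str,
    term: Term,
    net: InteractionNetwork,
    n_background: int,
    universe: set[str] | None,
) -> EnrichmentCounts:
    if not net.has_node(gene):
        raise TermRankError(f"gene {gene!r} is not a network node")
    g1 = set(term.members)
    g2 = net.neighbors(gene)
    if universe is not None:
        g1 &= universe
        g2 &= universe
    if not g1:
        raise TermRankError(
            f"term {term.term_id!r} has no members in the analysis universe"
        )
    if n_background < max(len(g1), len(g2)):
        raise TermRankError(
            f"background N={n_background} smaller than max(|G1|={len(g1)}, "
            f"|G2|={len(g2)})"
        )
    return EnrichmentCounts(N=n_background, M=len(g1), n=len(g2), m=len(g1 & g2))


def enrichment_score(
    gene: str,
    term: Term,
    net: InteractionNetwork,
    n_background: int,
    universe: set[str] | None = None,
) -> float:
    """Enrichment score of ``term`` for ``gene``'s network neighbourhood.

    ``universe``, when given, restricts both the term's member set and the
    neighbourhood before counting; ``n_background`` is the background gene
    count N (by convention the size of the analyzed universe).
    """
    counts = _neighbour_counts(gene, term, net, n_background, universe)
    return score_from_p(upper_tail_p(counts))


def score_gene(
    gene: str,
    catalogue: AnnotationCatalogue,
    net: InteractionNetwork,
    n_background: int,
    universe: set[str] | None = None,
) -> np.ndarray:
    """Feature vector of ``gene``: one enrichment score per catalogue term.

    Entry order is the catalogue order (GO terms first, then KEGG pathways).
    """
    return np.array(
        [
            enrichment_score(gene, term, net, n_background, universe)
            for term in catalogue
        ],
        dtype=np.float64,
    )
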