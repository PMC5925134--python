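"""Core domain types for the network-enrichment / MaxRel pipeline.

The pipeline relates three kinds of objects:

* an undirected protein--protein interaction network over gene identifiers,
  defining each gene's neighbourhood;
* a catalogue of functional terms (GO terms and KEGG pathways), each with a
  member gene set;
* a binary labelling of a gene universe (disease-associated positives versus
  everything else).

Gene identifiers are opaque, case-sensitive strings; no identifier mapping is
performed.  All containers here validate their structural invariants at
construction time so downstream numerical code can assume them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

GO_NAMESPACES: tuple[str, ...] = (
    "biological_process",
    "cellular_component",
    "molecular_function",
)
KEGG_NAMESPACE = "kegg_pathway"
NAMESPACES: tuple[str, ...] = GO_NAMESPACES + (KEGG_NAMESPACE,)


class TermRankError(Exception):
    """Base class for errors raised by this package."""


class ParseError(TermRankError):
    """A file could not be parsed; message carries path and line number."""


def _check_gene_id(gene: str) -> str:
    if not gene or any(ch.isspace() for ch in gene):
        raise TermRankError(f"invalid gene identifier: {gene!r}")
    return gene


class InteractionNetwork:
    """Undirected, optionally confidence-weighted gene interaction network.

    Wraps a :class:`networkx.Graph`.  Invariants: no self-loops; an edge and
    its reverse are the same edge; ``neighbors(g)`` never contains ``g``.
    """

    def __init__(self, graph: nx.Graph):
        loops = list(nx.selfloop_edges(graph))
        if loops:
            raise TermRankError(f"network contains {len(loops)} self-loop(s)")
        self.graph = graph

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str] | tuple[str, str, float]]
    ) -> "InteractionNetwork":
        """Build a network from (a, b[, score]) tuples.

        Duplicate and reversed edges are merged keeping the maximum score;
        self-loops are rejected with an error (readers drop them with a
        warning before reaching this constructor).
        """
        g = nx.Graph()
        for edge in edges:
            a, b = _check_gene_id(edge[0]), _check_gene_id(edge[1])
            if a == b:
                raise TermRankError(f"self-loop on {a!r}")
            score = float(edge[2]) if len(edge) > 2 else None  # type: ignore[misc]
            if g.has_edge(a, b):
                old = g.edges[a, b].get("score")
                if score is not None and (old is None or score > old):
                    g.edges[a, b]["score"] = score
            else:
                if score is None:
                    g.add_edge(a, b)
                else:
                    g.add_edge(a, b, score=score)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_node(self, gene: str) -> bool:
        return self.graph.has_node(gene)

    def neighbors(self, gene: str) -> set[str]:
        """Strict neighbourhood of ``gene`` (never contains ``gene``)."""
        if not self.graph.has_node(gene):
            raise TermRankError(f"gene {gene!r} is not a network node")
        return set(self.graph.neighbors(gene))

    def degree(self, gene: str) -> int:
        return len(self.neighbors(gene))

    def edge_score(self, a: str, b: str) -> float | None:
        return self.graph.edges[a, b].get("score")

    def edges(self) -> Iterator[tuple[str, str, float | None]]:
        """Iterate edges as (min_id, max_id, score), sorted for determinism."""
        items = []
        for a, b, data in self.graph.edges(data=True):
            lo, hi = sorted((a, b))
            items.append((lo, hi, data.get("score")))
        return iter(sorted(items, key=lambda t: (t[0], t[1])))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return list(self.edges()) == list(other.edges()) and self.nodes == other.nodes

    def __repr__(self) -> str:
        return f"InteractionNetwork(nodes={self.n_nodes}, edges={self.n_edges})"


@dataclass(frozen=True)
class Term:
    """A functional term (GO term or KEGG pathway) with its member gene set."""

    term_id: str
    namespace: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise TermRankError(
                f"unknown namespace {self.namespace!r} for term {self.term_id!r}; "
                f"allowed: {', '.join(NAMESPACES)}"
            )

    @property
    def is_go(self) -> bool:
        return self.namespace in GO_NAMESPACES

    @property
    def size(self) -> int:
        return len(self.members)


class AnnotationCatalogue:
    """Ordered term collection: GO terms first, then KEGG pathways.

    A term's feature index is its position in this ordering and is stable for
    the lifetime of the catalogue.
    """

    def __init__(self, terms: Sequence[Term]):
        seen: set[str] = set()
        kegg_started = False
        for t in terms:
            if t.term_id in seen:
                raise TermRankError(f"duplicate term_id {t.term_id!r}")
            seen.add(t.term_id)
            if t.namespace == KEGG_NAMESPACE:
                kegg_started = True
            elif kegg_started:
                raise TermRankError(
                    f"GO term {t.term_id!r} appears after a KEGG pathway; "
                    "catalogue ordering is GO first, then KEGG"
                )
        self.terms: list[Term] = list(terms)
        self._index: dict[str, int] = {t.term_id: i for i, t in enumerate(self.terms)}

    @classmethod
    def ordered(cls, terms: Iterable[Term]) -> "AnnotationCatalogue":
        """Stably partition terms into the GO-then-KEGG ordering."""
        ts = list(terms)
        go = [t for t in ts if t.is_go]
        kegg = [t for t in ts if not t.is_go]
        return cls(go + kegg)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[Term]:
        return iter(self.terms)

    def __getitem__(self, i: int) -> Term:
        return self.terms[i]

    @property
    def term_ids(self) -> list[str]:
        return [t.term_id for t in self.terms]

    @property
    def n_go(self) -> int:
        return sum(1 for t in self.terms if t.is_go)

    @property
    def n_kegg(self) -> int:
        return len(self.terms) - self.n_go

    def index_of(self, term_id: str) -> int:
        try:
            return self._index[term_id]
        except KeyError:
            raise TermRankError(f"unknown term_id {term_id!r}") from None

    def get(self, term_id: str) -> Term:
        return self.terms[self.index_of(term_id)]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._index

    def restricted_to(
        self, universe: Iterable[str]
    ) -> tuple["AnnotationCatalogue", list[str]]:
        """Intersect every term's members with ``universe``.

        Terms emptied by the restriction are dropped; their ids are returned
        so callers can log a warning.
        """
        uni = set(universe)
        kept: list[Term] = []
        dropped: list[str] = []
        for t in self.terms:
            members = frozenset(t.members & uni)
            if members:
                kept.append(Term(t.term_id, t.namespace, members, t.description))
            else:
                dropped.append(t.term_id)
        return AnnotationCatalogue(kept), dropped

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationCatalogue):
            return NotImplemented
        return self.terms == other.terms

    def __repr__(self) -> str:
        return f"AnnotationCatalogue(go={self.n_go}, kegg={self.n_kegg})"


class LabeledGeneSet:
    """A gene universe with a binary label: disease positives vs the rest."""

    def __init__(self, universe: Sequence[str], positives: Iterable[str]):
        uni = [_check_gene_id(g) for g in universe]
        if len(set(uni)) != len(uni):
            raise TermRankError("universe contains duplicate gene ids")
        pos = frozenset(positives)
        extra = pos - set(uni)
        if extra:
            raise TermRankError(
                "positives not in universe: " + ", ".join(sorted(extra))
            )
        if not pos:
            raise TermRankError("positive set is empty")
        if len(pos) >= len(uni):
            raise TermRankError("positive set must be a proper subset of the universe")
        self.universe: list[str] = uni
        self.positives: frozenset[str] = pos

    @property
    def n(self) -> int:
        return len(self.universe)

    @property
    def n_positives(self) -> int:
        return len(self.positives)

    @property
    def n_negatives(self) -> int:
        return self.n - self.n_positives

    def label(self, gene: str) -> int:
        return 1 if gene in self.positives else 0

    @property
    def labels(self) -> np.ndarray:
        """0/1 label vector in universe order."""
        return np.fromiter(
            (1 if g in self.positives else 0 for g in self.universe),
            dtype=np.int8,
            count=self.n,
        )

    def restricted_to(self, keep: Iterable[str]) -> "LabeledGeneSet":
        keep_set = set(keep)
        uni = [g for g in self.universe if g in keep_set]
        pos = self.positives & keep_set
        if not pos:
            raise TermRankError("restriction removed every positive gene")
        return LabeledGeneSet(uni, pos)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabeledGeneSet):
            return NotImplemented
        return self.universe == other.universe and self.positives == other.positives

    def __repr__(self) -> str:
        return f"LabeledGeneSet(n={self.n}, positives={self.n_positives})"


@dataclass(frozen=True)
class EnrichmentCounts:
    """Counts for the hypergeometric neighbourhood-overlap test.

    N: background gene count; M: term member count (G1); n: neighbourhood
    size (G2); m: overlap |G1 ∩ G2|.
    """

    N: int
    M: int
    n: int
    m: int

    def __post_init__(self) -> None:
        for name in ("N", "M", "n", "m"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise TermRankError(f"count {name} must be a non-negative integer, got {v!r}")
        if self.M > self.N or self.n > self.N:
            raise TermRankError(
                f"counts violate M <= N and n <= N: N={self.N}, M={self.M}, n={self.n}"
            )
        if self.m > min(self.M, self.n):
            raise TermRankError(
                f"overlap m={self.m} exceeds min(M={self.M}, n={self.n})"
            )


class FeatureMatrix:
    """Sparse genes x terms matrix of enrichment scores (−log10 p units).

    Rows follow the labelled universe order, columns the catalogue order.
    Absent entries are exact zeros; stored values are strictly positive.
    """

    def __init__(
        self,
        row_index: Sequence[str],
        col_index: Sequence[str],
        values: sp.spmatrix,
    ):
        values = sp.csr_matrix(values, dtype=np.float64)
        values.eliminate_zeros()
        if values.shape != (len(row_index), len(col_index)):
            raise TermRankError(
                f"matrix shape {values.shape} does not match index sizes "
                f"({len(row_index)}, {len(col_index)})"
            )
        if values.nnz and values.data.min() < 0:
            raise TermRankError("enrichment scores must be non-negative")
        self.row_index: list[str] = list(row_index)
        self.col_index: list[str] = list(col_index)
        self.values: sp.csr_matrix = values
        self._row_pos = {g: i for i, g in enumerate(self.row_index)}
        self._col_pos = {t: j for j, t in enumerate(self.col_index)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, gene: str) -> np.ndarray:
        try:
            i = self._row_pos[gene]
        except KeyError:
            raise TermRankError(f"unknown gene {gene!r}") from None
        return np.asarray(self.values.getrow(i).todense()).ravel()

    def column(self, term_id: str) -> np.ndarray:
        try:
            j = self._col_pos[term_id]
        except KeyError:
            raise TermRankError(f"unknown term {term_id!r}") from None
        return np.asarray(self.values.getcol(j).todense()).ravel()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return (
            self.row_index == other.row_index
            and self.col_index == other.col_index
            and (self.values != other.values).nnz == 0
        )

    def __repr__(self) -> str:
        return f"FeatureMatrix(shape={self.shape}, nnz={self.values.nnz})"


@dataclass(frozen=True)
class MaxRelEntry:
    rank: int
    term_id: str
    namespace: str
    description: str
    mi: float  # mutual information with the label, in the configured log base


class MaxRelList:
    """Terms ranked by mutual information with the disease label (descending)."""

    def __init__(self, entries: Sequence[MaxRelEntry]):
        for i, e in enumerate(entries):
            if e.rank != i + 1:
                raise TermRankError(
                    f"ranks must be consecutive from 1; entry {i} has rank {e.rank}"
                )
            if i and entries[i - 1].mi < e.mi - 1e-15:
                raise TermRankError("MI values must be non-increasing with rank")
        self.entries: list[MaxRelEntry] = list(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[MaxRelEntry]:
        return iter(self.entries)

    def __getitem__(self, i: int) -> MaxRelEntry:
        return self.entries[i]

    @property
    def term_ids(self) -> list[str]:
        return [e.term_id for e in self.entries]

    @property
    def mi_values(self) -> np.ndarray:
        return np.array([e.mi for e in self.entries], dtype=float)

    def top(self, k: int) -> list[str]:
        return self.term_ids[:k]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MaxRelList):
            return NotImplemented
        return self.entries == other.entries

    def __repr__(self) -> str:
        return f"MaxRelList(n={len(self)})"


@dataclass(frozen=True)
class DiscretizedJoint:
    """2 x 3 contingency table: label state (0/1) by discretized feature state."""

    counts: np.ndarray  # shape (2, 3), non-negative ints

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (2, 3):
            raise TermRankError(f"joint table must be 2x3, got {c.shape}")
        if (c < 0).any():
            raise TermRankError("joint table counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


class CutoffCurve:
    """Number of features whose MI meets or exceeds each candidate cutoff."""

    def __init__(self, points: Sequence[tuple[float, int]]):
        pts = sorted(points, key=lambda p: p[0])
        for (c0, n0), (c1, n1) in zip(pts, pts[1:]):
            if c1 > c0 and n1 > n0:
                raise TermRankError("selected count must be non-increasing in cutoff")
        self.points: list[tuple[float, int]] = [(float(c), int(n)) for c, n in pts]

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self) -> Iterator[tuple[float, int]]:
        return iter(self.points)

    def n_selected(self, cutoff: float) -> int:
        for c, n in self.points:
            if math.isclose(c, cutoff, rel_tol=0.0, abs_tol=0.0) or c == cutoff:
                return n
        raise TermRankError(f"cutoff {cutoff} not on the curve")
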