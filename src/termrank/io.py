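"""Readers, writers and sample-restriction for the pipeline's file formats.

Formats (all plain text):

* edge list — whitespace/tab separated, 2 or 3 columns
  (``gene_a  gene_b  [confidence]``), ``#`` comment lines ignored;
* annotations — tab-separated ``term_id  namespace  gene_id  [description]``;
* universe / positives — one gene identifier per line.

Readers are order-insensitive except that the catalogue's column order is
the first-appearance order of term ids (GO namespaces first, then KEGG).
Writers emit deterministic, sorted output so that write→read round-trips are
exact and repeated runs are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .model import (
    NAMESPACES,
    AnnotationCatalogue,
    InteractionNetwork,
    LabeledGeneSet,
    ParseError,
    Term,
    TermRankError,
)

logger = logging.getLogger(__name__)


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_edge_list(
    path: str | Path, min_score: float | None = None
) -> InteractionNetwork:
    """Read an undirected interaction network from a STRING-style edge list.

    Duplicate and reversed edges are merged keeping the maximum confidence
    score; self-loops are dropped (a warning reports how many).  If
    ``min_score`` is given, merged edges whose score is below it are dropped;
    unscored edges are kept regardless.
    """
    path = Path(path)
    edges: dict[tuple[str, str], float | None] = {}
    n_self_loops = 0
    n_lines = 0
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) not in (2, 3):
            raise ParseError(
                f"{path}:{lineno}: expected 2 or 3 columns, got {len(fields)}"
            )
        a, b = fields[0], fields[1]
        score: float | None = None
        if len(fields) == 3:
            try:
                score = float(fields[2])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric score {fields[2]!r}"
                ) from None
        n_lines += 1
        if a == b:
            n_self_loops += 1
            continue
        key = (a, b) if a <= b else (b, a)
        old = edges.get(key, None)
        if key not in edges or (
            score is not None and (old is None or score > old)
        ):
            edges[key] = score
    if n_lines == 0:
        raise ParseError(f"{path}: no edges found")
    if n_self_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_self_loops)
    if min_score is not None:
        edges = {k: s for k, s in edges.items() if s is None or s >= min_score}
    return InteractionNetwork.from_edges(
        [(a, b) if s is None else (a, b, s) for (a, b), s in edges.items()]
    )


def write_edge_list(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b, score in net.edges():
            if score is None:
                fh.write(f"{a}\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\t{score!r}\n")


def read_annotations(path: str | Path) -> AnnotationCatalogue:
    """Read a term-annotation catalogue from a TSV file.

    Columns: ``term_id  namespace  gene_id  [description]``.  One term per
    distinct term_id with the union of its gene ids; duplicate (term, gene)
    pairs are deduplicated silently.  Column order downstream is the
    first-appearance order of term ids, GO namespaces before KEGG pathways.
    """
    path = Path(path)
    order: list[str] = []
    namespace: dict[str, str] = {}
    members: dict[str, set[str]] = {}
    description: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) not in (3, 4):
            raise ParseError(
                f"{path}:{lineno}: expected 3 or 4 tab-separated columns, "
                f"got {len(fields)}"
            )
        term_id, ns, gene = fields[0].strip(), fields[1].strip(), fields[2].strip()
        if ns not in NAMESPACES:
            raise ParseError(
                f"{path}:{lineno}: unknown namespace {ns!r} "
                f"(allowed: {', '.join(NAMESPACES)})"
            )
        if not term_id or not gene:
            raise ParseError(f"{path}:{lineno}: empty term_id or gene_id")
        if term_id not in namespace:
            order.append(term_id)
            namespace[term_id] = ns
            members[term_id] = set()
            description[term_id] = ""
        elif namespace[term_id] != ns:
            raise ParseError(
                f"{path}:{lineno}: term {term_id!r} re-declared with namespace "
                f"{ns!r} (was {namespace[term_id]!r})"
            )
        members[term_id].add(gene)
        if len(fields) == 4 and fields[3] and not description[term_id]:
            description[term_id] = fields[3]
    if not order:
        raise ParseError(f"{path}: no annotation lines found")
    terms = [
        Term(tid, namespace[tid], frozenset(members[tid]), description[tid])
        for tid in order
    ]
    return AnnotationCatalogue.ordered(terms)


def write_annotations(catalogue: AnnotationCatalogue, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in catalogue:
            for gene in sorted(term.members):
                if term.description:
                    fh.write(
                        f"{term.term_id}\t{term.namespace}\t{gene}\t{term.description}\n"
                    )
                else:
                    fh.write(f"{term.term_id}\t{term.namespace}\t{gene}\n")


def _read_id_list(path: Path) -> list[str]:
    ids = [line.strip() for _, line in _data_lines(path)]
    return ids


def read_labels(
    universe_path: str | Path, positives_path: str | Path
) -> LabeledGeneSet:
    """Read the gene universe and positive gene list (one id per line)."""
    universe_path, positives_path = Path(universe_path), Path(positives_path)
    universe = _read_id_list(universe_path)
    if not universe:
        raise ParseError(f"{universe_path}: empty universe")
    positives = _read_id_list(positives_path)
    if not positives:
        raise ParseError(f"{positives_path}: empty positive gene list")
    missing = sorted(set(positives) - set(universe))
    if missing:
        raise TermRankError(
            "positive genes absent from the universe: " + ", ".join(missing)
        )
    return LabeledGeneSet(universe, positives)


def write_labels(
    labels: LabeledGeneSet, universe_path: str | Path, positives_path: str | Path
) -> None:
    with open(universe_path, "w", encoding="utf-8") as fh:
        for g in labels.universe:
            fh.write(g + "\n")
    with open(positives_path, "w", encoding="utf-8") as fh:
        for g in sorted(labels.positives):
            fh.write(g + "\n")


@dataclass(frozen=True)
class RestrictionReport:
    """Counts of genes dropped while restricting the sample to analyzable genes."""

    n_input: int
    n_dropped_not_in_network: int
    n_dropped_unannotatable: int
    n_kept: int
    n_positives_input: int
    n_positives_dropped_not_in_network: int
    n_positives_dropped_unannotatable: int
    n_positives_kept: int

    def to_dict(self) -> dict[str, int]:
        return dict(self.__dict__)

    def __str__(self) -> str:
        return (
            f"universe {self.n_input} -> {self.n_kept} "
            f"(dropped {self.n_dropped_not_in_network} not in network, "
            f"{self.n_dropped_unannotatable} without annotation evidence); "
            f"positives {self.n_positives_input} -> {self.n_positives_kept} "
            f"(dropped {self.n_positives_dropped_not_in_network} not in network, "
            f"{self.n_positives_dropped_unannotatable} without annotation evidence)"
        )


def restrict_to_analyzable(
    net: InteractionNetwork,
    catalogue: AnnotationCatalogue,
    labels: LabeledGeneSet,
) -> tuple[LabeledGeneSet, RestrictionReport]:
    """Drop universe genes that cannot be encoded.

    A gene is analyzable if (a) it is a network node and (b) it is annotated
    to at least one term or has at least one annotated network neighbour
    (otherwise its feature vector would be identically zero).  The operation
    is idempotent.
    """
    annotated: set[str] = set()
    for term in catalogue:
        annotated |= term.members

    in_network = [g for g in labels.universe if net.has_node(g)]
    in_network_set = set(in_network)
    kept = [
        g
        for g in in_network
        if g in annotated or not annotated.isdisjoint(net.neighbors(g))
    ]
    kept_set = set(kept)

    pos = labels.positives
    pos_in_network = pos & in_network_set
    pos_kept = pos & kept_set
    report = RestrictionReport(
        n_input=labels.n,
        n_dropped_not_in_network=labels.n - len(in_network),
        n_dropped_unannotatable=len(in_network) - len(kept),
        n_kept=len(kept),
        n_positives_input=len(pos),
        n_positives_dropped_not_in_network=len(pos) - len(pos_in_network),
        n_positives_dropped_unannotatable=len(pos_in_network) - len(pos_kept),
        n_positives_kept=len(pos_kept),
    )
    if not pos_kept:
        raise TermRankError(
            "restriction removed every positive gene; " + str(report)
        )
    restricted = labels.restricted_to(kept_set)
    if report.n_kept != labels.n:
        logger.info("sample restriction: %s", report)
    return restricted, report
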