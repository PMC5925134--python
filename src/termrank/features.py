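"""Assembly and persistence of the gene x term enrichment feature matrix.

The matrix has one row per gene of the labelled universe (universe order) and
one column per catalogue term (catalogue order).  It is overwhelmingly zero —
a gene scores nonzero on a term only when its neighbourhood overlaps the
term's members — so it is built from the sparse overlap pattern
``adjacency @ annotation`` and stored as a sparse triplet TSV.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from pathlib import Path

from .enrichment import ZERO_TOL, tail_scores
from .model import (
    AnnotationCatalogue,
    FeatureMatrix,
    InteractionNetwork,
    LabeledGeneSet,
    ParseError,
    TermRankError,
)


def build_matrix(
    labels: LabeledGeneSet,
    catalogue: AnnotationCatalogue,
    net: InteractionNetwork,
    n_background: int | None = None,
) -> FeatureMatrix:
    """Build the full enrichment feature matrix for a restricted universe.

    Every universe gene must be a network node (run
    :func:`termrank.io.restrict_to_analyzable` first) and every catalogue
    term must retain at least one member inside the universe.  The default
    background size N is the universe size.  Construction is deterministic.
    """
    universe = labels.universe
    uni_set = set(universe)
    pos = {g: i for i, g in enumerate(universe)}
    if n_background is None:
        n_background = len(universe)

    missing = [g for g in universe if not net.has_node(g)]
    if missing:
        raise TermRankError(
            "universe genes missing from the network (restrict first): "
            + ", ".join(missing[:5])
            + ("..." if len(missing) > 5 else "")
        )

    # annotation incidence: genes x terms
    rows: list[int] = []
    cols: list[int] = []
    for j, term in enumerate(catalogue):
        members = term.members & uni_set
        if not members:
            raise TermRankError(
                f"term {term.term_id!r} has no members in the analysis universe"
            )
        for g in members:
            rows.append(pos[g])
            cols.append(j)
    ann = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int32), (rows, cols)),
        shape=(len(universe), len(catalogue)),
    )

    # adjacency restricted to the universe
    arows: list[int] = []
    acols: list[int] = []
    for a, b, _ in net.edges():
        if a in pos and b in pos:
            arows.extend((pos[a], pos[b]))
            acols.extend((pos[b], pos[a]))
    adj = sp.csr_matrix(
        (np.ones(len(arows), dtype=np.int32), (arows, acols)),
        shape=(len(universe), len(universe)),
    )

    neigh_size = np.asarray(adj.sum(axis=1)).ravel().astype(np.int64)
    term_size = np.asarray(ann.sum(axis=0)).ravel().astype(np.int64)
    if n_background < max(
        int(term_size.max(initial=0)), int(neigh_size.max(initial=0))
    ):
        raise TermRankError(
            f"background N={n_background} smaller than the largest term or "
            "neighbourhood in the universe"
        )

    overlap = (adj @ ann).tocoo()  # m = |members ∩ neighbours| where nonzero
    scores = tail_scores(
        overlap.data.astype(np.int64),
        n_background,
        term_size[overlap.col],
        neigh_size[overlap.row],
    )
    keep = scores >= ZERO_TOL
    values = sp.csr_matrix(
        (scores[keep], (overlap.row[keep], overlap.col[keep])),
        shape=(len(universe), len(catalogue)),
    )
    return FeatureMatrix(universe, catalogue.term_ids, values)


def write_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as sparse triplets with explicit orderings.

    Two header lines (``#rows``, ``#cols``) carry the row and column id
    orders; each following line is ``gene_id<TAB>term_id<TAB>score`` with the
    score at 17 significant digits, so the round-trip is bit-exact.
    """
    coo = matrix.values.tocoo()
    order = np.lexsort((coo.col, coo.row))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#rows\t" + "\t".join(matrix.row_index) + "\n")
        fh.write("#cols\t" + "\t".join(matrix.col_index) + "\n")
        for k in order:
            fh.write(
                f"{matrix.row_index[coo.row[k]]}\t"
                f"{matrix.col_index[coo.col[k]]}\t"
                f"{coo.data[k]:.17g}\n"
            )


def read_matrix(path: str | Path) -> FeatureMatrix:
    """Read a feature matrix written by :func:`write_matrix`."""
    path = Path(path)
    row_index: list[str] | None = None
    col_index: list[str] | None = None
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    row_pos: dict[str, int] = {}
    col_pos: dict[str, int] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#rows\t"):
                row_index = line.split("\t")[1:]
                row_pos = {g: i for i, g in enumerate(row_index)}
                continue
            if line.startswith("#cols\t"):
                col_index = line.split("\t")[1:]
                col_pos = {t: j for j, t in enumerate(col_index)}
                continue
            if line.startswith("#"):
                continue
            if row_index is None or col_index is None:
                raise ParseError(
                    f"{path}:{lineno}: triplet before #rows/#cols header"
                )
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            gene, term, score_s = fields
            if gene not in row_pos:
                raise ParseError(f"{path}:{lineno}: unknown gene {gene!r}")
            if term not in col_pos:
                raise ParseError(f"{path}:{lineno}: unknown term {term!r}")
            try:
                score = float(score_s)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric score {score_s!r}"
                ) from None
            rows.append(row_pos[gene])
            cols.append(col_pos[term])
            data.append(score)
    if row_index is None or col_index is None:
        raise ParseError(f"{path}: missing #rows/#cols header")
    values = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(row_index), len(col_index))
    )
    return FeatureMatrix(row_index, col_index, values)
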