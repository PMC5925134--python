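"""Maximum-relevance (MaxRel) ranking of features by mutual information.

Each feature column is discretized into three states around its mean:
below mean − k·sd, within mean ± k·sd, above mean + k·sd (the discretization
conventionally used with mRMR-style mutual-information estimators).  Mutual
information between the discretized feature and the binary disease label is

    I(c; f) = Σ p(c, s) log( p(c, s) / (p(c) p(s)) )

summed over label states c ∈ {0, 1} and feature states s ∈ {0, 1, 2}, with
0·log(·) ≡ 0.  The default log base is 2 (bits).  Features are ranked by MI
descending; ties keep catalogue column order, giving a deterministic list.
Only the maximum-relevance half of mRMR is implemented — no redundancy term
and no classifier.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable

import numpy as np

from .model import (
    AnnotationCatalogue,
    CutoffCurve,
    DiscretizedJoint,
    FeatureMatrix,
    LabeledGeneSet,
    MaxRelEntry,
    MaxRelList,
    ParseError,
    TermRankError,
)

logger = logging.getLogger(__name__)


def discretize(column: np.ndarray, k: float = 1.0) -> np.ndarray:
    """Discretize a score column into states {0, 1, 2} at mean ± k·sd.

    The standard deviation is the sample (n−1) estimate.  A constant column
    (sd = 0, including length-1 columns) maps every gene to state 1.
    """
    column = np.asarray(column, dtype=np.float64)
    if column.ndim != 1:
        raise TermRankError("column must be one-dimensional")
    states = np.ones(column.shape, dtype=np.int8)
    if column.size < 2:
        return states
    mu = column.mean()
    sd = column.std(ddof=1)
    if sd == 0.0 or not np.isfinite(sd):
        return states
    states[column < mu - k * sd] = 0
    states[column > mu + k * sd] = 2
    return states


def joint_counts(labels: np.ndarray, states: np.ndarray) -> DiscretizedJoint:
    """Tabulate the 2x3 (label, feature-state) contingency table."""
    labels = np.asarray(labels)
    states = np.asarray(states)
    if labels.shape != states.shape:
        raise TermRankError(
            f"label/state length mismatch: {labels.shape} vs {states.shape}"
        )
    counts = np.bincount(
        labels.astype(np.int64) * 3 + states.astype(np.int64), minlength=6
    ).reshape(2, 3)
    return DiscretizedJoint(counts)


def mutual_information(joint: DiscretizedJoint, base: float = 2.0) -> float:
    """Mutual information of the 2x3 joint table, in units of log ``base``.

    Returns a value in [0, min(H(c), H(s))]; empty cells contribute nothing.
    """
    total = joint.total
    if total == 0:
        raise TermRankError("joint table is empty")
    p = joint.counts / total
    pc = p.sum(axis=1, keepdims=True)
    ps = p.sum(axis=0, keepdims=True)
    mask = p > 0
    ratio = np.ones_like(p)  # log(1) = 0 stands in for empty cells
    np.divide(p, pc * ps, out=ratio, where=mask)
    return max(float((p * np.log(ratio)).sum() / math.log(base)), 0.0)


def column_mi(
    column: np.ndarray, labels: np.ndarray, k: float = 1.0, base: float = 2.0
) -> float:
    """MI between one score column and the label vector (discretize + MI)."""
    return mutual_information(joint_counts(labels, discretize(column, k)), base)


def maxrel_rank(
    matrix: FeatureMatrix,
    labels: LabeledGeneSet,
    catalogue: AnnotationCatalogue,
    k: float = 1.0,
    base: float = 2.0,
) -> MaxRelList:
    """Rank every catalogue term by MI with the disease label.

    Rows of ``matrix`` must align with ``labels.universe`` and columns with
    the catalogue's term order.  Ties in MI are broken by catalogue column
    index ascending, so the list is fully deterministic.
    """
    if matrix.row_index != labels.universe:
        raise TermRankError("matrix rows do not match the labelled universe")
    if matrix.col_index != catalogue.term_ids:
        raise TermRankError("matrix columns do not match the catalogue")
    y = labels.labels
    csc = matrix.values.tocsc()
    mi = np.empty(len(catalogue), dtype=np.float64)
    for j in range(len(catalogue)):
        col = np.zeros(labels.n, dtype=np.float64)
        start, stop = csc.indptr[j], csc.indptr[j + 1]
        col[csc.indices[start:stop]] = csc.data[start:stop]
        mi[j] = column_mi(col, y, k=k, base=base)
    order = np.argsort(-mi, kind="stable")  # stable: ties keep column order
    entries = [
        MaxRelEntry(
            rank=r + 1,
            term_id=catalogue[j].term_id,
            namespace=catalogue[j].namespace,
            description=catalogue[j].description,
            mi=float(mi[j]),
        )
        for r, j in enumerate(order)
    ]
    return MaxRelList(entries)


def cutoff_curve(mlist: MaxRelList, cutoffs: Iterable[float]) -> CutoffCurve:
    """Count selected features (MI ≥ cutoff, inclusive) per candidate cutoff."""
    cuts = [float(c) for c in cutoffs]
    if not cuts:
        raise TermRankError("cutoff list is empty")
    mi = mlist.mi_values
    return CutoffCurve([(c, int((mi >= c).sum())) for c in cuts])


def select(mlist: MaxRelList, cutoff: float) -> MaxRelList:
    """Truncate the ranked list to entries with MI ≥ cutoff (unrounded).

    An empty selection returns an empty list with a logged warning.
    """
    kept = [e for e in mlist if e.mi >= cutoff]
    if not kept:
        logger.warning("MI cutoff %g selects no features", cutoff)
    return MaxRelList(kept)


MAXREL_HEADER = ["term_id", "description", "namespace", "mi_value", "rank", "mi_exact"]


def write_maxrel(mlist: MaxRelList, path: str | Path) -> None:
    """Write a ranked term list as TSV.

    Columns mirror the standard ranked-report layout (term id, description,
    namespace, MI rounded to 3 decimals, rank); a final ``mi_exact`` column
    carries the unrounded MI so the list can be re-filtered losslessly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(MAXREL_HEADER) + "\n")
        for e in mlist:
            fh.write(
                f"{e.term_id}\t{e.description}\t{e.namespace}\t"
                f"{e.mi:.3f}\t{e.rank}\t{e.mi:.17g}\n"
            )


def read_maxrel(path: str | Path) -> MaxRelList:
    """Read a ranked term list written by :func:`write_maxrel`."""
    path = Path(path)
    entries: list[MaxRelEntry] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != MAXREL_HEADER[:5]:
            raise ParseError(f"{path}: unrecognized MaxRel header")
        has_exact = len(header) > 5 and header[5] == "mi_exact"
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: expected ≥5 columns")
            mi = float(fields[5]) if has_exact else float(fields[3])
            entries.append(
                MaxRelEntry(
                    rank=int(fields[4]),
                    term_id=fields[0],
                    namespace=fields[2],
                    description=fields[1],
                    mi=mi,
                )
            )
    return MaxRelList(entries)


def write_cutoff_curve(
    curve: CutoffCurve, path: str | Path, plot_path: str | Path | None = None
) -> None:
    """Write the cutoff curve as TSV; optionally render a step plot."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cutoff\tn_selected\n")
        for c, n in curve:
            fh.write(f"{c:.17g}\t{n}\n")
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        xs = [c for c, _ in curve]
        ys = [n for _, n in curve]
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.step(xs, ys, where="post")
        ax.set_xlabel("MI cutoff")
        ax.set_ylabel("features selected")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
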