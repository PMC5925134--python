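"""End-to-end orchestration: restrict → encode → rank → select.

The pipeline reads the four input files, drops genes that cannot be encoded,
builds the gene × term enrichment matrix, ranks terms by mutual information
with the disease label, writes the cutoff curve, and truncates the ranked
list at the configured MI cutoff.  Every count a study report narrates
(genes dropped and why, class sizes, GO/KEGG/feature totals, number of
selected terms) is logged and returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import features, io, maxrel
from .model import CutoffCurve, FeatureMatrix, MaxRelList, TermRankError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Inputs and tunables of one pipeline run."""

    network: Path
    annotations: Path
    universe: Path
    positives: Path
    out_dir: Path
    min_score: float | None = None
    background_n: int | None = None
    mi_base: float = 2.0
    disc_k: float = 1.0
    cutoff: float = 0.003

    def __post_init__(self) -> None:
        if self.cutoff < 0:
            raise TermRankError("cutoff must be non-negative")
        for name in ("network", "annotations", "universe", "positives", "out_dir"):
            object.__setattr__(self, name, Path(getattr(self, name)))

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        """Load a YAML (or flat key: value) config file; kwargs override it."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise TermRankError(f"{path}: config must be a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class RunResult:
    """Artefact paths plus the counts the run log reports."""

    matrix_path: Path
    maxrel_path: Path
    curve_path: Path
    selected_path: Path
    log_path: Path
    counts: dict[str, int]
    ranking: MaxRelList
    selected: MaxRelList
    curve: CutoffCurve
    matrix: FeatureMatrix = field(repr=False)


def _curve_cutoffs(mi_values, configured: float) -> list[float]:
    """Candidate cutoffs: every distinct MI value plus 0 and the configured one."""
    cuts = {0.0, float(configured)}
    cuts.update(float(v) for v in mi_values)
    return sorted(cuts)


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline; outputs land in ``config.out_dir``.

    Any stage failure aborts with the stage name and cause, and removes the
    partial output files written by this run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    matrix_path = out / "feature_matrix.tsv"
    maxrel_path = out / "maxrel.tsv"
    curve_path = out / "cutoff_curve.tsv"
    selected_path = out / "selected_terms.tsv"
    written: list[Path] = []

    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("termrank")
    root.addHandler(handler)
    old_level = root.level
    if root.level > logging.INFO or root.level == logging.NOTSET:
        root.setLevel(logging.INFO)
    written.append(log_path)

    stage = "load"
    try:
        net = io.read_edge_list(config.network, min_score=config.min_score)
        catalogue = io.read_annotations(config.annotations)
        labels = io.read_labels(config.universe, config.positives)
        logger.info(
            "loaded network (%d nodes, %d edges), catalogue (%d GO + %d KEGG), "
            "universe (%d genes, %d positives)",
            net.n_nodes, net.n_edges, catalogue.n_go, catalogue.n_kegg,
            labels.n, labels.n_positives,
        )

        stage = "restrict"
        labels, report = io.restrict_to_analyzable(net, catalogue, labels)
        catalogue, dropped_terms = catalogue.restricted_to(labels.universe)
        if dropped_terms:
            logger.warning(
                "%d term(s) had no members in the restricted universe and "
                "were dropped: %s%s",
                len(dropped_terms), ", ".join(dropped_terms[:5]),
                "..." if len(dropped_terms) > 5 else "",
            )
        logger.info("restriction: %s", report)

        stage = "encode"
        n_background = (
            config.background_n if config.background_n is not None else labels.n
        )
        matrix = features.build_matrix(labels, catalogue, net, n_background)
        features.write_matrix(matrix, matrix_path)
        written.append(matrix_path)
        logger.info(
            "feature matrix: %d genes x %d features (%d GO + %d KEGG), "
            "background N=%d, nnz=%d",
            matrix.shape[0], matrix.shape[1], catalogue.n_go, catalogue.n_kegg,
            n_background, matrix.values.nnz,
        )

        stage = "rank"
        ranking = maxrel.maxrel_rank(
            matrix, labels, catalogue, k=config.disc_k, base=config.mi_base
        )
        maxrel.write_maxrel(ranking, maxrel_path)
        written.append(maxrel_path)
        curve = maxrel.cutoff_curve(
            ranking, _curve_cutoffs(ranking.mi_values, config.cutoff)
        )
        maxrel.write_cutoff_curve(curve, curve_path)
        written.append(curve_path)

        stage = "select"
        selected = maxrel.select(ranking, config.cutoff)
        maxrel.write_maxrel(selected, selected_path)
        written.append(selected_path)
        logger.info(
            "selected %d of %d features at MI cutoff %g",
            len(selected), len(ranking), config.cutoff,
        )

        counts = {
            **report.to_dict(),
            "n_universe": labels.n,
            "n_positives": labels.n_positives,
            "n_negatives": labels.n_negatives,
            "n_go_terms": catalogue.n_go,
            "n_kegg_terms": catalogue.n_kegg,
            "n_features": len(catalogue),
            "n_terms_dropped_empty": len(dropped_terms),
            "n_background": n_background,
            "n_selected": len(selected),
        }
        logger.info("counts: %s", counts)
        return RunResult(
            matrix_path=matrix_path,
            maxrel_path=maxrel_path,
            curve_path=curve_path,
            selected_path=selected_path,
            log_path=log_path,
            counts=counts,
            ranking=ranking,
            selected=selected,
            curve=curve,
            matrix=matrix,
        )
    except Exception as exc:
        for p in written:
            if p != log_path:
                p.unlink(missing_ok=True)
        raise TermRankError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        handler.close()
        root.removeHandler(handler)
        root.setLevel(old_level)
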