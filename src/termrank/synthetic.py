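"""Synthetic benchmark generator with planted label-associated terms.

The generator emulates the shape of a real disease-gene study at desk scale:
a sparse undirected interaction network over a few thousand genes, a
catalogue of GO-like and KEGG-like terms of heterogeneous (log-uniform)
size, and an extremely imbalanced binary labelling (tens of positives among
thousands of genes).  A chosen subset of terms is "planted": a fraction ρ of
each positive gene's incident edges is rewired so that the far endpoint is a
member of a randomly chosen planted term.  Rewiring (rather than adding
edges) preserves each positive's degree, so any recoverable signal lives in
neighbourhood *composition*, not in a degree confound.

Everything is drawn from one seeded :class:`numpy.random.Generator` and all
files are written in sorted, deterministic order: the same configuration
always produces byte-identical output.  A ground-truth manifest records the
planted term ids and positive genes for downstream evaluation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import write_annotations, write_edge_list, write_labels
from .model import (
    GO_NAMESPACES,
    KEGG_NAMESPACE,
    AnnotationCatalogue,
    InteractionNetwork,
    LabeledGeneSet,
    ParseError,
    Term,
    TermRankError,
)

_REWIRE_ATTEMPTS = 200


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shape parameters for the synthetic benchmark."""

    n_genes: int = 2000
    n_go_terms: int = 280
    n_kegg_terms: int = 20
    term_size_min: int = 5
    term_size_max: int = 200
    mean_degree: float = 20.0
    n_positives: int = 25
    n_planted_terms: int = 5
    signal_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 3:
            raise TermRankError("n_genes must be at least 3")
        if not (0 < self.n_positives < self.n_genes):
            raise TermRankError("need 0 < n_positives < n_genes")
        if self.n_planted_terms > self.n_go_terms + self.n_kegg_terms:
            raise TermRankError("more planted terms than terms")
        if not (0.0 <= self.signal_fraction <= 1.0):
            raise TermRankError("signal_fraction must lie in [0, 1]")
        if not (1 <= self.term_size_min <= self.term_size_max <= self.n_genes):
            raise TermRankError(
                "need 1 <= term_size_min <= term_size_max <= n_genes"
            )
        if self.signal_fraction > 0 and self.term_size_min < 2:
            raise TermRankError(
                "planted terms need at least 2 members to supply rewiring "
                "endpoints distinct from the positive gene"
            )
        if self.mean_degree <= 0:
            raise TermRankError("mean_degree must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for evaluating recovery."""

    planted_term_ids: list[str]
    positive_gene_ids: list[str]
    config: GeneratorConfig


@dataclass(frozen=True)
class SyntheticDataset:
    """Paths of the emitted files plus the in-memory objects and truth."""

    network_path: Path
    annotations_path: Path
    universe_path: Path
    positives_path: Path
    manifest_path: Path
    network: InteractionNetwork
    catalogue: AnnotationCatalogue
    labels: LabeledGeneSet
    truth: GroundTruth


def _draw_terms(
    cfg: GeneratorConfig, genes: list[str], rng: np.random.Generator
) -> AnnotationCatalogue:
    terms: list[Term] = []
    lo, hi = np.log(cfg.term_size_min), np.log(cfg.term_size_max)
    for j in range(cfg.n_go_terms):
        size = int(np.clip(round(np.exp(rng.uniform(lo, hi))),
                           cfg.term_size_min, cfg.term_size_max))
        members = rng.choice(cfg.n_genes, size=size, replace=False)
        ns = GO_NAMESPACES[j % len(GO_NAMESPACES)]
        terms.append(
            Term(
                f"SGO:{j:04d}", ns,
                frozenset(genes[i] for i in members),
                f"synthetic GO-like term {j}",
            )
        )
    for j in range(cfg.n_kegg_terms):
        size = int(np.clip(round(np.exp(rng.uniform(lo, hi))),
                           cfg.term_size_min, cfg.term_size_max))
        members = rng.choice(cfg.n_genes, size=size, replace=False)
        terms.append(
            Term(
                f"SKP:{j:03d}", KEGG_NAMESPACE,
                frozenset(genes[i] for i in members),
                f"synthetic pathway {j}",
            )
        )
    return AnnotationCatalogue(terms)


def _stub_pairing_network(
    cfg: GeneratorConfig, genes: list[str], rng: np.random.Generator
) -> set[tuple[str, str]]:
    """Poisson stub pairing: draw Poisson(mean_degree) stubs per gene, pair
    uniformly; self-pairs and duplicate pairs are rejected and their stubs
    re-paired."""
    stubs_per_gene = rng.poisson(cfg.mean_degree, size=cfg.n_genes)
    if stubs_per_gene.sum() % 2 == 1:
        stubs_per_gene[rng.integers(cfg.n_genes)] += 1
    pool = np.repeat(np.arange(cfg.n_genes), stubs_per_gene)
    edges: set[tuple[int, int]] = set()
    for _ in range(_REWIRE_ATTEMPTS):
        if len(pool) < 2:
            break
        pool = rng.permutation(pool)
        leftovers: list[int] = []
        for i in range(0, len(pool) - 1, 2):
            a, b = int(pool[i]), int(pool[i + 1])
            key = (a, b) if a < b else (b, a)
            if a == b or key in edges:
                leftovers.extend((a, b))
            else:
                edges.add(key)
        if len(pool) % 2:
            leftovers.append(int(pool[-1]))
        if len(leftovers) == len(pool):
            break  # nothing pairable is left
        pool = np.array(leftovers, dtype=np.int64)
    return {(genes[a], genes[b]) for a, b in edges}


def _plant_signal(
    cfg: GeneratorConfig,
    edges: set[tuple[str, str]],
    positives: list[str],
    planted: list[Term],
    rng: np.random.Generator,
) -> set[tuple[str, str]]:
    """Rewire a fraction ρ of each positive's incident edges into planted
    terms, preserving the positive's degree."""
    if cfg.signal_fraction == 0.0 or not positives:
        return edges
    planted_members = [sorted(t.members) for t in planted]
    adj: dict[str, set[str]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    def has_edge(a: str, b: str) -> bool:
        return b in adj.get(a, ())

    for g in sorted(positives):
        incident = sorted(adj.get(g, ()))
        n_rewire = int(round(cfg.signal_fraction * len(incident)))
        if n_rewire == 0:
            continue
        chosen = [incident[i] for i in rng.permutation(len(incident))[:n_rewire]]
        for old in chosen:
            new: str | None = None
            for _ in range(_REWIRE_ATTEMPTS):
                members = planted_members[rng.integers(len(planted_members))]
                cand = members[rng.integers(len(members))]
                if cand != g and not has_edge(g, cand):
                    new = cand
                    break
            if new is None:
                continue  # keep the original edge
            key_old = (g, old) if g < old else (old, g)
            key_new = (g, new) if g < new else (new, g)
            edges.discard(key_old)
            edges.add(key_new)
            adj[g].discard(old)
            adj.get(old, set()).discard(g)
            adj.setdefault(g, set()).add(new)
            adj.setdefault(new, set()).add(g)
    return edges


def generate(config: GeneratorConfig, out_dir: str | Path) -> SyntheticDataset:
    """Generate a complete synthetic study into ``out_dir``.

    Emits ``network.tsv``, ``annotations.tsv``, ``universe.txt``,
    ``positives.txt`` and ``manifest.txt`` in the exact dialects the readers
    consume.  Identical configurations produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]

    catalogue = _draw_terms(config, genes, rng)
    edges = _stub_pairing_network(config, genes, rng)
    positives = sorted(
        genes[i]
        for i in rng.choice(config.n_genes, size=config.n_positives, replace=False)
    )
    planted_idx = sorted(
        int(i)
        for i in rng.choice(len(catalogue), size=config.n_planted_terms, replace=False)
    )
    planted = [catalogue[i] for i in planted_idx]
    edges = _plant_signal(config, edges, positives, planted, rng)

    network = InteractionNetwork.from_edges(sorted(edges))
    labels = LabeledGeneSet(genes, positives)
    truth = GroundTruth(
        planted_term_ids=[t.term_id for t in planted],
        positive_gene_ids=positives,
        config=config,
    )

    network_path = out_dir / "network.tsv"
    annotations_path = out_dir / "annotations.tsv"
    universe_path = out_dir / "universe.txt"
    positives_path = out_dir / "positives.txt"
    manifest_path = out_dir / "manifest.txt"
    write_edge_list(network, network_path)
    write_annotations(catalogue, annotations_path)
    write_labels(labels, universe_path, positives_path)
    write_manifest(truth, manifest_path)
    return SyntheticDataset(
        network_path=network_path,
        annotations_path=annotations_path,
        universe_path=universe_path,
        positives_path=positives_path,
        manifest_path=manifest_path,
        network=network,
        catalogue=catalogue,
        labels=labels,
        truth=truth,
    )


def write_manifest(truth: GroundTruth, path: str | Path) -> None:
    """Flat key=value ground-truth manifest."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("planted_term_ids=" + ",".join(truth.planted_term_ids) + "\n")
        fh.write("positive_gene_ids=" + ",".join(truth.positive_gene_ids) + "\n")
        for f in dataclasses.fields(GeneratorConfig):
            fh.write(f"config.{f.name}={getattr(truth.config, f.name)}\n")


def read_manifest(path: str | Path) -> GroundTruth:
    """Read a manifest written by :func:`write_manifest`."""
    path = Path(path)
    values: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected key=value")
            key, _, value = line.partition("=")
            values[key] = value
    try:
        cfg_kwargs = {}
        for f in dataclasses.fields(GeneratorConfig):
            cfg_kwargs[f.name] = _coerce(f, values[f"config.{f.name}"])
        return GroundTruth(
            planted_term_ids=values["planted_term_ids"].split(","),
            positive_gene_ids=values["positive_gene_ids"].split(","),
            config=GeneratorConfig(**cfg_kwargs),
        )
    except KeyError as exc:
        raise ParseError(f"{path}: missing manifest key {exc}") from None


def _coerce(f: dataclasses.Field, raw: str):
    if f.name in ("mean_degree", "signal_fraction"):
        return float(raw)
    return int(raw)
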