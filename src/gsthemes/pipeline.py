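"""End-to-end theme analysis: restrict -> similarity -> graph -> themes -> reports.

The pipeline chains the stage modules into one run over a gene-set
collection and its per-set statistics:

1. restrict the collection to the measured-gene universe,
2. pairwise similarity under the chosen measure,
3. threshold into the overlap graph, attach statistics, drop isolated sets,
4. walktrap communities, ordered by the product-of-ranks statistic,
5. TF-IDF term table per theme,
6. gene frequency/statistic table per theme,
7. optionally, induced PPI subnetwork per theme.

Every stage count (sets in, nodes, edges, dropped, clusters) is logged and
recorded in the bundle metadata, and the run is deterministic for fixed
inputs and configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from . import __version__
from .geneset import (
    GeneSetCollection,
    read_gene_statistics,
    read_gmt,
    read_set_statistics,
)
from .genestats import attach_statistics, gene_cluster_frequency, rank_genes
from .network import build_graph, export_graph, prune_isolated
from .ppi import PPIEdge, induce_subnetwork, map_orthologs, read_ppi
from .similarity import pairwise_similarity
from .textmine import build_corpus_idf, cluster_term_scores, default_exclusions
from .themes import ThemePartition, order_clusters, walktrap_communities

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "run_from_config", "write_bundle"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """File-based configuration of one pipeline run (the CLI's contract)."""

    gmt: str
    set_stats: str | None = None
    gene_stats: str | None = None
    universe: str | None = None  # optional one-gene-per-line file
    ppi: str | None = None
    ppi_dialect: str = "tsv"
    ortholog_map: str | None = None
    measure: str = "ari"
    threshold: float = 0.25
    strict: bool = False
    steps: int = 4
    direction: str = "larger-better"
    use_absolute: bool = False
    source: str = "name"
    exclusions: str | None = None  # path to a replacement exclusion list
    top_n_terms: int = 25
    min_confidence: float = 0.0
    min_degree: int = 0
    include_inferred: bool = True
    outdir: str | None = None
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a plain-text ``key = value`` / ``key: value`` file."""
        cfg: dict[str, object] = {}
        types = cls.__dataclass_fields__
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.replace(":", "=", 1).partition("=")
                key, val = key.strip(), val.strip()
                if key not in types:
                    raise ValueError(f"unknown config key {key!r}")
                typ = types[key].type
                if "bool" in typ:
                    cfg[key] = val.lower() in ("1", "true", "yes")
                elif "int" in typ:
                    cfg[key] = int(val)
                elif "float" in typ:
                    cfg[key] = float(val)
                else:
                    cfg[key] = val
        return cls(**cfg)  # type: ignore[arg-type]


@dataclass
class ReportBundle:
    """In-memory results of one run plus the metadata describing it."""

    graph: nx.Graph
    dropped: list[str]
    partition: ThemePartition
    term_tables: pd.DataFrame  # long form: cluster + term columns
    gene_tables: pd.DataFrame  # long form: cluster + gene columns
    ppi_networks: dict[int, nx.Graph] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    notices: list[str] = field(default_factory=list)


def _read_exclusions(path: str | Path) -> frozenset[str]:
    words = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip().lower()
            if line:
                words.add(line)
    return frozenset(words)


def run_pipeline(
    collection: GeneSetCollection,
    set_stats: pd.DataFrame | None = None,
    gene_stats: pd.Series | None = None,
    *,
    universe: Iterable[str] | None = None,
    measure: str = "ari",
    threshold: float = 0.25,
    strict: bool = False,
    steps: int = 4,
    direction: str = "larger-better",
    use_absolute: bool = False,
    source: str = "name",
    exclusions: Iterable[str] | None = None,
    top_n_terms: int = 25,
    corpus: GeneSetCollection | None = None,
    ppi_edges: Sequence[PPIEdge] | None = None,
    min_confidence: float = 0.0,
    min_degree: int = 0,
    include_inferred: bool = True,
) -> ReportBundle:
    """Run the full theme analysis on in-memory inputs.

    ``corpus`` is the reference collection for IDFs (defaults to the
    analysed collection itself — use the full database when available).
    Missing optional inputs simply omit the corresponding outputs, with a
    notice in the bundle.
    """
    notices: list[str] = []
    if universe is not None:
        collection = collection.restrict_to_universe(universe)
    n_input = len(collection)
    empty = collection.empty_set_names
    if empty:
        notices.append(f"{len(empty)} set(s) empty after universe restriction: excluded")

    simmat = pairwise_similarity(collection, measure)
    sizes = {s.name: len(s.members & collection.universe) for s in collection.nonempty_sets}
    graph = build_graph(simmat, threshold, node_stats=set_stats, set_sizes=sizes, strict=strict)
    graph, dropped = prune_isolated(graph)
    logger.info(
        "overlap graph: %d nodes, %d edges (%d isolated set(s) dropped)",
        graph.number_of_nodes(), graph.number_of_edges(), len(dropped),
    )

    partition = walktrap_communities(graph, steps=steps)
    partition = order_clusters(partition, direction=direction, use_absolute=use_absolute)
    logger.info("walktrap: %d cluster(s)", partition.n_clusters)
    if partition.n_clusters == 0:
        notices.append("empty post-threshold graph: no themes detected")

    corpus_idf = build_corpus_idf(corpus or collection, source=source, exclusions=exclusions)
    term_frames = []
    gene_frames = []
    ppi_networks: dict[int, nx.Graph] = {}
    for _, row in partition.clusters.iterrows():
        cid = int(row["cluster"])
        members = [collection[name] for name in row["members"]]
        members = [gs.restrict(collection.universe) for gs in members]
        terms = cluster_term_scores(
            members, corpus_idf, source=source, top_n=top_n_terms, exclusions=exclusions
        )
        terms.insert(0, "cluster", cid)
        term_frames.append(terms)
        gtab = gene_cluster_frequency(members)
        if gene_stats is not None:
            gtab = rank_genes(attach_statistics(gtab, gene_stats))
        gtab.insert(0, "cluster", cid)
        gene_frames.append(gtab)
        if ppi_edges is not None:
            genes = set().union(*(gs.members for gs in members))
            ppi_networks[cid] = induce_subnetwork(
                ppi_edges,
                genes,
                min_confidence=min_confidence,
                min_degree=min_degree,
                include_inferred=include_inferred,
                gene_stats=gene_stats,
            )
    if ppi_edges is None:
        notices.append("no PPI edge list supplied: PPI subnetworks omitted")

    term_tables = (
        pd.concat(term_frames, ignore_index=True)
        if term_frames
        else pd.DataFrame(columns=["cluster", "term", "tf", "idf", "tfidf", "rank", "novel"])
    )
    gene_tables = (
        pd.concat(gene_frames, ignore_index=True)
        if gene_frames
        else pd.DataFrame(columns=["cluster", "gene", "frequency"])
    )
    metadata = {
        "version": __version__,
        "parameters": {
            "measure": measure,
            "threshold": threshold,
            "strict": strict,
            "steps": steps,
            "direction": direction,
            "use_absolute": use_absolute,
            "source": source,
            "top_n_terms": top_n_terms,
            "min_confidence": min_confidence,
            "min_degree": min_degree,
            "include_inferred": include_inferred,
        },
        "counts": {
            "input_sets": n_input,
            "empty_sets": len(empty),
            "nodes": graph.number_of_nodes(),
            "edges": graph.number_of_edges(),
            "dropped": len(dropped),
            "clusters": partition.n_clusters,
        },
    }
    return ReportBundle(
        graph=graph,
        dropped=dropped,
        partition=partition,
        term_tables=term_tables,
        gene_tables=gene_tables,
        ppi_networks=ppi_networks,
        metadata=metadata,
        notices=notices,
    )


def write_bundle(bundle: ReportBundle, outdir: str | Path) -> None:
    """Write the report bundle as TSV/GraphML/JSON files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    export_graph(bundle.graph, outdir / "graph.graphml", "graphml")
    pd.DataFrame({"set_name": bundle.dropped}).to_csv(
        outdir / "dropped.tsv", sep="\t", index=False
    )
    clusters = bundle.partition.clusters.copy()
    if not clusters.empty:
        clusters["members"] = clusters["members"].map(";".join)
    clusters.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    bundle.term_tables.to_csv(outdir / "terms.tsv", sep="\t", index=False)
    bundle.gene_tables.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    if bundle.ppi_networks:
        ppidir = outdir / "ppi"
        ppidir.mkdir(exist_ok=True)
        for cid, net in bundle.ppi_networks.items():
            export_graph(net, ppidir / f"cluster_{cid}.graphml", "graphml")
    with open(outdir / "metadata.json", "w", encoding="utf-8") as fh:
        json.dump({**bundle.metadata, "notices": bundle.notices}, fh, indent=1, sort_keys=True)


def run_from_config(config: RunConfig) -> ReportBundle:
    """Load the inputs named in ``config``, run the pipeline, write the bundle."""
    collection = read_gmt(config.gmt)
    universe = None
    if config.universe:
        with open(config.universe, encoding="utf-8") as fh:
            universe = [ln.strip() for ln in fh if ln.strip()]
    set_stats = read_set_statistics(config.set_stats) if config.set_stats else None
    gene_stats = read_gene_statistics(config.gene_stats) if config.gene_stats else None
    exclusions = _read_exclusions(config.exclusions) if config.exclusions else None
    ppi_edges = None
    if config.ppi:
        ppi_edges = read_ppi(config.ppi, dialect=config.ppi_dialect)
        if config.ortholog_map:
            omap = pd.read_csv(config.ortholog_map, sep="\t", header=None, dtype=str)
            mapping: dict[str, list[str]] = {}
            for a, b in zip(omap.iloc[:, 0], omap.iloc[:, 1]):
                mapping.setdefault(a, []).append(b)
            ppi_edges = map_orthologs(ppi_edges, mapping)
    bundle = run_pipeline(
        collection,
        set_stats,
        gene_stats,
        universe=universe,
        measure=config.measure,
        threshold=config.threshold,
        strict=config.strict,
        steps=config.steps,
        direction=config.direction,
        use_absolute=config.use_absolute,
        source=config.source,
        exclusions=exclusions,
        top_n_terms=config.top_n_terms,
        ppi_edges=ppi_edges,
        min_confidence=config.min_confidence,
        min_degree=config.min_degree,
        include_inferred=config.include_inferred,
    )
    if config.outdir:
        write_bundle(bundle, config.outdir)
    return bundle
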