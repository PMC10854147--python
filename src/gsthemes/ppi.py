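"""Protein-protein interaction context for themes.

Known physical interactions among a theme's member genes provide a line of
evidence for the underlying process that is independent of gene-set
membership.  This module ingests interaction edge lists (a PSI-MI TAB 2.5
subset as distributed by IMEx-style resources, or a simple TSV), cleans
them — same-species records only, self-edges dropped, duplicate pairs
combined keeping the maximum confidence — optionally infers edges across
organisms through a two-column ortholog map (flagging them as inferred),
and induces per-theme subnetworks with confidence and degree filtering.

Identifier namespaces are caller-managed: whatever ids the edge list uses
must match the gene ids of the gene-sets (map upstream if needed).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = ["PPIEdge", "read_ppi", "dedup_edges", "map_orthologs", "induce_subnetwork"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PPIEdge:
    """An undirected interaction between two genes; (a,b) == (b,a)."""

    gene_a: str
    gene_b: str
    confidence: float = 1.0
    inferred: bool = False

    @property
    def key(self) -> tuple[str, str]:
        """Canonical unordered pair key."""
        return (self.gene_a, self.gene_b) if self.gene_a <= self.gene_b else (self.gene_b, self.gene_a)


def dedup_edges(edges: Iterable[PPIEdge]) -> list[PPIEdge]:
    """Drop self-edges; combine duplicate pairs keeping maximum confidence.

    When a native and an inferred record tie on confidence the native
    (inferred=False) record wins the flag.  Max is associative and
    commutative, so the result is independent of input order and the
    operation is idempotent.  Output is sorted by pair key.
    """
    best: dict[tuple[str, str], PPIEdge] = {}
    for e in edges:
        if e.gene_a == e.gene_b:
            continue
        k = e.key
        cur = best.get(k)
        if cur is None or e.confidence > cur.confidence or (
            e.confidence == cur.confidence and cur.inferred and not e.inferred
        ):
            best[k] = PPIEdge(k[0], k[1], e.confidence, e.inferred)
    return [best[k] for k in sorted(best)]


# --- PSI-MI TAB 2.5 subset -------------------------------------------------
# columns used: 0,1 interactor ids ("uniprotkb:P12345"), 9,10 taxids
# ("taxid:9606(human)"), 14 confidence ("intact-miscore:0.56").

_TAXID_RE = re.compile(r"taxid:(-?\d+)")
_SCORE_RE = re.compile(r"(?:miscore|score):([0-9.eE+-]+)")


def _psimitab_id(field: str) -> str:
    first = field.split("|")[0].strip()
    return first.split(":", 1)[1] if ":" in first else first


def _psimitab_taxid(field: str) -> str | None:
    m = _TAXID_RE.search(field)
    return m.group(1) if m else None


def _psimitab_confidence(field: str) -> float:
    for part in field.split("|"):
        m = _SCORE_RE.search(part)
        if m:
            try:
                return float(m.group(1))
            except ValueError:
                continue
    return 1.0


def read_ppi(path: str | Path, dialect: str = "tsv") -> list[PPIEdge]:
    """Read an interaction edge list and clean it.

    ``dialect='tsv'``: columns gene_a, gene_b, confidence[, inferred], with
    an optional header line.  ``dialect='psimitab'``: PSI-MI TAB 2.5 subset;
    records whose two interactors belong to different species are dropped,
    and the confidence column is scanned for a miscore-style value.
    Unparsable lines are skipped with a warning.  Duplicates are combined by
    maximum confidence and self-edges removed.
    """
    if dialect not in ("tsv", "psimitab"):
        raise ValueError("dialect must be 'tsv' or 'psimitab'")
    edges: list[PPIEdge] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "tsv":
                    if lineno == 1 and fields[0].strip().lower() in ("gene_a", "genea", "source"):
                        continue  # header
                    a, b = fields[0].strip(), fields[1].strip()
                    conf = float(fields[2]) if len(fields) > 2 and fields[2].strip() else 1.0
                    inferred = (
                        fields[3].strip().lower() in ("1", "true", "yes")
                        if len(fields) > 3
                        else False
                    )
                    edges.append(PPIEdge(a, b, conf, inferred))
                else:
                    if len(fields) < 15:
                        raise ValueError("need >=15 PSI-MI TAB columns")
                    tax_a = _psimitab_taxid(fields[9])
                    tax_b = _psimitab_taxid(fields[10])
                    if tax_a is None or tax_b is None or tax_a != tax_b:
                        continue  # cross-species or unannotated record
                    a = _psimitab_id(fields[0])
                    b = _psimitab_id(fields[1])
                    conf = _psimitab_confidence(fields[14])
                    edges.append(PPIEdge(a, b, conf))
            except (IndexError, ValueError) as exc:
                skipped += 1
                warnings.warn(f"{path}: line {lineno}: skipped ({exc})")
    if skipped:
        logger.info("read_ppi: skipped %d unparsable line(s) in %s", skipped, path)
    return dedup_edges(edges)


def map_orthologs(
    edges: Sequence[PPIEdge], ortholog_table: Mapping[str, Iterable[str] | str]
) -> list[PPIEdge]:
    """Infer target-organism edges through an ortholog map and merge.

    ``ortholog_table`` maps source-organism gene ids to one or more
    target-organism ids.  Every edge whose two endpoints both map yields
    inferred edge(s) (one per ortholog combination, ``inferred=True``);
    edges with an unmappable endpoint contribute nothing to the inferred
    set.  The inferred edges are merged with the input edges by
    maximum-confidence dedup, native records winning ties.
    """
    norm: dict[str, list[str]] = {
        k: ([v] if isinstance(v, str) else list(v)) for k, v in ortholog_table.items()
    }
    inferred: list[PPIEdge] = []
    for e in edges:
        targets_a = norm.get(e.gene_a)
        targets_b = norm.get(e.gene_b)
        if not targets_a or not targets_b:
            continue
        for ta in targets_a:
            for tb in targets_b:
                if ta != tb:
                    inferred.append(PPIEdge(ta, tb, e.confidence, inferred=True))
    return dedup_edges(list(edges) + inferred)


def induce_subnetwork(
    edges: Sequence[PPIEdge],
    genes: Iterable[str],
    min_confidence: float = 0.0,
    min_degree: int = 0,
    include_inferred: bool = True,
    gene_stats: Mapping[str, float] | pd.Series | None = None,
) -> nx.Graph:
    """Induce the interaction subnetwork among a theme's member genes.

    Keeps edges with both endpoints in ``genes``, confidence >=
    ``min_confidence`` and (unless ``include_inferred``) not inferred.  Node
    degree is computed once on that filtered graph; nodes below
    ``min_degree`` are removed together with their incident edges in a
    single pass (no iteration to a fixpoint), and any node thereby left
    isolated is removed as well.  Node attributes: ``degree`` (post-filter),
    and ``statistic`` where ``gene_stats`` supplies one.
    """
    genes = set(genes)
    g = nx.Graph()
    for e in edges:
        if e.gene_a in genes and e.gene_b in genes and e.confidence >= min_confidence:
            if e.inferred and not include_inferred:
                continue
            g.add_edge(e.gene_a, e.gene_b, weight=e.confidence, inferred=e.inferred)
    if min_degree > 0:
        low = [n for n in g.nodes if g.degree[n] < min_degree]
        g.remove_nodes_from(low)
        g.remove_nodes_from([n for n in g.nodes if g.degree[n] == 0])
    for n in g.nodes:
        g.nodes[n]["degree"] = g.degree[n]
        if gene_stats is not None and n in gene_stats:
            g.nodes[n]["statistic"] = float(gene_stats[n])
    return g
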