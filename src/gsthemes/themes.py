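"""Theme detection: walktrap communities on the overlap graph, rank-product ordering.

Clusters of mutually overlapping gene-sets are read as higher-order
biological themes.  Community detection uses the Pons-Latapy walktrap
algorithm — agglomerative merging of communities by short random-walk
distance, cut at maximum modularity — with similarity values as edge
weights, so densely overlapping gene-sets end up in one theme and
disconnected components never share a cluster.

Detected themes are then prioritised by the product-of-ranks statistic:
clusters are ranked by size (1 = largest) and by median gene-set statistic
(1 = best under the chosen direction), and ordered by the product of the two
ranks, lower being better.  This surfaces themes that are simultaneously
large and strongly affected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["ThemePartition", "walktrap_communities", "order_clusters"]


@dataclass
class ThemePartition:
    """A non-overlapping clustering of the pruned overlap graph.

    ``assignment`` maps gene-set name -> cluster id (1-based).  ``clusters``
    is one row per cluster: members, size, median gene-set statistic, and —
    after :func:`order_clusters` — size rank, statistic rank, rank product
    and final order (1 = top theme).
    """

    assignment: dict[str, int] = field(default_factory=dict)
    clusters: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["cluster", "members", "size", "median_statistic"]
        )
    )

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def members_of(self, cluster_id: int) -> list[str]:
        row = self.clusters.loc[self.clusters["cluster"] == cluster_id]
        if row.empty:
            raise KeyError(cluster_id)
        return list(row.iloc[0]["members"])

    def write_tsv(self, path: str | Path) -> None:
        """Long-form export: one row per (cluster, member set)."""
        rows = []
        for _, c in self.clusters.iterrows():
            for m in c["members"]:
                rows.append({"cluster": c["cluster"], "set_name": m, **{
                    k: c[k] for k in c.index if k not in ("cluster", "members")
                }})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _to_igraph(graph: nx.Graph) -> tuple[ig.Graph, list[str]]:
    nodes = list(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in graph.edges]
    weights = [float(d.get("weight", 1.0)) for _, _, d in graph.edges(data=True)]
    g = ig.Graph(n=len(nodes), edges=edges)
    g.es["weight"] = weights
    return g, nodes


def walktrap_communities(graph: nx.Graph, steps: int = 4) -> ThemePartition:
    """Detect gene-set communities with walktrap (walk length ``steps``).

    Edge weights (similarities) act as random-walk transition weights.  The
    merge dendrogram is cut at maximum modularity.  The result is
    deterministic for a fixed graph; cluster ids are assigned in order of
    each cluster's lexicographically smallest member so relabelling of the
    input cannot change ids.

    An empty graph yields an empty partition.
    """
    if graph.number_of_nodes() == 0:
        return ThemePartition()
    g, nodes = _to_igraph(graph)
    if g.ecount() > 0:
        dendro = g.community_walktrap(weights="weight", steps=steps)
        membership = dendro.as_clustering().membership
    else:
        membership = list(range(len(nodes)))  # all singletons
    groups: dict[int, list[str]] = {}
    for name, lab in zip(nodes, membership):
        groups.setdefault(lab, []).append(name)
    # deterministic ids: sort clusters by their smallest member name
    ordered = sorted(groups.values(), key=lambda ms: min(ms))
    assignment = {}
    rows = []
    for cid, members in enumerate(ordered, start=1):
        members = sorted(members)
        for m in members:
            assignment[m] = cid
        med = _median_statistic(graph, members)
        rows.append(
            {"cluster": cid, "members": members, "size": len(members), "median_statistic": med}
        )
    return ThemePartition(assignment, pd.DataFrame(rows))


def _median_statistic(graph: nx.Graph, members: list[str]) -> float:
    vals = [graph.nodes[m].get("statistic", float("nan")) for m in members]
    vals = [v for v in vals if v is not None and not np.isnan(v)]
    return float(np.median(vals)) if vals else float("nan")


def order_clusters(
    partition: ThemePartition,
    direction: str = "larger-better",
    use_absolute: bool = False,
) -> ThemePartition:
    """Order themes by the product of size rank and median-statistic rank.

    ``direction`` is ``larger-better`` (e.g. -log10 FDR, |score|) or
    ``smaller-better`` (e.g. raw p-values); ``use_absolute`` ranks on the
    absolute median statistic, for signed two-sided statistics.  Missing
    median statistics are imputed as the worst statistic rank.  Equal rank
    products are broken by the better statistic rank, then by cluster id, so
    the final order is a total order independent of cluster labelling.
    """
    if direction not in ("larger-better", "smaller-better"):
        raise ValueError("direction must be 'larger-better' or 'smaller-better'")
    df = partition.clusters.copy()
    if df.empty:
        return ThemePartition(dict(partition.assignment), df)
    sizes = df["size"].to_numpy(dtype=float)
    df["size_rank"] = rankdata(-sizes, method="min").astype(int)
    stat = df["median_statistic"].to_numpy(dtype=float)
    if use_absolute:
        stat = np.abs(stat)
    key = -stat if direction == "larger-better" else stat
    key = np.where(np.isnan(key), np.inf, key)  # missing medians -> worst rank
    df["statistic_rank"] = rankdata(key, method="min").astype(int)
    df["rank_product"] = df["size_rank"] * df["statistic_rank"]
    order_idx = df.sort_values(
        ["rank_product", "statistic_rank", "cluster"], kind="mergesort"
    ).index
    df.loc[order_idx, "order"] = np.arange(1, len(df) + 1)
    df["order"] = df["order"].astype(int)
    df = df.sort_values("order", kind="mergesort").reset_index(drop=True)
    return ThemePartition(dict(partition.assignment), df)
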