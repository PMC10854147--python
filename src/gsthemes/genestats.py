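"""Per-cluster gene-level tables: set-membership frequency vs experimental statistic.

For one theme, every gene in the union of member gene-sets gets a row with
its *frequency* — the number of member sets containing it — and, once
joined, the caller's per-gene statistic (logFC, factor loading, ...).  Genes
with both high frequency and a strong statistic are the ones that explain
the theme in the context of the experiment; high-frequency genes alone are
representative of the theme regardless of the experiment.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geneset import GeneSet

__all__ = ["gene_cluster_frequency", "attach_statistics", "rank_genes"]


def gene_cluster_frequency(cluster_sets: Sequence[GeneSet]) -> pd.DataFrame:
    """Count, for each gene, the member gene-sets that contain it.

    Returns one row per distinct gene (columns ``gene``, ``frequency``),
    sorted by descending frequency then gene id.  Sets should be restricted
    to the measured-gene universe first so frequencies reflect measured
    genes only.
    """
    if not cluster_sets:
        raise ValueError("cluster must be non-empty")
    counts: dict[str, int] = {}
    for gs in cluster_sets:
        for g in gs.members:
            counts[g] = counts.get(g, 0) + 1
    df = pd.DataFrame(sorted(counts.items()), columns=["gene", "frequency"])
    return df.sort_values(
        ["frequency", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def attach_statistics(
    table: pd.DataFrame, gene_stats: pd.Series | Mapping[str, float]
) -> pd.DataFrame:
    """Join per-gene statistics onto a frequency table by gene id.

    Genes without a statistic are retained with ``statistic`` NaN and
    ``missing_statistic`` True.  The join is a plain key lookup, so it is
    independent of row order on either side.
    """
    stats = pd.Series(gene_stats, dtype=float) if not isinstance(gene_stats, pd.Series) else gene_stats
    out = table.copy()
    out["statistic"] = out["gene"].map(stats)
    out["missing_statistic"] = out["statistic"].isna()
    return out


def rank_genes(table: pd.DataFrame) -> pd.DataFrame:
    """Order a joined table by frequency (desc), then |statistic| (desc).

    A convenience ranking that surfaces the "high frequency and high
    statistic" genes first; missing statistics sort last within a frequency.
    """
    out = table.copy()
    out["_abs"] = out["statistic"].abs().fillna(-np.inf)
    out = out.sort_values(
        ["frequency", "_abs", "gene"], ascending=[False, False, True], kind="mergesort"
    ).drop(columns="_abs")
    return out.reset_index(drop=True)
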