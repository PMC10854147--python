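"""Rank-based gene-set scoring of factor loadings.

Factor analyses of expression data (PCA most commonly) attach a loading to
every gene, reflecting its relevance to the factor.  To discover what a
factor means biologically, gene-sets are scored against the loading vector
with a rank-based single-sample score: genes are ranked by loading
(ascending, mid-rank ties), and a set's score is its members' mean rank,
normalised and centred so that

    score = (mean_rank - (m+1)/2) / (n - m) - 0.5

lies in [-0.5, +0.5], hitting +0.5 exactly when the m members occupy the
top m ranks and -0.5 at the bottom m.  Because only ranks enter, the score
is invariant under any strictly monotone transform of the loadings, and
negating the loadings negates every score.

Sets with |score| above a threshold (0.2 by default) are carried into theme
detection with the score as their gene-set statistic, enabling unsupervised
phenotype discovery one factor at a time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .geneset import GeneSet

__all__ = ["RankedLoadings", "SetScore", "rank_by_loading", "set_score", "score_collection", "select_scored_sets"]

logger = logging.getLogger(__name__)


@dataclass
class RankedLoadings:
    """Genes ranked by loading: rank 1 = smallest loading, ties mid-ranked."""

    ranks: pd.Series  # index: gene id, values: float ranks in 1..n

    @property
    def n(self) -> int:
        return len(self.ranks)

    def __contains__(self, gene: str) -> bool:
        return gene in self.ranks.index


@dataclass(frozen=True)
class SetScore:
    """A gene-set's centred mean-rank score against one loading vector."""

    name: str
    size_scored: int  # m = |members ∩ ranked genes|
    mean_rank: float
    score: float  # in [-0.5, 0.5]


def rank_by_loading(loadings: pd.Series | Mapping[str, float]) -> RankedLoadings:
    """Rank genes ascending by loading value (average ranks for ties).

    Genes with missing (NaN) loadings are excluded and logged.
    """
    s = pd.Series(loadings, dtype=float)
    if s.isna().any():
        dropped = s.index[s.isna()].tolist()
        logger.info("rank_by_loading: excluding %d gene(s) with missing loadings", len(dropped))
        s = s.dropna()
    if len(s) < 2:
        raise ValueError("need at least 2 genes with loadings")
    return RankedLoadings(pd.Series(rankdata(s.to_numpy()), index=s.index))


def set_score(ranked: RankedLoadings, gene_set: GeneSet) -> SetScore:
    """Score one gene-set against ranked loadings.

    Undefined (raises) when no member is ranked (m=0) or every ranked gene
    is a member (m=n) — the score has no contrast in either case.
    """
    member_ranks = ranked.ranks.loc[ranked.ranks.index.intersection(gene_set.members)]
    m = len(member_ranks)
    n = ranked.n
    if m == 0:
        raise ValueError(f"gene-set {gene_set.name!r}: no member has a loading (m=0)")
    if m == n:
        raise ValueError(f"gene-set {gene_set.name!r}: covers all ranked genes (m=n, degenerate)")
    mean_rank = float(member_ranks.mean())
    score = (mean_rank - (m + 1) / 2) / (n - m) - 0.5
    return SetScore(gene_set.name, m, mean_rank, score)


def score_collection(
    ranked: RankedLoadings, sets: Iterable[GeneSet]
) -> tuple[list[SetScore], list[str]]:
    """Score every scorable set; returns (scores, names of unscorable sets)."""
    scores: list[SetScore] = []
    flagged: list[str] = []
    for gs in sets:
        try:
            scores.append(set_score(ranked, gs))
        except ValueError:
            flagged.append(gs.name)
    if flagged:
        logger.info("score_collection: %d set(s) unscorable (m=0 or m=n)", len(flagged))
    return scores, flagged


def select_scored_sets(scores: Sequence[SetScore], threshold: float = 0.2) -> pd.DataFrame:
    """Select sets with |score| strictly above ``threshold``.

    Returns a per-set statistics table (index set_name; columns statistic,
    direction, size_scored) ready to attach to overlap-graph nodes: the
    score is the statistic, its sign the direction.
    """
    rows = [
        {
            "set_name": s.name,
            "statistic": s.score,
            "direction": "up" if s.score >= 0 else "down",
            "size_scored": s.size_scored,
        }
        for s in scores
        if abs(s.score) > threshold
    ]
    return pd.DataFrame(
        rows, columns=["set_name", "statistic", "direction", "size_scored"]
    ).set_index("set_name")
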