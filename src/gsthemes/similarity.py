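"""Pairwise gene-set similarity: adjusted Rand index, Jaccard, overlap coefficient.

Two gene-sets X and Y over a universe of n measured genes induce two binary
partitions of the universe (in-set vs out-of-set).  Their agreement is
summarised by a 2x2 contingency table::

            Y=0    Y=1   sums
    X=0     n00    n01    a0
    X=1     n10    n11    a1
    sums    b0     b1     n

from which three similarity measures are computed:

* adjusted Rand index (ARI) — chance-corrected partition agreement; can be
  negative, equals 1 for identical partitions,
* Jaccard index, JI = n11 / (n01 + n10 + n11),
* overlap coefficient, OC = n11 / min(a1, b1) — equals 1 whenever one set
  contains the other, which makes it the measure of choice inside a single
  hierarchically structured database (GO, Reactome) and ARI/JI preferable
  across databases.

Binomial coefficients in the ARI are evaluated in exact integer arithmetic;
only the final ratio is floating point, so there is no overflow or precision
drift for large universes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .geneset import GeneSet, GeneSetCollection

__all__ = [
    "ContingencyTable",
    "SimilarityMatrix",
    "contingency",
    "ari",
    "jaccard",
    "overlap_coefficient",
    "pairwise_similarity",
    "MEASURES",
]

MEASURES = ("ari", "jaccard", "overlap")


@dataclass(frozen=True)
class ContingencyTable:
    """Joint membership counts of two gene-sets over the universe."""

    n11: int  # |X ∩ Y|
    n10: int  # |X \ Y|
    n01: int  # |Y \ X|
    n00: int  # neither

    @property
    def n(self) -> int:
        return self.n00 + self.n01 + self.n10 + self.n11

    @property
    def a1(self) -> int:
        """|X| (restricted to the universe)."""
        return self.n10 + self.n11

    @property
    def b1(self) -> int:
        """|Y| (restricted to the universe)."""
        return self.n01 + self.n11

    @property
    def a0(self) -> int:
        return self.n00 + self.n01

    @property
    def b0(self) -> int:
        return self.n00 + self.n10


def contingency(x: GeneSet, y: GeneSet, universe: Iterable[str]) -> ContingencyTable:
    """Build the 2x2 contingency table for two sets over ``universe``.

    Both sets must already be restricted to the universe.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    xm, ym = x.members, y.members
    if xm - universe or ym - universe:
        raise ValueError("gene-sets must be restricted to the universe first")
    n11 = len(xm & ym)
    n10 = len(xm) - n11
    n01 = len(ym) - n11
    n00 = len(universe) - n11 - n10 - n01
    return ContingencyTable(n11=n11, n10=n10, n01=n01, n00=n00)


def ari(ct: ContingencyTable) -> float:
    """Adjusted Rand index of the two binary partitions.

    Degenerate denominators (both partitions trivial: both sets empty, or
    both equal to the full universe) follow the convention of standard
    adjusted-Rand implementations: 1 if the partitions are identical, else 0.
    """
    if ct.n < 2:
        raise ValueError("ARI needs a universe of at least 2 genes")
    sum_ij = comb(ct.n00, 2) + comb(ct.n01, 2) + comb(ct.n10, 2) + comb(ct.n11, 2)
    sum_a = comb(ct.a0, 2) + comb(ct.a1, 2)
    sum_b = comb(ct.b0, 2) + comb(ct.b1, 2)
    cn2 = comb(ct.n, 2)
    # exact integer cross-multiplied test for a zero denominator:
    # den = (sum_a + sum_b)/2 - sum_a*sum_b/cn2 == 0  <=>
    #       cn2*(sum_a + sum_b) == 2*sum_a*sum_b
    if cn2 * (sum_a + sum_b) == 2 * sum_a * sum_b:
        identical = ct.n10 == 0 and ct.n01 == 0
        return 1.0 if identical else 0.0
    expected = sum_a * sum_b / cn2
    return (sum_ij - expected) / (0.5 * (sum_a + sum_b) - expected)


def jaccard(ct: ContingencyTable) -> float:
    """Jaccard index n11/(n01+n10+n11); 0 by convention when both sets are empty."""
    denom = ct.n01 + ct.n10 + ct.n11
    return ct.n11 / denom if denom else 0.0


def overlap_coefficient(ct: ContingencyTable) -> float:
    """Overlap coefficient n11/min(|X|,|Y|); 0 by convention if either set is empty."""
    m = min(ct.a1, ct.b1)
    return ct.n11 / m if m else 0.0


_MEASURE_FUNCS = {"ari": ari, "jaccard": jaccard, "overlap": overlap_coefficient}


def pair_similarity(x: GeneSet, y: GeneSet, universe: Iterable[str], measure: str) -> float:
    """Similarity of a single pair under ``measure`` (one of %s).""" % (MEASURES,)
    if measure not in _MEASURE_FUNCS:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    return _MEASURE_FUNCS[measure](contingency(x, y, universe))


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise gene-set similarity under one measure.

    ``values`` is a symmetric square DataFrame keyed by gene-set name, with
    diagonal 1 for the (non-empty) sets it covers.
    """

    measure: str
    values: pd.DataFrame

    @property
    def names(self) -> list[str]:
        return list(self.values.index)

    def to_long(self) -> pd.DataFrame:
        """Long-form table (setA, setB, measure, value), upper triangle only."""
        rows = []
        names = self.names
        vals = self.values.to_numpy()
        for i, j in combinations(range(len(names)), 2):
            rows.append((names[i], names[j], self.measure, vals[i, j]))
        return pd.DataFrame(rows, columns=["setA", "setB", "measure", "value"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)


def pairwise_similarity(collection: GeneSetCollection, measure: str = "ari") -> SimilarityMatrix:
    """All-pairs similarity over the non-empty sets of a restricted collection.

    Intersection sizes are obtained in one integer matrix product over the
    binary membership matrix; each entry then equals the single-pair measure
    applied to that pair's contingency table.
    """
    if measure not in _MEASURE_FUNCS:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    sets = collection.nonempty_sets
    if len(sets) < 2:
        raise ValueError("need at least 2 non-empty sets for pairwise similarity")
    n = len(collection.universe)
    if n == 0:
        raise ValueError("universe must be non-empty")
    member = np.stack([collection.membership_vector(s) for s in sets]).astype(np.int64)
    sizes = member.sum(axis=1)
    inter = member @ member.T  # |X ∩ Y| for every pair
    k = len(sets)
    out = np.eye(k)
    func = _MEASURE_FUNCS[measure]
    for i, j in combinations(range(k), 2):
        n11 = int(inter[i, j])
        ct = ContingencyTable(
            n11=n11,
            n10=int(sizes[i]) - n11,
            n01=int(sizes[j]) - n11,
            n00=n - int(sizes[i]) - int(sizes[j]) + n11,
        )
        out[i, j] = out[j, i] = func(ct)
    names = [s.name for s in sets]
    return SimilarityMatrix(measure, pd.DataFrame(out, index=names, columns=names))
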