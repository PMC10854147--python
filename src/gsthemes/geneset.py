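"""Gene-set data model and GMT input/output.

A gene-set is a named collection of gene identifiers representing a
biological process or signature (a GO term, a Reactome pathway, a curated
expression signature, ...).  Collections of such sets are exchanged in the
GMT format: one tab-separated line per set holding the set name, a free-text
description, and the member genes.

All downstream similarity computations are performed over a *universe* — the
set of genes actually measured in the experiment — so collections can be
restricted to a universe, and sets can be encoded as binary membership
vectors over it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "GmtParseError",
    "read_gmt",
    "write_gmt",
    "read_set_statistics",
    "read_gene_statistics",
]


class GmtParseError(ValueError):
    """Raised when a GMT file cannot be parsed."""


@dataclass(frozen=True)
class GeneSet:
    """A named gene-set.

    Parameters
    ----------
    name:
        Non-empty identifier, unique within a collection.
    description:
        Free-text description; may be empty.
    members:
        Gene identifiers; duplicates collapse under set semantics.  Gene
        identifiers are opaque, case-sensitive strings — no symbol/ID
        conversion is attempted here.
    """

    name: str
    description: str = ""
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene-set name must be non-empty")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def restrict(self, universe: frozenset[str] | set[str]) -> "GeneSet":
        """Return a copy with members intersected with ``universe``."""
        return GeneSet(self.name, self.description, self.members & frozenset(universe))


class GeneSetCollection:
    """An ordered collection of uniquely named gene-sets over a gene universe.

    The universe defaults to the union of all members when not supplied,
    mirroring the common case where no separate list of measured genes is
    available.  After :meth:`restrict_to_universe` every member of every set
    lies in the universe; sets rendered empty by restriction are retained
    (and reported by :attr:`empty_set_names`) but are skipped by similarity
    computations downstream.
    """

    def __init__(self, sets: Iterable[GeneSet], universe: Iterable[str] | None = None):
        self.sets: list[GeneSet] = list(sets)
        names = [s.name for s in self.sets]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate gene-set names: {sorted(dupes)}")
        if universe is None:
            universe = set().union(*(s.members for s in self.sets)) if self.sets else set()
        self.universe: frozenset[str] = frozenset(universe)
        # fixed, documented gene ordering: lexicographic over the universe
        self._gene_order: tuple[str, ...] = tuple(sorted(self.universe))
        self._index: dict[str, int] = {g: i for i, g in enumerate(self._gene_order)}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    @property
    def gene_order(self) -> tuple[str, ...]:
        """The fixed gene ordering used by :meth:`membership_vector`."""
        return self._gene_order

    @property
    def empty_set_names(self) -> list[str]:
        """Names of sets with no members inside the universe."""
        return [s.name for s in self.sets if not (s.members & self.universe)]

    @property
    def nonempty_sets(self) -> list[GeneSet]:
        return [s for s in self.sets if s.members & self.universe]

    def restrict_to_universe(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe`` and adopt it as the universe.

        Sets rendered empty are retained and flagged via
        :attr:`empty_set_names`; silently dropping them would hide data
        issues.
        """
        universe = frozenset(universe)
        if not universe:
            raise ValueError("universe must be non-empty")
        return GeneSetCollection([s.restrict(universe) for s in self.sets], universe)

    def membership_vector(self, name_or_set: str | GeneSet) -> np.ndarray:
        """Binary indicator of set membership over the universe gene ordering.

        The gene-set must already be restricted to the universe; a member
        outside it is an error (restriction must happen first).
        """
        gs = self[name_or_set] if isinstance(name_or_set, str) else name_or_set
        outside = gs.members - self.universe
        if outside:
            raise ValueError(
                f"gene-set {gs.name!r} has members outside the universe "
                f"(restrict first): {sorted(outside)[:5]}"
            )
        vec = np.zeros(len(self._gene_order), dtype=np.int8)
        for g in gs.members:
            vec[self._index[g]] = 1
        return vec


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (tab-separated: name, description, member genes...).

    Duplicate member tokens on a line collapse under set semantics.  The
    universe defaults to the union of all members unless supplied.

    Raises
    ------
    GmtParseError
        If a non-empty line has fewer than 3 tab-separated fields, or two
        lines share a set name.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description, *genes = fields
            members = frozenset(g for g in genes if g)
            sets.append(GeneSet(name, description, members))
    names = [s.name for s in sets]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise GmtParseError(f"{path}: duplicate gene-set names: {dupes}")
    return GeneSetCollection(sets, universe)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT; member order is canonicalised (sorted)."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def read_set_statistics(path: str | Path) -> pd.DataFrame:
    """Read a per-gene-set statistics table.

    TSV with columns ``set_name``, ``statistic`` and optionally
    ``direction``; indexed by set name.  The statistic is whatever the caller
    considers the quantity of interest (a signed enrichment score, a
    -log10 FDR, a factor score, ...) — no transformation is applied here.
    """
    df = pd.read_csv(path, sep="\t", dtype={"set_name": str})
    if "set_name" not in df.columns or "statistic" not in df.columns:
        raise ValueError("set statistics table needs columns: set_name, statistic")
    return df.set_index("set_name")


def read_gene_statistics(path: str | Path) -> pd.Series:
    """Read a per-gene statistics table (TSV columns ``gene``, ``statistic``)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    if "gene" not in df.columns or "statistic" not in df.columns:
        raise ValueError("gene statistics table needs columns: gene, statistic")
    return df.set_index("gene")["statistic"]
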