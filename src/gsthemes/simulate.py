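"""Synthetic gene-set collections with planted theme structure.

The generator emulates the input to a theme analysis: a collection of
gene-sets drawn from K latent *themes*.  Each theme owns a pool of P genes
(disjoint pools by default; a pool-overlap fraction produces correlated
themes); every set of a theme samples a fraction f of the pool plus q
uniform background genes, so sets of one theme overlap strongly while sets
of different themes barely overlap.  Set names concatenate the theme's
keyword with random filler tokens and a serial number using "_" separators,
exercising the tokenizer exactly as database-style names (GO_..., KEGG_...)
do.  Per-gene statistics are Normal(theme mean, theme sd) for pool genes
and Normal(0, background sd) otherwise; a set's statistic is the mean over
its members.  Everything is drawn from one seeded generator, so a spec plus
seed reproduces the collection bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd

from .geneset import GeneSet, GeneSetCollection, write_gmt

__all__ = ["SyntheticSpec", "SyntheticTruth", "simulate_collection", "write_inputs", "DEFAULT_KEYWORDS"]

DEFAULT_KEYWORDS = (
    "collagen",
    "ribosome",
    "cytokine",
    "autophagy",
    "chromatin",
    "spindle",
    "telomere",
    "proteasome",
    "interferon",
    "glycolysis",
)


def _filler_words() -> tuple[str, ...]:
    text = resources.files("gsthemes").joinpath("data/fillers.txt").read_text("utf-8")
    return tuple(
        w for w in (ln.split("#", 1)[0].strip() for ln in text.splitlines()) if w
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-theme generator.

    Defaults describe a mid-sized enrichment result: 100 gene-sets from 5
    themes over a 5000-gene universe, with theme pools of 150 genes, 40%
    pool sampling and 10 background genes per set — enough noise that sets
    of one theme overlap imperfectly, while between-theme overlap stays
    near zero.
    """

    n_genes: int = 5000
    n_themes: int = 5
    sets_per_theme: int = 20
    pool_size: int = 150
    sample_fraction: float = 0.4
    noise_genes: int = 10
    pool_overlap: float = 0.0  # fraction of each pool shared with the next theme
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS[:5]
    theme_stat_means: tuple[float, ...] | None = None  # default: ±linspace(3,1,K)
    theme_stat_sd: float = 0.5
    background_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_themes * self.pool_size > self.n_genes:
            raise ValueError("theme pools exceed the universe (P*K > n)")
        if not (0 < self.sample_fraction <= 1):
            raise ValueError("sample_fraction must be in (0, 1]")
        if len(self.keywords) < self.n_themes:
            raise ValueError("need one keyword per theme")

    @property
    def stat_means(self) -> tuple[float, ...]:
        if self.theme_stat_means is not None:
            if len(self.theme_stat_means) < self.n_themes:
                raise ValueError("need one statistic mean per theme")
            return tuple(self.theme_stat_means[: self.n_themes])
        mags = np.linspace(3.0, 1.0, self.n_themes)
        signs = np.where(np.arange(self.n_themes) % 2 == 0, 1.0, -1.0)
        return tuple(float(v) for v in mags * signs)


@dataclass
class SyntheticTruth:
    """Planted ground truth: set -> theme, gene -> theme, theme -> keyword."""

    set_theme: dict[str, int]
    gene_theme: dict[str, int]
    theme_keyword: dict[int, str]


def simulate_collection(
    spec: SyntheticSpec,
) -> tuple[GeneSetCollection, pd.DataFrame, pd.Series, SyntheticTruth]:
    """Generate (collection, per-set statistics, per-gene statistics, truth).

    The per-set statistics table is indexed by set name with columns
    ``statistic`` (mean member statistic) and ``direction``; the per-gene
    statistics are a Series indexed by gene id.
    """
    rng = np.random.default_rng(spec.seed)
    fillers = _filler_words()
    genes = np.array([f"G{i:05d}" for i in range(spec.n_genes)])
    perm = rng.permutation(spec.n_genes)

    # theme pools: consecutive blocks of the permuted universe, optionally
    # shifted so adjacent themes share a fraction of their pools
    shared = int(round(spec.pool_overlap * spec.pool_size))
    stride = spec.pool_size - shared if spec.n_themes > 1 else spec.pool_size
    pools = []
    for k in range(spec.n_themes):
        start = k * stride
        pools.append(perm[start : start + spec.pool_size])
    gene_theme: dict[str, int] = {}
    for k, pool in enumerate(pools, start=1):
        for gi in pool:
            gene_theme.setdefault(str(genes[gi]), k)

    means = spec.stat_means
    gene_stat = rng.normal(0.0, spec.background_sd, size=spec.n_genes)
    for k, pool in enumerate(pools):
        gene_stat[pool] = rng.normal(means[k], spec.theme_stat_sd, size=len(pool))
    gene_stats = pd.Series(gene_stat, index=genes, name="statistic")

    n_core = ceil(spec.sample_fraction * spec.pool_size)
    sets: list[GeneSet] = []
    set_theme: dict[str, int] = {}
    stat_rows = []
    for k, pool in enumerate(pools, start=1):
        keyword = spec.keywords[k - 1]
        for j in range(spec.sets_per_theme):
            core = rng.choice(pool, size=n_core, replace=False)
            noise = rng.choice(spec.n_genes, size=spec.noise_genes, replace=False)
            members = frozenset(str(genes[i]) for i in np.concatenate([core, noise]))
            toks = rng.choice(len(fillers), size=2, replace=False)
            name = "_".join(
                [
                    keyword.upper(),
                    fillers[toks[0]].upper(),
                    fillers[toks[1]].upper(),
                    str(j + 1),
                ]
            )
            desc = f"{keyword} related synthetic set {j + 1} of theme {k}"
            sets.append(GeneSet(name, desc, members))
            set_theme[name] = k
            stat = float(np.mean([gene_stat[i] for i in np.concatenate([core, noise])]))
            stat_rows.append(
                {
                    "set_name": name,
                    "statistic": stat,
                    "direction": "up" if stat >= 0 else "down",
                }
            )
    collection = GeneSetCollection(sets, universe=genes)
    set_stats = pd.DataFrame(stat_rows).set_index("set_name")
    truth = SyntheticTruth(
        set_theme=set_theme,
        gene_theme=gene_theme,
        theme_keyword={k: spec.keywords[k - 1] for k in range(1, spec.n_themes + 1)},
    )
    return collection, set_stats, gene_stats, truth


def write_inputs(
    spec: SyntheticSpec, outdir: str | Path
) -> dict[str, Path]:
    """Generate and write the standard pipeline inputs.

    Writes ``sets.gmt``, ``universe.txt`` (the measured genes, one per
    line), ``set_stats.tsv``, ``gene_stats.tsv`` and ``truth.tsv`` under
    ``outdir``; returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    collection, set_stats, gene_stats, truth = simulate_collection(spec)
    paths = {
        "gmt": outdir / "sets.gmt",
        "universe": outdir / "universe.txt",
        "set_stats": outdir / "set_stats.tsv",
        "gene_stats": outdir / "gene_stats.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_gmt(collection, paths["gmt"])
    paths["universe"].write_text("\n".join(sorted(collection.universe)) + "\n")
    set_stats.reset_index().to_csv(paths["set_stats"], sep="\t", index=False)
    gene_stats.rename_axis("gene").reset_index().to_csv(
        paths["gene_stats"], sep="\t", index=False
    )
    pd.DataFrame(
        [(s, t, truth.theme_keyword[t]) for s, t in truth.set_theme.items()],
        columns=["set_name", "theme", "keyword"],
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths
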