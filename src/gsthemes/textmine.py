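"""Theme annotation by TF-IDF text mining of gene-set names/descriptions.

Each theme (gene-set cluster) is characterised by the words that are
frequent in its member gene-sets' names (or short descriptions) yet rare
across the whole reference collection.  The concatenated text of a cluster's
members forms one *document*; every gene-set in the reference collection is
one *document* of the corpus used for inverse document frequencies, which
down-weights words over-represented in the database (removing
database-specific bias).

Pipeline: split on the naming separators ``_ / @ ( ) |`` and whitespace,
strip punctuation, lowercase, drop purely numeric tokens, drop English stop
words and excluded words (database prefixes such as "kegg" or "hallmark" by
default), lemmatise, then score terms by tf x idf with idf = log(N/df).
Up to 25 top-scoring terms represent each cluster.

Stop words come from scikit-learn's built-in English list; lemmatisation is
a compact rule-based English inflection stripper (regular plurals plus a
small exception dictionary), adequate for the controlled vocabulary of
curated gene-set names.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from .geneset import GeneSet, GeneSetCollection

__all__ = [
    "tokenize",
    "lemmatize",
    "default_exclusions",
    "CorpusIDF",
    "build_corpus_idf",
    "cluster_term_scores",
]

_SPLIT_RE = re.compile(r"[_/@()|\s]+")
_PUNCT_RE = re.compile(r"[^\w]+")
_NUM_RE = re.compile(r"^\d+$")

# irregulars and domain words the suffix rules would mangle
_LEMMA_EXCEPTIONS = {
    "analyses": "analysis",
    "axes": "axis",
    "bacteria": "bacterium",
    "children": "child",
    "criteria": "criterion",
    "feet": "foot",
    "fungi": "fungus",
    "matrices": "matrix",
    "media": "medium",
    "men": "man",
    "mice": "mouse",
    "mitochondria": "mitochondrion",
    "nuclei": "nucleus",
    "people": "person",
    "phenomena": "phenomenon",
    "stimuli": "stimulus",
    "teeth": "tooth",
    "vertebrae": "vertebra",
    "viruses": "virus",
    "women": "woman",
    # words ending in s that are not plurals
    "apoptosis": "apoptosis",
    "biogenesis": "biogenesis",
    "diabetes": "diabetes",
    "homeostasis": "homeostasis",
    "meiosis": "meiosis",
    "mitosis": "mitosis",
    "series": "series",
    "species": "species",
    "synthesis": "synthesis",
}


def lemmatize(word: str) -> str:
    """Map an English word to a base form (regular plural stripping).

    Handles ``-ies`` -> ``-y``, ``-xes/-ches/-shes/-sses/-zes`` -> stem, and
    trailing ``-s`` (but not ``-ss``, ``-us``, ``-is``), with an exception
    dictionary for common irregulars.  Unknown or already-singular words map
    to themselves.
    """
    if word in _LEMMA_EXCEPTIONS:
        return _LEMMA_EXCEPTIONS[word]
    if len(word) > 3 and word.endswith("ies"):
        return word[:-3] + "y"
    for suffix in ("xes", "ches", "shes", "sses"):
        if len(word) > len(suffix) + 1 and word.endswith(suffix):
            return word[: -2]
    if len(word) > 3 and word.endswith("s") and not word.endswith(("ss", "us", "is")):
        return word[:-1]
    return word


def default_exclusions() -> frozenset[str]:
    """The packaged default exclusion list (database prefixes/suffixes)."""
    text = resources.files("gsthemes").joinpath("data/exclusions.txt").read_text("utf-8")
    words = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip().lower()
        if line:
            words.add(line)
    return frozenset(words)


def tokenize(
    text: str,
    exclusions: Iterable[str] | None = None,
    stop_words: Iterable[str] | None = None,
) -> list[str]:
    """Tokenise gene-set text into clean, lowercase, lemmatised words.

    Splits on ``_ / @ ( ) |`` and whitespace; strips punctuation; lowercases;
    removes purely numeric tokens, English stop words, and excluded words
    (defaults to the packaged database-prefix list).  Exclusions are
    re-applied after lemmatisation so an excluded word cannot reappear as a
    lemma.
    """
    excl = frozenset(w.lower() for w in exclusions) if exclusions is not None else default_exclusions()
    stops = frozenset(stop_words) if stop_words is not None else ENGLISH_STOP_WORDS
    tokens: list[str] = []
    for raw in _SPLIT_RE.split(text):
        tok = _PUNCT_RE.sub("", raw).lower()
        if not tok or _NUM_RE.match(tok):
            continue
        if tok in stops or tok in excl:
            continue
        tok = lemmatize(tok)
        if tok and tok not in stops and tok not in excl:
            tokens.append(tok)
    return tokens


@dataclass
class CorpusIDF:
    """Inverse document frequencies over a reference gene-set collection.

    ``df`` maps term -> number of gene-sets whose token set contains it;
    ``idf(t) = log(N/df(t))`` in ``log_base`` (natural log by default, so
    idf = 0 exactly when a term occurs in every gene-set).
    """

    n_documents: int
    df: dict[str, int]
    log_base: float | None = None  # None = natural log
    source: str = "name"

    def idf(self, term: str) -> float:
        """idf of ``term``; terms unseen in the corpus get df=1 (maximal idf)."""
        d = self.df.get(term, 1)
        val = math.log(self.n_documents / d)
        if self.log_base is not None:
            val /= math.log(self.log_base)
        return val

    def __contains__(self, term: str) -> bool:
        return term in self.df


def _document_text(gs: GeneSet, source: str) -> str:
    if source == "name":
        return gs.name
    if source == "description":
        return gs.description
    raise ValueError("source must be 'name' or 'description'")


def build_corpus_idf(
    corpus: GeneSetCollection | Sequence[GeneSet],
    source: str = "name",
    exclusions: Iterable[str] | None = None,
    log_base: float | None = None,
) -> CorpusIDF:
    """Document frequencies and IDFs over a reference collection.

    Ideally the corpus is the entire database the analysed gene-sets came
    from, so database-wide common words are down-weighted; any collection
    works.
    """
    sets = list(corpus)
    if not sets:
        raise ValueError("corpus must be non-empty")
    df: dict[str, int] = {}
    for gs in sets:
        for term in set(tokenize(_document_text(gs, source), exclusions)):
            df[term] = df.get(term, 0) + 1
    return CorpusIDF(n_documents=len(sets), df=df, log_base=log_base, source=source)


def cluster_term_scores(
    cluster_sets: Sequence[GeneSet],
    corpus_idf: CorpusIDF,
    source: str = "name",
    top_n: int = 25,
    exclusions: Iterable[str] | None = None,
    relative_tf: bool = False,
) -> pd.DataFrame:
    """Rank the terms characterising one theme by TF-IDF.

    tf is the raw term count in the cluster's concatenated document
    (``relative_tf=True`` divides by document length); tfidf = tf x idf.
    Returns up to ``top_n`` rows sorted by descending tfidf with
    alphabetical tie-break, columns: term, tf, idf, tfidf, rank, novel
    (True for terms absent from the corpus, scored at df=1).
    """
    if not cluster_sets:
        raise ValueError("cluster must be non-empty")
    tf: dict[str, float] = {}
    total = 0
    for gs in cluster_sets:
        for term in tokenize(_document_text(gs, source), exclusions):
            tf[term] = tf.get(term, 0) + 1
            total += 1
    rows = []
    for term, count in tf.items():
        freq = count / total if (relative_tf and total) else float(count)
        rows.append(
            {
                "term": term,
                "tf": freq,
                "idf": corpus_idf.idf(term),
                "novel": term not in corpus_idf,
            }
        )
    out = pd.DataFrame(rows, columns=["term", "tf", "idf", "novel"])
    if out.empty:
        out["tfidf"] = []
        out["rank"] = []
        return out[["term", "tf", "idf", "tfidf", "rank", "novel"]]
    out["tfidf"] = out["tf"] * out["idf"]
    out = out.sort_values(["tfidf", "term"], ascending=[False, True], kind="mergesort")
    out = out.head(top_n).reset_index(drop=True)
    out["rank"] = out.index + 1
    return out[["term", "tf", "idf", "tfidf", "rank", "novel"]]
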