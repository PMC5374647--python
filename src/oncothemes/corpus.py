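"""Semantic representation of genes from free-text annotations.

Each gene's functional description (in real data: pooled GeneRIFs plus the
NCBI gene summary) is turned into a bag of stemmed tokens; tf-idf over the
corpus of all gene documents selects the informative words; each gene is
then represented by its top-scoring word vector, with the gene's own symbol
and aliases boosted to the top of the vector so that identity information is
never lost.

The tf-idf weight of word *w* in gene document *d* over corpus *D* is

    tfidf(w, d, D) = tf(w, d) * log10(|D| / df(w, D))

where tf is the in-document count and df the number of gene documents
containing *w*. A global vocabulary keeps the ``vocab_size`` words with the
highest cumulative tf-idf (summed over gene documents).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from ._stem import porter_stem

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[a-z0-9]+")

DEFAULT_VOCAB_SIZE = 20_000
DEFAULT_VECTOR_SIZE = 200


def load_stopwords() -> frozenset[str]:
    """English stop-word list packaged with the library (deterministic)."""
    text = (resources.files("oncothemes") / "data" / "stopwords.txt").read_text()
    return frozenset(w for w in text.split() if w)


def preprocess(text: str, stopwords: frozenset[str] | set[str] | None = None) -> list[str]:
    """Lower-case, tokenize, drop stop words, Porter-stem.

    Tokenization splits on any non-alphanumeric character. Tokens are kept
    if they have at least two characters or contain a digit (so "p53"
    survives). Stop words are removed before stemming.
    """
    if stopwords is None:
        stopwords = load_stopwords()
    out = []
    for tok in _TOKEN_RE.findall(text.lower()):
        if len(tok) < 2 and not any(c.isdigit() for c in tok):
            continue
        if tok in stopwords:
            continue
        out.append(porter_stem(tok))
    return out


def tfidf(tf: int, df: int, corpus_size: int) -> float:
    """tf * log10(corpus_size / df); df must be >= 1."""
    if df <= 0:
        raise ValueError("df must be positive: word not in corpus")
    if tf < 1 or df > corpus_size:
        raise ValueError(f"invalid tf-idf arguments tf={tf} df={df} |D|={corpus_size}")
    return tf * math.log10(corpus_size / df)


@dataclass
class GeneText:
    """Raw per-gene annotation text with its symbol/alias list."""

    gene_id: str
    aliases: list[str]
    text: str

    def __post_init__(self) -> None:
        if not self.aliases:
            raise ValueError(f"gene {self.gene_id}: aliases must be non-empty")


@dataclass
class Vocabulary:
    """Global token vocabulary ranked by cumulative tf-idf."""

    tokens: list[str]
    cumulative_tfidf: dict[str, float]
    df: dict[str, int]
    corpus_size: int
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {t: i for i, t in enumerate(self.tokens)}

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __len__(self) -> int:
        return len(self.tokens)

    def index(self, token: str) -> int:
        return self._index[token]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "token": self.tokens,
                "df": [self.df[t] for t in self.tokens],
                "cumulative_tfidf": [self.cumulative_tfidf[t] for t in self.tokens],
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, corpus_size: int) -> "Vocabulary":
        tab = pd.read_csv(path, sep="\t", dtype={"token": str})
        return cls(
            tokens=list(tab["token"]),
            cumulative_tfidf=dict(zip(tab["token"], tab["cumulative_tfidf"])),
            df=dict(zip(tab["token"], tab["df"].astype(int))),
            corpus_size=corpus_size,
        )


@dataclass
class GeneDocument:
    """A gene's selected word vector: counts, tf-idf weights, top tokens."""

    gene_id: str
    tf: dict[str, int]
    tfidf: dict[str, float]
    selected: list[str]

    @property
    def is_empty(self) -> bool:
        return not self.selected

    def selected_counts(self) -> dict[str, int]:
        """Integer counts of the selected tokens (alias-boosted)."""
        return {t: self.tf[t] for t in self.selected}


def _count_tokens(tokens: list[str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for t in tokens:
        counts[t] = counts.get(t, 0) + 1
    return counts


def build_vocabulary(
    docs: list[GeneText],
    vocab_size: int = DEFAULT_VOCAB_SIZE,
    stopwords: frozenset[str] | None = None,
) -> tuple[Vocabulary, dict[str, dict[str, int]]]:
    """Rank tokens by cumulative tf-idf over the gene corpus.

    Returns the vocabulary and the per-gene raw token counts (so callers do
    not re-tokenize when building gene documents). Ties at the vocabulary
    boundary break lexicographically.
    """
    if not docs:
        raise ValueError("empty corpus")
    if stopwords is None:
        stopwords = load_stopwords()
    gene_tf: dict[str, dict[str, int]] = {}
    df: dict[str, int] = {}
    for doc in docs:
        counts = _count_tokens(preprocess(doc.text, stopwords))
        gene_tf[doc.gene_id] = counts
        for tok in counts:
            df[tok] = df.get(tok, 0) + 1
    n = len(docs)
    cumulative = {tok: 0.0 for tok in df}
    for counts in gene_tf.values():
        for tok, c in counts.items():
            cumulative[tok] += tfidf(c, df[tok], n)
    ranked = sorted(cumulative, key=lambda t: (-cumulative[t], t))[:vocab_size]
    vocab = Vocabulary(
        tokens=ranked,
        cumulative_tfidf={t: cumulative[t] for t in ranked},
        df={t: df[t] for t in ranked},
        corpus_size=n,
    )
    return vocab, gene_tf


def build_gene_document(
    doc: GeneText,
    vocab: Vocabulary,
    gene_tf: dict[str, int],
    vector_size: int = DEFAULT_VECTOR_SIZE,
    stopwords: frozenset[str] | None = None,
) -> GeneDocument:
    """Select the gene's top-``vector_size`` tf-idf tokens and boost aliases.

    Aliases (preprocessed like ordinary text) that occur in the gene's text
    and survive vocabulary restriction are forced to the maximum tf-idf (and
    maximum count) of the selection, inserted if necessary by evicting the
    lowest-ranked non-alias token when at capacity.
    """
    if stopwords is None:
        stopwords = load_stopwords()
    in_vocab = {t: c for t, c in gene_tf.items() if t in vocab}
    if not in_vocab:
        logger.warning("gene %s: no tokens survive vocabulary restriction", doc.gene_id)
        return GeneDocument(doc.gene_id, {}, {}, [])
    scores = {t: tfidf(c, vocab.df[t], vocab.corpus_size) for t, c in in_vocab.items()}
    ranked = sorted(scores, key=lambda t: (-scores[t], t))
    selected = ranked[:vector_size]

    alias_tokens: list[str] = []
    seen = set()
    for alias in doc.aliases:
        for tok in preprocess(alias, stopwords):
            if tok in in_vocab and tok not in seen:
                seen.add(tok)
                alias_tokens.append(tok)

    counts = dict(in_vocab)
    if alias_tokens:
        sel_set = set(selected)
        max_score = max(scores[t] for t in selected)
        max_count = max(counts[t] for t in selected)
        for tok in alias_tokens:
            scores[tok] = max_score
            counts[tok] = max_count
            if tok not in sel_set:
                if len(selected) >= vector_size:
                    # evict the lowest-ranked non-alias token
                    for i in range(len(selected) - 1, -1, -1):
                        if selected[i] not in seen:
                            del selected[i]
                            break
                    else:  # pragma: no cover - all slots are aliases
                        continue
                selected.append(tok)
                sel_set.add(tok)
        selected = sorted(selected, key=lambda t: (-scores[t], t))
    return GeneDocument(doc.gene_id, counts, scores, selected)


def build_corpus(
    docs: list[GeneText],
    vocab_size: int = DEFAULT_VOCAB_SIZE,
    vector_size: int = DEFAULT_VECTOR_SIZE,
) -> tuple[Vocabulary, dict[str, GeneDocument]]:
    """Vocabulary + per-gene word vectors in one pass."""
    stopwords = load_stopwords()
    vocab, gene_tf = build_vocabulary(docs, vocab_size, stopwords)
    gene_docs = {
        d.gene_id: build_gene_document(d, vocab, gene_tf[d.gene_id], vector_size, stopwords)
        for d in docs
    }
    return vocab, gene_docs


def read_gene_text(path: str | Path) -> list[GeneText]:
    """Read a gene-description table: gene_id, aliases (pipe-separated), text."""
    tab = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"gene_id", "aliases", "text"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"gene text table missing columns: {sorted(missing)}")
    return [
        GeneText(r.gene_id, [a for a in r.aliases.split("|") if a], r.text)
        for r in tab.itertuples()
    ]


def write_gene_documents(gene_docs: dict[str, GeneDocument], path: str | Path) -> None:
    rows = []
    for gid in sorted(gene_docs):
        gdoc = gene_docs[gid]
        for tok in gdoc.selected:
            rows.append((gid, tok, gdoc.tf[tok], gdoc.tfidf[tok]))
    pd.DataFrame(rows, columns=["gene_id", "token", "tf", "tfidf"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_documents(path: str | Path) -> dict[str, GeneDocument]:
    tab = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "token": str})
    out: dict[str, GeneDocument] = {}
    for gid, grp in tab.groupby("gene_id", sort=True):
        out[str(gid)] = GeneDocument(
            gene_id=str(gid),
            tf=dict(zip(grp["token"], grp["tf"].astype(int))),
            tfidf=dict(zip(grp["token"], grp["tfidf"].astype(float))),
            selected=list(grp["token"]),
        )
    return out
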