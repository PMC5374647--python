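"""Mapping SGAs and tumor clusters onto topics.

A gene g is associated with topic t through the words of its vector and the
documents of the corpus:

    p(g|t) ∝ Σ_d Σ_w count(w|g) · p(w|t) · p(t|d)

with count(w|g) the (alias-boosted) count of word w in the gene's selected
word vector, p(w|t) the topic-word probability and p(t|d) the document
allocation. Scores are normalized over genes for each topic. The document
sum runs over *all* tumor documents, following the unconditional form of
the score; conditioning on tumors that actually carry g is a plausible
alternative not used here.

A topic is associated with a document when at least ``threshold`` (default
1%) of the document's words are allocated to it; cluster-topic association
is the fraction of a cluster's documents associated with the topic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus import GeneDocument
from .nhdp import TopicModelFit

logger = logging.getLogger(__name__)

DEFAULT_DOC_ASSOC_THRESHOLD = 0.01


@dataclass(frozen=True)
class GeneTopicScore:
    gene_id: str
    node_id: int
    score: float


def gene_topic_scores(
    fit: TopicModelFit,
    gene_docs: dict[str, GeneDocument],
    genes: list[str],
    token_index: dict[str, int],
) -> pd.DataFrame:
    """p(g|t) for every gene in ``genes`` against every topic.

    Returns a tidy frame (node_id, gene_id, score) where scores sum to one
    over genes within each topic that received any raw mass. The triple sum
    factorizes as (Σ_w count·p(w|t)) · (Σ_d p(t|d)); both factors are
    computed densely.
    """
    n_nodes, _ = fit.phi.shape
    counts = np.zeros((len(genes), fit.phi.shape[1]))
    for i, g in enumerate(genes):
        gdoc = gene_docs.get(g)
        if gdoc is None or gdoc.is_empty:
            logger.warning("gene %s has an empty word vector; p(g|t) = 0", g)
            continue
        for tok, c in gdoc.selected_counts().items():
            j = token_index.get(tok)
            if j is not None:
                counts[i, j] = c
    word_part = counts @ fit.phi.T          # (genes, nodes)
    doc_part = fit.theta.sum(axis=0)        # (nodes,)
    raw = word_part * doc_part[None, :]
    totals = raw.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(totals > 0, raw / totals, 0.0)
    out = pd.DataFrame(norm, index=genes).stack().reset_index()
    out.columns = ["gene_id", "node_id", "score"]
    return out[["node_id", "gene_id", "score"]].sort_values(
        ["node_id", "score", "gene_id"], ascending=[True, False, True]
    ).reset_index(drop=True)


def doc_topic_associations(
    fit: TopicModelFit, threshold: float = DEFAULT_DOC_ASSOC_THRESHOLD
) -> dict[int, set[int]]:
    """document index -> set of node ids with theta >= threshold."""
    out = {}
    for d in range(fit.theta.shape[0]):
        out[d] = set(np.nonzero(fit.theta[d] >= threshold)[0].tolist())
    return out


def cluster_topic_proportions(
    assoc: dict[int, set[int]], clusters: dict[int, int], n_nodes: int
) -> pd.DataFrame:
    """Fraction of each cluster's documents associated with each topic.

    ``clusters`` maps document index -> cluster id; every document must be
    assigned and clusters must be non-empty.
    """
    missing = set(assoc) - set(clusters)
    if missing:
        raise ValueError(f"documents without a cluster id: {sorted(missing)[:5]}")
    members: dict[int, list[int]] = {}
    for d, c in clusters.items():
        members.setdefault(c, []).append(d)
    if not members:
        raise ValueError("no clusters: every cluster is empty")
    rows = []
    for c in sorted(members):
        docs = members[c]
        if not docs:
            raise ValueError(f"cluster {c} is empty")
        for t in range(n_nodes):
            prop = sum(1 for d in docs if t in assoc[d]) / len(docs)
            rows.append((c, t, prop))
    return pd.DataFrame(rows, columns=["cluster_id", "node_id", "proportion"])
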