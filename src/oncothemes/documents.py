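"""Tumors as text documents.

A tumor's mutation profile is re-expressed in word space: the selected
(alias-boosted) token counts of every gene altered in the tumor are summed
into one sparse bag of words. Two tumors perturbing the same pathway through
*different* genes then share vocabulary — the representation the downstream
topic model relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .corpus import GeneDocument, Vocabulary
from .sga import SgaMatrix

logger = logging.getLogger(__name__)


@dataclass
class TumorDocument:
    sample_id: str
    cancer_type: str | None
    counts: dict[str, int]
    source_genes: list[str] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not self.counts

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def pool_documents(
    sga: SgaMatrix, gene_docs: dict[str, GeneDocument]
) -> list[TumorDocument]:
    """Sum selected token counts over each tumor's altered genes.

    Genes without a word vector are skipped (logged once). Tumors whose
    pooled document is empty are retained with a warning; order of genes
    cannot affect the result (integer addition commutes).
    """
    missing = sorted(g for g in sga.genes if g not in gene_docs or gene_docs[g].is_empty)
    if missing:
        logger.warning(
            "%d SGA genes have no usable word vector: %s%s",
            len(missing), ", ".join(missing[:5]), "..." if len(missing) > 5 else "",
        )
    docs = []
    ctype = sga.cancer_type or {}
    for i, tumor in enumerate(sga.tumors):
        counts: dict[str, int] = {}
        genes_used = []
        for j in np.nonzero(sga.events[i])[0]:
            gene = sga.genes[j]
            gdoc = gene_docs.get(gene)
            if gdoc is None or gdoc.is_empty:
                continue
            genes_used.append(gene)
            for tok, c in gdoc.selected_counts().items():
                counts[tok] = counts.get(tok, 0) + c
        if not counts:
            logger.warning("tumor %s: empty document", tumor)
        docs.append(TumorDocument(tumor, ctype.get(tumor), counts, genes_used))
    return docs


def documents_to_matrix(
    docs: list[TumorDocument], vocab: Vocabulary
) -> sparse.csr_matrix:
    """Sparse document-term count matrix over the shared vocabulary."""
    rows, cols, vals = [], [], []
    for i, doc in enumerate(docs):
        for tok, c in doc.counts.items():
            rows.append(i)
            cols.append(vocab.index(tok))
            vals.append(c)
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(docs), len(vocab)), dtype=np.float64
    )


def write_documents(docs: list[TumorDocument], vocab: Vocabulary, outdir: str | Path) -> None:
    """Triplet TSV (doc_index, token_index, count) + index maps."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, doc in enumerate(docs):
        for tok in sorted(doc.counts):
            rows.append((i, vocab.index(tok), doc.counts[tok]))
    pd.DataFrame(rows, columns=["doc_index", "token_index", "count"]).to_csv(
        outdir / "doc_term.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {
            "doc_index": range(len(docs)),
            "sample_id": [d.sample_id for d in docs],
            "cancer_type": [d.cancer_type or "" for d in docs],
            "source_genes": ["|".join(d.source_genes) for d in docs],
        }
    ).to_csv(outdir / "doc_index.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"token_index": range(len(vocab)), "token": vocab.tokens}
    ).to_csv(outdir / "token_index.tsv", sep="\t", index=False)


def read_documents(outdir: str | Path) -> tuple[list[TumorDocument], list[str]]:
    """Inverse of :func:`write_documents`; returns documents + token list."""
    outdir = Path(outdir)
    toks = pd.read_csv(outdir / "token_index.tsv", sep="\t", dtype={"token": str})
    tokens = list(toks["token"])
    meta = pd.read_csv(outdir / "doc_index.tsv", sep="\t", dtype=str).fillna("")
    trip = pd.read_csv(outdir / "doc_term.tsv", sep="\t")
    counts_by_doc: dict[int, dict[str, int]] = {int(i): {} for i in meta["doc_index"]}
    for r in trip.itertuples():
        counts_by_doc[int(r.doc_index)][tokens[int(r.token_index)]] = int(r.count)
    docs = []
    for r in meta.itertuples():
        i = int(r.doc_index)
        docs.append(
            TumorDocument(
                sample_id=r.sample_id,
                cancer_type=r.cancer_type or None,
                counts=counts_by_doc[i],
                source_genes=[g for g in r.source_genes.split("|") if g],
            )
        )
    return docs, tokens
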