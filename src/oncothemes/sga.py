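"""Calling somatic genomic alteration (SGA) events.

An SGA is a binary per-tumor, per-gene event: the gene carries a functional
somatic mutation, or a high-level copy-number change (GISTIC state +/-2)
whose expression is concordantly shifted. The two channels are unioned and
genes altered in fewer than a recurrence threshold of tumors are discarded
as likely passengers.

Functional mutations are frame-shift, nonsense, splice-site and
multi-nucleotide variants, plus missense variants labelled possibly or
probably damaging by an upstream impact predictor (e.g. PolyPhen-2; running
the predictor is out of scope — labels are consumed as input).

For copy number, expression of each candidate (gene, sample) is compared to
a normal distribution fitted to that gene's copy-neutral samples; a
one-tailed p-value below ``p_threshold`` (upper tail for amplification,
lower tail for deletion) calls the event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FUNCTIONAL_CLASSES = frozenset(
    {"frame_shift", "nonsense", "splice_site", "multi_nucleotide"}
)
VARIANT_CLASSES = FUNCTIONAL_CLASSES | {"missense", "other"}
DAMAGING_LABELS = frozenset({"probably_damaging", "possibly_damaging"})
IMPACT_LABELS = DAMAGING_LABELS | {"benign", "unknown"}

DEFAULT_P_THRESHOLD = 0.01
DEFAULT_MIN_RECURRENCE = 20

# Common MAF spellings accepted on input.
MAF_COLUMN_ALIASES = {
    "Tumor_Sample_Barcode": "sample_id",
    "Hugo_Symbol": "gene_id",
    "Variant_Classification": "variant_class",
    "impact": "impact_label",
}
MAF_CLASS_ALIASES = {
    "missense_mutation": "missense",
    "frame_shift_del": "frame_shift",
    "frame_shift_ins": "frame_shift",
    "nonsense_mutation": "nonsense",
    "splice_site": "splice_site",
    "de_novo_start_outofframe": "other",
    "multi_hit": "multi_nucleotide",
    "mnp": "multi_nucleotide",
    "silent": "other",
}


@dataclass(frozen=True)
class MutationRecord:
    sample_id: str
    gene_id: str
    variant_class: str
    impact_label: str = "unknown"

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if self.impact_label not in IMPACT_LABELS:
            raise ValueError(f"unknown impact_label {self.impact_label!r}")


@dataclass(frozen=True)
class CnvCall:
    sample_id: str
    gene_id: str
    cn_state: int

    def __post_init__(self) -> None:
        if self.cn_state not in (-2, -1, 0, 1, 2):
            raise ValueError(f"cn_state must be in -2..2, got {self.cn_state}")


@dataclass
class SgaMatrix:
    """Binary tumor x gene event matrix."""

    tumors: list[str]
    genes: list[str]
    events: np.ndarray  # shape (n_tumors, n_genes), dtype int8, values 0/1
    cancer_type: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.int8)
        if self.events.shape != (len(self.tumors), len(self.genes)):
            raise ValueError("events shape inconsistent with tumor/gene lists")
        if not np.isin(self.events, (0, 1)).all():
            raise ValueError("events must be binary")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, index=self.tumors, columns=self.genes)

    def event_pairs(self) -> list[tuple[str, str]]:
        ti, gi = np.nonzero(self.events)
        return [(self.tumors[i], self.genes[j]) for i, j in zip(ti, gi)]

    def write(self, path: str | Path, dense: bool = False) -> None:
        if dense:
            self.to_frame().to_csv(path, sep="\t")
        else:
            pd.DataFrame(self.event_pairs(), columns=["sample_id", "gene_id"]).to_csv(
                path, sep="\t", index=False
            )

    @classmethod
    def from_pairs(
        cls,
        pairs: set[tuple[str, str]],
        cancer_type: dict[str, str] | None = None,
        tumors: list[str] | None = None,
    ) -> "SgaMatrix":
        if tumors is None:
            tumors = sorted({s for s, _ in pairs})
        genes = sorted({g for _, g in pairs})
        t_idx = {t: i for i, t in enumerate(tumors)}
        g_idx = {g: i for i, g in enumerate(genes)}
        events = np.zeros((len(tumors), len(genes)), dtype=np.int8)
        for s, g in pairs:
            events[t_idx[s], g_idx[g]] = 1
        return cls(tumors, genes, events, cancer_type)


def read_mutations(path: str | Path) -> list[MutationRecord]:
    """Parse a mutation TSV; MAF-style column and class names are accepted."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    tab = tab.rename(columns=MAF_COLUMN_ALIASES)
    required = {"sample_id", "gene_id", "variant_class"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    if "impact_label" not in tab.columns:
        tab["impact_label"] = "unknown"
    tab["impact_label"] = tab["impact_label"].fillna("unknown")
    records = []
    for i, row in enumerate(tab.itertuples(), start=2):  # 1-based incl. header
        vc = str(row.variant_class).strip().lower()
        vc = MAF_CLASS_ALIASES.get(vc, vc)
        label = str(row.impact_label).strip().lower().replace(" ", "_")
        if vc not in VARIANT_CLASSES:
            raise ValueError(f"{path}:{i}: unknown variant_class {row.variant_class!r}")
        if label not in IMPACT_LABELS:
            raise ValueError(f"{path}:{i}: unknown impact_label {row.impact_label!r}")
        records.append(MutationRecord(str(row.sample_id), str(row.gene_id), vc, label))
    return records


def read_cnv(path: str | Path) -> list[CnvCall]:
    """Read a gene x sample matrix of GISTIC states (-2..2) into calls."""
    tab = pd.read_csv(path, sep="\t", index_col=0)
    calls = []
    for gene, row in tab.iterrows():
        for sample, state in row.items():
            state = int(state)
            if state != 0:
                calls.append(CnvCall(str(sample), str(gene), state))
    return calls


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene x sample real-valued expression matrix."""
    return pd.read_csv(path, sep="\t", index_col=0)


def call_functional_mutations(records: list[MutationRecord]) -> set[tuple[str, str]]:
    """(sample, gene) pairs with at least one functional mutation."""
    pairs = set()
    for rec in records:
        if rec.variant_class in FUNCTIONAL_CLASSES or (
            rec.variant_class == "missense" and rec.impact_label in DAMAGING_LABELS
        ):
            pairs.add((rec.sample_id, rec.gene_id))
    return pairs


def cnv_pvalue(x: float, mu: float, sigma: float, cn_state: int) -> float:
    """One-tailed normal p-value for a CNV-expression concordance call.

    Upper tail for amplification (+2), lower tail for deletion (-2): the
    only direction in which the expression change corroborates the
    copy-number change.
    """
    if cn_state not in (-2, 2):
        raise ValueError("concordance is defined for |cn_state| = 2 only")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if cn_state == 2:
        return float(stats.norm.sf(x, loc=mu, scale=sigma))
    return float(stats.norm.cdf(x, loc=mu, scale=sigma))


def cnv_concordance_test(
    cnv: list[CnvCall],
    expr: pd.DataFrame,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> set[tuple[str, str]]:
    """Keep |cn|=2 calls whose expression is concordantly extreme.

    The reference distribution per gene is the normal fitted (mean,
    unbiased variance) to samples with cn_state = 0. Amplifications are
    tested against the upper tail, deletions against the lower tail; pairs
    with p < ``p_threshold`` are kept. Genes with fewer than two copy-neutral
    samples, zero reference variance, or missing from the expression matrix
    are skipped with a warning.
    """
    high = [c for c in cnv if abs(c.cn_state) == 2]
    by_gene: dict[str, list[CnvCall]] = {}
    for c in high:
        by_gene.setdefault(c.gene_id, []).append(c)

    # samples with any non-zero CNV call, per gene
    nonzero: dict[str, set[str]] = {}
    for c in cnv:
        nonzero.setdefault(c.gene_id, set()).add(c.sample_id)

    kept: set[tuple[str, str]] = set()
    for gene in sorted(by_gene):
        if gene not in expr.index:
            logger.warning("gene %s absent from expression matrix; skipped", gene)
            continue
        row = expr.loc[gene]
        neutral = [s for s in expr.columns if s not in nonzero.get(gene, set())]
        if len(neutral) < 2:
            logger.warning("gene %s: <2 copy-neutral samples; skipped", gene)
            continue
        ref = row[neutral].to_numpy(dtype=float)
        mu = float(np.mean(ref))
        sigma2 = float(np.var(ref, ddof=1))
        if sigma2 == 0.0:
            logger.warning("gene %s: zero reference variance; skipped", gene)
            continue
        sigma = np.sqrt(sigma2)
        for c in by_gene[gene]:
            if c.sample_id not in expr.columns:
                continue
            x = float(row[c.sample_id])
            p = cnv_pvalue(x, mu, sigma, c.cn_state)
            if p < p_threshold:
                kept.add((c.sample_id, c.gene_id))
    return kept


def build_sga_matrix(
    mut_pairs: set[tuple[str, str]],
    cnv_pairs: set[tuple[str, str]],
    min_recurrence: int = DEFAULT_MIN_RECURRENCE,
    cancer_type: dict[str, str] | None = None,
) -> SgaMatrix:
    """Union the two channels and drop genes below the recurrence threshold.

    Tumors left without any event after filtering are retained (they become
    empty documents downstream) and logged.
    """
    union = mut_pairs | cnv_pairs
    if not union:
        raise ValueError("no SGA events")
    tumors = sorted({s for s, _ in union})
    mat = SgaMatrix.from_pairs(union, cancer_type, tumors=tumors)
    colsums = mat.events.sum(axis=0)
    keep = colsums >= min_recurrence
    genes = [g for g, k in zip(mat.genes, keep) if k]
    events = mat.events[:, keep]
    empty = [t for t, s in zip(tumors, events.sum(axis=1)) if s == 0]
    if empty:
        logger.warning(
            "%d tumors have no SGA events after the recurrence filter: %s%s",
            len(empty), ", ".join(empty[:5]), "..." if len(empty) > 5 else "",
        )
    return SgaMatrix(tumors, genes, events, cancer_type)
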