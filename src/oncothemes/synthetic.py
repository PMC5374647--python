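"""Synthetic cohorts with planted pathway structure.

The generator encodes the premise the pipeline is built on: tumors of the
same subtype perturb the same pathways but through *different* member genes
(rotating drivers), so they look dissimilar in SGA space while sharing
functional themes in word space.

What is planted:

* pathways — disjoint gene modules; each pathway has a vocabulary "theme"
  (a token distribution concentrated on its own theme tokens);
* gene texts — theme/background token mixtures plus the gene's own symbol
  (its alias), passengers draw from background only;
* tumors — a subtype determines which pathways are perturbed; one member
  gene per perturbed pathway is drawn uniformly as the driver; passenger
  genes are added as rare Bernoulli events;
* alterations — each event is emitted either as a functional mutation
  record or as a +/-2 copy-number call with expression shifted by 4
  reference standard deviations (so the SGA-calling filters recover the
  planted events by construction); non-functional mutation noise and +/-1
  copy-number noise are sprinkled in;
* survival — exponential times with subtype-specific hazards and uniform
  thinning censoring; synthetic "cancer type" labels are assigned
  independently of subtype, so clusters mix cancer types.

Everything is drawn from a single seeded generator; identical configs give
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import GeneText


@dataclass
class SyntheticConfig:
    n_pathways: int = 5
    genes_per_pathway: int = 20
    n_passenger_genes: int = 300
    vocab_size: int = 2000
    theme_tokens_per_pathway: int = 40
    n_background_tokens: int = 300
    background_mixture_weight: float = 0.5
    n_subtypes: int = 4
    pathways_per_subtype: int = 2
    n_tumors: int = 600
    passenger_rate: float = 0.002
    hazard_per_subtype: tuple[float, ...] = (1 / 300, 1 / 600, 1 / 900, 1 / 1200)
    censoring_rate: float = 0.25
    n_cancer_types: int = 3
    tokens_per_gene_text: int = 120
    noise_mutations_per_tumor: float = 1.0
    seed: int = 7

    def __post_init__(self) -> None:
        if self.pathways_per_subtype > self.n_pathways:
            raise ValueError("pathways_per_subtype exceeds n_pathways")
        if comb(self.n_pathways, self.pathways_per_subtype) < self.n_subtypes:
            raise ValueError("not enough distinct pathway combinations for subtypes")
        if len(self.hazard_per_subtype) != self.n_subtypes:
            raise ValueError("need one hazard per subtype")
        if not all(h > 0 for h in self.hazard_per_subtype):
            raise ValueError("hazards must be positive")
        for name in ("background_mixture_weight", "passenger_rate", "censoring_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SyntheticTruth:
    pathway_genes: dict[int, list[str]]
    pathway_theme: dict[int, dict[str, float]]
    subtype_pathways: dict[int, list[int]]
    tumor_subtype: dict[str, int]
    tumor_drivers: dict[str, list[str]]
    tumor_passengers: dict[str, list[str]]
    tumor_survival: dict[str, tuple[float, int]]

    @property
    def driver_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.tumor_drivers.values():
            out.update(genes)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload = {k: {str(kk): vv for kk, vv in v.items()} for k, v in payload.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    gene_text: pd.DataFrame
    mutations: pd.DataFrame
    cnv: pd.DataFrame          # gene x sample, GISTIC states
    expression: pd.DataFrame   # gene x sample
    clinical: pd.DataFrame
    truth: SyntheticTruth

    def gene_texts(self) -> list[GeneText]:
        return [
            GeneText(r.gene_id, [a for a in r.aliases.split("|") if a], r.text)
            for r in self.gene_text.itertuples()
        ]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.gene_text.to_csv(outdir / "gene_text.tsv", sep="\t", index=False)
        self.mutations.to_csv(outdir / "mutations.tsv", sep="\t", index=False)
        self.cnv.to_csv(outdir / "cnv.tsv", sep="\t")
        self.expression.to_csv(outdir / "expression.tsv", sep="\t", float_format="%.6f")
        self.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
        self.truth.to_json(outdir / "truth.json")


def _assign_subtype_pathways(cfg: SyntheticConfig) -> dict[int, list[int]]:
    """Distinct pathway combinations with coverage kept as even as possible.

    Prefers restricting to the largest prefix of pathways over which the
    total number of subtype-pathway slots divides evenly (leftover pathways
    act as unperturbed negative controls).
    """
    slots = cfg.n_subtypes * cfg.pathways_per_subtype
    m = cfg.n_pathways
    for cand in range(cfg.n_pathways, cfg.pathways_per_subtype - 1, -1):
        if slots % cand == 0 and comb(cand, cfg.pathways_per_subtype) >= cfg.n_subtypes:
            m = cand
            break
    pool = list(combinations(range(m), cfg.pathways_per_subtype))
    coverage = np.zeros(m, dtype=int)
    chosen: list[tuple[int, ...]] = []
    for _ in range(cfg.n_subtypes):
        best = min(
            (c for c in pool if c not in chosen),
            key=lambda c: (sum(coverage[list(c)]), c),
        )
        chosen.append(best)
        for p in best:
            coverage[p] += 1
    return {s: list(c) for s, c in enumerate(chosen)}


def generate(cfg: SyntheticConfig | None = None) -> SyntheticDataset:
    """Draw a full synthetic cohort (all five input tables + ground truth)."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)

    # --- vocabulary universe (digits keep every token stemmer-stable) ---
    bg_tokens = [f"bg{i:04d}" for i in range(cfg.n_background_tokens)]
    theme_tokens = {
        p: [f"th{p}x{i:03d}" for i in range(cfg.theme_tokens_per_pathway)]
        for p in range(cfg.n_pathways)
    }

    # --- genes ---
    pathway_genes: dict[int, list[str]] = {}
    gene_ids: list[str] = []
    for p in range(cfg.n_pathways):
        genes = [f"g{p}x{i:03d}" for i in range(cfg.genes_per_pathway)]
        pathway_genes[p] = genes
        gene_ids.extend(genes)
    passenger_ids = [f"pg{i:04d}" for i in range(cfg.n_passenger_genes)]
    gene_ids.extend(passenger_ids)

    w = cfg.background_mixture_weight
    text_rows = []
    for p in range(cfg.n_pathways):
        theme = theme_tokens[p]
        for g in pathway_genes[p]:
            n_theme = int(rng.binomial(cfg.tokens_per_gene_text, 1.0 - w))
            toks = list(rng.choice(theme, size=n_theme)) + list(
                rng.choice(bg_tokens, size=cfg.tokens_per_gene_text - n_theme)
            )
            rng.shuffle(toks)
            text_rows.append((g, g, " ".join(toks + [g])))
    for g in passenger_ids:
        toks = list(rng.choice(bg_tokens, size=cfg.tokens_per_gene_text))
        text_rows.append((g, g, " ".join(toks + [g])))
    gene_text = pd.DataFrame(text_rows, columns=["gene_id", "aliases", "text"])

    # --- tumors ---
    subtype_pathways = _assign_subtype_pathways(cfg)
    tumor_ids = [f"T{i:04d}" for i in range(cfg.n_tumors)]
    subtypes = rng.integers(cfg.n_subtypes, size=cfg.n_tumors)
    cancer_types = [
        f"CT{rng.integers(cfg.n_cancer_types) + 1}" for _ in range(cfg.n_tumors)
    ]

    mut_rows: list[tuple[str, str, str, str]] = []
    cnv_states = pd.DataFrame(
        0, index=gene_ids, columns=tumor_ids, dtype=int
    )
    mu = rng.uniform(6.0, 10.0, size=len(gene_ids))
    expr = rng.normal(mu[:, None], 1.0, size=(len(gene_ids), cfg.n_tumors))
    expr_df = pd.DataFrame(expr, index=gene_ids, columns=tumor_ids)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    def emit_alteration(tumor: str, gene: str) -> None:
        if rng.random() < 0.5:
            vclass = rng.choice(
                ["missense", "frame_shift", "nonsense", "splice_site", "multi_nucleotide"],
                p=[0.5, 0.2, 0.15, 0.1, 0.05],
            )
            if vclass == "missense":
                impact = rng.choice(["probably_damaging", "possibly_damaging"])
            else:
                impact = "unknown"
            mut_rows.append((tumor, gene, str(vclass), str(impact)))
        else:
            sign = 1 if rng.random() < 0.5 else -1
            cnv_states.loc[gene, tumor] = 2 * sign
            expr_df.loc[gene, tumor] = mu[gene_pos[gene]] + sign * 4.0 + rng.normal(0.0, 0.2)

    tumor_drivers: dict[str, list[str]] = {}
    tumor_passengers: dict[str, list[str]] = {}
    for i, tumor in enumerate(tumor_ids):
        s = int(subtypes[i])
        drivers = []
        for p in subtype_pathways[s]:
            gene = str(rng.choice(pathway_genes[p]))
            drivers.append(gene)
            emit_alteration(tumor, gene)
        tumor_drivers[tumor] = drivers
        hits = np.nonzero(rng.random(cfg.n_passenger_genes) < cfg.passenger_rate)[0]
        passengers = [passenger_ids[j] for j in hits]
        for gene in passengers:
            emit_alteration(tumor, gene)
        tumor_passengers[tumor] = passengers
        # non-functional mutation noise (never passes the filter)
        for _ in range(rng.poisson(cfg.noise_mutations_per_tumor)):
            gene = gene_ids[int(rng.integers(len(gene_ids)))]
            if rng.random() < 0.5:
                mut_rows.append((tumor, gene, "missense", "benign"))
            else:
                mut_rows.append((tumor, gene, "other", "unknown"))

    # low-level copy-number noise (state +/-1: ignored by the filter)
    n_noise = int(0.005 * len(gene_ids) * cfg.n_tumors)
    gi = rng.integers(len(gene_ids), size=n_noise)
    ti = rng.integers(cfg.n_tumors, size=n_noise)
    sg = rng.choice([-1, 1], size=n_noise)
    for g, t, s_ in zip(gi, ti, sg):
        if cnv_states.iat[g, t] == 0:
            cnv_states.iat[g, t] = int(s_)

    mutations = pd.DataFrame(
        mut_rows, columns=["sample_id", "gene_id", "variant_class", "impact_label"]
    )

    # --- survival ---
    hazards = np.asarray(cfg.hazard_per_subtype)
    times = rng.exponential(1.0 / hazards[subtypes])
    events = np.ones(cfg.n_tumors, dtype=int)
    censor = rng.random(cfg.n_tumors) < cfg.censoring_rate
    times = np.where(censor, times * rng.random(cfg.n_tumors), times)
    events[censor] = 0
    clinical = pd.DataFrame(
        {
            "sample_id": tumor_ids,
            "cancer_type": cancer_types,
            "time_days": np.round(times, 2),
            "event": events,
        }
    )

    truth = SyntheticTruth(
        pathway_genes=pathway_genes,
        pathway_theme={
            p: {t: 1.0 / len(theme_tokens[p]) for t in theme_tokens[p]}
            for p in range(cfg.n_pathways)
        },
        subtype_pathways=subtype_pathways,
        tumor_subtype={t: int(s) for t, s in zip(tumor_ids, subtypes)},
        tumor_drivers=tumor_drivers,
        tumor_passengers=tumor_passengers,
        tumor_survival={
            t: (float(x), int(e)) for t, x, e in zip(tumor_ids, times, events)
        },
    )
    return SyntheticDataset(
        config=cfg,
        gene_text=gene_text,
        mutations=mutations,
        cnv=cnv_states,
        expression=expr_df,
        clinical=clinical,
        truth=truth,
    )


def evaluate_recovery(
    truth: SyntheticTruth,
    sga=None,
    fit=None,
    clusters: dict[str, int] | None = None,
    survival_table: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Deterministic recovery metrics for whatever stages are supplied.

    * SGA matrix -> driver sensitivity and spurious-gene fraction;
    * topic fit -> mean best cosine between the planted themes of perturbed
      pathways and allocated topic-word distributions;
    * cluster assignments -> adjusted Rand index against planted subtypes;
    * survival table -> smallest "filtered"-run log-rank p-value.
    """
    from sklearn.metrics import adjusted_rand_score

    metrics: dict[str, float] = {}
    if sga is not None:
        called = set(sga.genes)
        drivers = truth.driver_genes
        metrics["driver_sensitivity"] = len(called & drivers) / len(drivers)
        metrics["spurious_gene_fraction"] = (
            len(called - drivers) / len(called) if called else 0.0
        )
    if fit is not None:
        from .nhdp import allocated_topics

        token_pos = {t: j for j, t in enumerate(fit.tokens or [])}
        alloc = sorted(allocated_topics(fit, min_doc_mass=0.01))
        perturbed = {p for ps in truth.subtype_pathways.values() for p in ps}
        cosines = []
        for p, theme in truth.pathway_theme.items():
            if p not in perturbed:
                continue  # control pathways leave no trace in any document
            vec = np.zeros(fit.phi.shape[1])
            for tok, w_ in theme.items():
                j = token_pos.get(tok)
                if j is not None:
                    vec[j] = w_
            if vec.sum() == 0:
                continue
            best = 0.0
            for n in alloc:
                phi = fit.phi[n]
                c = float(vec @ phi / (np.linalg.norm(vec) * np.linalg.norm(phi)))
                best = max(best, c)
            cosines.append(best)
        if cosines:
            metrics["mean_theme_topic_cosine"] = float(np.mean(cosines))
    if clusters is not None:
        tumors = sorted(clusters)
        metrics["ari"] = float(
            adjusted_rand_score(
                [truth.tumor_subtype[t] for t in tumors],
                [clusters[t] for t in tumors],
            )
        )
    if survival_table is not None:
        filt = survival_table[survival_table["run"] == "filtered"]
        if len(filt):
            metrics["min_survival_p"] = float(filt["p"].min())
    return metrics
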