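"""Truncated nested hierarchical Dirichlet process (nHDP) topic model.

Topics live on a tree (default truncation: branching 10, 5, 3 below the
root, i.e. 1 + 10 + 50 + 150 = 211 candidate nodes). Each document owns a
nested stick-breaking distribution over subtrees — at every internal node a
truncated stick-breaking draw selects among the children — and per-node
"switch" probabilities that let words stop at internal nodes instead of
descending to a leaf, so a document can spread its words over the entire
tree while still concentrating on a few paths.

Generative model (truncated):

    phi_t ~ Dirichlet(beta0)                      topic-word distributions
    V_{d,u,i} ~ Beta(1, alpha)                    per-doc sticks at node u
    U_{d,u} ~ Beta(g1, g2)                        per-doc stop probability
    z_{d,n} ~ p(t | d)  with
        p(t|d) = U_t * prod_{a < t} (1 - U_a) * prod_(edges) stick weight
    w_{d,n} ~ phi_{z_{d,n}}

Inference is full-batch mean-field coordinate ascent: per-word (actually
per-token-type) topic responsibilities, per-document Beta posteriors for
sticks and switches, and Dirichlet posteriors for topics, iterated until the
relative change of the evidence lower bound (ELBO) falls below ``tol``.
Every individual update is an exact coordinate maximization, so the ELBO is
non-decreasing across iterations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import digamma, gammaln

logger = logging.getLogger(__name__)

DEFAULT_BRANCHING = (10, 5, 3)
DEFAULT_BETA0 = 0.01


@dataclass
class TopicTree:
    """Truncated topic tree; node 0 is the root, breadth-first order."""

    branching: tuple[int, ...]
    parent: np.ndarray  # parent[0] = -1
    depth: np.ndarray

    @classmethod
    def build(cls, branching=DEFAULT_BRANCHING) -> "TopicTree":
        branching = tuple(int(b) for b in branching)
        if any(b < 1 for b in branching):
            raise ValueError("branching factors must be positive")
        parent = [-1]
        depth = [0]
        frontier = [0]
        for level, b in enumerate(branching):
            new_frontier = []
            for u in frontier:
                for _ in range(b):
                    parent.append(u)
                    depth.append(level + 1)
                    new_frontier.append(len(parent) - 1)
            frontier = new_frontier
        return cls(branching, np.asarray(parent), np.asarray(depth))

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def max_depth(self) -> int:
        return len(self.branching)

    def children(self) -> list[np.ndarray]:
        kids: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for n in range(1, self.n_nodes):
            kids[self.parent[n]].append(n)
        return [np.asarray(k, dtype=int) for k in kids]

    def to_records(self) -> list[dict]:
        return [
            {"node_id": int(n), "parent_id": int(self.parent[n]), "depth": int(self.depth[n])}
            for n in range(self.n_nodes)
        ]


@dataclass
class TopicModelFit:
    """Fitted nHDP: topic tree, topic-word matrix, document allocations."""

    tree: TopicTree
    phi: np.ndarray          # (n_nodes, vocab) rows sum to 1
    theta: np.ndarray        # (n_docs, n_nodes) rows sum to 1
    log_likelihood: float    # final ELBO (cumulative over documents)
    beta0: float
    seed: int
    elbo_trace: list[float] = field(default_factory=list)
    doc_ids: list[str] | None = None
    tokens: list[str] | None = None
    fitted_mask: np.ndarray | None = None  # False where the document was empty

    def node_phi(self, node_id: int) -> np.ndarray:
        return self.phi[node_id]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "tree.json", "w") as fh:
            json.dump(self.tree.to_records(), fh, indent=1)
        tokens = self.tokens or [f"w{j}" for j in range(self.phi.shape[1])]
        doc_ids = self.doc_ids or [f"d{i}" for i in range(self.theta.shape[0])]
        pd.DataFrame(self.phi, columns=tokens).to_csv(
            outdir / "phi.tsv", sep="\t", index_label="node_id", float_format="%.12g"
        )
        pd.DataFrame(self.theta, index=doc_ids).to_csv(
            outdir / "theta.tsv", sep="\t", index_label="sample_id", float_format="%.12g"
        )
        manifest = {
            "beta0": self.beta0,
            "seed": int(self.seed),
            "branching": list(self.tree.branching),
            "log_likelihood": self.log_likelihood,
            "elbo_trace": self.elbo_trace,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)


def _beta_elogs(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = digamma(a + b)
    return digamma(a) - d, digamma(b) - d


def _beta_kl_vs_prior(a, b, p1, p2):
    """E_q[log Beta(x; p1, p2)] - E_q[log q(x)] for q = Beta(a, b)."""
    elog, elog1m = _beta_elogs(a, b)
    log_b_prior = gammaln(p1) + gammaln(p2) - gammaln(p1 + p2)
    e_logp = -log_b_prior + (p1 - 1.0) * elog + (p2 - 1.0) * elog1m
    log_b_q = gammaln(a) + gammaln(b) - gammaln(a + b)
    e_logq = -log_b_q + (a - 1.0) * elog + (b - 1.0) * elog1m
    return np.sum(e_logp - e_logq)


class _TreeIndex:
    """Precomputed index arrays for vectorized tree traversals."""

    def __init__(self, tree: TopicTree):
        self.tree = tree
        children = tree.children()
        self.internal = np.asarray(
            [n for n in range(tree.n_nodes) if len(children[n]) > 0], dtype=int
        )
        self.is_internal = np.zeros(tree.n_nodes, dtype=bool)
        self.is_internal[self.internal] = True
        self.internal_pos = -np.ones(tree.n_nodes, dtype=int)
        self.internal_pos[self.internal] = np.arange(len(self.internal))
        # child "slots": children of internal nodes, concatenated
        slot_nodes, slot_owner, slot_rank, slot_last = [], [], [], []
        for u in self.internal:
            kids = children[u]
            for i, c in enumerate(kids):
                slot_nodes.append(c)
                slot_owner.append(self.internal_pos[u])
                slot_rank.append(i)
                slot_last.append(i == len(kids) - 1)
        self.slot_nodes = np.asarray(slot_nodes, dtype=int)
        self.slot_owner = np.asarray(slot_owner, dtype=int)
        self.slot_last = np.asarray(slot_last, dtype=bool)
        self.n_slots = len(slot_nodes)
        self.slot_of_node = -np.ones(tree.n_nodes, dtype=int)
        self.slot_of_node[self.slot_nodes] = np.arange(self.n_slots)
        # slot ranges per internal node (children are contiguous)
        starts = np.searchsorted(self.slot_owner, np.arange(len(self.internal)))
        ends = np.searchsorted(self.slot_owner, np.arange(len(self.internal)), side="right")
        self.slot_ranges = list(zip(starts, ends))
        # per-slot start index and last index of the owning node's range
        self.slot_range_start = starts[self.slot_owner]
        self.slot_range_last = ends[self.slot_owner] - 1
        # nodes grouped by depth (vectorized tree sweeps)
        self.nodes_by_depth = [
            np.nonzero(tree.depth == d)[0] for d in range(tree.max_depth + 1)
        ]


def _kmeans_tree_init(
    X: sparse.csr_matrix,
    fit_rows: np.ndarray,
    tree: TopicTree,
    corpus_freq: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Recursive k-means over row-normalized documents to seed every node.

    The root is seeded with the corpus mean; each internal node splits its
    assigned documents into ``len(children)`` k-means clusters, one child
    per cluster. Nodes left without documents are seeded from a random
    document. Returns one probability vector per node.
    """
    import warnings

    from sklearn.cluster import KMeans
    from sklearn.exceptions import ConvergenceWarning

    V = X.shape[1]
    rows = X[fit_rows].toarray()
    rows /= rows.sum(axis=1, keepdims=True)
    children = tree.children()
    init = np.tile(corpus_freq, (tree.n_nodes, 1))
    assigned: dict[int, np.ndarray] = {0: np.arange(len(fit_rows))}
    for u in range(tree.n_nodes):
        kids = children[u]
        if len(kids) == 0:
            continue
        members = assigned.get(u, np.arange(0))
        if len(members) >= len(kids):
            with warnings.catch_warnings():
                # duplicate documents at deep nodes make fewer distinct
                # clusters than requested; harmless here
                warnings.simplefilter("ignore", ConvergenceWarning)
                km = KMeans(
                    n_clusters=len(kids),
                    n_init=4,
                    random_state=int(rng.integers(2**31 - 1)),
                ).fit(rows[members])
            for i, c in enumerate(kids):
                sel = members[km.labels_ == i]
                assigned[c] = sel
                if len(sel):
                    init[c] = km.cluster_centers_[i].clip(min=0.0)
        for c in kids:
            if len(assigned.get(c, ())) == 0:
                pick = int(rng.integers(len(rows)))
                init[c] = 0.5 * rows[pick] + 0.5 * corpus_freq
    init /= init.sum(axis=1, keepdims=True).clip(min=1e-300)
    # mild smoothing keeps initial topics from being exactly degenerate
    return 0.9 * init + 0.1 * corpus_freq[None, :]


class _DocState:
    """Per-document variational parameters (sticks + switches)."""

    __slots__ = ("a", "b", "c", "e")

    def __init__(self, idx: _TreeIndex, alpha: float, switch_prior):
        self.a = np.ones(idx.n_slots)
        self.b = np.full(idx.n_slots, alpha)
        self.c = np.full(len(idx.internal), float(switch_prior[0]))
        self.e = np.full(len(idx.internal), float(switch_prior[1]))


def _doc_log_prior(idx: _TreeIndex, st: _DocState) -> np.ndarray:
    """E[log p(z = node)] for every node under the document's sticks/switches."""
    tree = idx.tree
    elog_v, elog_1mv = _beta_elogs(st.a, st.b)
    # truncated sticks: the last child's V is fixed to 1 (log V = 0) and its
    # log(1-V) never enters any prefix sum within its own range
    elog_v = np.where(idx.slot_last, 0.0, elog_v)
    elog_1mv = np.where(idx.slot_last, 0.0, elog_1mv)
    # stick log-weight per slot: E[log V_i] + sum_{j<i} E[log(1-V_j)]
    cs = np.concatenate(([0.0], np.cumsum(elog_1mv)))  # cs[j] = sum over slots < j
    stick_logw = elog_v + (cs[np.arange(idx.n_slots)] - cs[idx.slot_range_start])
    elog_u, elog_1mu = _beta_elogs(st.c, st.e)
    prefix = np.zeros(tree.n_nodes)
    for nodes in idx.nodes_by_depth[1:]:
        par = tree.parent[nodes]
        prefix[nodes] = (
            prefix[par]
            + stick_logw[idx.slot_of_node[nodes]]
            + elog_1mu[idx.internal_pos[par]]
        )
    logp = prefix
    logp[idx.internal] += elog_u
    return logp


def _doc_kl(st: _DocState, idx: _TreeIndex, alpha: float, switch_prior) -> float:
    free = ~idx.slot_last
    kl = _beta_kl_vs_prior(st.a[free], st.b[free], 1.0, alpha)
    kl += _beta_kl_vs_prior(st.c, st.e, switch_prior[0], switch_prior[1])
    return float(kl)


def _subtree_masses(idx: _TreeIndex, m: np.ndarray) -> np.ndarray:
    s = m.copy()
    for nodes in reversed(idx.nodes_by_depth[1:]):  # leaves up
        np.add.at(s, idx.tree.parent[nodes], s[nodes])
    return s


def fit_nhdp(
    X: sparse.spmatrix | np.ndarray,
    branching=DEFAULT_BRANCHING,
    beta0: float = DEFAULT_BETA0,
    seed: int = 0,
    max_iters: int = 100,
    tol: float = 1e-5,
    alpha: float = 1.0,
    switch_prior: tuple[float, float] = (1.0, 1.0),
    doc_ids: list[str] | None = None,
    tokens: list[str] | None = None,
) -> TopicModelFit:
    """Fit the truncated nHDP to a document-term count matrix.

    Parameters
    ----------
    X : (n_docs, vocab) sparse count matrix. Empty rows (documents) are
        excluded from inference and receive a uniform allocation over the
        allocated nodes afterwards.
    branching : children per node at each level below the root; its length
        is the tree depth.
    beta0 : symmetric Dirichlet concentration of the topic prior.
    alpha : nested stick-breaking (DP) concentration at every level.
    switch_prior : Beta prior of the per-node stop probability.
    tol : relative ELBO change convergence criterion; ``tol=0`` runs
        exactly ``max_iters`` iterations.
    """
    X = sparse.csr_matrix(X, dtype=np.float64)
    n_docs_all, V = X.shape
    doc_totals = np.asarray(X.sum(axis=1)).ravel()
    fitted_mask = doc_totals > 0
    fit_rows = np.nonzero(fitted_mask)[0]
    if len(fit_rows) < 2:
        raise ValueError("need at least 2 non-empty documents")

    tree = TopicTree.build(branching)
    idx = _TreeIndex(tree)
    N = tree.n_nodes
    rng = np.random.default_rng(seed)

    # init: hierarchical k-means down the tree (data-driven symmetry
    # breaking, as in reference nHDP implementations), smoothed toward the
    # corpus frequencies; unreached nodes get seeded random documents
    corpus_freq = np.asarray(X.sum(axis=0)).ravel()
    corpus_freq = corpus_freq / corpus_freq.sum()
    lam = beta0 + 50.0 * _kmeans_tree_init(X, fit_rows, tree, corpus_freq, rng)

    states = {d: _DocState(idx, alpha, switch_prior) for d in fit_rows}
    masses = np.zeros((n_docs_all, N))

    elbo_trace: list[float] = []
    log_b_beta0 = V * gammaln(beta0) - gammaln(V * beta0)
    prev_elbo = -np.inf
    for it in range(max_iters):
        elogphi = digamma(lam) - digamma(lam.sum(axis=1, keepdims=True))
        lam_new = np.full((N, V), beta0)
        token_term = 0.0
        doc_kl = 0.0
        for d in fit_rows:
            st = states[d]
            toks = X.indices[X.indptr[d] : X.indptr[d + 1]]
            cnts = X.data[X.indptr[d] : X.indptr[d + 1]]
            logp = _doc_log_prior(idx, st)
            logits = elogphi[:, toks].T + logp[None, :]
            logits -= logits.max(axis=1, keepdims=True)
            r = np.exp(logits)
            r /= r.sum(axis=1, keepdims=True)
            m = r.T @ cnts
            masses[d] = m
            # exact coordinate updates for the document's sticks/switches
            s_mass = _subtree_masses(idx, m)
            child_mass = s_mass[idx.slot_nodes]
            ic = np.cumsum(child_mass)  # inclusive cumsum across all slots
            tail = ic[idx.slot_range_last] - ic  # later-sibling subtree mass
            st.a = 1.0 + child_mass
            st.b = alpha + tail
            st.c = switch_prior[0] + m[idx.internal]
            st.e = switch_prior[1] + (s_mass[idx.internal] - m[idx.internal])
            # ELBO pieces at the current (post-update) document parameters
            logp_new = _doc_log_prior(idx, st)
            rw = r * cnts[:, None]
            token_term += float(m @ logp_new)
            token_term += float(np.sum(rw * elogphi[:, toks].T))
            nz = r > 0
            token_term -= float(np.sum(rw[nz] * np.log(r[nz])))
            doc_kl += _doc_kl(st, idx, alpha, switch_prior)
            lam_new[:, toks] += rw.T
        # global (topic) KL at the pre-update lambda, consistent with elogphi
        log_b_lam = np.sum(gammaln(lam), axis=1) - gammaln(lam.sum(axis=1))
        global_term = float(
            np.sum(-log_b_beta0 + log_b_lam)
            + np.sum((beta0 - lam) * elogphi)
        )
        elbo = token_term + doc_kl + global_term
        elbo_trace.append(elbo)
        lam = lam_new
        if not np.isfinite(elbo):
            raise FloatingPointError(
                f"non-finite variational objective at iteration {it}: {elbo}"
            )
        if it > 0 and tol > 0:
            denom = max(abs(prev_elbo), 1.0)
            if abs(elbo - prev_elbo) / denom < tol:
                prev_elbo = elbo
                break
        prev_elbo = elbo

    phi = lam / lam.sum(axis=1, keepdims=True)
    theta = np.zeros((n_docs_all, N))
    with np.errstate(invalid="ignore"):
        theta[fit_rows] = masses[fit_rows] / masses[fit_rows].sum(axis=1, keepdims=True)
    fit = TopicModelFit(
        tree=tree,
        phi=phi,
        theta=theta,
        log_likelihood=float(prev_elbo),
        beta0=beta0,
        seed=seed,
        elbo_trace=elbo_trace,
        doc_ids=doc_ids,
        tokens=tokens,
        fitted_mask=fitted_mask,
    )
    if not fitted_mask.all():
        alloc = sorted(allocated_topics(fit))
        theta[~fitted_mask] = 0.0
        theta[np.ix_(~fitted_mask, alloc)] = 1.0 / len(alloc)
    return fit


def best_of_k(
    X,
    k: int = 10,
    seeds: list[int] | None = None,
    seed: int = 0,
    **kwargs,
) -> TopicModelFit:
    """Fit ``k`` models with distinct seeds; keep the highest-ELBO fit.

    All per-run likelihoods are logged; with ``k=1`` this is ``fit_nhdp``.
    """
    if seeds is None:
        seeds = [int(seed) + i for i in range(k)]
    if len(seeds) != k:
        raise ValueError("need exactly k seeds")
    best = None
    lls = []
    for s in seeds:
        fit = fit_nhdp(X, seed=s, **kwargs)
        lls.append(fit.log_likelihood)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    logger.info("best_of_k likelihoods: %s", dict(zip(seeds, lls)))
    best.all_run_likelihoods = dict(zip(seeds, lls))  # type: ignore[attr-defined]
    return best


def allocated_topics(fit: TopicModelFit, min_doc_mass: float = 0.0) -> set[int]:
    """Nodes whose allocation exceeds ``min_doc_mass`` in at least one document."""
    rows = fit.theta if fit.fitted_mask is None else fit.theta[fit.fitted_mask]
    return set(np.nonzero((rows > min_doc_mass).any(axis=0))[0].tolist())
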