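"""Truncated nHDP: tree structure, inference sanity, recovery, determinism."""

import numpy as np
import pytest
from scipy import sparse

from oncothemes import TopicTree, allocated_topics, best_of_k, fit_nhdp


def _greedy_matched_cosines(recovered, planted):
    def cos(a, b):
        return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))

    cands = sorted(
        ((cos(r, p), i, j) for i, r in enumerate(recovered) for j, p in enumerate(planted)),
        reverse=True,
    )
    used_r, used_p, out = set(), set(), []
    for c, i, j in cands:
        if i not in used_r and j not in used_p:
            out.append(c)
            used_r.add(i)
            used_p.add(j)
    return out


class TestTopicTree:
    def test_default_truncation_has_211_nodes(self):
        tree = TopicTree.build([10, 5, 3])
        assert tree.n_nodes == 1 + 10 + 50 + 150
        assert tree.max_depth == 3

    def test_parent_child_depths_consistent(self):
        tree = TopicTree.build([4, 2])
        for n in range(1, tree.n_nodes):
            assert tree.depth[n] == tree.depth[tree.parent[n]] + 1

    def test_branching_respected(self):
        tree = TopicTree.build([3, 2])
        kids = tree.children()
        assert len(kids[0]) == 3
        for n in np.nonzero(tree.depth == 1)[0]:
            assert len(kids[n]) == 2


class TestFitSanity:
    def test_degenerate_corpus_concentrates_on_root_path(self):
        X = sparse.csr_matrix(np.tile([5.0, 0.0, 0.0], (10, 1)))
        fit = fit_nhdp(X, branching=[3], seed=1, max_iters=40, tol=0)
        assert fit.phi[0, 0] > 0.99
        # all documents put essentially all mass on the root's path
        assert fit.theta.sum(axis=1) == pytest.approx(np.ones(10), abs=1e-9)

    def test_distributions_normalized(self, planted_tree_corpus):
        X, _, _ = planted_tree_corpus
        fit = fit_nhdp(X, branching=[3, 2], seed=3, max_iters=15, tol=0)
        assert fit.phi.sum(axis=1) == pytest.approx(np.ones(fit.phi.shape[0]), abs=1e-9)
        assert fit.theta.sum(axis=1) == pytest.approx(np.ones(fit.theta.shape[0]), abs=1e-9)

    def test_elbo_monotone_non_decreasing(self, planted_tree_corpus):
        X, _, _ = planted_tree_corpus
        fit = fit_nhdp(X, branching=[3], seed=5, max_iters=60, tol=0)
        tr = np.asarray(fit.elbo_trace)
        assert len(tr) == 60
        assert np.all(np.diff(tr) >= -1e-6 * np.abs(tr[:-1]))

    def test_empty_documents_get_uniform_allocation(self):
        rows = np.vstack([np.eye(4) * 5, np.zeros((1, 4))])
        fit = fit_nhdp(sparse.csr_matrix(rows), branching=[2], seed=0, max_iters=20, tol=0)
        alloc = sorted(allocated_topics(fit))
        expected = np.zeros(fit.tree.n_nodes)
        expected[alloc] = 1.0 / len(alloc)
        assert fit.theta[-1] == pytest.approx(expected)

    def test_too_few_documents_rejected(self):
        with pytest.raises(ValueError):
            fit_nhdp(sparse.csr_matrix(np.zeros((3, 4))), branching=[2])


class TestRecovery:
    def test_planted_children_recovered(self, planted_tree_corpus):
        X, root, children = planted_tree_corpus
        fit = fit_nhdp(X, branching=[3], beta0=0.01, seed=7, max_iters=100, tol=1e-6)
        cosines = _greedy_matched_cosines([fit.phi[n] for n in (1, 2, 3)], children)
        assert np.mean(cosines) >= 0.8
        # the planted child topics are all allocated to documents
        assert {1, 2, 3} <= allocated_topics(fit, min_doc_mass=0.05)

    def test_fitted_model_beats_single_topic_baseline(self, planted_tree_corpus):
        X, root, children = planted_tree_corpus
        fit = fit_nhdp(X, branching=[3], seed=7, max_iters=60, tol=1e-6)
        Xd = X.toarray()
        # held-out-style per-word log-likelihood under the fitted mixture
        ll_fit = 0.0
        for d in range(Xd.shape[0]):
            mix = fit.theta[d] @ fit.phi
            nz = Xd[d] > 0
            ll_fit += float(Xd[d, nz] @ np.log(mix[nz]))
        mle = Xd.sum(axis=0) / Xd.sum()
        ll_single = float((Xd.sum(axis=0)[mle > 0] * np.log(mle[mle > 0])).sum())
        assert ll_fit > ll_single


class TestBestOfK:
    def test_k1_equals_fit_nhdp(self, planted_tree_corpus):
        X, _, _ = planted_tree_corpus
        a = best_of_k(X, k=1, seed=2, branching=[3], max_iters=10, tol=0)
        b = fit_nhdp(X, seed=2, branching=[3], max_iters=10, tol=0)
        assert a.log_likelihood == b.log_likelihood
        assert np.array_equal(a.phi, b.phi)

    def test_argmax_contract(self, planted_tree_corpus):
        X, _, _ = planted_tree_corpus
        best = best_of_k(X, k=3, seeds=[1, 2, 3], branching=[3], max_iters=10, tol=0)
        lls = best.all_run_likelihoods
        assert len(lls) == 3
        assert best.log_likelihood == max(lls.values())

    def test_rerun_identical_selection(self, planted_tree_corpus):
        X, _, _ = planted_tree_corpus
        a = best_of_k(X, k=2, seeds=[5, 6], branching=[3], max_iters=8, tol=0)
        b = best_of_k(X, k=2, seeds=[5, 6], branching=[3], max_iters=8, tol=0)
        assert a.seed == b.seed
        assert np.array_equal(a.theta, b.theta)


class TestAllocatedTopics:
    def test_zero_threshold_returns_touched_nodes(self, planted_tree_corpus):
        X, _, _ = planted_tree_corpus
        fit = fit_nhdp(X, branching=[3], seed=1, max_iters=10, tol=0)
        alloc = allocated_topics(fit, min_doc_mass=0.0)
        assert alloc == set(np.nonzero((fit.theta > 0).any(axis=0))[0].tolist())

    def test_full_mass_threshold_empty(self, planted_tree_corpus):
        X, _, _ = planted_tree_corpus
        fit = fit_nhdp(X, branching=[3], seed=1, max_iters=10, tol=0)
        assert allocated_topics(fit, min_doc_mass=1.0) == set()


def test_seeded_determinism_bitwise(planted_tree_corpus, tmp_path):
    X, _, _ = planted_tree_corpus
    a = fit_nhdp(X, branching=[3, 2], seed=9, max_iters=12, tol=0)
    b = fit_nhdp(X, branching=[3, 2], seed=9, max_iters=12, tol=0)
    a.write(tmp_path / "a")
    b.write(tmp_path / "b")
    for name in ["tree.json", "phi.tsv", "theta.tsv", "manifest.json"]:
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
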