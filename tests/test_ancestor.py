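import itertools

import numpy as np
import pytest

from phylorder.genome_io import Genome, PhyloTree
from phylorder.encoding import BinaryCharacterMatrix
from phylorder.evo_model import transition_matrix
from phylorder.phylogeny import ModelParams
from phylorder.ancestor import (
    AncestorPosterior,
    CharacterPrior,
    apply_wgd,
    partial_likelihood,
    posterior,
    reconstruct_all,
    select_content,
)

from test_phylogeny import matrix_from_rows


def enumeration_posterior(tree, node_name, col, m, p, f):
    """Bayes' rule by explicit summation over internal-node states."""
    work = tree.unroot() if tree.root is not None else tree.copy()
    target = work.node_by_name(node_name)
    internals = [v for v in work.internal_nodes() if v != target]
    order = work.postorder(target)
    leaf_state = {t: int(m.data[i, col]) for i, t in enumerate(m.taxa)}
    lik = {0: 0.0, 1: 0.0}
    for target_state in (0, 1):
        for assign in itertools.product((0, 1), repeat=len(internals)):
            states = dict(zip(internals, assign))
            states[target] = target_state
            for v in work.nodes:
                if work.is_leaf(v):
                    states[v] = leaf_state[work.names[v]]
            term = 1.0
            for v, parent in order:
                if parent is None:
                    continue
                T = transition_matrix(p.loss, p.gain, work.length(parent, v))
                term *= T[states[parent], states[v]]
            lik[target_state] += term
    num = f * lik[1]
    den = num + (1 - f) * lik[0]
    return f if den == 0 else num / den


@pytest.fixture
def four_leaf_tree():
    return PhyloTree.parse_newick(
        "((A:0.3,B:0.2)N1:0.25,(C:0.4,D:0.15)N2:0.1);").unroot()


class TestPartialLikelihood:
    def test_zero_branches_give_indicator(self):
        m = matrix_from_rows({"A": [1], "B": [1], "C": [0]})
        t = PhyloTree()
        c = t.add_node("N")
        t.add_edge(c, t.add_node("A"), 0.0)
        t.add_edge(c, t.add_node("B"), 0.0)
        t.add_edge(c, t.add_node("C"), 5.0)
        p = ModelParams(loss=1.0, gain=0.5)
        part = partial_likelihood(t, "N", "C:0", m, p)
        assert part[1] > 0
        assert part[0] == pytest.approx(0.0, abs=1e-12)

    def test_deep_caterpillar_stays_finite(self):
        # 12-leaf caterpillar with short branches: scaled partials must not
        # underflow to zero
        newick = "A1:0.01"
        for i in range(2, 13):
            newick = f"({newick},A{i}:0.01):0.01"
        t = PhyloTree.parse_newick(newick + ";")
        rows = {f"A{i}": [1] for i in range(1, 13)}
        m = matrix_from_rows(rows)
        p = ModelParams(loss=1.0, gain=1e-6)
        root_name = "R"
        t.names[t.root] = root_name
        part = partial_likelihood(t, root_name, "C:0", m, p)
        assert np.isfinite(part).all()
        assert part[1] > 0


class TestPosterior:
    def test_all_present_gives_one(self, four_leaf_tree):
        m = matrix_from_rows({t: [1] for t in "ABCD"})
        val = posterior(four_leaf_tree, "N1", "C:0", m,
                        ModelParams(loss=1.0, gain=0.1))
        assert val == pytest.approx(1.0)

    def test_all_absent_gives_zero(self, four_leaf_tree):
        m = matrix_from_rows({t: [0] for t in "ABCD"})
        val = posterior(four_leaf_tree, "N1", "C:0", m,
                        ModelParams(loss=1.0, gain=0.1))
        assert val == pytest.approx(0.0)

    def test_matches_enumeration_oracle(self, four_leaf_tree, rng):
        m = matrix_from_rows({t: rng.integers(0, 2, 6) for t in "ABCD"})
        p = ModelParams(loss=0.9, gain=0.2)
        prior = CharacterPrior.from_matrix(m)
        aps = reconstruct_all(four_leaf_tree, m, p)
        for ap in aps:
            for col in range(m.n_columns):
                expected = enumeration_posterior(
                    four_leaf_tree, ap.node, col, m, p, prior.f[col])
                assert ap.probs[col] == pytest.approx(expected, abs=1e-10)

    def test_monotone_in_prior(self, four_leaf_tree, rng):
        m = matrix_from_rows({t: rng.integers(0, 2, 4) for t in "ABCD"})
        p = ModelParams(loss=1.0, gain=0.2)
        vals = []
        for f in (0.1, 0.3, 0.5, 0.7, 0.9):
            prior = CharacterPrior(np.full(m.n_columns, f))
            vals.append(posterior(four_leaf_tree, "N1", "C:1", m, p, prior))
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_uniform_character_same_posterior_everywhere(self, rng):
        t = PhyloTree.parse_newick(
            "((A:0.3,B:0.7)N1:0.2,(C:0.5,(D:0.4,E:0.6)N3:0.3)N2:0.1);").unroot()
        m = matrix_from_rows({x: [1, 0] for x in "ABCDE"})
        p = ModelParams(loss=1.0, gain=0.4)
        aps = reconstruct_all(t, m, p)
        for col in range(2):
            vals = [ap.probs[col] for ap in aps]
            assert np.allclose(vals, vals[0], atol=1e-10)


def updown_posteriors(tree, m, p, prior):
    """Independent two-pass (up/down) message-passing implementation.

    up[v]: P(data below v | state at v); down[v]: P(data above v | state
    at v).  Per-column rescaling factors apply equally to both states, so
    they cancel in the posterior ratio.
    """
    work = tree.unroot()
    root = work.internal_nodes()[0]
    order = work.postorder(root)
    parent_of = {v: par for v, par in order}
    states = {t: m.data[i].astype(float) for i, t in enumerate(m.taxa)}

    def T_edge(u, v):
        return transition_matrix(p.loss, p.gain, work.length(u, v))

    up = {}
    for v, parent in order:  # children before parents
        children = [c for c in work.neighbors(v) if c != parent]
        if not children:
            x = states[work.names[v]]
            up[v] = np.stack([1 - x, x], axis=1)
            continue
        acc = np.ones((m.n_columns, 2))
        for c in children:
            acc *= up[c] @ T_edge(v, c).T
        up[v] = acc / acc.sum(axis=1, keepdims=True)

    down = {root: np.ones((m.n_columns, 2))}
    for v, parent in order[::-1]:  # parents before children
        if parent is None:
            continue
        msg = down[parent].copy()
        for s in work.neighbors(parent):
            if s == v or s == parent_of[parent]:
                continue
            msg *= up[s] @ T_edge(parent, s).T
        # edge traversed child->parent in the re-rooted orientation
        msg = msg @ T_edge(parent, v).T
        down[v] = msg / msg.sum(axis=1, keepdims=True)

    out = {}
    for v in work.internal_nodes():
        L = down[v].copy()
        for c in work.neighbors(v):
            if c == parent_of[v]:
                continue
            L *= up[c] @ T_edge(v, c).T
        num = prior.f * L[:, 1]
        den = num + (1 - prior.f) * L[:, 0]
        out[work.names[v]] = np.where(den > 0, num / np.where(den > 0, den, 1), prior.f)
    return out


class TestReconstructAll:
    def test_ancestor_count_is_leaves_minus_two(self, four_leaf_tree, rng):
        m = matrix_from_rows({t: rng.integers(0, 2, 5) for t in "ABCD"})
        aps = reconstruct_all(four_leaf_tree, m, ModelParams(loss=1.0, gain=0.2))
        assert len(aps) == 2

    def test_twenty_leaves_give_eighteen_ancestors(self, rng):
        from phylorder.simulator import random_tree
        t = random_tree(20, seed=0)
        for u, v in t.edges():
            t.set_length(u, v, 0.3)
        names = [f"S{i}" for i in range(1, 21)]
        m = matrix_from_rows({n: rng.integers(0, 2, 3) for n in names})
        aps = reconstruct_all(t, m, ModelParams(loss=1.0, gain=0.2))
        assert len(aps) == 18

    def test_rerooting_equals_updown_oracle(self, rng):
        t = PhyloTree.parse_newick(
            "((A:0.3,B:0.7)N1:0.2,(C:0.5,(D:0.4,E:0.6)N3:0.3)N2:0.1);").unroot()
        m = matrix_from_rows({x: rng.integers(0, 2, 8) for x in "ABCDE"})
        p = ModelParams(loss=1.0, gain=0.3)
        prior = CharacterPrior.from_matrix(m)
        aps = {ap.node: ap.probs for ap in reconstruct_all(t, m, p)}
        oracle = updown_posteriors(t, m, p, prior)
        for name, probs in aps.items():
            assert np.allclose(probs, oracle[name], atol=1e-8)


class TestSelectContent:
    def test_threshold_selection(self):
        ap = AncestorPosterior("N", ["C:1", "C:2"], np.array([0.9, 0.1]))
        assert select_content(ap) == {1}

    def test_exact_threshold_excluded(self):
        ap = AncestorPosterior("N", ["C:1"], np.array([0.5]))
        assert select_content(ap, 0.5) == set()

    def test_adjacency_labels_ignored(self):
        ap = AncestorPosterior("N", ["A:1t|2h", "C:3"], np.array([0.99, 0.8]))
        assert select_content(ap) == {3}

    def test_invalid_threshold(self):
        ap = AncestorPosterior("N", ["C:1"], np.array([0.5]))
        with pytest.raises(ValueError):
            select_content(ap, 1.5)


class TestWGD:
    def test_doubling(self):
        g = Genome("pre", [[1, 2], [3]])
        d = apply_wgd(g)
        assert d.chromosomes == [[1, 2], [3], [1, 2], [3]]
        assert d.family_counts()[1] == 2
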