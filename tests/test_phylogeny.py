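import itertools

import numpy as np
import pytest

from phylorder.genome_io import PhyloTree
from phylorder.encoding import BinaryCharacterMatrix
from phylorder.evo_model import transition_matrix, stationary_distribution
from phylorder.phylogeny import (
    ModelParams,
    SupportLevel,
    bootstrap_support,
    fit_model,
    infer_tree,
    log_likelihood,
    optimize_branch_lengths,
    support_level,
)


def matrix_from_rows(rows: dict) -> BinaryCharacterMatrix:
    taxa = list(rows)
    data = np.stack([np.asarray(rows[t], dtype=np.uint8) for t in taxa])
    return BinaryCharacterMatrix(
        taxa=taxa, adjacency_columns=[],
        content_columns=list(range(data.shape[1])), data=data,
    )


def enumeration_loglik(tree: PhyloTree, m: BinaryCharacterMatrix,
                       p: ModelParams) -> float:
    """Brute force: sum over all internal-node state assignments."""
    work = tree.unroot() if tree.root is not None else tree.copy()
    internals = work.internal_nodes()
    root = internals[0]
    pi = stationary_distribution(p.loss, p.gain)
    order = work.postorder(root)
    total = 0.0
    for col in range(m.n_columns):
        leaf_state = {t: int(m.data[i, col]) for i, t in enumerate(m.taxa)}
        lik = 0.0
        for assign in itertools.product((0, 1), repeat=len(internals)):
            states = dict(zip(internals, assign))
            for v in work.nodes:
                if work.is_leaf(v):
                    states[v] = leaf_state[work.names[v]]
            term = pi[states[root]]
            for v, parent in order:
                if parent is None:
                    continue
                T = transition_matrix(p.loss, p.gain, work.length(parent, v))
                term *= T[states[parent], states[v]]
            lik += term
        total += np.log(lik)
    return total


@pytest.fixture
def clean_split_matrix(rng):
    rows = {}
    rows["A"] = rng.integers(0, 2, 200)
    rows["C"] = rng.integers(0, 2, 200)
    rows["B"] = rows["A"].copy()
    rows["D"] = rows["C"].copy()
    return matrix_from_rows(rows)


class TestLogLikelihood:
    def test_matches_enumeration_three_leaves(self, rng):
        m = matrix_from_rows({t: rng.integers(0, 2, 5) for t in "ABC"})
        t = PhyloTree()
        c = t.add_node()
        for i, name in enumerate("ABC"):
            leaf = t.add_node(name)
            t.add_edge(c, leaf, 0.2 + 0.1 * i)
        p = ModelParams(loss=1.0, gain=0.3)
        assert log_likelihood(t, m, p) == pytest.approx(
            enumeration_loglik(t, m, p), abs=1e-10)

    def test_matches_enumeration_five_leaves(self, rng):
        m = matrix_from_rows({t: rng.integers(0, 2, 4) for t in "ABCDE"})
        t = PhyloTree.parse_newick("((A:0.2,B:0.3):0.15,(C:0.4,(D:0.1,E:0.5):0.2):0.3);")
        p = ModelParams(loss=0.8, gain=0.1)
        assert log_likelihood(t, m, p) == pytest.approx(
            enumeration_loglik(t, m, p), abs=1e-10)

    def test_degenerate_branches_give_prior_loglik(self):
        m = matrix_from_rows({"A": [1, 0], "B": [1, 0], "C": [1, 0]})
        t = PhyloTree()
        c = t.add_node()
        for name in "ABC":
            t.add_edge(c, t.add_node(name), 1e-12)
        p = ModelParams(loss=1.0, gain=0.5)
        pi = stationary_distribution(p.loss, p.gain)
        assert log_likelihood(t, m, p) == pytest.approx(
            np.log(pi[1]) + np.log(pi[0]), abs=1e-6)

    def test_invariant_to_rerooting(self, rng):
        m = matrix_from_rows({t: rng.integers(0, 2, 30) for t in "ABCDE"})
        t = PhyloTree.parse_newick("((A:0.2,B:0.3):0.15,(C:0.4,(D:0.1,E:0.5):0.2):0.3);")
        u = t.unroot()
        p = ModelParams(loss=1.0, gain=0.2)
        ref = log_likelihood(u, m, p)
        # pruning from every internal vantage point gives the same value
        from phylorder.phylogeny import _leaf_states, _partials
        for root in u.internal_nodes():
            states = _leaf_states(m, np.arange(m.n_columns))
            part, ls = _partials(u, root, states, p.loss, p.gain)
            pi = stationary_distribution(p.loss, p.gain)
            ll = float(np.sum(np.log(part @ pi) + ls))
            assert ll == pytest.approx(ref, abs=1e-8)

    def test_label_mismatch_rejected(self, rng):
        m = matrix_from_rows({t: rng.integers(0, 2, 3) for t in "ABC"})
        t = PhyloTree.parse_newick("((A:1,B:1):1,X:1);")
        with pytest.raises(ValueError, match="match"):
            log_likelihood(t, m, ModelParams())


class TestInferTree:
    def test_three_taxa_single_topology(self, rng):
        m = matrix_from_rows({t: rng.integers(0, 2, 20) for t in "ABC"})
        t = infer_tree(m, ModelParams(loss=1.0, gain=0.3))
        assert sorted(t.leaf_names()) == ["A", "B", "C"]
        assert t.is_binary()

    def test_recovers_clean_split_and_beats_alternatives(self, clean_split_matrix):
        p = ModelParams(loss=1.0, gain=0.3)
        t = infer_tree(clean_split_matrix, p)
        assert t.bipartitions() == {frozenset({"C", "D"})}
        # exact check: the returned topology maximizes the likelihood over
        # all three 4-taxon topologies with optimized branch lengths
        best = {}
        for split in ({"C", "D"}, {"B", "D"}, {"B", "C"}):
            others = sorted({"A", "B", "C", "D"} - split)
            s = sorted(split)
            cand = PhyloTree.parse_newick(
                f"(({others[0]},{others[1]}),({s[0]},{s[1]}));").unroot()
            best[frozenset(split)] = optimize_branch_lengths(
                cand, clean_split_matrix, p, sweeps=4)
        assert max(best, key=best.get) == frozenset({"C", "D"})

    def test_identical_taxa_become_siblings(self, rng):
        rows = {t: rng.integers(0, 2, 120) for t in "ABCDE"}
        rows["A2"] = rows["A"].copy()
        m = matrix_from_rows(rows)
        t = infer_tree(m, ModelParams(loss=1.0, gain=0.3))
        # the A|A2 split canonicalizes to its complement (the side without A)
        assert frozenset({"B", "C", "D", "E"}) in t.bipartitions()

    def test_column_permutation_invariance(self, rng):
        rows = {t: rng.integers(0, 2, 60) for t in "ABCDE"}
        m1 = matrix_from_rows(rows)
        perm = rng.permutation(60)
        m2 = matrix_from_rows({t: np.asarray(r)[perm] for t, r in rows.items()})
        p = ModelParams(loss=1.0, gain=0.3)
        assert infer_tree(m1, p).bipartitions() == infer_tree(m2, p).bipartitions()

    def test_hill_climb_trace_is_monotone(self, rng):
        rows = {f"T{i}": rng.integers(0, 2, 40) for i in range(6)}
        m = matrix_from_rows(rows)
        _, trace = infer_tree(m, ModelParams(loss=1.0, gain=0.3), return_trace=True)
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_too_few_taxa_rejected(self, rng):
        m = matrix_from_rows({t: rng.integers(0, 2, 5) for t in "AB"})
        with pytest.raises(ValueError):
            infer_tree(m, ModelParams())


class TestBootstrap:
    def test_clean_signal_full_support(self, clean_split_matrix):
        t = bootstrap_support(clean_split_matrix, ModelParams(loss=1.0, gain=0.3),
                              B=50, seed=0)
        (edge,) = t.internal_edges()
        assert t.supports[edge] == 100.0

    def test_single_replicate_supports_are_zero_or_hundred(self, rng):
        rows = {f"T{i}": rng.integers(0, 2, 40) for i in range(5)}
        m = matrix_from_rows(rows)
        t = bootstrap_support(m, ModelParams(loss=1.0, gain=0.3), B=1, seed=3)
        for edge in t.internal_edges():
            assert t.supports[edge] in (0.0, 100.0)

    @pytest.mark.parametrize("value,level", [
        (91, SupportLevel.STRONG),
        (84, SupportLevel.MEDIUM),
        (59, SupportLevel.WEAK),
        (60, SupportLevel.MEDIUM),
        (90, SupportLevel.MEDIUM),
    ])
    def test_support_classification(self, value, level):
        assert support_level(value) is level


class TestFitModel:
    def test_fitting_does_not_decrease_likelihood(self, rng):
        rows = {f"T{i}": rng.integers(0, 2, 50) for i in range(5)}
        m = matrix_from_rows(rows)
        p0 = ModelParams(loss=1.0, gain=1e-3)
        t = infer_tree(m, p0)
        ll0 = log_likelihood(t, m, p0)
        fitted = fit_model(t, m, p0, rounds=1)
        assert log_likelihood(t, m, fitted) >= ll0 - 1e-9
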