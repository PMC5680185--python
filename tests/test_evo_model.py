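import itertools
from collections import deque

import numpy as np
import pytest
from scipy.linalg import expm

from phylorder.genome_io import Genome
from phylorder.evo_model import (
    EventRates,
    adjacency_gain_prob,
    adjacency_loss_prob,
    dcj_distance,
    event_breakdown,
    stationary_distribution,
    transition_matrix,
)


class TestRateFormulas:
    def test_no_events_no_change(self):
        er = EventRates(R=0, D=0, I=0, d=0, n=100, C=2)
        assert adjacency_loss_prob(er) == 0.0
        assert adjacency_gain_prob(er) == 0.0

    def test_loss_prob_values(self):
        er = EventRates(R=100, D=0, I=0, d=0, n=5000, C=8)
        assert adjacency_loss_prob(er) == pytest.approx(200 / 5008)
        er = EventRates(R=10, D=5, I=5, d=5, n=100, C=2)
        assert adjacency_loss_prob(er) == pytest.approx(50 / 102)

    def test_gain_prob_values(self):
        er = EventRates(R=100, D=0, I=0, d=0, n=5000, C=8)
        # C(2n+2, 2) = 10002 * 10001 / 2 = 50,015,001 possible end pairs
        assert adjacency_gain_prob(er) == pytest.approx(200 / 50_015_001)

    def test_gain_much_smaller_than_loss(self):
        for n in (2, 10, 1000):
            er = EventRates(R=3, D=1, I=1, d=1, n=n, C=1)
            assert adjacency_gain_prob(er) < adjacency_loss_prob(er)

    def test_clamped_to_unit_interval(self):
        er = EventRates(R=1e9, D=0, I=0, d=0, n=10, C=1)
        assert adjacency_loss_prob(er) == 1.0

    def test_monotone_in_each_event_count(self):
        base = dict(R=1.0, D=1.0, I=1.0, d=1.0)
        er0 = EventRates(n=50, C=2, **base)
        for key in base:
            bumped = EventRates(n=50, C=2, **{**base, key: 2.0})
            assert adjacency_loss_prob(bumped) >= adjacency_loss_prob(er0)
            assert adjacency_gain_prob(bumped) >= adjacency_gain_prob(er0)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            EventRates(R=-1, D=0, I=0, d=0, n=10, C=1)


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        assert np.allclose(transition_matrix(0.3, 0.1, 0.0), np.eye(2))

    def test_symmetric_rates_converge_to_half(self):
        T = transition_matrix(1.0, 1.0, 1e6)
        assert np.allclose(T, 0.5)

    def test_rows_stochastic_and_limit_is_stationary(self):
        lam, mu = 0.04, 4e-6
        T = transition_matrix(lam, mu, 3.7)
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-12)
        Tinf = transition_matrix(lam, mu, 1e9)
        pi = stationary_distribution(lam, mu)
        assert np.allclose(Tinf, np.vstack([pi, pi]), atol=1e-12)

    def test_matches_matrix_exponential(self):
        lam, mu = 0.04, 4e-6
        Q = np.array([[-mu, mu], [lam, -lam]])
        for t in (0.1, 1.0, 7.3):
            assert np.allclose(transition_matrix(lam, mu, t), expm(Q * t),
                               atol=1e-12)

    def test_chapman_kolmogorov(self):
        lam, mu = 0.7, 0.2
        for s, t in ((0.1, 0.5), (1.0, 2.0), (0.0, 3.0)):
            lhs = transition_matrix(lam, mu, s) @ transition_matrix(lam, mu, t)
            assert np.allclose(lhs, transition_matrix(lam, mu, s + t), atol=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            transition_matrix(1.0, 1.0, -0.1)
        with pytest.raises(ValueError):
            transition_matrix(0.0, 1.0, 1.0)


# --------------------------------------------------------------------------
# BFS oracle for DCJ: states are adjacency sets over gene extremities;
# one DCJ move recombines two adjacencies, cuts one, or joins two telomeres.
# --------------------------------------------------------------------------

def _genome_state(chroms):
    from phylorder.encoding import gene_extremities, canonical_adjacency

    adjs = set()
    for chrom in chroms:
        for a, b in zip(chrom, chrom[1:]):
            adjs.add(canonical_adjacency(gene_extremities(a)[1],
                                         gene_extremities(b)[0]))
    return frozenset(adjs)


def _dcj_neighbors(state, extremities):
    from phylorder.encoding import canonical_adjacency

    adjs = list(state)
    bound = {e for a in adjs for e in a}
    free = [e for e in extremities if e not in bound]
    out = set()
    # recombine two adjacencies
    for (p, q), (r, s) in itertools.combinations(adjs, 2):
        rest = state - {(p, q), (r, s)}
        out.add(frozenset(rest | {canonical_adjacency(p, r),
                                  canonical_adjacency(q, s)}))
        out.add(frozenset(rest | {canonical_adjacency(p, s),
                                  canonical_adjacency(q, r)}))
    # adjacency + telomere
    for a in adjs:
        p, q = a
        rest = state - {a}
        out.add(frozenset(rest))  # cut into two telomeres
        for e in free:
            out.add(frozenset(rest | {canonical_adjacency(p, e)}))
            out.add(frozenset(rest | {canonical_adjacency(q, e)}))
    # join two telomeres
    for e1, e2 in itertools.combinations(free, 2):
        out.add(frozenset(state | {canonical_adjacency(e1, e2)}))
    out.discard(state)
    return out


def bfs_dcj(a_chroms, b_chroms, max_depth=6):
    fams = {abs(x) for c in a_chroms for x in c}
    extremities = [(f, e) for f in sorted(fams) for e in ("h", "t")]
    start = _genome_state(a_chroms)
    goal = _genome_state(b_chroms)
    if start == goal:
        return 0
    seen = {start}
    frontier = deque([(start, 0)])
    while frontier:
        state, depth = frontier.popleft()
        if depth >= max_depth:
            continue
        for nxt in _dcj_neighbors(state, extremities):
            if nxt == goal:
                return depth + 1
            if nxt not in seen:
                seen.add(nxt)
                frontier.append((nxt, depth + 1))
    raise AssertionError("goal unreachable within max_depth")


class TestDCJDistance:
    def test_identical_genomes(self):
        g = Genome("a", [[1, 2, 3]])
        assert dcj_distance(g, g.copy("b")) == 0

    def test_single_inversion(self):
        assert dcj_distance(Genome("a", [[1, 2, 3]]),
                            Genome("b", [[1, -2, 3]])) == 1

    def test_transposition_like_case(self):
        a = Genome("a", [[1, 2, 3, 4]])
        b = Genome("b", [[2, 1, 3, 4]])
        assert dcj_distance(a, b) == bfs_dcj(a.chromosomes, b.chromosomes)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bfs_oracle_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 5))
        def rand_chroms():
            perm = rng.permutation(np.arange(1, n + 1))
            signs = rng.choice([1, -1], n)
            genes = [int(p * s) for p, s in zip(perm, signs)]
            if n > 2 and rng.random() < 0.4:
                k = int(rng.integers(1, n))
                return [genes[:k], genes[k:]]
            return [genes]
        a, b = rand_chroms(), rand_chroms()
        assert dcj_distance(Genome("a", a), Genome("b", b)) == bfs_dcj(a, b)

    @pytest.mark.parametrize("seed", range(6))
    def test_metric_properties(self, seed):
        rng = np.random.default_rng(100 + seed)
        def rand_genome(name):
            perm = rng.permutation(np.arange(1, 6))
            signs = rng.choice([1, -1], 5)
            return Genome(name, [[int(p * s) for p, s in zip(perm, signs)]])
        x, y, z = (rand_genome(n) for n in "xyz")
        assert dcj_distance(x, y) == dcj_distance(y, x)
        assert dcj_distance(x, x.copy("x2")) == 0
        assert dcj_distance(x, z) <= dcj_distance(x, y) + dcj_distance(y, z)

    def test_duplicates_reduced_to_exemplars(self):
        a = Genome("a", [[1, 2, 1, 3]])  # exemplar: 1 2 3
        b = Genome("b", [[1, 2, 3]])
        assert dcj_distance(a, b) == 0

    def test_disjoint_content_rejected(self):
        with pytest.raises(ValueError):
            dcj_distance(Genome("a", [[1]]), Genome("b", [[2]]))


class TestEventBreakdown:
    def test_identical(self):
        g = Genome("a", [[1, 2, 3]])
        eb = event_breakdown(g, g.copy("b"))
        assert (eb.rearrangements, eb.gene_losses, eb.gene_gains, eb.total) == (0, 0, 0, 0)

    def test_loss_only(self):
        eb = event_breakdown(Genome("a", [[1, 2, 3]]), Genome("b", [[1, 3]]))
        assert eb.gene_losses == 1
        assert eb.gene_gains == 0
        assert eb.rearrangements == 0
        assert eb.total == 1

    def test_swapping_arguments_swaps_losses_and_gains(self, rng):
        a = Genome("a", [[1, 2, 3, 4, 5]])
        b = Genome("b", [[1, -3, 2, 6]])
        ab, ba = event_breakdown(a, b), event_breakdown(b, a)
        assert ab.gene_losses == ba.gene_gains
        assert ab.gene_gains == ba.gene_losses
        assert ab.rearrangements == ba.rearrangements
        assert ab.total == ba.total
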