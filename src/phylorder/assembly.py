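"""Assembling ancestral genes and adjacency posteriors into chromosomes.

Choosing gene orders that maximize the product of adjacency posteriors is a
traveling-salesman problem: each selected gene is a city with two ports (its
head and tail extremities), a synthetic cap node stands for the chromosome
ends, and the cost of placing extremities u, v next to each other is
-log(eps + P({u, v})).  A heuristic tour (greedy edge matching, then 2-opt
and segment relocation — full-neighborhood on small instances, candidate-list
on large ones — with chained double-bridge restarts) approximates the
minimum-cost Hamiltonian cycle; an exact Held-Karp solver is available for
small instances.

The closed tour is then opened at the cap and cut into linear chromosomes.
Cut points are chosen by how widely the created extremities are telomeric in
the neighboring genomes (one parent, two children), in strict priority:
(1) telomeric in all three, (2) in both children, (3) in any two of the
three, (4) in the parent, (5) in one child; cutting stops once the target
chromosome count (median of the neighbors' counts) is reached, falling back
to the lowest-posterior junctions if candidates run out.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Optional

import numpy as np

from .genome_io import Genome
from .encoding import (
    HEAD,
    TAIL,
    TELOMERE,
    canonical_adjacency,
    decode_column,
    gene_extremities,
    is_telomeric,
    telomeric_extremities,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AdjacencyGraph",
    "AncestralGenome",
    "build_tsp",
    "solve_tour",
    "tour_cost",
    "split_into_chromosomes",
    "assemble_ancestor",
]


@dataclass
class AdjacencyGraph:
    """Weighted extremity graph of a TSP assembly instance.

    ``adj_probs`` maps canonical non-telomeric adjacencies between selected
    families to posterior probabilities; ``telomere_probs`` (optional) maps
    extremities to telomeric-adjacency posteriors.  Head-tail pairing within
    a gene is handled by contraction (a gene is one TSP node with two
    ports), so no forced edges appear explicitly.
    """

    families: list[int]
    adj_probs: dict
    telomere_probs: Optional[dict] = None
    eps: float = 1e-9

    def cost(self, u, v) -> float:
        return -math.log(self.eps + self.adj_probs.get(canonical_adjacency(u, v), 0.0))

    def cap_cost(self, e) -> float:
        if self.telomere_probs is None:
            return -math.log(self.eps)
        return -math.log(self.eps + self.telomere_probs.get(e, 0.0))


def build_tsp(families: Iterable[int], char_probs: Mapping, eps: float = 1e-9) -> AdjacencyGraph:
    """TSP instance over the selected families.

    ``char_probs`` maps either column labels ('A:1t|2h') or adjacency tuples
    to posterior probabilities; adjacencies touching unselected families are
    dropped, telomeric ones populate the cap weights when present.
    """
    fams = sorted(set(families))
    if not fams:
        raise ValueError("no families selected")
    fam_set = set(fams)
    adj_probs: dict = {}
    tel_probs: dict = {}
    for key, prob in char_probs.items():
        if isinstance(key, str):
            if not key.startswith("A:"):
                continue
            adj = decode_column(key)
        else:
            adj = key
        if is_telomeric(adj):
            ext = adj[0] if adj[1] == TELOMERE else adj[1]
            if ext[0] in fam_set:
                tel_probs[ext] = max(tel_probs.get(ext, 0.0), float(prob))
            continue
        (f1, _), (f2, _) = adj
        if f1 in fam_set and f2 in fam_set:
            adj_probs[adj] = max(adj_probs.get(adj, 0.0), float(prob))
    return AdjacencyGraph(
        families=fams,
        adj_probs=adj_probs,
        telomere_probs=tel_probs or None,
        eps=eps,
    )


# ---------------------------------------------------------------------------
# Tours
# ---------------------------------------------------------------------------
# A tour is a list of signed family IDs; +f is traversed head->tail.  The cap
# is implicit: the list is the cycle opened at the cap node.

def _left_ext(s: int):
    return gene_extremities(s)[0]


def _right_ext(s: int):
    return gene_extremities(s)[1]


def tour_cost(g: AdjacencyGraph, tour: list[int]) -> float:
    """Cost of the closed tour cap -> tour[0] -> ... -> tour[-1] -> cap."""
    c = g.cap_cost(_left_ext(tour[0])) + g.cap_cost(_right_ext(tour[-1]))
    for a, b in zip(tour, tour[1:]):
        c += g.cost(_right_ext(a), _left_ext(b))
    return c


def _candidates(g: AdjacencyGraph) -> dict:
    """extremity -> [(partner extremity, prob)] sorted by decreasing prob."""
    cand: dict = {}
    for (u, v), prob in g.adj_probs.items():
        cand.setdefault(u, []).append((v, prob))
        cand.setdefault(v, []).append((u, prob))
    for lst in cand.values():
        lst.sort(key=lambda t: (-t[1], t[0]))
    return cand


def _greedy_edge_tour(g: AdjacencyGraph) -> list[int]:
    """Greedy matching construction: accept adjacencies by decreasing
    posterior while each extremity stays unused and no premature cycle
    forms; chain the resulting paths."""
    parent: dict[int, int] = {f: f for f in g.families}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    used: set = set()
    partner: dict = {}
    for adj, prob in sorted(g.adj_probs.items(), key=lambda kv: (-kv[1], kv[0])):
        u, v = adj
        if u in used or v in used:
            continue
        ru, rv = find(u[0]), find(v[0])
        if ru == rv:
            continue
        parent[ru] = rv
        used.add(u)
        used.add(v)
        partner[u] = v
        partner[v] = u

    # walk each path from a free extremity, smallest family first
    def opposite(ext):
        return (ext[0], TAIL if ext[1] == HEAD else HEAD)

    tour: list[int] = []
    visited: set[int] = set()
    for f in g.families:
        if f in visited:
            continue
        # march from f until a free exit extremity is found; the path is
        # then traversed in the reverse direction, entering through it
        exit_ext = (f, TAIL)
        for _ in range(len(g.families) + 1):
            if exit_ext not in partner:
                break
            exit_ext = opposite(partner[exit_ext])
        entry = exit_ext
        while True:
            cur_f = entry[0]
            visited.add(cur_f)
            tour.append(cur_f if entry[1] == HEAD else -cur_f)
            nxt = partner.get(opposite(entry))
            if nxt is None:
                break
            entry = nxt
    return tour


def _improve(g: AdjacencyGraph, tour: list[int], cand: dict,
             trace: Optional[list] = None) -> list[int]:
    """2-opt and single-gene relocation restricted to candidate adjacencies."""
    n = len(tour)
    pos = {abs(s): i for i, s in enumerate(tour)}

    def exit_cost(i: int) -> float:
        # cost of the edge leaving position i to the right (cap beyond ends)
        if i == n - 1:
            return g.cap_cost(_right_ext(tour[i]))
        return g.cost(_right_ext(tour[i]), _left_ext(tour[i + 1]))

    def entry_cost_of(i: int) -> float:
        if i == 0:
            return g.cap_cost(_left_ext(tour[0]))
        return g.cost(_right_ext(tour[i - 1]), _left_ext(tour[i]))

    improved = True
    while improved:
        improved = False
        # --- 2-opt: make (exit of i-1) adjacent to a strong partner ------
        for i in range(n):
            e = _right_ext(tour[i - 1]) if i > 0 else None
            partners = cand.get(e, ()) if e is not None else ()
            for w, _prob in partners:
                j = pos[w[0]]
                if j < i:
                    continue
                # after reversing tour[i..j], position i starts with the flip
                # of tour[j]; its entry extremity is tour[j]'s current exit.
                cur_exit = _right_ext(tour[j])
                if cur_exit != w:
                    continue
                old = entry_cost_of(i) + exit_cost(j)
                new = g.cost(_right_ext(tour[i - 1]), cur_exit)
                # reversed segment ends with -tour[i], whose exit extremity
                # is the old entry extremity of tour[i]
                if j == n - 1:
                    new += g.cap_cost(_left_ext(tour[i]))
                else:
                    new += g.cost(_left_ext(tour[i]), _left_ext(tour[j + 1]))
                if new < old - 1e-12:
                    tour[i:j + 1] = [-s for s in reversed(tour[i:j + 1])]
                    pos.update({abs(s): k for k, s in enumerate(tour[i:j + 1], start=i)})
                    if trace is not None:
                        trace.append(tour_cost(g, tour))
                    improved = True
                    break
            if improved:
                break
        if improved:
            continue
        # --- or-opt: relocate one gene next to a strong partner ----------
        for (u, v), prob in sorted(g.adj_probs.items(),
                                   key=lambda kv: (-kv[1], kv[0])):
            for a_ext, b_ext in ((u, v), (v, u)):
                i = pos[a_ext[0]]
                j = pos[b_ext[0]]
                if i == j:
                    continue
                # want: gene of b placed right after gene of a, oriented so
                # that a exits via a_ext and b enters via b_ext
                want_a = tour[i] if _right_ext(tour[i]) == a_ext else -tour[i]
                want_b = tour[j] if _left_ext(tour[j]) == b_ext else -tour[j]
                if tour[i] == want_a and i + 1 <= n - 1 and tour[i + 1] == want_b:
                    continue  # already realized
                if tour[i] != want_a:
                    continue  # only relocate b; flipping a handled elsewhere
                sb = want_b
                # remove j
                old = entry_cost_of(j) + exit_cost(j)
                if j == 0:
                    bridge = g.cap_cost(_left_ext(tour[1])) if n > 1 else 0.0
                elif j == n - 1:
                    bridge = g.cap_cost(_right_ext(tour[j - 1]))
                else:
                    bridge = g.cost(_right_ext(tour[j - 1]), _left_ext(tour[j + 1]))
                gain = old - bridge
                i2 = i if j > i else i - 1  # index of a after removal
                # insert after a
                ins_old = exit_cost(i) if j != i + 1 else bridge
                removed = tour[j]
                del tour[j]
                after = tour[i2 + 1] if i2 + 1 < len(tour) else None
                ins_old = (g.cost(_right_ext(tour[i2]), _left_ext(after))
                           if after is not None else g.cap_cost(_right_ext(tour[i2])))
                ins_new = g.cost(_right_ext(tour[i2]), _left_ext(sb))
                ins_new += (g.cost(_right_ext(sb), _left_ext(after))
                            if after is not None else g.cap_cost(_right_ext(sb)))
                delta = (ins_new - ins_old) - gain
                if delta < -1e-12:
                    tour.insert(i2 + 1, sb)
                    pos.clear()
                    pos.update({abs(s): k for k, s in enumerate(tour)})
                    if trace is not None:
                        trace.append(tour_cost(g, tour))
                    improved = True
                    break
                tour.insert(j, removed)
            if improved:
                break
    return tour


def _double_bridge(tour: list[int], rng: np.random.Generator) -> list[int]:
    n = len(tour)
    if n < 8:
        return list(tour)
    cuts = sorted(rng.choice(np.arange(1, n), size=3, replace=False))
    a, b, c = cuts
    return tour[:a] + tour[b:c] + tour[a:b] + tour[c:]


def _exact_tour(g: AdjacencyGraph) -> list[int]:
    """Held-Karp dynamic program over (subset, last oriented gene)."""
    fams = g.families
    n = len(fams)
    if n > 12:
        raise ValueError("exact solver limited to 12 genes")
    oriented = [(f, o) for f in fams for o in (1, -1)]
    idx = {f: i for i, f in enumerate(fams)}

    def signed(f, o):
        return f * o

    start_cost = {
        (f, o): g.cap_cost(_left_ext(signed(f, o))) for f, o in oriented
    }
    INF = float("inf")
    dp: dict[tuple[int, tuple], tuple[float, Optional[tuple]]] = {}
    for f, o in oriented:
        dp[(1 << idx[f], (f, o))] = (start_cost[(f, o)], None)
    full = (1 << n) - 1
    for mask in range(1, full + 1):
        for f, o in oriented:
            key = (mask, (f, o))
            if key not in dp:
                continue
            base, _ = dp[key]
            e = _right_ext(signed(f, o))
            for f2, o2 in oriented:
                if mask & (1 << idx[f2]):
                    continue
                c = base + g.cost(e, _left_ext(signed(f2, o2)))
                nkey = (mask | (1 << idx[f2]), (f2, o2))
                if c < dp.get(nkey, (INF, None))[0]:
                    dp[nkey] = (c, (mask, (f, o)))
    best, best_key = INF, None
    for f, o in oriented:
        key = (full, (f, o))
        if key in dp:
            c = dp[key][0] + g.cap_cost(_right_ext(signed(f, o)))
            if c < best:
                best, best_key = c, key
    tour = []
    key = best_key
    while key is not None:
        mask, (f, o) = key
        tour.append(signed(f, o))
        key = dp[key][1]
    tour.reverse()
    return tour


_EXHAUSTIVE_LIMIT = 16  # below this, run full-neighborhood local search


def _exhaustive_improve(g: AdjacencyGraph, tour: list[int],
                        trace: Optional[list] = None) -> list[int]:
    """Full 2-opt (segment reversal incl. single-gene flips) plus single-gene
    relocation with orientation choice; affordable on small instances."""
    best = tour_cost(g, tour)
    n = len(tour)
    improved = True
    while improved:
        improved = False
        for i in range(n):
            for j in range(i, n):
                cand = tour[:i] + [-s for s in reversed(tour[i:j + 1])] + tour[j + 1:]
                c = tour_cost(g, cand)
                if c < best - 1e-12:
                    tour, best, improved = cand, c, True
                    if trace is not None:
                        trace.append(c)
        for length in (1, 2, 3):
            for i in range(n - length + 1):
                seg = tour[i:i + length]
                rest = tour[:i] + tour[i + length:]
                for j in range(len(rest) + 1):
                    for piece in (seg, [-s for s in reversed(seg)]):
                        cand = rest[:j] + piece + rest[j:]
                        if cand == tour:
                            continue
                        c = tour_cost(g, cand)
                        if c < best - 1e-12:
                            tour, best, improved = cand, c, True
                            if trace is not None:
                                trace.append(c)
    return tour


def solve_tour(g: AdjacencyGraph, seed: int = 0, restarts: int = 4,
               exact: bool = False, return_trace: bool = False):
    """Minimum-cost Hamiltonian cycle through all selected genes.

    Heuristic mode: greedy edge-matching construction, local improvement
    (full-neighborhood 2-opt/relocation on small instances, candidate-list
    moves on large ones), then ``restarts`` chained double-bridge
    perturbations keeping the best tour.  ``exact=True`` runs Held-Karp
    (instances of <= 12 genes).  Deterministic given ``seed``.
    """
    if len(g.families) == 1:
        tour = [g.families[0]]
        return (tour, [tour_cost(g, tour)]) if return_trace else tour
    if exact:
        tour = _exact_tour(g)
        return (tour, [tour_cost(g, tour)]) if return_trace else tour
    rng = np.random.default_rng(seed)
    cand = _candidates(g)
    trace: list[float] = []
    small = len(g.families) <= _EXHAUSTIVE_LIMIT
    if small:
        # rugged little instances need more perturbation rounds; scale with size
        restarts = max(restarts, 6 * len(g.families))

    def polish(t: list[int], tr: Optional[list] = None) -> list[int]:
        if small:
            return _exhaustive_improve(g, t, tr)
        # _improve only realizes candidate junctions rightward of the scan
        # position; improving the flipped tour covers the mirror moves.
        while True:
            before = tour_cost(g, t)
            t = _improve(g, t, cand, tr)
            t = [-s for s in reversed(t)]
            t = _improve(g, t, cand, tr)
            t = [-s for s in reversed(t)]
            if tour_cost(g, t) >= before - 1e-12:
                return t

    tour = _greedy_edge_tour(g)
    trace.append(tour_cost(g, tour))
    tour = polish(tour, trace)
    best, best_cost = list(tour), tour_cost(g, tour)
    for _ in range(restarts):
        if small:
            pert = [int(o) * int(f)
                    for f, o in zip(rng.permutation(g.families),
                                    rng.choice([1, -1], len(g.families)))]
        else:
            pert = _double_bridge(best, rng)
        pert = polish(pert)
        c = tour_cost(g, pert)
        if c < best_cost - 1e-12:
            best, best_cost = pert, c
            trace.append(c)
    return (best, trace) if return_trace else best


# ---------------------------------------------------------------------------
# Chromosome splitting
# ---------------------------------------------------------------------------

@dataclass
class AncestralGenome:
    """A reconstructed ancestor with per-adjacency posterior provenance."""

    node: str
    genome: Genome
    provenance: dict = field(default_factory=dict)


def _priority_class(e, parent_tels, child1_tels, child2_tels) -> Optional[int]:
    in_p = parent_tels is not None and e in parent_tels
    in_c1 = e in child1_tels
    in_c2 = e in child2_tels
    if in_p and in_c1 and in_c2:
        return 1
    if in_c1 and in_c2:
        return 2
    if (int(in_p) + int(in_c1) + int(in_c2)) >= 2:
        return 3
    if in_p:
        return 4
    if in_c1 or in_c2:
        return 5
    return None


def _canonical_chromosome(chrom: list[int]) -> list[int]:
    """Flip so the first family ID is no larger than the last (determinism)."""
    if abs(chrom[0]) > abs(chrom[-1]) or (
        abs(chrom[0]) == abs(chrom[-1]) and chrom[0] < 0
    ):
        return [-x for x in reversed(chrom)]
    return list(chrom)


def split_into_chromosomes(
    tour: list[int],
    parent: Optional[Genome],
    child1: Genome,
    child2: Genome,
    adjacency_probs: Optional[Mapping] = None,
    target_count: Optional[int] = None,
    node_name: str = "ancestor",
) -> AncestralGenome:
    """Cut the opened tour into linear chromosomes by telomere priority.

    The tour arrives already opened at the cap (its two ends are telomeres).
    Additional cuts are introduced at junctions whose created extremities are
    telomeric in the neighboring genomes, highest priority class first, until
    the chromosome count reaches the target (median of the neighbors'
    chromosome counts unless given); ties break on lower adjacency posterior,
    then position.  If candidates run out, the lowest-posterior junctions are
    cut (logged).
    """
    if not tour:
        return AncestralGenome(node_name, Genome(node_name, []), {})
    probs = dict(adjacency_probs or {})

    if target_count is None:
        counts = [g.n_chromosomes for g in (parent, child1, child2) if g is not None]
        target_count = int(math.floor(median(counts) + 0.5))
    target_count = max(1, min(target_count, len(tour)))

    p_tels = telomeric_extremities(parent) if parent is not None else None
    c1_tels = telomeric_extremities(child1)
    c2_tels = telomeric_extremities(child2)

    def junction_prob(i: int) -> float:
        adj = canonical_adjacency(_right_ext(tour[i - 1]), _left_ext(tour[i]))
        return float(probs.get(adj, probs.get(_adj_label_cache(adj), 0.0)))

    def _adj_label_cache(adj):
        from .encoding import adjacency_label
        return adjacency_label(adj)

    ranked = []
    unranked = []
    for i in range(1, len(tour)):
        e1 = _right_ext(tour[i - 1])
        e2 = _left_ext(tour[i])
        cls = [c for c in (
            _priority_class(e1, p_tels, c1_tels, c2_tels),
            _priority_class(e2, p_tels, c1_tels, c2_tels),
        ) if c is not None]
        if cls:
            ranked.append((min(cls), junction_prob(i), i))
        else:
            unranked.append((junction_prob(i), i))
    ranked.sort()
    unranked.sort()

    n_cuts = target_count - 1
    cuts = [i for _, _, i in ranked[:n_cuts]]
    if len(cuts) < n_cuts:
        shortfall = n_cuts - len(cuts)
        extra = [i for _, i in unranked[:shortfall]]
        if extra:
            logger.warning(
                "%s: only %d telomere candidates for %d cuts; "
                "cutting %d lowest-posterior junctions",
                node_name, len(cuts), n_cuts, len(extra),
            )
        cuts.extend(extra)
    cuts = sorted(set(cuts))

    chroms = []
    prev = 0
    for i in cuts + [len(tour)]:
        chroms.append(_canonical_chromosome(tour[prev:i]))
        prev = i
    chroms.sort(key=lambda c: (abs(c[0]), len(c), c))

    genome = Genome(node_name, chroms)
    provenance = {}
    for chrom in chroms:
        for a, b in zip(chrom, chrom[1:]):
            adj = canonical_adjacency(_right_ext(a), _left_ext(b))
            if adj in probs:
                provenance[adj] = float(probs[adj])
    return AncestralGenome(node_name, genome, provenance)


def assemble_ancestor(
    node_name: str,
    families: Iterable[int],
    char_probs: Mapping,
    parent: Optional[Genome],
    child1: Genome,
    child2: Genome,
    seed: int = 0,
    target_count: Optional[int] = None,
    restarts: int = 4,
) -> AncestralGenome:
    """Full assembly of one ancestor: TSP build, tour search, splitting."""
    fams = sorted(set(families))
    if not fams:
        return AncestralGenome(node_name, Genome(node_name, []), {})
    graph = build_tsp(fams, char_probs)
    tour = solve_tour(graph, seed=seed, restarts=restarts)
    return split_into_chromosomes(
        tour, parent, child1, child2,
        adjacency_probs=graph.adj_probs,
        target_count=target_count,
        node_name=node_name,
    )
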