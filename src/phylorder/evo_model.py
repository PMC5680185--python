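"""Two-state evolutionary model over gene/adjacency presence, and DCJ counting.

Under a double-cut-and-join (DCJ) view of rearrangement, every event removes
two adjacencies and creates two new ones among the 2n+2 available gene ends.
A genome with n genes and C chromosomes carries n + C adjacencies (counting
telomeric ones), out of C(2n+2, 2) possible pairs of ends, which yields the
per-adjacency loss and gain probability estimates implemented here.  The
presence/absence of each character then evolves as an asymmetric two-state
continuous-time Markov chain with loss rate lambda and gain rate mu.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genome_io import Genome
from .encoding import gene_extremities

__all__ = [
    "EventRates",
    "EventBreakdown",
    "adjacency_loss_prob",
    "adjacency_gain_prob",
    "transition_matrix",
    "stationary_distribution",
    "dcj_distance",
    "event_breakdown",
    "exemplar_reduction",
]


@dataclass(frozen=True)
class EventRates:
    """Expected numbers of events for a lineage, plus its genome dimensions.

    R: rearrangements, D: duplications, I: insertions, d: deletions;
    n: gene count, C: chromosome count.
    """

    R: float
    D: float
    I: float
    d: float
    n: int
    C: int = 1

    def __post_init__(self) -> None:
        if min(self.R, self.D, self.I, self.d) < 0:
            raise ValueError("event counts must be non-negative")
        if self.n < 1 or self.C < 1:
            raise ValueError("need n >= 1 genes and C >= 1 chromosomes")

    @property
    def total_events(self) -> float:
        return self.R + self.D + self.I + self.d


def adjacency_loss_prob(er: EventRates) -> float:
    """Probability that a given adjacency is lost: 2(R+D+I+d) / (n + C).

    A genome holds n + C adjacencies (telomeric included) and each event
    removes two of them.
    """
    p = 2.0 * er.total_events / (er.n + er.C)
    return min(max(p, 0.0), 1.0)


def adjacency_gain_prob(er: EventRates) -> float:
    """Probability that a given absent adjacency is gained.

    Each event creates two new adjacencies among C(2n+2, 2) possible pairs
    of the 2n gene ends plus two fresh telomeres.
    """
    pairs = (2 * er.n + 2) * (2 * er.n + 1) / 2.0
    p = 2.0 * er.total_events / pairs
    return min(max(p, 0.0), 1.0)


def stationary_distribution(loss_rate: float, gain_rate: float) -> np.ndarray:
    """Stationary frequencies (pi_absent, pi_present) of the two-state chain."""
    s = loss_rate + gain_rate
    return np.array([loss_rate / s, gain_rate / s])


def transition_matrix(loss_rate: float, gain_rate: float, t: float) -> np.ndarray:
    """2x2 transition matrix T(t) over states {0 absent, 1 present}.

    Continuous-time chain with gain rate mu (0->1) and loss rate lambda
    (1->0):  P(1->0; t) = lam/(lam+mu) (1 - exp(-(lam+mu) t)), and
    symmetrically for gains.  T(0) is the identity; as t -> inf the rows
    approach the stationary distribution.
    """
    if loss_rate <= 0 or gain_rate <= 0:
        raise ValueError("rates must be positive")
    if t < 0:
        raise ValueError("branch length must be non-negative")
    lam, mu = loss_rate, gain_rate
    s = lam + mu
    e = math.exp(-s * t)
    p01 = (mu / s) * (1.0 - e)
    p10 = (lam / s) * (1.0 - e)
    return np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])


# ---------------------------------------------------------------------------
# DCJ distance
# ---------------------------------------------------------------------------

def exemplar_reduction(g: Genome, keep: set[int] | None = None) -> Genome:
    """Keep the first occurrence of each family (scan order), drop the rest.

    Optionally also restrict to the families in ``keep``.  Chromosomes that
    end up empty are dropped.
    """
    seen: set[int] = set()
    chroms: list[list[int]] = []
    for chrom in g.chromosomes:
        cur: list[int] = []
        for x in chrom:
            f = abs(x)
            if f in seen or (keep is not None and f not in keep):
                continue
            seen.add(f)
            cur.append(x)
        if cur:
            chroms.append(cur)
    return Genome(g.name, chroms)


def _reduce_pair(a: Genome, b: Genome) -> tuple[Genome, Genome, set[int]]:
    shared = a.families() & b.families()
    if not shared:
        raise ValueError("genomes share no gene content")
    ra = exemplar_reduction(a, keep=shared)
    rb = exemplar_reduction(b, keep=shared)
    return ra, rb, shared


def _adjacency_vertices(g: Genome) -> tuple[list, dict]:
    """Vertices of one genome's side of the adjacency graph.

    Each adjacency {p, q} is one vertex; each telomere is a singleton vertex.
    Returns (vertices, extremity -> vertex index).
    """
    verts: list = []
    ext_to_v: dict = {}

    def new_vertex(exts) -> None:
        idx = len(verts)
        verts.append(exts)
        for e in exts:
            ext_to_v[e] = idx

    for chrom in g.chromosomes:
        new_vertex((gene_extremities(chrom[0])[0],))  # left telomere
        for x, y in zip(chrom, chrom[1:]):
            new_vertex((gene_extremities(x)[1], gene_extremities(y)[0]))
        new_vertex((gene_extremities(chrom[-1])[1],))  # right telomere
    return verts, ext_to_v


def dcj_distance(a: Genome, b: Genome) -> int:
    """DCJ distance N - (cycles + odd_paths/2) on the adjacency graph.

    Computed on the shared gene content after exemplar duplicate reduction.
    Zero iff the reduced genomes have identical gene orders.
    """
    ra, rb, shared = _reduce_pair(a, b)
    n = len(shared)

    verts_a, ext_a = _adjacency_vertices(ra)
    verts_b, ext_b = _adjacency_vertices(rb)

    seen_a = [False] * len(verts_a)
    seen_b = [False] * len(verts_b)
    cycles = 0
    odd_paths = 0

    for start in range(len(verts_a)):
        if seen_a[start]:
            continue
        # Walk the component containing A-vertex `start`.  Edges of the
        # adjacency graph join an A-vertex and a B-vertex per shared
        # extremity, so the edge count equals the number of distinct
        # extremities carried by the component's vertices.
        seen_a[start] = True
        comp = [("A", start)]
        frontier = [("A", start)]
        while frontier:
            side, v = frontier.pop()
            exts = verts_a[v] if side == "A" else verts_b[v]
            other_map = ext_b if side == "A" else ext_a
            other_seen = seen_b if side == "A" else seen_a
            for e in exts:
                w = other_map[e]
                if not other_seen[w]:
                    other_seen[w] = True
                    nxt = ("B" if side == "A" else "A", w)
                    comp.append(nxt)
                    frontier.append(nxt)
        exts_in_comp: set = set()
        for side, v in comp:
            exts_in_comp.update(verts_a[v] if side == "A" else verts_b[v])
        n_edges = len(exts_in_comp)
        if n_edges == len(comp):  # every vertex has degree 2: a cycle
            cycles += 1
        elif n_edges % 2 == 1:  # path with an odd number of edges
            odd_paths += 1

    return n - cycles - odd_paths // 2


@dataclass(frozen=True)
class EventBreakdown:
    """Decomposition of the divergence between two genomes."""

    rearrangements: int
    gene_losses: int
    gene_gains: int

    @property
    def total(self) -> int:
        return self.rearrangements + self.gene_losses + self.gene_gains


def event_breakdown(a: Genome, b: Genome) -> EventBreakdown:
    """Rearrangements (DCJ on shared content) plus content gains/losses a -> b."""
    fam_a, fam_b = a.families(), b.families()
    return EventBreakdown(
        rearrangements=dcj_distance(a, b),
        gene_losses=len(fam_a - fam_b),
        gene_gains=len(fam_b - fam_a),
    )
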