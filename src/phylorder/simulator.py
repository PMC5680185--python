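"""Ground-truthed genome evolution simulator.

A random binary tree is drawn, a root genome (identity gene order split
evenly into chromosomes) is placed at a designated internal node, and
genomes evolve outward along every edge: events are sampled from a
configurable mix (inversion, translocation, fusion, fission, deletion,
insertion, duplication, optional whole-genome duplication on chosen edges)
until the realized number of gene-adjacency changes on the edge reaches a
budget drawn uniformly from a configured interval.  Adjacency change is
counted as the symmetric difference of the telomere-inclusive adjacency
sets before and after each event, maintained incrementally so full-size
simulations stay cheap.

Every intermediate ancestor genome and every applied event is recorded, so
reconstructions can be scored against exact ground truth and leaves can be
re-derived by replaying the log.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .genome_io import Genome, GenomeSet, PhyloTree
from .encoding import TELOMERE, canonical_adjacency, gene_extremities

__all__ = [
    "SimConfig",
    "SimResult",
    "EventRecord",
    "random_tree",
    "apply_event",
    "apply_move",
    "evolve",
]

DEFAULT_EVENT_MIX = {
    "inversion": 0.70,
    "translocation": 0.10,
    "fusion": 0.02,
    "fission": 0.02,
    "deletion": 0.08,
    "insertion": 0.04,
    "duplication": 0.04,
}


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Defaults follow the reference protocol: 20 genomes, a start genome of
    5,000 genes on 8 chromosomes, and a per-edge adjacency-change budget
    drawn uniformly from [2750, 8250] (a high enough rate that almost no
    adjacency survives across the whole tree).  Segment lengths for
    inversions, deletions, insertions and duplications are geometric with
    mean ``segment_mean``, truncated at ``max_segment``.
    """

    n_taxa: int = 20
    n_genes: int = 5000
    n_chromosomes: int = 8
    adjacency_changes_per_edge: tuple[int, int] = (2750, 8250)
    event_mix: dict = field(default_factory=lambda: dict(DEFAULT_EVENT_MIX))
    segment_mean: float = 5.0
    max_segment: int = 50
    wgd_edges: frozenset = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.adjacency_changes_per_edge
        if lo > hi or lo < 0:
            raise ValueError("invalid adjacency-change interval")
        if self.n_taxa < 3 or self.n_genes < 1 or self.n_chromosomes < 1:
            raise ValueError("invalid genome/tree dimensions")
        w = self.event_mix
        if any(x < 0 for x in w.values()):
            raise ValueError("event weights must be non-negative")
        total = sum(w.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("event weights must sum to 1")
        unknown = set(w) - set(DEFAULT_EVENT_MIX)
        if unknown:
            raise ValueError(f"unknown event kinds: {sorted(unknown)}")


@dataclass
class EventRecord:
    edge: tuple[str, str]  # (parent name, child name)
    kind: str
    move: tuple
    changes: int


@dataclass
class SimResult:
    tree: PhyloTree              # true branch lengths = realized changes
    leaves: GenomeSet
    ancestors: dict              # internal node name -> true Genome
    root_name: str
    events: list
    config: SimConfig


# ---------------------------------------------------------------------------
# Random topology
# ---------------------------------------------------------------------------

def random_tree(n_taxa: int, seed: int = 0) -> PhyloTree:
    """Uniform-attachment random unrooted binary tree.

    Starts from the 3-leaf star and attaches each further leaf to an edge
    chosen uniformly at random.  Leaves are named S1..Sn, internal nodes
    A1..A(n-2) in construction order.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    t = PhyloTree()
    center = t.add_node("A1")
    for i in range(1, 4):
        leaf = t.add_node(f"S{i}")
        t.add_edge(center, leaf)
    next_internal = 2
    for i in range(4, n_taxa + 1):
        edges = t.edges()
        u, v = edges[rng.integers(0, len(edges))]
        mid = t.add_node(f"A{next_internal}")
        next_internal += 1
        t.remove_edge(u, v)
        t.add_edge(u, mid)
        t.add_edge(mid, v)
        leaf = t.add_node(f"S{i}")
        t.add_edge(mid, leaf)
    return t


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------
# A move is a concrete, replayable event: ("inversion", chrom, i, j), etc.
# _boundary(chrom, i) is the adjacency spanning positions i-1 / i, telomeric
# at the chromosome ends.

def _boundary(chrom: list[int], i: int):
    if i == 0:
        return canonical_adjacency(gene_extremities(chrom[0])[0], TELOMERE)
    if i == len(chrom):
        return canonical_adjacency(gene_extremities(chrom[-1])[1], TELOMERE)
    return canonical_adjacency(
        gene_extremities(chrom[i - 1])[1], gene_extremities(chrom[i])[0]
    )


def _internal_adjs(genes: list[int]) -> list:
    return [
        canonical_adjacency(gene_extremities(a)[1], gene_extremities(b)[0])
        for a, b in zip(genes, genes[1:])
    ]


def genome_adjacency_counter(chroms: list[list[int]]) -> Counter:
    """Telomere-inclusive adjacency multiset of a genome."""
    c: Counter = Counter()
    for chrom in chroms:
        c[_boundary(chrom, 0)] += 1
        c[_boundary(chrom, len(chrom))] += 1
        for a in _internal_adjs(chrom):
            c[a] += 1
    return c


def _sample_segment_length(rng, cfg: SimConfig, limit: int) -> int:
    length = int(rng.geometric(1.0 / cfg.segment_mean))
    return max(1, min(length, cfg.max_segment, limit))


def sample_move(chroms: list[list[int]], kind: str, rng,
                cfg: SimConfig, next_family: int) -> Optional[tuple]:
    """Draw a concrete move of the given kind, or None if inapplicable."""
    sizes = np.array([len(c) for c in chroms], dtype=float)
    n_total = int(sizes.sum())

    def pick_chrom() -> int:
        return int(rng.choice(len(chroms), p=sizes / sizes.sum()))

    if kind == "inversion":
        c = pick_chrom()
        L = _sample_segment_length(rng, cfg, len(chroms[c]))
        i = int(rng.integers(0, len(chroms[c]) - L + 1))
        return ("inversion", c, i, i + L)

    if kind == "translocation":
        if len(chroms) < 2:
            return None
        c1, c2 = rng.choice(len(chroms), size=2, replace=False)
        c1, c2 = int(c1), int(c2)
        # cut points chosen so neither product is empty
        for _ in range(10):
            i1 = int(rng.integers(0, len(chroms[c1]) + 1))
            i2 = int(rng.integers(0, len(chroms[c2]) + 1))
            if 0 < i1 + (len(chroms[c2]) - i2) and 0 < i2 + (len(chroms[c1]) - i1):
                return ("translocation", c1, c2, i1, i2)
        return None

    if kind == "fusion":
        if len(chroms) < 2:
            return None
        c1, c2 = rng.choice(len(chroms), size=2, replace=False)
        flip = bool(rng.integers(0, 2))
        return ("fusion", int(c1), int(c2), flip)

    if kind == "fission":
        eligible = [i for i, c in enumerate(chroms) if len(c) >= 2]
        if not eligible:
            return None
        c = int(rng.choice(eligible))
        i = int(rng.integers(1, len(chroms[c])))
        return ("fission", c, i)

    if kind == "deletion":
        c = pick_chrom()
        L = _sample_segment_length(rng, cfg, len(chroms[c]))
        if L >= n_total:  # never empty the genome
            return None
        i = int(rng.integers(0, len(chroms[c]) - L + 1))
        return ("deletion", c, i, i + L)

    if kind == "insertion":
        c = pick_chrom()
        L = _sample_segment_length(rng, cfg, cfg.max_segment)
        i = int(rng.integers(0, len(chroms[c]) + 1))
        genes = [
            int(s) * (next_family + k)
            for k, s in enumerate(rng.choice([1, -1], size=L))
        ]
        return ("insertion", c, i, tuple(genes))

    if kind == "duplication":
        c = pick_chrom()
        L = _sample_segment_length(rng, cfg, len(chroms[c]))
        i = int(rng.integers(0, len(chroms[c]) - L + 1))
        for _ in range(10):
            c2 = pick_chrom()
            k = int(rng.integers(0, len(chroms[c2]) + 1))
            if c2 != c or k <= i or k >= i + L:
                return ("duplication", c, i, i + L, c2, k)
        return None

    if kind == "wgd":
        return ("wgd",)

    raise ValueError(f"unknown event kind {kind!r}")


def apply_move(chroms: list[list[int]], move: tuple) -> tuple[list, list]:
    """Apply a move in place; return (removed, added) local adjacency lists.

    The two lists are the exact multiset delta of the genome's
    telomere-inclusive adjacency multiset, computed from the touched
    neighborhood only.
    """
    kind = move[0]

    if kind == "inversion":
        _, c, i, j = move
        ch = chroms[c]
        removed = [_boundary(ch, i), _boundary(ch, j)]
        ch[i:j] = [-x for x in reversed(ch[i:j])]
        added = [_boundary(ch, i), _boundary(ch, j)]
        return removed, added

    if kind == "translocation":
        _, c1, c2, i1, i2 = move
        ch1, ch2 = chroms[c1], chroms[c2]
        removed = [_boundary(ch1, i1), _boundary(ch2, i2)]
        new1 = ch1[:i1] + ch2[i2:]
        new2 = ch2[:i2] + ch1[i1:]
        chroms[c1] = new1
        chroms[c2] = new2
        added = [_boundary(new1, i1), _boundary(new2, i2)]
        return removed, added

    if kind == "fusion":
        _, c1, c2, flip = move
        ch2 = [-x for x in reversed(chroms[c2])] if flip else chroms[c2]
        removed = [_boundary(chroms[c1], len(chroms[c1])), _boundary(ch2, 0)]
        joined = chroms[c1] + ch2
        added = [_boundary(joined, len(chroms[c1]))]
        chroms[c1] = joined
        del chroms[c2]
        return removed, added

    if kind == "fission":
        _, c, i = move
        ch = chroms[c]
        removed = [_boundary(ch, i)]
        left, right = ch[:i], ch[i:]
        chroms[c] = left
        chroms.append(right)
        added = [_boundary(left, len(left)), _boundary(right, 0)]
        return removed, added

    if kind == "deletion":
        _, c, i, j = move
        ch = chroms[c]
        seg = ch[i:j]
        # boundary(ch, i) spans i-1/i, boundary(ch, j) spans j-1/j, and the
        # segment's internal adjacencies span i..j-1: j-i+1 removals in all
        removed = [_boundary(ch, i)] + _internal_adjs(seg) + [_boundary(ch, j)]
        del ch[i:j]
        if ch:
            added = [_boundary(ch, i)]
        else:
            added = []
            del chroms[c]
        return removed, added

    if kind == "insertion":
        _, c, i, genes = move
        ch = chroms[c]
        removed = [_boundary(ch, i)]
        ch[i:i] = list(genes)
        added = ([_boundary(ch, i)] + _internal_adjs(list(genes))
                 + [_boundary(ch, i + len(genes))])
        return removed, added

    if kind == "duplication":
        _, c, i, j, c2, k = move
        seg = list(chroms[c][i:j])
        ch2 = chroms[c2]
        removed = [_boundary(ch2, k)]
        ch2[k:k] = seg
        added = ([_boundary(ch2, k)] + _internal_adjs(seg)
                 + [_boundary(ch2, k + len(seg))])
        return removed, added

    if kind == "wgd":
        chroms.extend([list(c) for c in chroms])
        return [], []  # set-level adjacency content unchanged

    raise ValueError(f"unknown move {move!r}")


def _count_changes(counter: Counter, removed: list, added: list) -> int:
    """Update the adjacency multiset; return the adjacency-*set* symmetric
    difference this delta causes (0 <-> nonzero transitions)."""
    delta: Counter = Counter(added)
    delta.subtract(removed)
    changes = 0
    for adj, d in delta.items():
        if d == 0:
            continue
        before = counter[adj]
        after = before + d
        if (before == 0) != (after == 0):
            changes += 1
        if after:
            counter[adj] = after
        else:
            del counter[adj]
    return changes


def apply_event(g: Genome, kind: str, rng, cfg: Optional[SimConfig] = None,
                next_family: Optional[int] = None) -> tuple[Genome, int]:
    """Public single-event interface: returns (new genome, adjacency changes).

    The change count is the symmetric difference of the telomere-inclusive
    adjacency sets before and after.  Inapplicable events raise ValueError.
    """
    cfg = cfg or SimConfig()
    chroms = [list(c) for c in g.chromosomes]
    if next_family is None:
        next_family = max(g.families(), default=0) + 1
    move = sample_move(chroms, kind, rng, cfg, next_family)
    if move is None:
        raise ValueError(f"event {kind!r} not applicable to this genome")
    before = set(genome_adjacency_counter(chroms))
    apply_move(chroms, move)
    after = set(genome_adjacency_counter(chroms))
    return Genome(g.name, chroms), len(before ^ after)


# ---------------------------------------------------------------------------
# Evolution along the tree
# ---------------------------------------------------------------------------

def _root_genome(cfg: SimConfig) -> list[list[int]]:
    n, C = cfg.n_genes, cfg.n_chromosomes
    base, extra = divmod(n, C)
    chroms = []
    g = 1
    for i in range(C):
        size = base + (1 if i < extra else 0)
        chroms.append(list(range(g, g + size)))
        g += size
    return [c for c in chroms if c]


def evolve(cfg: SimConfig) -> SimResult:
    """Simulate a full dataset; deterministic given ``cfg.seed``.

    Returns the true tree (branch lengths = realized adjacency changes per
    edge), leaf genomes, every true ancestral genome, and the replayable
    event log.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = random_tree(cfg.n_taxa, seed=int(rng.integers(0, 2**31 - 1)))
    root = tree.node_by_name("A1")

    kinds = sorted(cfg.event_mix)
    weights = np.array([cfg.event_mix[k] for k in kinds])
    weights = weights / weights.sum()
    lo, hi = cfg.adjacency_changes_per_edge

    genomes: dict[int, list[list[int]]] = {root: _root_genome(cfg)}
    counters: dict[int, Counter] = {root: genome_adjacency_counter(genomes[root])}
    next_family = cfg.n_genes + 1
    events: list[EventRecord] = []

    order = tree.postorder(root)[::-1]  # parents before children
    for node, parent in order:
        if parent is None:
            continue
        chroms = [list(c) for c in genomes[parent]]
        counter = Counter(counters[parent])
        edge_name = (tree.names.get(parent, str(parent)), tree.names.get(node, str(node)))
        realized = 0
        if tree.edge_key(parent, node) in cfg.wgd_edges or edge_name in cfg.wgd_edges:
            removed, added = apply_move(chroms, ("wgd",))
            realized += _count_changes(counter, removed, added)
            events.append(EventRecord(edge_name, "wgd", ("wgd",), 0))
        budget = int(rng.integers(lo, hi + 1))
        guard = 0
        max_iter = 1000 + 100 * (budget + 1)
        while realized < budget:
            guard += 1
            if guard > max_iter:
                raise RuntimeError("event sampling failed to meet the budget")
            kind = kinds[int(rng.choice(len(kinds), p=weights))]
            move = sample_move(chroms, kind, rng, cfg, next_family)
            if move is None:
                continue
            if move[0] == "insertion":
                next_family += len(move[3])
            removed, added = apply_move(chroms, move)
            changes = _count_changes(counter, removed, added)
            realized += changes
            events.append(EventRecord(edge_name, kind, move, changes))
        tree.set_length(parent, node, float(realized))
        genomes[node] = chroms
        counters[node] = counter

    leaf_genomes = []
    ancestors = {}
    for v in tree.nodes:
        name = tree.names[v]
        g = Genome(name, [list(c) for c in genomes[v]])
        if tree.is_leaf(v):
            leaf_genomes.append(g)
        else:
            ancestors[name] = g
    leaf_genomes.sort(key=lambda g: g.name)
    return SimResult(
        tree=tree,
        leaves=GenomeSet(leaf_genomes),
        ancestors=ancestors,
        root_name="A1",
        events=events,
        config=cfg,
    )
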