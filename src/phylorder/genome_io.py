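"""Gene-order genomes and phylogenetic trees: containers and file dialects.

Genomes are read and written in the GRIMM dialect (``>name`` header lines,
whitespace-separated signed integers, ``$`` terminating each linear
chromosome), the de facto interchange format of rearrangement tools.  Trees
use Newick; parsing is delegated to dendropy, writing is done here so the
canonical form is under our control.

All downstream modules consume only the types defined here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from collections import Counter
from typing import Iterable, Iterator, Optional

import dendropy

__all__ = [
    "Genome",
    "GenomeSet",
    "PhyloTree",
    "GenomeParseError",
    "TreeParseError",
    "read_gene_orders",
    "write_gene_orders",
    "read_newick",
    "write_newick",
]


class GenomeParseError(ValueError):
    """Raised on malformed gene-order input; message names the line."""


class TreeParseError(ValueError):
    """Raised on malformed Newick input."""


@dataclass
class Genome:
    """A named set of linear chromosomes of signed homology-family IDs.

    The sign of an ID encodes the reading strand.  Family IDs may repeat
    (duplicated genes); an ID of 0 is forbidden.
    """

    name: str
    chromosomes: list[list[int]]

    def __post_init__(self) -> None:
        for chrom in self.chromosomes:
            if not chrom:
                raise ValueError(f"genome {self.name!r}: empty chromosome")
            for g in chrom:
                if g == 0:
                    raise ValueError(f"genome {self.name!r}: family ID 0 is not allowed")

    def families(self) -> set[int]:
        """Set of unsigned family IDs present (any copy number)."""
        return {abs(g) for chrom in self.chromosomes for g in chrom}

    def family_counts(self) -> Counter:
        return Counter(abs(g) for chrom in self.chromosomes for g in chrom)

    @property
    def n_genes(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def copy(self, name: Optional[str] = None) -> "Genome":
        return Genome(name or self.name, [list(c) for c in self.chromosomes])


class GenomeSet:
    """Ordered collection of uniquely named genomes."""

    def __init__(self, genomes: Iterable[Genome]):
        self._genomes: dict[str, Genome] = {}
        for g in genomes:
            if g.name in self._genomes:
                raise ValueError(f"duplicate taxon name {g.name!r}")
            self._genomes[g.name] = g

    @property
    def names(self) -> list[str]:
        return list(self._genomes)

    @property
    def family_universe(self) -> set[int]:
        u: set[int] = set()
        for g in self._genomes.values():
            u |= g.families()
        return u

    def __iter__(self) -> Iterator[Genome]:
        return iter(self._genomes.values())

    def __len__(self) -> int:
        return len(self._genomes)

    def __getitem__(self, name: str) -> Genome:
        return self._genomes[name]

    def __contains__(self, name: str) -> bool:
        return name in self._genomes


# ---------------------------------------------------------------------------
# GRIMM dialect
# ---------------------------------------------------------------------------

def read_gene_orders(path) -> GenomeSet:
    """Parse a GRIMM-style gene-order file into a :class:`GenomeSet`.

    Every ``$``-terminated run of signed integers becomes one linear
    chromosome; order and signs are preserved exactly.  Lines starting with
    ``#`` are comments.  Malformed tokens, duplicate taxon names and empty
    genomes raise :class:`GenomeParseError` naming the offending line.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()

    genomes: list[Genome] = []
    seen: set[str] = set()
    name: Optional[str] = None
    chroms: list[list[int]] = []
    current: list[int] = []

    def flush(lineno: int) -> None:
        nonlocal name, chroms, current
        if name is None:
            return
        if current:
            raise GenomeParseError(
                f"line {lineno}: genome {name!r} has an unterminated chromosome "
                "(missing '$')"
            )
        if not chroms:
            raise GenomeParseError(f"line {lineno}: genome {name!r} is empty")
        if name in seen:
            raise GenomeParseError(f"line {lineno}: duplicate taxon name {name!r}")
        seen.add(name)
        genomes.append(Genome(name, chroms))
        name, chroms, current = None, [], []

    lineno = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush(lineno)
            name = line[1:].strip()
            if not name:
                raise GenomeParseError(f"line {lineno}: header with no taxon name")
            continue
        if name is None:
            raise GenomeParseError(f"line {lineno}: gene data before any '>' header")
        for tok in line.split():
            if tok == "$":
                if not current:
                    raise GenomeParseError(f"line {lineno}: '$' terminating an empty chromosome")
                chroms.append(current)
                current = []
            else:
                try:
                    g = int(tok)
                except ValueError:
                    raise GenomeParseError(f"line {lineno}: malformed token {tok!r}") from None
                if g == 0:
                    raise GenomeParseError(f"line {lineno}: family ID 0 is not allowed")
                current.append(g)
    flush(lineno + 1)
    return GenomeSet(genomes)


def write_gene_orders(gs: GenomeSet | Iterable[Genome], path) -> None:
    """Write genomes in canonical GRIMM form.

    Canonical form: genomes sorted by name, one chromosome per line,
    genes space-separated, each line terminated by ``$``.
    """
    genomes = sorted(gs, key=lambda g: g.name)
    buf = io.StringIO()
    for g in genomes:
        buf.write(f">{g.name}\n")
        for chrom in g.chromosomes:
            buf.write(" ".join(str(x) for x in chrom) + " $\n")
    data = buf.getvalue()
    if hasattr(path, "write"):
        path.write(data)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(data)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class PhyloTree:
    """Unrooted (or rooted) phylogenetic tree with branch lengths and supports.

    Nodes are integer IDs.  Leaves carry taxon labels; internal nodes may be
    named (ancestor labels).  A tree is *rooted* when :attr:`root` is set to a
    degree-2 node; otherwise it is treated as unrooted and binary means every
    internal node has degree 3.

    The structure is a plain adjacency map, which keeps re-rooting, NNI
    rearrangement and bipartition extraction straightforward.
    """

    def __init__(self) -> None:
        self._adj: dict[int, list[int]] = {}
        self.names: dict[int, str] = {}
        self.lengths: dict[tuple[int, int], Optional[float]] = {}
        self.supports: dict[tuple[int, int], float] = {}
        self.root: Optional[int] = None
        self._next_id = 0

    # -- construction ------------------------------------------------------

    def add_node(self, name: Optional[str] = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self._adj[nid] = []
        if name is not None:
            self.names[nid] = name
        return nid

    @staticmethod
    def edge_key(u: int, v: int) -> tuple[int, int]:
        return (u, v) if u < v else (v, u)

    def add_edge(self, u: int, v: int, length: Optional[float] = None) -> None:
        if v in self._adj[u]:
            raise ValueError("edge already present")
        self._adj[u].append(v)
        self._adj[v].append(u)
        self.lengths[self.edge_key(u, v)] = length

    def remove_edge(self, u: int, v: int) -> None:
        self._adj[u].remove(v)
        self._adj[v].remove(u)
        self.lengths.pop(self.edge_key(u, v), None)
        self.supports.pop(self.edge_key(u, v), None)

    def remove_node(self, v: int) -> None:
        for nbr in list(self._adj[v]):
            self.remove_edge(v, nbr)
        del self._adj[v]
        self.names.pop(v, None)

    # -- inspection --------------------------------------------------------

    @property
    def nodes(self) -> list[int]:
        return list(self._adj)

    def neighbors(self, v: int) -> list[int]:
        return list(self._adj[v])

    def degree(self, v: int) -> int:
        return len(self._adj[v])

    def is_leaf(self, v: int) -> bool:
        return len(self._adj[v]) <= 1

    def leaves(self) -> list[int]:
        return sorted((v for v in self._adj if self.is_leaf(v)),
                      key=lambda v: self.names.get(v, str(v)))

    def leaf_names(self) -> list[str]:
        return [self.names[v] for v in self.leaves()]

    def internal_nodes(self) -> list[int]:
        return sorted(v for v in self._adj if not self.is_leaf(v))

    def edges(self) -> list[tuple[int, int]]:
        return sorted(self.lengths)

    def internal_edges(self) -> list[tuple[int, int]]:
        return [e for e in self.edges()
                if not self.is_leaf(e[0]) and not self.is_leaf(e[1])]

    def length(self, u: int, v: int) -> Optional[float]:
        return self.lengths[self.edge_key(u, v)]

    def set_length(self, u: int, v: int, t: float) -> None:
        self.lengths[self.edge_key(u, v)] = t

    def node_by_name(self, name: str) -> int:
        for v, n in self.names.items():
            if n == name:
                return v
        raise KeyError(name)

    def is_binary(self) -> bool:
        for v in self._adj:
            d = len(self._adj[v])
            if d == 1:
                continue
            if self.root is not None and v == self.root:
                if d != 2:
                    return False
            elif d != 3:
                return False
        return True

    def copy(self) -> "PhyloTree":
        t = PhyloTree()
        t._adj = {v: list(nbrs) for v, nbrs in self._adj.items()}
        t.names = dict(self.names)
        t.lengths = dict(self.lengths)
        t.supports = dict(self.supports)
        t.root = self.root
        t._next_id = self._next_id
        return t

    # -- traversal ---------------------------------------------------------

    def postorder(self, root: int) -> list[tuple[int, Optional[int]]]:
        """(node, parent) pairs, children strictly before parents."""
        out: list[tuple[int, Optional[int]]] = []
        stack: list[tuple[int, Optional[int]]] = [(root, None)]
        while stack:
            v, p = stack.pop()
            out.append((v, p))
            for nbr in self._adj[v]:
                if nbr != p:
                    stack.append((nbr, v))
        out.reverse()
        return out

    def side_leaves(self, u: int, v: int) -> frozenset[str]:
        """Leaf labels on the *v* side of edge (u, v)."""
        labels = []
        stack = [(v, u)]
        while stack:
            node, parent = stack.pop()
            if self.is_leaf(node):
                labels.append(self.names[node])
            for nbr in self._adj[node]:
                if nbr != parent:
                    stack.append((nbr, node))
        return frozenset(labels)

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, canonicalized as the side *not* containing
        the lexicographically smallest taxon."""
        ref = min(self.leaf_names())
        out = set()
        for u, v in self.internal_edges():
            side = self.side_leaves(u, v)
            if ref in side:
                side = frozenset(self.leaf_names()) - side
            if 1 < len(side) < len(self.leaf_names()) - 1:
                out.add(side)
        return out

    def unroot(self) -> "PhyloTree":
        """Return a copy with a degree-2 root spliced out (no-op if unrooted)."""
        t = self.copy()
        if t.root is None:
            return t
        r = t.root
        if t.degree(r) == 2:
            a, b = t.neighbors(r)
            la = t.length(r, a)
            lb = t.length(r, b)
            length = None if la is None and lb is None else (la or 0.0) + (lb or 0.0)
            t.remove_node(r)
            t.add_edge(a, b, length)
        t.root = None
        return t

    # -- Newick ------------------------------------------------------------

    @classmethod
    def parse_newick(cls, text: str) -> "PhyloTree":
        try:
            dt = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeParseError(f"invalid Newick: {exc}") from exc
        t = cls()
        ids: dict = {}
        for node in dt.preorder_node_iter():
            label = None
            support = None
            if node.taxon is not None:
                label = node.taxon.label
            elif node.label is not None:
                try:
                    support = float(node.label)
                except ValueError:
                    label = node.label
            ids[node] = t.add_node(label)
            if node.parent_node is not None:
                length = node.edge.length
                if length is not None and length < 0:
                    raise TreeParseError("negative branch length")
                t.add_edge(ids[node.parent_node], ids[node], length)
                if support is not None:
                    t.supports[t.edge_key(ids[node.parent_node], ids[node])] = support
        seed = ids[dt.seed_node]
        t.root = seed if t.degree(seed) == 2 else None
        names = set()
        for leaf in t.leaves():
            if leaf not in t.names:
                raise TreeParseError("unlabeled leaf")
            if t.names[leaf] in names:
                raise TreeParseError(f"duplicate leaf label {t.names[leaf]!r}")
            names.add(t.names[leaf])
        return t

    def newick(self, include_supports: bool = False,
               include_internal_names: bool = False,
               precision: int = 10) -> str:
        if self.root is not None:
            base = self.root
        else:
            internals = self.internal_nodes()
            base = internals[0] if internals else self.leaves()[0]

        def fmt(node: int, parent: Optional[int]) -> str:
            children = [n for n in self._adj[node] if n != parent]
            if not children:
                s = self.names.get(node, "")
            else:
                inner = ",".join(fmt(c, node) for c in children)
                label = ""
                if parent is not None and include_supports:
                    sup = self.supports.get(self.edge_key(parent, node))
                    if sup is not None:
                        label = f"{sup:g}"
                if not label and include_internal_names:
                    label = self.names.get(node, "")
                s = f"({inner}){label}"
            if parent is not None:
                t = self.lengths[self.edge_key(parent, node)]
                if t is not None:
                    s += f":{t:.{precision}g}"
            return s

        return fmt(base, None) + ";"


def read_newick(path, require_binary: bool = False) -> PhyloTree:
    """Read a Newick tree; optionally reject non-binary topologies."""
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    t = PhyloTree.parse_newick(text)
    if require_binary and not t.is_binary():
        raise TreeParseError("tree is not binary")
    return t


def write_newick(tree: PhyloTree, path, **kwargs) -> None:
    text = tree.newick(**kwargs) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
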