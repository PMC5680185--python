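"""Binary encoding of gene content and gene adjacencies.

Each gene has two extremities: the head (5' end) and the tail (3' end).  Two
consecutive genes on a chromosome form an adjacency between the right
extremity of the first and the left extremity of the second; a signed gene
``+f`` is traversed head->tail and ``-f`` tail->head.  A genome is then fully
described (up to chromosome order) by its adjacency set, and a set of genomes
becomes a binary taxa x characters matrix: one presence column per observed
adjacency and one per gene family.

The canonical extremity order sorts the tail before the head within a family,
which reproduces the conventional column layout of the worked example
(e.g. {1t,2t} before {1t,2h}).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .genome_io import Genome, GenomeSet

__all__ = [
    "HEAD",
    "TAIL",
    "TELOMERE",
    "Extremity",
    "Adjacency",
    "extremity_key",
    "canonical_adjacency",
    "is_telomeric",
    "gene_extremities",
    "genome_to_adjacencies",
    "telomeric_extremities",
    "adjacency_label",
    "content_label",
    "decode_column",
    "BinaryCharacterMatrix",
    "encode",
]

HEAD = "h"
TAIL = "t"

#: Sentinel extremity standing for a chromosome end.
TELOMERE: "Extremity" = (0, "$")

Extremity = tuple  # (family: int, end: str)
Adjacency = tuple  # (Extremity, Extremity), canonical order


def extremity_key(e: Extremity) -> tuple[int, int]:
    """Sort key with tail < head within a family (telomere sorts last)."""
    fam, end = e
    if e == TELOMERE:
        return (1 << 60, 2)
    return (fam, 0 if end == TAIL else 1)


def canonical_adjacency(u: Extremity, v: Extremity) -> Adjacency:
    """Unordered pair in canonical order; a telomere always comes second."""
    if extremity_key(u) <= extremity_key(v):
        return (u, v)
    return (v, u)


def is_telomeric(adj: Adjacency) -> bool:
    return adj[0] == TELOMERE or adj[1] == TELOMERE


def gene_extremities(signed_gene: int) -> tuple[Extremity, Extremity]:
    """(left, right) extremities of a signed gene as laid on the chromosome."""
    f = abs(signed_gene)
    if signed_gene > 0:
        return (f, HEAD), (f, TAIL)
    return (f, TAIL), (f, HEAD)


def genome_to_adjacencies(g: Genome, include_telomeres: bool = False) -> set:
    """Adjacency set of a genome.

    For consecutive signed genes a, b the right extremity of a pairs with the
    left extremity of b.  With ``include_telomeres`` each chromosome also
    contributes two extremity-TELOMERE pairs.
    """
    out: set = set()
    for chrom in g.chromosomes:
        if include_telomeres:
            out.add(canonical_adjacency(gene_extremities(chrom[0])[0], TELOMERE))
            out.add(canonical_adjacency(gene_extremities(chrom[-1])[1], TELOMERE))
        for a, b in zip(chrom, chrom[1:]):
            out.add(canonical_adjacency(gene_extremities(a)[1], gene_extremities(b)[0]))
    return out


def telomeric_extremities(g: Genome) -> set:
    """Extremities sitting at chromosome ends (used by assembly's rules)."""
    out: set = set()
    for chrom in g.chromosomes:
        out.add(gene_extremities(chrom[0])[0])
        out.add(gene_extremities(chrom[-1])[1])
    return out


# ---------------------------------------------------------------------------
# Column labels
# ---------------------------------------------------------------------------

def _ext_str(e: Extremity) -> str:
    if e == TELOMERE:
        return "$"
    return f"{e[0]}{e[1]}"


def adjacency_label(adj: Adjacency) -> str:
    return f"A:{_ext_str(adj[0])}|{_ext_str(adj[1])}"


def content_label(family: int) -> str:
    return f"C:{family}"


def _parse_ext(s: str) -> Extremity:
    if s == "$":
        return TELOMERE
    fam, end = int(s[:-1]), s[-1]
    if end not in (HEAD, TAIL) or fam <= 0:
        raise ValueError(f"bad extremity {s!r}")
    return (fam, end)


def decode_column(label: str) -> Union[Adjacency, int]:
    """Inverse of the column labeling: 'A:1t|2t' -> adjacency, 'C:5' -> family."""
    try:
        kind, rest = label.split(":", 1)
        if kind == "C":
            fam = int(rest)
            if fam <= 0:
                raise ValueError
            return fam
        if kind == "A":
            u, v = rest.split("|")
            return canonical_adjacency(_parse_ext(u), _parse_ext(v))
    except (ValueError, IndexError):
        pass
    raise ValueError(f"unknown column label {label!r}")


# ---------------------------------------------------------------------------
# Character matrix
# ---------------------------------------------------------------------------

@dataclass
class BinaryCharacterMatrix:
    """Taxa x {adjacency, content} presence matrix plus a duplicate side table.

    ``data`` holds adjacency columns first (in canonical label order), then
    content columns (by family ID).  ``duplicate_table`` records copy numbers
    >= 2 only, keyed by (taxon, family).
    """

    taxa: list[str]
    adjacency_columns: list  # list[Adjacency]
    content_columns: list[int]
    data: np.ndarray
    duplicate_table: dict = field(default_factory=dict)

    @property
    def n_adjacency(self) -> int:
        return len(self.adjacency_columns)

    @property
    def n_content(self) -> int:
        return len(self.content_columns)

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    @property
    def column_labels(self) -> list[str]:
        return [adjacency_label(a) for a in self.adjacency_columns] + [
            content_label(f) for f in self.content_columns
        ]

    @property
    def column_classes(self) -> np.ndarray:
        """Per-column class code: 'A' for adjacency, 'C' for content."""
        return np.array(["A"] * self.n_adjacency + ["C"] * self.n_content)

    def row(self, taxon: str) -> np.ndarray:
        return self.data[self.taxa.index(taxon)]

    def adjacencies_of(self, taxon: str) -> set:
        r = self.row(taxon)
        return {a for a, x in zip(self.adjacency_columns, r[: self.n_adjacency]) if x}

    def content_of(self, taxon: str) -> set[int]:
        r = self.row(taxon)[self.n_adjacency:]
        return {f for f, x in zip(self.content_columns, r) if x}

    # -- exports -----------------------------------------------------------

    def to_phylip(self, path) -> None:
        """Relaxed PHYLIP with binary states, for external ML programs."""
        lines = [f"{len(self.taxa)} {self.n_columns}"]
        for i, t in enumerate(self.taxa):
            lines.append(f"{t}  {''.join(str(int(x)) for x in self.data[i])}")
        text = "\n".join(lines) + "\n"
        if hasattr(path, "write"):
            path.write(text)
        else:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.data, index=self.taxa, columns=self.column_labels)
        df.to_csv(path, sep="\t", index_label="taxon")


def encode(gs: GenomeSet, include_telomeres: bool = False) -> BinaryCharacterMatrix:
    """Build the binary character matrix of a genome set.

    Adjacency columns are the union of the genomes' adjacency sets; content
    columns are the family universe.  Column order is the canonical sort of
    the labels, fixed across runs.  Copy numbers >= 2 go to the duplicate
    side table; the presence character stays binary.
    """
    genomes = list(gs)
    if len(genomes) < 2:
        raise ValueError("encode requires at least 2 genomes")

    adj_sets = {g.name: genome_to_adjacencies(g, include_telomeres) for g in genomes}
    adj_union: set = set()
    for s in adj_sets.values():
        adj_union |= s
    adjacency_columns = sorted(
        adj_union, key=lambda a: (extremity_key(a[0]), extremity_key(a[1]))
    )
    content_columns = sorted({f for g in genomes for f in g.families()})

    adj_index = {a: j for j, a in enumerate(adjacency_columns)}
    fam_index = {f: j + len(adjacency_columns) for j, f in enumerate(content_columns)}

    data = np.zeros((len(genomes), len(adjacency_columns) + len(content_columns)),
                    dtype=np.uint8)
    duplicate_table: dict = {}
    for i, g in enumerate(genomes):
        for a in adj_sets[g.name]:
            data[i, adj_index[a]] = 1
        counts = g.family_counts()
        for f, k in counts.items():
            data[i, fam_index[f]] = 1
            if k >= 2:
                duplicate_table[(g.name, f)] = k

    return BinaryCharacterMatrix(
        taxa=[g.name for g in genomes],
        adjacency_columns=adjacency_columns,
        content_columns=content_columns,
        data=data,
        duplicate_table=duplicate_table,
    )
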