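"""Reconstruction metrics: accuracy with FP/FN, non-split adjacencies,
synteny blocks and dot-plot coordinates.

Accuracy is the Jaccard index |G intersect G'| / |G union G'| between the
reconstructed and true sets (gene families for content, telomere-free
adjacencies for gene order), with FP = reconstructed-only and FN =
missed-true counts.  Synteny blocks are maximal runs of two or more
single-copy genes with identical order and relative orientation in two
genomes (a reversed, sign-flipped run counts as one reversed block).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .genome_io import Genome, GenomeSet
from .encoding import canonical_adjacency, gene_extremities, genome_to_adjacencies

__all__ = [
    "AccuracyReport",
    "SyntenyBlock",
    "SyntenySummary",
    "accuracy",
    "non_split_adjacencies",
    "synteny_blocks",
    "dotplot_coords",
]


@dataclass(frozen=True)
class AccuracyReport:
    content_accuracy: float
    adjacency_accuracy: float
    content_fp: int
    content_fn: int
    adjacency_fp: int
    adjacency_fn: int


def _jaccard(rec: set, true: set) -> tuple[float, int, int]:
    union = rec | true
    if not union:
        return 1.0, 0, 0
    return len(rec & true) / len(union), len(rec - true), len(true - rec)


def accuracy(reconstructed: Genome, truth: Genome) -> AccuracyReport:
    """Jaccard accuracy of content and adjacency sets, with FP/FN counts.

    FP counts elements present only in the reconstruction, FN elements
    present only in the truth.  Telomeric adjacencies are excluded.
    """
    ca, cfp, cfn = _jaccard(reconstructed.families(), truth.families())
    aa, afp, afn = _jaccard(
        genome_to_adjacencies(reconstructed), genome_to_adjacencies(truth)
    )
    return AccuracyReport(
        content_accuracy=ca,
        adjacency_accuracy=aa,
        content_fp=cfp,
        content_fn=cfn,
        adjacency_fp=afp,
        adjacency_fn=afn,
    )


def non_split_adjacencies(gs: GenomeSet) -> set:
    """Adjacencies present in every genome (never split during evolution)."""
    if len(gs) < 2:
        raise ValueError("need at least 2 genomes")
    out: Optional[set] = None
    for g in gs:
        s = genome_to_adjacencies(g)
        out = s if out is None else out & s
    return out or set()


# ---------------------------------------------------------------------------
# Synteny
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntenyBlock:
    """A maximal conserved run between two genomes (1-based inclusive)."""

    chrom_a: int
    start_a: int
    end_a: int
    chrom_b: int
    start_b: int
    end_b: int
    length: int
    orientation: str  # "forward" | "reversed"


@dataclass(frozen=True)
class SyntenySummary:
    genes: int
    blocks: int
    avg_length: float


def _single_copy_positions(g: Genome) -> dict:
    """family -> (chrom index, gene index, sign) for single-copy families."""
    counts = g.family_counts()
    pos: dict = {}
    for ci, chrom in enumerate(g.chromosomes):
        for gi, x in enumerate(chrom):
            f = abs(x)
            if counts[f] == 1:
                pos[f] = (ci, gi, 1 if x > 0 else -1)
    return pos


def synteny_blocks(a: Genome, b: Genome) -> tuple[list[SyntenyBlock], SyntenySummary]:
    """Maximal gap-free conserved runs between two genomes.

    Only single-copy shared families anchor blocks.  Two consecutive genes
    of ``a`` extend a block iff ``b`` carries the same oriented adjacency
    (which covers both a forward copy and a reversed, sign-flipped copy).
    Blocks have length >= 2; the summary reports total syntenic genes,
    block count and mean genes per block.
    """
    pos_a = _single_copy_positions(a)
    pos_b = _single_copy_positions(b)
    shared = set(pos_a) & set(pos_b)
    b_adjs = genome_to_adjacencies(b)

    blocks: list[SyntenyBlock] = []
    for ci, chrom in enumerate(a.chromosomes):
        run_start = None
        for gi in range(len(chrom)):
            f = abs(chrom[gi])
            anchored = f in shared
            extends = False
            if anchored and gi > 0 and abs(chrom[gi - 1]) in shared:
                adj = canonical_adjacency(
                    gene_extremities(chrom[gi - 1])[1],
                    gene_extremities(chrom[gi])[0],
                )
                extends = adj in b_adjs
            if extends:
                if run_start is None:
                    run_start = gi - 1
            else:
                if run_start is not None:
                    blocks.append(_make_block(a, b, pos_a, pos_b, ci, run_start, gi - 1))
                    run_start = None
                if not anchored:
                    run_start = None
        if run_start is not None:
            blocks.append(_make_block(a, b, pos_a, pos_b, ci, run_start, len(chrom) - 1))

    genes = sum(bl.length for bl in blocks)
    n = len(blocks)
    summary = SyntenySummary(genes=genes, blocks=n, avg_length=genes / n if n else 0.0)
    return blocks, summary


def _make_block(a, b, pos_a, pos_b, ci, i0, i1) -> SyntenyBlock:
    f0, f1 = abs(a.chromosomes[ci][i0]), abs(a.chromosomes[ci][i1])
    cb0, gb0, sb0 = pos_b[f0]
    cb1, gb1, _ = pos_b[f1]
    sa0 = 1 if a.chromosomes[ci][i0] > 0 else -1
    orientation = "forward" if sa0 == sb0 else "reversed"
    return SyntenyBlock(
        chrom_a=ci + 1,
        start_a=i0 + 1,
        end_a=i1 + 1,
        chrom_b=cb0 + 1,
        start_b=min(gb0, gb1) + 1,
        end_b=max(gb0, gb1) + 1,
        length=i1 - i0 + 1,
        orientation=orientation,
    )


def dotplot_coords(a: Genome, b: Genome) -> list[tuple]:
    """One point per shared single-copy family.

    Returns (pos_a, pos_b, chrom_a, chrom_b, sign_agreement) tuples with
    1-based cumulative gene positions (chromosomes concatenated in order);
    sign_agreement is +1 when the gene has the same strand in both genomes.
    """
    def cumulative(g: Genome, pos: dict) -> dict:
        offsets = []
        total = 0
        for chrom in g.chromosomes:
            offsets.append(total)
            total += len(chrom)
        return {f: (offsets[ci] + gi + 1, ci + 1, s) for f, (ci, gi, s) in pos.items()}

    pa = cumulative(a, _single_copy_positions(a))
    pb = cumulative(b, _single_copy_positions(b))
    out = []
    for f in sorted(set(pa) & set(pb)):
        (xa, ca, sa), (xb, cb, sb) = pa[f], pb[f]
        out.append((xa, xb, ca, cb, sa * sb))
    return out
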