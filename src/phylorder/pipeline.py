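"""End-to-end orchestration: encode -> tree -> posteriors -> assembly -> metrics.

The pipeline is deterministic under a fixed seed: every stage writes its
output under the configured directory with sorted, fixed-format records, so
identical configurations produce byte-identical artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .genome_io import (
    Genome,
    GenomeSet,
    PhyloTree,
    read_gene_orders,
    read_newick,
    write_gene_orders,
    write_newick,
)
from .encoding import encode
from .evo_model import EventRates
from .phylogeny import ModelParams, bootstrap_support, fit_model, infer_tree
from .ancestor import reconstruct_all, select_content
from .assembly import AncestralGenome, assemble_ancestor
from .evaluation import accuracy
from .simulator import SimConfig, evolve

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "assemble_ancestors"]


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Either ``genomes_path`` (GRIMM file) or ``sim`` (simulate a dataset)
    must be given.  A guide tree fixes the topology (branch lengths are
    still optimized under the model); otherwise the tree is inferred.
    """

    out_dir: str
    genomes_path: Optional[str] = None
    tree_path: Optional[str] = None
    sim: Optional[SimConfig] = None
    threshold: float = 0.5
    bootstrap: int = 0
    seed: int = 0
    model: Optional[ModelParams] = None
    tsp_restarts: int = 2


@dataclass
class PipelineResult:
    tree: PhyloTree
    posteriors: list
    ancestors: dict                      # node name -> AncestralGenome
    reports: Optional[dict] = None       # node name -> AccuracyReport


def _default_model(gs: GenomeSet) -> ModelParams:
    n = int(np.mean([g.n_genes for g in gs]))
    C = int(round(np.mean([g.n_chromosomes for g in gs])))
    er = EventRates(R=1.0, D=0.0, I=0.0, d=0.0, n=max(n, 1), C=max(C, 1))
    return ModelParams.from_event_rates(er)


def assemble_ancestors(
    tree: PhyloTree,
    gs: GenomeSet,
    posteriors: list,
    threshold: float = 0.5,
    seed: int = 0,
    root_name: Optional[str] = None,
    restarts: int = 2,
) -> dict:
    """Assemble every ancestor, children before parents.

    Processing is post-order from a designated root so the two child-side
    neighbor genomes of each ancestor (leaf or already-assembled ancestor)
    are available for the telomere priority rules; the rootward neighbor
    serves as the parent when it has been assembled (only at the root, whose
    three neighbors are all child-side).
    """
    work = tree.unroot()
    post = {ap.node: ap for ap in posteriors}
    if root_name is None:
        root_name = min(
            (work.names[v] for v in work.internal_nodes() if work.names.get(v)),
            key=lambda s: (len(s), s),
        )
    root = work.node_by_name(root_name)

    assembled: dict[str, AncestralGenome] = {}

    def genome_of(node: int) -> Optional[Genome]:
        name = work.names.get(node)
        if name is None:
            return None
        if name in gs:
            return gs[name]
        if name in assembled:
            g = assembled[name].genome
            return g if g.chromosomes else None
        return None

    order = [(v, par) for v, par in work.postorder(root) if not work.is_leaf(v)]
    for node, parent in order:
        name = work.names[node]
        ap = post[name]
        fams = select_content(ap, threshold)
        nbrs = [n for n in work.neighbors(node) if n != parent]
        child_genomes = [genome_of(n) for n in nbrs]
        child_genomes = [g for g in child_genomes if g is not None]
        parent_genome = genome_of(parent) if parent is not None else None
        if parent_genome is None and len(child_genomes) > 2:
            parent_genome = child_genomes[2]
        c1 = child_genomes[0] if child_genomes else None
        c2 = child_genomes[1] if len(child_genomes) > 1 else c1
        if c1 is None:
            # no assembled neighbor at all: fall back to arbitrary leaf
            c1 = c2 = next(iter(gs))
        assembled[name] = assemble_ancestor(
            name, fams, ap.char_probs, parent_genome, c1, c2,
            seed=seed, restarts=restarts,
        )
    return assembled


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    truth = None
    guide = None
    if cfg.sim is not None:
        logger.info("stage simulate: %d taxa, %d genes", cfg.sim.n_taxa, cfg.sim.n_genes)
        sim = evolve(cfg.sim)
        gs = sim.leaves
        guide = sim.tree
        truth = sim.ancestors
        write_gene_orders(gs, out / "leaves.grimm")
        write_gene_orders(sim.ancestors.values(), out / "true_ancestors.grimm")
        write_newick(sim.tree, out / "true_tree.nwk")
    elif cfg.genomes_path is not None:
        gs = read_gene_orders(cfg.genomes_path)
        if cfg.tree_path is not None:
            guide = read_newick(cfg.tree_path, require_binary=True)
    else:
        raise ValueError("either genomes_path or sim must be configured")

    logger.info("stage encode: %d genomes", len(gs))
    matrix = encode(gs)
    matrix.to_phylip(out / "characters.phy")

    model = cfg.model or _default_model(gs)

    if guide is None:
        logger.info("stage tree: inferring topology (%d taxa)", len(gs))
        if cfg.bootstrap > 0:
            tree = bootstrap_support(matrix, model, cfg.bootstrap, cfg.seed)
        else:
            tree = infer_tree(matrix, model, cfg.seed)
    else:
        tree = guide.unroot()
        for u, v in tree.edges():
            tree.set_length(u, v, None)
    logger.info("stage model fit: rates and branch lengths")
    model = fit_model(tree, matrix, model)
    write_newick(tree, out / "tree.nwk", include_supports=cfg.bootstrap > 0)

    logger.info("stage reconstruct: posteriors at %d ancestors", len(gs) - 2)
    posteriors = reconstruct_all(tree, matrix, model)
    with open(out / "posteriors.tsv", "w", encoding="utf-8") as fh:
        fh.write("node\tcharacter\tposterior\n")
        for ap in posteriors:
            for label, prob in zip(ap.labels, ap.probs):
                fh.write(f"{ap.node}\t{label}\t{prob:.6f}\n")

    logger.info("stage assemble")
    ancestors = assemble_ancestors(
        tree, gs, posteriors, threshold=cfg.threshold, seed=cfg.seed,
        restarts=cfg.tsp_restarts,
    )
    write_gene_orders((a.genome for a in ancestors.values() if a.genome.chromosomes),
                      out / "ancestors.grimm")

    reports = None
    if truth is not None:
        reports = {
            name: accuracy(anc.genome, truth[name])
            for name, anc in ancestors.items()
            if name in truth
        }
        with open(out / "accuracy.tsv", "w", encoding="utf-8") as fh:
            fh.write("node\tcontent_accuracy\tadjacency_accuracy\t"
                     "content_fp\tcontent_fn\tadjacency_fp\tadjacency_fn\n")
            for name in sorted(reports, key=lambda s: (len(s), s)):
                r = reports[name]
                fh.write(f"{name}\t{r.content_accuracy:.6f}\t{r.adjacency_accuracy:.6f}"
                         f"\t{r.content_fp}\t{r.content_fn}"
                         f"\t{r.adjacency_fp}\t{r.adjacency_fn}\n")

    logger.info("pipeline done in %.1fs", time.time() - t_start)
    # run manifest stays free of timings so equal seeds give equal bytes
    with open(out / "run.json", "w", encoding="utf-8") as fh:
        json.dump({"seed": cfg.seed, "threshold": cfg.threshold,
                   "bootstrap": cfg.bootstrap}, fh, indent=1)
    return PipelineResult(tree=tree, posteriors=posteriors,
                          ancestors=ancestors, reports=reports)
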