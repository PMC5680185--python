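"""Probabilistic ancestral reconstruction of genes and adjacencies.

For every internal node of the guide tree, the posterior probability that
the ancestor carried a character G is

    P(G_a | O_a) = f_G p_a(G_a) / sum_G f_G p_a(G_a)

where p_a is the pruning partial likelihood of the leaves given the
ancestral state and f_G is the character's prior frequency, taken as its
empirical frequency among the leaves.  Following the re-rooting scheme, the
queried ancestor is treated as the root, so the partial product runs over
all three incident subtrees of the unrooted tree and every genome in the
dataset informs the reconstruction, not just the descendants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genome_io import Genome, PhyloTree
from .encoding import BinaryCharacterMatrix
from .phylogeny import ModelParams, _check_labels, _class_column_groups, _leaf_states, _partials

__all__ = [
    "CharacterPrior",
    "AncestorPosterior",
    "partial_likelihood",
    "posterior",
    "reconstruct_all",
    "select_content",
    "apply_wgd",
]


@dataclass
class CharacterPrior:
    """Per-character prior frequency f_G of state 'present'."""

    f: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.f, float)
        if np.any((f < 0) | (f > 1)):
            raise ValueError("prior frequencies must lie in [0, 1]")
        self.f = f

    @classmethod
    def from_matrix(cls, m: BinaryCharacterMatrix) -> "CharacterPrior":
        """Empirical leaf frequency of each character."""
        return cls(m.data.mean(axis=0))


@dataclass
class AncestorPosterior:
    """Posterior P(present) for every matrix column at one ancestral node."""

    node: str
    labels: list[str]
    probs: np.ndarray

    @property
    def char_probs(self) -> dict:
        return dict(zip(self.labels, self.probs))

    def prob(self, label: str) -> float:
        return float(self.probs[self.labels.index(label)])


def _ensure_internal_names(tree: PhyloTree) -> None:
    i = 1
    for v in tree.internal_nodes():
        if v not in tree.names:
            while f"A{i}" in tree.names.values():
                i += 1
            tree.names[v] = f"A{i}"


def _node_partials(tree: PhyloTree, node: int, m: BinaryCharacterMatrix,
                   p: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Scaled pruning partials at ``node`` treated as the root (all classes)."""
    partial = np.empty((m.n_columns, 2))
    logscale = np.empty(m.n_columns)
    for loss, gain, cols in _class_column_groups(m, p):
        if len(cols) == 0:
            continue
        states = _leaf_states(m, cols)
        part, ls = _partials(tree, node, states, loss, gain)
        partial[cols] = part
        logscale[cols] = ls
    return partial, logscale


def partial_likelihood(tree: PhyloTree, node_name: str, char_label: str,
                       m: BinaryCharacterMatrix, p: ModelParams) -> np.ndarray:
    """Unscaled partial likelihood vector (absent, present) for one character."""
    _check_labels(tree, m)
    node = tree.node_by_name(node_name)
    part, ls = _node_partials(tree, node, m, p)
    j = m.column_labels.index(char_label)
    return part[j] * np.exp(ls[j])


def _posteriors_at(tree: PhyloTree, node: int, m: BinaryCharacterMatrix,
                   p: ModelParams, prior: CharacterPrior) -> np.ndarray:
    part, _ = _node_partials(tree, node, m, p)
    f = prior.f
    num = f * part[:, 1]
    den = num + (1.0 - f) * part[:, 0]
    # Zero normalizer can only arise from a degenerate prior contradicting
    # the data (f in {0,1} with zero likelihood); fall back to the prior.
    out = np.where(den > 0, num / np.where(den > 0, den, 1.0), f)
    return out


def posterior(tree: PhyloTree, node_name: str, char_label: str,
              m: BinaryCharacterMatrix, p: ModelParams,
              prior: Optional[CharacterPrior] = None) -> float:
    """Posterior probability that the ancestor carries the character."""
    _check_labels(tree, m)
    if prior is None:
        prior = CharacterPrior.from_matrix(m)
    node = tree.node_by_name(node_name)
    probs = _posteriors_at(tree, node, m, p, prior)
    return float(probs[m.column_labels.index(char_label)])


def reconstruct_all(tree: PhyloTree, m: BinaryCharacterMatrix, p: ModelParams,
                    prior: Optional[CharacterPrior] = None) -> list[AncestorPosterior]:
    """Posterior tables for all (#leaves - 2) internal nodes.

    The tree is unrooted first if needed; each internal node is queried by
    re-rooting the pruning recursion there, so the whole dataset informs
    every ancestor.
    """
    _check_labels(tree, m)
    work = tree.unroot()
    if not work.is_binary():
        raise ValueError("reconstruction requires a binary tree")
    if prior is None:
        prior = CharacterPrior.from_matrix(m)
    _ensure_internal_names(work)
    labels = m.column_labels
    out = []
    for node in sorted(work.internal_nodes(),
                       key=lambda v: (len(work.names[v]), work.names[v])):
        probs = _posteriors_at(work, node, m, p, prior)
        out.append(AncestorPosterior(node=work.names[node], labels=labels, probs=probs))
    return out


def select_content(ap: AncestorPosterior, threshold: float = 0.5) -> set[int]:
    """Families whose posterior strictly exceeds the threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    out: set[int] = set()
    for label, prob in zip(ap.labels, ap.probs):
        if label.startswith("C:") and prob > threshold:
            out.add(int(label[2:]))
    return out


def apply_wgd(g: Genome) -> Genome:
    """Whole-genome duplication: every chromosome copied once.

    Used to derive a post-WGD ancestor from its reconstructed pre-WGD
    ancestor; never applied implicitly.
    """
    return Genome(g.name, [list(c) for c in g.chromosomes] * 2)
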