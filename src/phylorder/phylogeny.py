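"""Maximum-likelihood phylogeny inference on binary presence characters.

The model is the asymmetric two-state chain of :mod:`phylorder.evo_model`:
each character (an adjacency or a gene family) is present/absent and evolves
independently along the tree with loss rate lambda and gain rate mu.  The
root is weighted by the stationary distribution, which makes the chain
reversible and the likelihood invariant to the rooting of an unrooted tree.

Tree search follows the classic recipe: a neighbor-joining starting tree on
Jaccard distances between presence rows, then nearest-neighbor-interchange
hill climbing with per-edge branch-length optimization, accepting the first
improving move in a fixed deterministic order.  Nonparametric bootstrap
resamples characters with replacement and reports bipartition frequencies,
classified into the conventional strong (>90) / medium (60-90) / weak (<60)
support levels.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .genome_io import PhyloTree
from .encoding import BinaryCharacterMatrix
from .evo_model import EventRates, adjacency_gain_prob, adjacency_loss_prob, transition_matrix

__all__ = [
    "ModelParams",
    "SupportLevel",
    "support_level",
    "log_likelihood",
    "optimize_branch_lengths",
    "infer_tree",
    "bootstrap_support",
]


@dataclass(frozen=True)
class ModelParams:
    """Loss/gain rates, optionally distinct per character class ('A' / 'C').

    Only the gain/loss ratio is identifiable once branch lengths are free;
    the convention here fixes loss = 1 so branch lengths are measured in
    expected losses per present character.
    """

    loss: float = 1.0
    gain: float = 1e-3
    class_rates: Optional[dict] = None  # class code -> (loss, gain)

    def __post_init__(self) -> None:
        if self.loss <= 0 or self.gain <= 0:
            raise ValueError("rates must be positive")

    def rates_for(self, cls: str) -> tuple[float, float]:
        if self.class_rates and cls in self.class_rates:
            return self.class_rates[cls]
        return (self.loss, self.gain)

    @classmethod
    def from_event_rates(cls, er: EventRates) -> "ModelParams":
        """Rates whose ratio matches the DCJ loss/gain probability estimates.

        The estimated event total cancels in the ratio, leaving
        gain/loss = (n + C) / C(2n+2, 2); absolute scale goes into branch
        lengths.
        """
        er_unit = EventRates(R=1.0, D=0.0, I=0.0, d=0.0, n=er.n, C=er.C)
        ratio = adjacency_gain_prob(er_unit) / adjacency_loss_prob(er_unit)
        return cls(loss=1.0, gain=ratio)


class SupportLevel(enum.Enum):
    STRONG = "strong"
    MEDIUM = "medium"
    WEAK = "weak"


def support_level(bootstrap: float) -> SupportLevel:
    """strong: > 90; medium: 60..90 inclusive; weak: < 60."""
    if bootstrap > 90:
        return SupportLevel.STRONG
    if bootstrap >= 60:
        return SupportLevel.MEDIUM
    return SupportLevel.WEAK


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------

_DEFAULT_LENGTH = 0.1  # used when an edge has no length yet


def _leaf_states(m: BinaryCharacterMatrix, cols: np.ndarray) -> dict:
    return {t: m.data[i, cols] for i, t in enumerate(m.taxa)}


def _partials(tree: PhyloTree, root: int, states: dict, loss: float, gain: float):
    """Scaled partial likelihoods at ``root`` for every character.

    Returns (partial, logscale): ``partial`` has shape (n_chars, 2) and the
    true partial is partial * exp(logscale) column-wise.  Leaves contribute
    indicator vectors; internal nodes the pruning product over children.
    """
    partial: dict[int, np.ndarray] = {}
    logscale: dict[int, np.ndarray] = {}
    for node, parent in tree.postorder(root):
        children = [c for c in tree.neighbors(node) if c != parent]
        if not children:
            x = states[tree.names[node]].astype(float)
            partial[node] = np.stack([1.0 - x, x], axis=1)
            logscale[node] = np.zeros(len(x))
            continue
        acc = None
        ls = None
        for c in children:
            t = tree.length(node, c)
            T = transition_matrix(loss, gain, _DEFAULT_LENGTH if t is None else t)
            msg = partial.pop(c) @ T.T  # (chars, 2): sum_b T[a,b] p_c[b]
            child_ls = logscale.pop(c)
            acc = msg if acc is None else acc * msg
            ls = child_ls if ls is None else ls + child_ls
        scale = acc.max(axis=1)
        nz = scale > 0
        acc[nz] /= scale[nz, None]
        with np.errstate(divide="ignore"):
            ls = ls + np.where(nz, np.log(scale, where=nz, out=np.zeros_like(scale)), -np.inf)
        partial[node] = acc
        logscale[node] = ls
    return partial[root], logscale[root]


def _check_labels(tree: PhyloTree, m: BinaryCharacterMatrix) -> None:
    if set(tree.leaf_names()) != set(m.taxa):
        raise ValueError("tree leaf labels do not match matrix taxa")


def _class_column_groups(m: BinaryCharacterMatrix, p: ModelParams):
    """Yield (loss, gain, column index array) once per distinct rate class."""
    if not p.class_rates:
        yield p.loss, p.gain, np.arange(m.n_columns)
        return
    classes = m.column_classes
    for cls in sorted(set(classes)):
        loss, gain = p.rates_for(cls)
        yield loss, gain, np.flatnonzero(classes == cls)


def log_likelihood(
    tree: PhyloTree,
    m: BinaryCharacterMatrix,
    p: ModelParams,
    weights: Optional[np.ndarray] = None,
) -> float:
    """Log-likelihood of the matrix on the tree (characters independent).

    ``weights`` are per-character multiplicities (used by the bootstrap);
    default all ones.  The root term weights the partials by the stationary
    distribution of the rates, so re-rooting an unrooted tree leaves the
    value unchanged.
    """
    _check_labels(tree, m)
    root = tree.root
    if root is None:
        internals = tree.internal_nodes()
        root = internals[0] if internals else tree.leaves()[0]
    total = 0.0
    for loss, gain, cols in _class_column_groups(m, p):
        if len(cols) == 0:
            continue
        states = _leaf_states(m, cols)
        partial, ls = _partials(tree, root, states, loss, gain)
        s = loss + gain
        pi = np.array([loss / s, gain / s])
        with np.errstate(divide="ignore"):
            site_ll = np.log(partial @ pi) + ls
        w = np.ones(len(cols)) if weights is None else np.asarray(weights, float)[cols]
        total += float(np.dot(w, site_ll))
    return total


# ---------------------------------------------------------------------------
# Branch-length optimization and tree search
# ---------------------------------------------------------------------------

def optimize_branch_lengths(
    tree: PhyloTree,
    m: BinaryCharacterMatrix,
    p: ModelParams,
    weights: Optional[np.ndarray] = None,
    sweeps: int = 2,
    tol: float = 1e-6,
    max_length: float = 50.0,
) -> float:
    """Optimize each branch length in turn (univariate, bounded); in place.

    Returns the final log-likelihood.  Edges start from their current length
    (or a small default) and are optimized in a fixed edge order for
    ``sweeps`` rounds or until the likelihood gain drops below ``tol``.
    """
    for u, v in tree.edges():
        if tree.length(u, v) is None:
            tree.set_length(u, v, _DEFAULT_LENGTH)
    best = log_likelihood(tree, m, p, weights)
    for _ in range(sweeps):
        improved = False
        for u, v in tree.edges():
            def nll(t: float) -> float:
                tree.set_length(u, v, t)
                return -log_likelihood(tree, m, p, weights)

            current = tree.length(u, v)
            res = minimize_scalar(nll, bounds=(1e-8, max_length), method="bounded",
                                  options={"xatol": 1e-5})
            if -res.fun > best + 1e-12:
                tree.set_length(u, v, float(res.x))
                if -res.fun > best + tol:
                    improved = True
                best = -res.fun
            else:
                tree.set_length(u, v, current)
        if not improved:
            break
    return best


def fit_model(
    tree: PhyloTree,
    m: BinaryCharacterMatrix,
    p: ModelParams,
    weights: Optional[np.ndarray] = None,
    rounds: int = 8,
    tol: float = 5.0,
) -> ModelParams:
    """Maximum-likelihood estimation of per-class rates plus branch lengths.

    The adjacency class anchors the clock (loss = 1); its gain/loss ratio is
    free, and every other character class gets a free rate multiplier and
    gain/loss ratio (content characters typically evolve far slower than
    adjacencies, and their gain rate reflects insertions rather than
    rearrangement rejoins).  Parameters are profiled one at a time on the
    log scale, alternating with branch-length sweeps, until a round improves
    the log-likelihood by less than ``tol`` (the multiplier/branch-length
    ridge converges slowly, so a plain fixed round count under-fits) or
    ``rounds`` rounds have run.  ``tree`` is modified in place; the fitted
    :class:`ModelParams` is returned.
    """
    classes = sorted({str(c) for c in m.column_classes}) or ["A"]
    anchor = classes[0]
    # state: class -> (multiplier, gain ratio)
    state = {}
    for cls in classes:
        loss, gain = p.rates_for(cls)
        state[cls] = [loss, gain / loss]

    def params() -> ModelParams:
        anchor_loss = state[anchor][0]
        rates = {cls: (s / anchor_loss, s / anchor_loss * g)
                 for cls, (s, g) in state.items()}
        la, ga = rates[anchor]
        return ModelParams(loss=la, gain=ga, class_rates=rates)

    def profile(cls: str, slot: int, lo: float, hi: float) -> None:
        def nll(x: float) -> float:
            state[cls][slot] = math.exp(x)
            return -log_likelihood(tree, m, params(), weights)

        res = minimize_scalar(nll, bounds=(math.log(lo), math.log(hi)),
                              method="bounded", options={"xatol": 1e-3})
        state[cls][slot] = math.exp(float(res.x))

    last = -np.inf
    for _ in range(rounds):
        ll = optimize_branch_lengths(tree, m, params(), weights, sweeps=1)
        for cls in classes:
            if cls != anchor:
                profile(cls, 0, 1e-4, 1e2)   # rate multiplier
            profile(cls, 1, 1e-8, 1e2)       # gain/loss ratio
        if ll - last < tol:
            break
        last = ll
    optimize_branch_lengths(tree, m, params(), weights, sweeps=1)
    return params()


def _jaccard_distances(m: BinaryCharacterMatrix,
                       weights: Optional[np.ndarray] = None) -> np.ndarray:
    X = m.data.astype(float)
    w = np.ones(X.shape[1]) if weights is None else np.asarray(weights, float)
    inter = (X * w) @ X.T
    totals = (X * w).sum(axis=1)
    union = totals[:, None] + totals[None, :] - inter
    with np.errstate(invalid="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def _nj_start_tree(m: BinaryCharacterMatrix,
                   weights: Optional[np.ndarray] = None) -> PhyloTree:
    """Neighbor-joining starting topology from weighted Jaccard distances."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    d = _jaccard_distances(m, weights)
    d = (d + d.T) / 2.0
    dm = DistanceMatrix(d, ids=m.taxa)
    newick = str(nj(dm))
    tree = PhyloTree.parse_newick(newick).unroot()
    for u, v in tree.edges():
        t = tree.length(u, v)
        tree.set_length(u, v, max(t if t is not None else _DEFAULT_LENGTH, 1e-6))
    return tree


def _nni_variants(tree: PhyloTree, u: int, v: int):
    """The two NNI rearrangements around internal edge (u, v), as new trees."""
    au = sorted(n for n in tree.neighbors(u) if n != v)
    av = sorted(n for n in tree.neighbors(v) if n != u)
    b = au[-1]
    for c in av:
        t = tree.copy()
        lb = t.length(u, b)
        lc = t.length(v, c)
        t.remove_edge(u, b)
        t.remove_edge(v, c)
        t.add_edge(u, c, lc)
        t.add_edge(v, b, lb)
        yield t


def _three_taxon_tree(m: BinaryCharacterMatrix) -> PhyloTree:
    t = PhyloTree()
    center = t.add_node()
    for name in m.taxa:
        leaf = t.add_node(name)
        t.add_edge(center, leaf, _DEFAULT_LENGTH)
    return t


def _search(m, p, weights, opt_sweeps: int = 2, tol: float = 1e-6):
    tree = _nj_start_tree(m, weights)
    ll = optimize_branch_lengths(tree, m, p, weights, sweeps=opt_sweeps)
    trace = [ll]
    while True:
        improved = False
        for u, v in tree.internal_edges():
            for cand in _nni_variants(tree, u, v):
                cand_ll = optimize_branch_lengths(cand, m, p, weights, sweeps=opt_sweeps)
                if cand_ll > ll + tol:
                    tree, ll = cand, cand_ll
                    trace.append(ll)
                    improved = True
                    break
            if improved:
                break
        if not improved:
            break
    return tree, ll, trace


def infer_tree(
    m: BinaryCharacterMatrix,
    p: ModelParams,
    seed: int = 0,
    weights: Optional[np.ndarray] = None,
    return_trace: bool = False,
):
    """ML tree: NJ start, then first-improvement NNI hill climbing.

    Deterministic given the input; ``seed`` is accepted for interface
    stability (the search itself has no random component).  The returned
    tree is unrooted and binary with optimized branch lengths.
    """
    if len(m.taxa) < 3:
        raise ValueError("tree inference requires at least 3 taxa")
    if len(m.taxa) == 3:
        tree = _three_taxon_tree(m)
        ll = optimize_branch_lengths(tree, m, p, weights)
        return (tree, [ll]) if return_trace else tree
    tree, ll, trace = _search(m, p, weights)
    return (tree, trace) if return_trace else tree


def bootstrap_support(
    m: BinaryCharacterMatrix,
    p: ModelParams,
    B: int,
    seed: int = 0,
) -> PhyloTree:
    """Nonparametric bootstrap: column resampling with replacement.

    Infers the ML tree, then ``B`` replicate trees from resampled matrices
    (equal width); the support of an internal edge is the percentage of
    replicates whose tree contains that bipartition.
    """
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    tree = infer_tree(m, p, seed)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(B):
        idx = rng.integers(0, m.n_columns, m.n_columns)
        w = np.bincount(idx, minlength=m.n_columns).astype(float)
        rep = infer_tree(m, p, seed, weights=w)
        for bp in rep.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    ref = min(tree.leaf_names())
    all_names = frozenset(tree.leaf_names())
    for u, v in tree.internal_edges():
        side = tree.side_leaves(u, v)
        if ref in side:
            side = all_names - side
        pct = 100.0 * counts.get(side, 0) / B
        tree.supports[tree.edge_key(u, v)] = pct
    return tree
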