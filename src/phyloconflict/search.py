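"""Tree search: Poisson-corrected distances, neighbor joining, NNI
hill-climbing and nonparametric bootstrap supports.

The search strategy is the classic desk-scale recipe: a neighbor-joining
starting tree from Poisson-corrected pairwise distances, branch lengths
optimized by maximum likelihood, then nearest-neighbor-interchange moves
accepted one best improving move at a time until a local optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment, GAP, UNKNOWN
from .likelihood import PatternData, optimize_branch_lengths, tree_log_likelihood
from .model import SubstitutionModel
from .tree import Node, PhyloTree, canonical_side, leafset_below

D_MAX = 10.0


class SearchError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    taxon_ids: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxon_ids),) * 2:
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T) or np.any(np.diag(v) != 0) or np.any(v < 0):
            raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")
        self.values = v

    def distance(self, a: str, b: str) -> float:
        i, j = self.taxon_ids.index(a), self.taxon_ids.index(b)
        return float(self.values[i, j])


def pairwise_distances(aln: Alignment) -> DistanceMatrix:
    """Poisson-corrected distances d = -ln(1 - p) over shared ungapped columns.

    ``p`` is the mismatch fraction over columns where both rows carry a
    residue (not ``-`` or ``X``); distances are capped at ``D_MAX``.  A pair
    with no shared ungapped column is an error.
    """
    if aln.n_taxa < 2:
        raise SearchError("need at least two taxa")
    rows = [np.frombuffer(r.encode(), dtype="S1") for r in aln.rows]
    missing = [
        (r == GAP.encode()) | (r == UNKNOWN.encode()) for r in rows
    ]
    n = aln.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~(missing[i] | missing[j])
            m = int(shared.sum())
            if m == 0:
                raise SearchError(
                    f"taxa {aln.taxon_ids[i]!r} and {aln.taxon_ids[j]!r} share "
                    "no ungapped columns"
                )
            p = float((rows[i][shared] != rows[j][shared]).sum()) / m
            if p >= 1.0 - np.exp(-D_MAX):
                d = D_MAX
            else:
                d = -np.log(1.0 - p)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(aln.taxon_ids, D)


def neighbor_joining(dist: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lowest (i, j) index pair;
    negative intermediate branch lengths are clamped to zero.  Returns an
    unrooted tree (trifurcating root).
    """
    n = len(dist.taxon_ids)
    if n < 3:
        raise SearchError("neighbor joining needs at least 3 taxa")
    D = dist.values.copy()
    nodes = [Node(name=t) for t in dist.taxon_ids]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if best is None or Q[a, b] < best[0] - 1e-12:
                    best = (Q[a, b], a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances of the new node to the others
        newD = np.zeros(D.shape[0])
        for c in active:
            if c in (i, j):
                continue
            newD_c = 0.5 * (D[i, c] + D[j, c] - dij)
            newD[c] = max(newD_c, 0.0)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newD
        D[:-1, -1] = newD
        nodes.append(parent)
        active = [c for c in active if c not in (i, j)] + [len(nodes) - 1]
    # join the last three under an unrooted root
    root = Node()
    (i, j, k) = active
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    nodes[i].length = max(0.5 * (dij + dik - djk), 0.0)
    nodes[j].length = max(0.5 * (dij + djk - dik), 0.0)
    nodes[k].length = max(0.5 * (dik + djk - dij), 0.0)
    for idx in (i, j, k):
        root.add_child(nodes[idx])
    return PhyloTree(root, rooted=False)


@dataclass
class SearchResult:
    tree: PhyloTree
    log_likelihood: float
    accepted_moves: int
    trace: list = field(default_factory=list)


def _nni_candidates(tree: PhyloTree):
    """Internal edges eligible for NNI: child node internal, binary."""
    out = []
    for node in tree.postorder():
        if node.parent is None or node.is_leaf:
            continue
        if len(node.children) != 2:
            continue
        parent = node.parent
        others = [c for c in parent.children if c is not node]
        if not others:
            continue
        out.append(node)
    return out


def _apply_nni(tree: PhyloTree, edge_child: Node, alternative: int) -> None:
    """Swap one subtree across the edge (in place).

    ``edge_child`` is the child endpoint of an internal edge; alternative 0
    swaps its first child with a neighbor subtree of the parent endpoint,
    alternative 1 its second child.
    """
    parent = edge_child.parent
    neighbor = next(c for c in parent.children if c is not edge_child)
    moved = edge_child.children[alternative]
    # swap positions
    pi = parent.children.index(neighbor)
    ci = edge_child.children.index(moved)
    parent.children[pi] = moved
    moved.parent = parent
    edge_child.children[ci] = neighbor
    neighbor.parent = edge_child
    edge_child.support = None


def nni_search(start: PhyloTree, aln: Alignment, model: SubstitutionModel,
               improve_tol: float = 1e-6, max_rounds: int = 50,
               bl_sweeps_per_round: int = 2, bl_tol: float = 1e-3,
               data: PatternData | None = None) -> SearchResult:
    """Hill-climb over NNI rearrangements.

    Every internal edge contributes two alternative topologies per round;
    the central branch of each candidate is locally re-optimized before
    comparison, the single best improving move is accepted, and branch
    lengths are re-tuned after each accepted move.  Stops at a local
    optimum; the log-likelihood trace is strictly increasing.
    """
    if start.n_leaves < 4:
        raise SearchError("NNI search needs at least 4 leaves")
    if data is None:
        data = PatternData(aln)
    tree = start.copy()
    if tree.rooted:
        tree.unroot()
    optimize_branch_lengths(tree, aln, model, tol=bl_tol,
                            max_sweeps=max(2, bl_sweeps_per_round), data=data)
    current, _ = tree_log_likelihood(tree, aln, model, data)
    trace = [current]
    accepted = 0
    for _ in range(max_rounds):
        best_ll, best_move = current, None
        for node in _nni_candidates(tree):
            for alt in (0, 1):
                cand = tree.copy()
                cand_node = _matching_node(cand, tree, node)
                _apply_nni(cand, cand_node, alt)
                _optimize_single_edge(cand, cand_node, aln, model, data)
                ll, _ = tree_log_likelihood(cand, aln, model, data)
                if ll > best_ll + improve_tol:
                    best_ll, best_move = ll, (node, alt)
        if best_move is None:
            break
        node, alt = best_move
        _apply_nni(tree, node, alt)
        _optimize_single_edge(tree, node, aln, model, data)
        optimize_branch_lengths(tree, aln, model, tol=bl_tol,
                                max_sweeps=bl_sweeps_per_round, data=data)
        current, _ = tree_log_likelihood(tree, aln, model, data)
        accepted += 1
        trace.append(current)
    return SearchResult(tree=tree, log_likelihood=current,
                        accepted_moves=accepted, trace=trace)


def _matching_node(cand: PhyloTree, orig: PhyloTree, node: Node) -> Node:
    """Locate in a copied tree the node at the same postorder position."""
    for a, b in zip(cand.postorder(), orig.postorder()):
        if b is node:
            return a
    raise SearchError("node not found in copy")


def _optimize_single_edge(tree: PhyloTree, node: Node, aln, model, data):
    from .likelihood import (_down_partials, _edge_down, _edge_loglik_fn,
                             _outside_products)
    from scipy.optimize import minimize_scalar
    down = _down_partials(tree, data, model)
    h = _outside_products(tree, data, model, down)
    npat = data.patterns.shape[1]
    f = _edge_loglik_fn(h[node], _edge_down(node, data, model, down, npat),
                        model, data.weights)
    res = minimize_scalar(lambda t: -f(t), bounds=(1e-8, 20.0),
                          method="bounded", options={"xatol": 1e-6})
    if -res.fun > f(node.length):
        node.length = float(res.x)


def infer_ml_tree(aln: Alignment, model: SubstitutionModel,
                  improve_tol: float = 1e-6, max_rounds: int = 50,
                  bl_sweeps_per_round: int = 2, bl_tol: float = 1e-3) -> SearchResult:
    """NJ starting tree + ML branch lengths + NNI hill-climb."""
    start = neighbor_joining(pairwise_distances(aln))
    return nni_search(start, aln, model, improve_tol=improve_tol,
                      max_rounds=max_rounds,
                      bl_sweeps_per_round=bl_sweeps_per_round, bl_tol=bl_tol)


def bootstrap_support(aln: Alignment, model: SubstitutionModel, B: int = 100,
                      seed: int = 0, ml_result: SearchResult | None = None,
                      **search_kwargs) -> SearchResult:
    """Nonparametric bootstrap supports on the ML tree.

    ``B`` column-resampled pseudo-alignments are each analyzed with the full
    NJ + NNI inference; the support of each internal edge of the ML tree is
    the percentage of replicate trees containing the same bipartition.
    """
    if B < 1:
        raise SearchError("need at least one bootstrap replicate")
    if ml_result is None:
        ml_result = infer_ml_tree(aln, model, **search_kwargs)
    tree = ml_result.tree
    all_leaves = frozenset(tree.leaf_names())
    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    n = aln.n_columns
    for _ in range(B):
        cols = rng.integers(0, n, size=n)
        pseudo = aln.select_columns(cols.tolist())
        rep = infer_ml_tree(pseudo, model, **search_kwargs)
        for bp in rep.tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    for node in tree.postorder():
        if node.parent is None or node.is_leaf:
            continue
        side = leafset_below(node)
        if 2 <= len(side) <= len(all_leaves) - 2:
            key = canonical_side(side, all_leaves)
            node.support = 100.0 * counts[key] / B
    return ml_result
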