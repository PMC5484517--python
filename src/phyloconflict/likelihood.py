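"""Felsenstein pruning under a reversible model with discrete-gamma rates.

Likelihoods are computed over unique site patterns (with multiplicities) and
rescaled per pattern to avoid underflow.  Gaps and ``X`` contribute all-ones
partial vectors.  Per-site likelihoods are averaged over the gamma
categories with equal weights.

Branch lengths are optimized one edge at a time against "inside" (subtree)
and "outside" (rest-of-tree) conditional likelihoods; by reversibility the
likelihood of the whole tree is, for any edge of length ``t``,

    L_site(t) = sum_k w_k (pi * h_k) . P_k(t) . d_k

where ``d`` is the inside partial below the edge and ``h`` the outside
product at its parent endpoint.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import Alignment
from .model import MODEL_ALPHABET, SubstitutionModel
from .tree import Node, PhyloTree

MISSING = 20
BL_MIN, BL_MAX = 1e-8, 20.0

_CODE = {aa: i for i, aa in enumerate(MODEL_ALPHABET)}


class LikelihoodError(ValueError):
    pass


def encode_alignment(aln: Alignment) -> np.ndarray:
    """Integer codes (n_taxa, n_sites); gap/X/unknown -> MISSING."""
    out = np.full((aln.n_taxa, aln.n_columns), MISSING, dtype=np.int8)
    for i, row in enumerate(aln.rows):
        out[i] = [_CODE.get(ch, MISSING) for ch in row]
    return out


class PatternData:
    """Unique site patterns of an alignment with multiplicities."""

    def __init__(self, aln: Alignment):
        codes = encode_alignment(aln)
        patterns, inverse, counts = np.unique(
            codes, axis=1, return_inverse=True, return_counts=True
        )
        self.taxon_ids = aln.taxon_ids
        self.patterns = patterns          # (n_taxa, n_patterns)
        self.site_to_pattern = inverse    # (n_sites,)
        self.weights = counts.astype(float)
        self.n_sites = aln.n_columns
        self.index = {t: i for i, t in enumerate(aln.taxon_ids)}


def _check_leaves(tree: PhyloTree, data: PatternData):
    leaves = set(tree.leaf_names())
    taxa = set(data.taxon_ids)
    if leaves != taxa:
        raise LikelihoodError(
            f"tree/alignment taxon mismatch: only-in-tree={sorted(leaves - taxa)}, "
            f"only-in-alignment={sorted(taxa - leaves)}"
        )


def _leaf_contribution(P: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """F(i) = P(t)[i, code] per category, all-ones for missing data.

    P: (K, 20, 20); codes: (n_patterns,) -> returns (K, 20, n_patterns).
    """
    K = P.shape[0]
    n = codes.shape[0]
    out = np.ones((K, 20, n))
    present = codes != MISSING
    if present.any():
        out[:, :, present] = P[:, :, codes[present]]
    return out


def _down_partials(tree: PhyloTree, data: PatternData, model: SubstitutionModel):
    """Inside partials: node -> (array (K,20,P), logscale (P,)).

    ``down[v][k,i,p]`` is the scaled likelihood of the data below ``v`` given
    state ``i`` at ``v`` under category ``k``.
    """
    down: dict[Node, tuple[np.ndarray, np.ndarray]] = {}
    contrib: dict[Node, tuple[np.ndarray, np.ndarray]] = {}
    npat = data.patterns.shape[1]
    for node in tree.postorder():
        if node.is_leaf:
            pass
        else:
            arr = np.ones((model.n_categories, 20, npat))
            ls = np.zeros(npat)
            for child in node.children:
                c_arr, c_ls = contrib[child]
                arr *= c_arr
                ls += c_ls
                del contrib[child]
            scale = arr.max(axis=(0, 1))
            scale[scale == 0.0] = 1.0
            arr /= scale[None, None, :]
            ls += np.log(scale)
            down[node] = (arr, ls)
        if node.parent is not None:
            P = model.transition_matrices(node.length)
            if node.is_leaf:
                codes = data.patterns[data.index[node.name]]
                contrib[node] = (_leaf_contribution(P, codes), np.zeros(npat))
            else:
                arr, ls = down[node]
                contrib[node] = (np.einsum("kij,kjp->kip", P, arr), ls)
    return down


def _root_pattern_loglik(tree, down, model):
    arr, ls = down[tree.root]
    pi = model.frequencies
    L = np.einsum("i,kip->kp", pi, arr).mean(axis=0)
    if np.any(L <= 0) or not np.all(np.isfinite(L)):
        raise LikelihoodError("non-finite site likelihood")
    return np.log(L) + ls


def tree_log_likelihood(tree: PhyloTree, aln: Alignment, model: SubstitutionModel,
                        data: PatternData | None = None):
    """Total and per-site log-likelihood of ``aln`` on ``tree``."""
    if data is None:
        data = PatternData(aln)
    _check_leaves(tree, data)
    down = _down_partials(tree, data, model)
    pat_ll = _root_pattern_loglik(tree, down, model)
    total = float(pat_ll @ data.weights)
    per_site = pat_ll[data.site_to_pattern]
    if not np.isfinite(total):
        raise LikelihoodError("non-finite log-likelihood")
    return total, per_site


def _outside_products(tree: PhyloTree, data: PatternData, model: SubstitutionModel,
                      down):
    """Outside vectors h: node -> (array (K,20,P), logscale).

    For ``v`` with parent ``u``, ``h[v]`` is the product of the transported
    outside vector of ``u`` and the edge contributions of v's siblings, so
    that L_site(t_v) = sum_k w_k (pi*h_k) . P_k(t_v) . down_k[v].
    """
    npat = data.patterns.shape[1]
    K = model.n_categories
    h: dict[Node, tuple[np.ndarray, np.ndarray]] = {}
    up: dict[Node, tuple[np.ndarray, np.ndarray]] = {
        tree.root: (np.ones((K, 20, npat)), np.zeros(npat))
    }
    for node in tree.preorder():
        if node.is_leaf:
            continue
        up_arr, up_ls = up[node]
        # edge contributions of each child
        contribs = []
        for child in node.children:
            P = model.transition_matrices(child.length)
            if child.is_leaf:
                codes = data.patterns[data.index[child.name]]
                contribs.append((_leaf_contribution(P, codes), np.zeros(npat)))
            else:
                arr, ls = down[child]
                contribs.append((np.einsum("kij,kjp->kip", P, arr), ls))
        for idx, child in enumerate(node.children):
            arr = up_arr.copy()
            ls = up_ls.copy()
            for jdx, (c_arr, c_ls) in enumerate(contribs):
                if jdx == idx:
                    continue
                arr = arr * c_arr
                ls = ls + c_ls
            scale = arr.max(axis=(0, 1))
            scale[scale == 0.0] = 1.0
            arr = arr / scale[None, None, :]
            ls = ls + np.log(scale)
            h[child] = (arr, ls)
            if not child.is_leaf:
                # up[v]_j = sum_i P(t_v)_{ji} h_i  (v -> parent transition,
                # same P by reversibility)
                P = model.transition_matrices(child.length)
                up[child] = (np.einsum("kji,kip->kjp", P, arr), ls)
    return h


def _edge_loglik_fn(h_v, down_v, model: SubstitutionModel, weights):
    """Return f(t) = total log-likelihood as a function of one edge length."""
    h_arr, h_ls = h_v
    d_arr, d_ls = down_v
    pi = model.frequencies
    pih = pi[None, :, None] * h_arr
    const_ls = h_ls + d_ls

    def f(t: float) -> float:
        P = model.transition_matrices(t)
        L = np.einsum("kip,kij,kjp->p", pih, P, d_arr) / model.n_categories
        L = np.maximum(L, 1e-300)
        return float((np.log(L) + const_ls) @ weights)

    return f


def _edge_down(node: Node, data: PatternData, model, down, npat):
    """Inside partial below an edge; for a leaf, the state indicator."""
    if node.is_leaf:
        codes = data.patterns[data.index[node.name]]
        present = codes != MISSING
        ind = np.zeros((20, npat))
        ind[codes[present], np.nonzero(present)[0]] = 1.0
        ind[:, ~present] = 1.0
        arr = np.broadcast_to(ind, (model.n_categories, 20, npat)).copy()
        return arr, np.zeros(npat)
    return down[node]


def optimize_branch_lengths(tree: PhyloTree, aln: Alignment, model: SubstitutionModel,
                            tol: float = 1e-4, max_sweeps: int = 50,
                            data: PatternData | None = None):
    """Round-robin single-edge optimization until a sweep gains < ``tol``.

    Each sweep recomputes inside/outside partials once and optimizes every
    edge against them; if a sweep ever fails to improve the total
    log-likelihood (possible because partials go stale within a sweep), the
    sweep is redone edge-by-edge with fresh partials.  Returns
    ``(tree, trace, converged)``; the input tree is modified in place.
    """
    if data is None:
        data = PatternData(aln)
    _check_leaves(tree, data)
    npat = data.patterns.shape[1]
    total, _ = tree_log_likelihood(tree, aln, model, data)
    trace = [total]
    converged = False

    def optimize_edge(node, down, h):
        f = _edge_loglik_fn(h[node], _edge_down(node, data, model, down, npat),
                            model, data.weights)
        res = minimize_scalar(lambda t: -f(t), bounds=(BL_MIN, BL_MAX),
                              method="bounded", options={"xatol": 1e-6})
        if -res.fun > f(node.length):
            node.length = float(res.x)

    for _ in range(max_sweeps):
        saved = [(n, n.length) for n in tree.edges()]
        down = _down_partials(tree, data, model)
        h = _outside_products(tree, data, model, down)
        for node in tree.edges():
            optimize_edge(node, down, h)
        new_total, _ = tree_log_likelihood(tree, aln, model, data)
        if new_total < total - 1e-9:
            # stale-partial sweep hurt: redo exactly, one edge at a time
            for n, length in saved:
                n.length = length
            for node in tree.edges():
                down = _down_partials(tree, data, model)
                h = _outside_products(tree, data, model, down)
                optimize_edge(node, down, h)
            new_total, _ = tree_log_likelihood(tree, aln, model, data)
            new_total = max(new_total, total)
        gain = new_total - total
        total = max(total, new_total)
        trace.append(total)
        if gain < tol:
            converged = True
            break
    return tree, trace, converged
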