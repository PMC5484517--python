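"""Minimum-change analysis of discrete gene-architecture characters.

Built for the fused-vs-split RNA-polymerase A-subunit question: given a
rooted tree and a binary (extensible to k-state) character on the leaves,
count the minimum number of state changes (generalized Fitch), enumerate
all most-parsimonious reconstructions with typed events (Sankoff backtrace
with unit costs), and scan every possible outgroup attachment point of an
unrooted ingroup tree to see which rootings need the fewest events.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .tree import Node, PhyloTree

FUSED, SPLIT = "fused", "split"


class ParsimonyError(ValueError):
    pass


@dataclass(frozen=True)
class CharacterStateMap:
    """taxon -> character state (e.g. ``fused`` / ``split``)."""

    states: dict
    alphabet: tuple = ()

    def __post_init__(self):
        observed = tuple(sorted(set(self.states.values())))
        object.__setattr__(self, "alphabet",
                           tuple(self.alphabet) or observed)
        extra = set(self.states.values()) - set(self.alphabet)
        if extra:
            raise ParsimonyError(f"states outside the alphabet: {sorted(extra)}")

    def state(self, taxon: str) -> str:
        return self.states[taxon]

    def check_covers(self, taxa) -> None:
        missing = [t for t in taxa if t not in self.states]
        if missing:
            raise ParsimonyError(f"leaves without a state: {sorted(missing)}")


def read_states_tsv(path) -> CharacterStateMap:
    states = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("taxon"):
            raise ParsimonyError(f"{path}: expected header 'taxon\\tstate'")
        for line in fh:
            if not line.strip():
                continue
            taxon, state = line.rstrip("\n").split("\t")
            states[taxon] = state
    return CharacterStateMap(states)


def fitch_min_changes(tree: PhyloTree, states: CharacterStateMap) -> int:
    """Minimum number of state changes (generalized Fitch).

    Polytomies use the multi-child generalization: each node keeps the set
    of states attained by the maximum number of children; the change count
    increases by ``(number of children) - (that maximum)`` at each node.
    """
    states.check_covers(tree.leaf_names())
    changes = 0
    sets: dict[Node, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            sets[node] = frozenset([states.state(node.name)])
            continue
        votes: dict[str, int] = {}
        for child in node.children:
            for s in sets[child]:
                votes[s] = votes.get(s, 0) + 1
        top = max(votes.values())
        sets[node] = frozenset(s for s, v in votes.items() if v == top)
        changes += len(node.children) - top
    return changes


@dataclass(frozen=True)
class Event:
    edge_child_leafset: frozenset      # identifies the edge (leaves below it)
    from_state: str
    to_state: str
    kind: str                          # split | fusion | change


@dataclass
class ParsimonyResult:
    min_changes: int
    reconstructions: list              # list of (node-state dict keyed by leafset)
    events_per_mpr: list               # list of tuples of Event
    truncated: bool = False


def _event_kind(from_state: str, to_state: str) -> str:
    if (from_state, to_state) == (FUSED, SPLIT):
        return "split"
    if (from_state, to_state) == (SPLIT, FUSED):
        return "fusion"
    return "change"


def reconstruct_events(tree: PhyloTree, states: CharacterStateMap,
                       max_mprs: int = 10_000) -> ParsimonyResult:
    """Enumerate all most-parsimonious reconstructions with typed events.

    Unit-cost Sankoff: bottom-up minimal cost vectors, then a top-down
    backtrace that branches over every optimal ancestral assignment.  Each
    change is typed ``split`` (fused -> split), ``fusion`` (split -> fused)
    or ``change`` for non-binary alphabets.
    """
    states.check_covers(tree.leaf_names())
    alphabet = states.alphabet
    INF = float("inf")
    cost: dict[Node, dict[str, float]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            s0 = states.state(node.name)
            cost[node] = {s: (0.0 if s == s0 else INF) for s in alphabet}
        else:
            cost[node] = {
                s: sum(
                    min(cost[c][t] + (0.0 if t == s else 1.0) for t in alphabet)
                    for c in node.children
                )
                for s in alphabet
            }
    root_costs = cost[tree.root]
    min_changes = min(root_costs.values())

    leafsets: dict[Node, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            leafsets[node] = frozenset([node.name])
        else:
            leafsets[node] = frozenset().union(*(leafsets[c] for c in node.children))

    reconstructions: list[dict] = []
    events_per_mpr: list[tuple] = []
    truncated = False

    def backtrace(assignments: dict, events: list, pending: list):
        nonlocal truncated
        if len(reconstructions) >= max_mprs:
            truncated = True
            return
        if not pending:
            reconstructions.append(dict(assignments))
            events_per_mpr.append(tuple(events))
            return
        node, s = pending[0]
        rest = pending[1:]
        children = [c for c in node.children]

        def assign_children(idx: int, new_pending, new_events):
            nonlocal truncated
            if truncated:
                return
            if idx == len(children):
                backtrace(assignments, events + new_events, rest + new_pending)
                return
            c = children[idx]
            best = min(cost[c][t] + (0.0 if t == s else 1.0) for t in alphabet)
            for t in alphabet:
                if cost[c][t] + (0.0 if t == s else 1.0) == best:
                    assignments[leafsets[c]] = t
                    ev = new_events
                    if t != s:
                        ev = new_events + [Event(leafsets[c], s, t, _event_kind(s, t))]
                    assign_children(idx + 1,
                                    new_pending + ([(c, t)] if c.children else []),
                                    ev)
            # restore nothing needed: assignments overwritten per branch

        assign_children(0, [], [])

    for s in alphabet:
        if root_costs[s] == min_changes:
            assignments = {leafsets[tree.root]: s}
            backtrace(assignments, [], [(tree.root, s)])
    return ParsimonyResult(min_changes=int(min_changes),
                           reconstructions=reconstructions,
                           events_per_mpr=events_per_mpr,
                           truncated=truncated)


@dataclass
class RootingScan:
    """Per-candidate-attachment minimum change counts."""

    edge_counts: list                  # (edge leafset below, min_changes)
    min_changes: int
    argmin_edges: tuple


def rooting_scan(ingroup_tree: PhyloTree, outgroup_state: str,
                 states: CharacterStateMap,
                 outgroup_name: str = "__outgroup__") -> RootingScan:
    """Attach an outgroup leaf on every edge and count changes each time.

    The ingroup tree is unrooted; for each of its edges a pendant outgroup
    leaf carrying ``outgroup_state`` is attached mid-edge and the resulting
    tree is rooted at the junction before running Fitch.  The attachment(s)
    achieving the global minimum are reported by the leaf set below the
    edge.
    """
    states.check_covers(ingroup_tree.leaf_names())
    combined = CharacterStateMap(
        {**states.states, outgroup_name: outgroup_state},
        alphabet=tuple(sorted(set(states.alphabet) | {outgroup_state})),
    )
    base = ingroup_tree.copy()
    if base.rooted:
        base.unroot()
    edge_ids = []
    for i, node in enumerate(base.postorder()):
        if node.parent is not None:
            edge_ids.append(i)
    results = []
    for i in edge_ids:
        work = base.copy()
        node = list(work.postorder())[i]
        below = frozenset(
            leaf.name for leaf in work.leaves()
            if _is_below(leaf, node)
        )
        parent = node.parent
        junction = Node(length=node.length / 2)
        idx = parent.children.index(node)
        parent.children[idx] = junction
        junction.parent = parent
        node.length /= 2
        junction.add_child(node)
        junction.add_child(Node(name=outgroup_name, length=0.1))
        rooted = PhyloTree(work.root, rooted=False)
        rooted.reroot_at_node(junction)
        results.append((below, fitch_min_changes(rooted, combined)))
    best = min(c for _, c in results)
    argmin = tuple(ls for ls, c in results if c == best)
    return RootingScan(edge_counts=results, min_changes=best, argmin_edges=argmin)


def _is_below(leaf: Node, ancestor: Node) -> bool:
    cur = leaf
    while cur is not None:
        if cur is ancestor:
            return True
        cur = cur.parent
    return False


def brute_force_min_changes(tree: PhyloTree, states: CharacterStateMap) -> int:
    """Exhaustive minimum over all ancestral labelings (test oracle)."""
    states.check_covers(tree.leaf_names())
    internals = [n for n in tree.postorder() if not n.is_leaf]
    alphabet = states.alphabet
    best = None
    for assign in itertools.product(alphabet, repeat=len(internals)):
        amap = dict(zip((id(n) for n in internals), assign))

        def state_of(n: Node) -> str:
            return states.state(n.name) if n.is_leaf else amap[id(n)]

        changes = sum(
            1
            for n in tree.postorder()
            if n.parent is not None and state_of(n) != state_of(n.parent)
        )
        if best is None or changes < best:
            best = changes
    return best
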