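"""Topology interrogation: monophyly with supports, outgroup rooting,
three-domain classification of marker trees and the marker tabulation.

Classification follows the two competing tree-of-life shapes: a tree is
``woese`` when the archaeal leaves form a clade (three-domain topology,
Archaea and Eukarya sister groups), ``eocyte`` when the eukaryotic leaves
form a clade nested strictly inside the archaeal part of the tree (Archaea
paraphyletic), and ``unresolved`` otherwise.  Trees are always rooted with
the bacterial leaves as outgroup first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment import TaxonGroupMap
from .tree import Node, PhyloTree, canonical_side, leafset_below


class DiagnosticsError(ValueError):
    pass


@dataclass(frozen=True)
class CladeQuery:
    present: bool
    support: float | None = None


@dataclass(frozen=True)
class TopologyClass:
    label: str                                   # woese | eocyte | unresolved
    archaea_monophyly_support: float | None = None
    sister_of_eukarya: frozenset = frozenset()   # group labels
    eukarya_sister_support: float | None = None
    support_min: float = 0.0


def tree_bipartitions(tree: PhyloTree):
    """Canonical non-trivial bipartitions with their supports (dict)."""
    if tree.n_leaves < 4:
        return {}
    return tree.bipartitions(with_support=True)


def test_monophyly(tree: PhyloTree, taxa) -> CladeQuery:
    """Is ``taxa`` one side of some edge of the (unrooted) tree?

    Support is the support of that edge when annotated.  The full leaf set
    and single leaves are trivially monophyletic with absent support.
    """
    taxa = frozenset(taxa)
    all_leaves = frozenset(tree.leaf_names())
    unknown = taxa - all_leaves
    if unknown:
        raise DiagnosticsError(f"unknown taxa: {sorted(unknown)}")
    if taxa == all_leaves or len(taxa) == 1:
        return CladeQuery(present=True)
    if len(taxa) == len(all_leaves) - 1:
        # complement of one leaf: trivially an edge (the pendant edge)
        return CladeQuery(present=True)
    bips = tree.bipartitions(with_support=True)
    key = canonical_side(taxa, all_leaves)
    if key in bips:
        return CladeQuery(present=True, support=bips[key])
    return CladeQuery(present=False)


def root_with_outgroup(tree: PhyloTree, outgroup) -> PhyloTree:
    """Root on the edge separating the outgroup, at its midpoint.

    When the outgroup is not monophyletic in the unrooted sense, the edge
    whose bipartition side has the highest Jaccard similarity to the
    outgroup is used instead and a warning flag is set on the result (the
    returned tree's ``outgroup_monophyletic`` attribute).
    """
    outgroup = frozenset(outgroup)
    all_leaves = frozenset(tree.leaf_names())
    unknown = outgroup - all_leaves
    if unknown:
        raise DiagnosticsError(f"unknown outgroup taxa: {sorted(unknown)}")
    if not outgroup or outgroup == all_leaves:
        raise DiagnosticsError("outgroup must be a proper non-empty leaf subset")
    work = tree.copy()
    if work.rooted:
        work.unroot()
    best_node, best_jaccard, exact = None, -1.0, False
    for node in work.postorder():
        if node.parent is None:
            continue
        side = leafset_below(node)
        for candidate in (side, all_leaves - side):
            inter = len(candidate & outgroup)
            union = len(candidate | outgroup)
            j = inter / union
            if j > best_jaccard:
                best_jaccard, best_node = j, node
                exact = candidate == outgroup
    work.reroot_on_edge(best_node, fraction=0.5)
    # orient: make the outgroup-side child first for readability
    work.outgroup_monophyletic = exact
    return work


def sister_group(rooted_tree: PhyloTree, taxa) -> frozenset:
    """Leaf set of the sibling subtree of the clade ``taxa``."""
    if not rooted_tree.rooted:
        raise DiagnosticsError("sister_group needs a rooted tree")
    taxa = frozenset(taxa)
    mrca = _find_clade(rooted_tree, taxa)
    if mrca is None:
        raise DiagnosticsError(f"{sorted(taxa)} is not a clade of the rooted tree")
    parent = mrca.parent
    if parent is None:
        raise DiagnosticsError("clade is the whole tree; no sister")
    out = frozenset()
    for sib in parent.children:
        if sib is not mrca:
            out |= leafset_below(sib)
    return out


def _find_clade(tree: PhyloTree, taxa: frozenset) -> Node | None:
    for node in tree.postorder():
        if leafset_below(node) == taxa:
            return node
    return None


def classify_topology(tree: PhyloTree, groups: TaxonGroupMap,
                      support_min: float = 0.0) -> TopologyClass:
    """Classify a marker tree as woese / eocyte / unresolved.

    The tree is rooted with its bacterial leaves; ``woese`` requires the
    archaeal leaves to be monophyletic with support >= ``support_min`` (when
    supports are absent the support condition is waived); ``eocyte``
    requires the eukaryotic leaves to form a clade strictly inside the
    archaeal MRCA.  ``sister_of_eukarya`` reports the group labels of the
    Eukarya clade's sister leaves.
    """
    leaves = tree.leaf_names()
    groups.check_covers(leaves)
    bact = groups.taxa_in_domain("Bacteria", leaves)
    arch = groups.taxa_in_domain("Archaea", leaves)
    euk = groups.taxa_in_domain("Eukarya", leaves)
    for name, members in (("Bacteria", bact), ("Archaea", arch), ("Eukarya", euk)):
        if not members:
            raise DiagnosticsError(f"tree has no {name} leaves")
    rooted = root_with_outgroup(tree, bact)

    arch_q = test_monophyly(rooted, arch)
    if arch_q.present:
        ok = (arch_q.support is None or support_min <= 0
              or arch_q.support >= support_min)
        if ok:
            return TopologyClass("woese",
                                 archaea_monophyly_support=arch_q.support,
                                 support_min=support_min)
        return TopologyClass("unresolved",
                             archaea_monophyly_support=arch_q.support,
                             support_min=support_min)

    euk_clade = _find_clade(rooted, frozenset(euk))
    if euk_clade is not None:
        arch_mrca = _mrca(rooted, arch)
        nested = _is_descendant(euk_clade, arch_mrca)
        if nested:
            sister = sister_group(rooted, frozenset(euk))
            labels = frozenset(groups.group(t) for t in sister)
            support = euk_clade.parent.support if euk_clade.parent else None
            return TopologyClass("eocyte", sister_of_eukarya=labels,
                                 eukarya_sister_support=support,
                                 support_min=support_min)
    return TopologyClass("unresolved", support_min=support_min)


def _mrca(tree: PhyloTree, taxa) -> Node:
    taxa = frozenset(taxa)
    best = tree.root
    changed = True
    while changed:
        changed = False
        for child in best.children:
            if taxa <= leafset_below(child):
                best = child
                changed = True
                break
    return best


def _is_descendant(node: Node, ancestor: Node) -> bool:
    cur = node
    while cur is not None:
        if cur is ancestor:
            return True
        cur = cur.parent
    return False


# ---------------------------------------------------------------------------
# Marker tabulation (per-phylum monophyly counts at support thresholds)
# ---------------------------------------------------------------------------

@dataclass
class MarkerRow:
    marker_id: str
    label: str
    phylum_monophyly: dict          # phylum -> CladeQuery | None (absent)
    loki_sister: bool
    loki_sister_support: float | None
    loki_sister_subset: frozenset
    archaea_support: float | None


@dataclass
class MarkerTable:
    rows: list
    phyla: tuple
    thresholds: tuple = (50.0, 80.0)
    summary: dict = field(default_factory=dict)

    def applicable(self, phylum: str) -> int:
        return sum(1 for r in self.rows if r.phylum_monophyly[phylum] is not None)


def tabulate_marker_trees(marker_trees, groups: TaxonGroupMap, phyla_to_test,
                          loki_group: str = "Lokiarchaeota",
                          thresholds=(50.0, 80.0)) -> MarkerTable:
    """Tabulate per-marker monophyly and Loki-Eukarya sisterhood.

    Mirrors a comparative marker table: for every phylum the number of
    marker trees recovering its monophyly (at any support, and above each
    threshold), the number of trees with Archaea monophyletic at full
    support, and the number in which a (subset of the) Loki-labelled leaves
    is the sister group of the Eukarya clade.  Markers lacking a phylum
    entirely are excluded from that phylum's denominator.
    """
    seen = set()
    rows = []
    for marker_id, tree in marker_trees:
        if marker_id in seen:
            raise DiagnosticsError(f"duplicate marker id {marker_id!r}")
        seen.add(marker_id)
        leaves = tree.leaf_names()
        groups.check_covers(leaves)
        cls = classify_topology(tree, groups)
        bact = groups.taxa_in_domain("Bacteria", leaves)
        rooted = root_with_outgroup(tree, bact)
        phylum_res = {}
        for phylum in phyla_to_test:
            members = groups.taxa_in_group(phylum, leaves)
            if len(members) < 2:
                phylum_res[phylum] = None      # not applicable
            else:
                phylum_res[phylum] = test_monophyly(rooted, members)
        arch = groups.taxa_in_domain("Archaea", leaves)
        arch_q = test_monophyly(rooted, arch)
        # Loki-Eukarya sisterhood: Eukarya clade's sister is a subset of the
        # Loki-labelled leaves (one, two or all of them)
        loki = groups.taxa_in_group(loki_group, leaves)
        euk = groups.taxa_in_domain("Eukarya", leaves)
        sister_flag, sister_support, subset = False, None, frozenset()
        euk_clade = _find_clade(rooted, frozenset(euk))
        if euk_clade is not None and loki:
            sis = sister_group(rooted, frozenset(euk))
            if sis and sis <= loki:
                sister_flag = True
                subset = sis
                sister_support = (euk_clade.parent.support
                                  if euk_clade.parent else None)
        rows.append(MarkerRow(
            marker_id=marker_id, label=cls.label, phylum_monophyly=phylum_res,
            loki_sister=sister_flag, loki_sister_support=sister_support,
            loki_sister_subset=subset,
            archaea_support=arch_q.support if arch_q.present else None,
        ))
    table = MarkerTable(rows=rows, phyla=tuple(phyla_to_test),
                        thresholds=tuple(thresholds))
    table.summary = _summarize(table)
    return table


def _summarize(table: MarkerTable) -> dict:
    def count(pred):
        return sum(1 for r in table.rows if pred(r))

    summary = {}
    for phylum in table.phyla:
        qs = [r.phylum_monophyly[phylum] for r in table.rows]
        present = [q for q in qs if q is not None and q.present]
        entry = {"any": len(present)}
        for thr in table.thresholds:
            entry[f">{thr:g}"] = sum(
                1 for q in present if q.support is not None and q.support > thr
            )
        entry["n_applicable"] = sum(1 for q in qs if q is not None)
        summary[f"monophyly_{phylum}"] = entry
    summary["archaea_monophyly_100"] = count(
        lambda r: r.archaea_support is not None and r.archaea_support >= 100.0
    )
    loki_rows = [r for r in table.rows if r.loki_sister]
    entry = {"any": len(loki_rows)}
    for thr in table.thresholds:
        entry[f">{thr:g}"] = sum(
            1 for r in loki_rows
            if r.loki_sister_support is not None and r.loki_sister_support > thr
        )
    summary["loki_eukarya_sister"] = entry
    summary["class_counts"] = {
        label: count(lambda r, L=label: r.label == L)
        for label in ("woese", "eocyte", "unresolved")
    }
    return summary


# ---------------------------------------------------------------------------
# AU-based marker partitioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AUPartition:
    woese_relevant: tuple
    eocyte_relevant: tuple
    unresolved: tuple
    both_rejected: tuple


def partition_markers_by_au(au_results: dict, alpha: float = 0.05) -> AUPartition:
    """Split markers by which reference topology their AU p-values support.

    ``au_results`` maps marker_id -> (p_woese, p_eocyte).  A marker is
    woese-relevant iff it significantly rejects the eocyte topology while
    not rejecting the woese one (p_eocyte < alpha <= p_woese), and vice
    versa; everything else (including both-rejected, which is also reported
    separately) is unresolved.
    """
    woese, eocyte, unresolved, both = [], [], [], []
    for mid, (pw, pe) in au_results.items():
        if not (0 <= pw <= 1 and 0 <= pe <= 1):
            raise DiagnosticsError(f"marker {mid!r}: p-values outside [0,1]")
        if pe < alpha <= pw:
            woese.append(mid)
        elif pw < alpha <= pe:
            eocyte.append(mid)
        else:
            unresolved.append(mid)
            if pw < alpha and pe < alpha:
                both.append(mid)
    return AUPartition(tuple(woese), tuple(eocyte), tuple(unresolved), tuple(both))
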