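"""Monophyly queries, outgroup rooting, topology classification,
marker tabulation and AU-based partitioning."""

import itertools

import numpy as np
import pytest

from phyloconflict.alignment import TaxonGroupMap
from phyloconflict.diagnostics import (DiagnosticsError, classify_topology,
                                       partition_markers_by_au,
                                       root_with_outgroup, sister_group,
                                       tabulate_marker_trees,
                                       tree_bipartitions)
from phyloconflict.diagnostics import test_monophyly as monophyly_query
from phyloconflict.tree import leafset_below, parse_newick

from conftest import random_binary_tree

GROUPS = TaxonGroupMap({
    "b1": ("Bacteria", "Bacteria"), "b2": ("Bacteria", "Bacteria"),
    "e1": ("Eukarya", "Eukarya"), "e2": ("Eukarya", "Eukarya"),
    "l1": ("Lokiarchaeota", "Archaea"), "l2": ("Lokiarchaeota", "Archaea"),
    "y1": ("Euryarchaeota", "Archaea"), "y2": ("Euryarchaeota", "Archaea"),
    "c1": ("Crenarchaeota", "Archaea"), "c2": ("Crenarchaeota", "Archaea"),
})

WOESE = ("((b1:1,b2:1):1,((e1:1,e2:1):1,(((l1:1,l2:1):1,(y1:1,y2:1):1):1,"
         "(c1:1,c2:1):1):1):1);")
EOCYTE = ("((b1:1,b2:1):1,((((e1:1,e2:1):1,(l1:1,l2:1):1)90:1,(y1:1,y2:1):1)"
          ":1,(c1:1,c2:1):1):1);")


class TestBipartitions:
    def test_quartet_single_split(self):
        t = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assert len(tree_bipartitions(t)) == 1

    def test_star_tree_empty(self):
        assert tree_bipartitions(parse_newick("(a,b,c,d,e);")) == {}

    def test_binary_tree_count(self):
        rng = np.random.default_rng(2)
        for n in (5, 8, 12):
            t = random_binary_tree(rng, n)
            assert len(tree_bipartitions(t)) == n - 3


class TestMonophyly:
    def test_full_leafset_trivially_present(self):
        t = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        q = monophyly_query(t, {"a", "b", "c", "d"})
        assert q.present and q.support is None

    def test_exhaustive_subsets_match_bruteforce(self):
        rng = np.random.default_rng(4)
        t = random_binary_tree(rng, 6)
        names = t.leaf_names()
        sides = set()
        for node in t.postorder():
            if node.parent is not None:
                s = leafset_below(node)
                sides.add(s)
                sides.add(frozenset(names) - s)
        for r in range(1, 6):
            for combo in itertools.combinations(names, r):
                expected = frozenset(combo) in sides or r == len(names)
                assert monophyly_query(t, combo).present == expected

    def test_unknown_taxon_error(self):
        t = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        with pytest.raises(DiagnosticsError):
            monophyly_query(t, {"a", "zz"})


class TestRooting:
    def test_single_leaf_outgroup(self):
        t = parse_newick("(a:1,b:1,(c:1,d:1):1);")
        rooted = root_with_outgroup(t, {"a"})
        assert rooted.rooted
        first_split = {leafset_below(c) for c in rooted.root.children}
        assert frozenset({"a"}) in first_split
        assert rooted.outgroup_monophyletic

    def test_monophyletic_outgroup_keeps_ingroup(self):
        t = parse_newick("((o1:1,(o2:1,o3:1):1):1,((a:1,b:1):1,c:1):1);")
        rooted = root_with_outgroup(t, {"o1", "o2", "o3"})
        sides = {leafset_below(c) for c in rooted.root.children}
        assert frozenset({"o1", "o2", "o3"}) in sides
        assert frozenset({"a", "b", "c"}) in sides

    def test_rerooting_preserves_bipartitions(self):
        t = parse_newick(WOESE)
        rooted = root_with_outgroup(t, {"b1", "b2"})
        assert rooted.bipartitions() == parse_newick(WOESE).bipartitions()

    def test_non_monophyletic_outgroup_flagged(self):
        t = parse_newick("((o1:1,a:1):1,(o2:1,b:1):1);")
        rooted = root_with_outgroup(t, {"o1", "o2"})
        assert rooted.outgroup_monophyletic is False

    def test_whole_leafset_outgroup_error(self):
        t = parse_newick("(a:1,b:1,c:1,d:1);")
        with pytest.raises(DiagnosticsError):
            root_with_outgroup(t, {"a", "b", "c", "d"})


class TestSisterGroup:
    def test_cherry(self):
        t = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t.rooted = True
        assert sister_group(t, {"a"}) == {"b"}

    def test_caterpillar(self):
        t = parse_newick("(((a:1,b:1):1,c:1):1,d:1);")
        t.rooted = True
        assert sister_group(t, {"a", "b"}) == {"c"}
        assert sister_group(t, {"a", "b", "c"}) == {"d"}

    def test_random_trees_vs_parent_lookup(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            t = random_binary_tree(rng, 7)
            t.reroot_on_edge(t.find_leaf(t.leaf_names()[0]))
            for node in list(t.postorder()):
                if node.parent is None or node.parent.parent is None:
                    continue
                clade = leafset_below(node)
                siblings = frozenset().union(*(
                    leafset_below(s) for s in node.parent.children
                    if s is not node))
                assert sister_group(t, clade) == siblings

    def test_non_clade_error(self):
        t = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t.rooted = True
        with pytest.raises(DiagnosticsError):
            sister_group(t, {"a", "c"})


class TestClassify:
    def test_woese_tree(self):
        cls = classify_topology(parse_newick(WOESE), GROUPS)
        assert cls.label == "woese"

    def test_eocyte_tree_with_sister_label(self):
        cls = classify_topology(parse_newick(EOCYTE), GROUPS)
        assert cls.label == "eocyte"
        assert cls.sister_of_eukarya == frozenset({"Lokiarchaeota"})
        assert cls.eukarya_sister_support == 90.0

    def test_invariant_to_initial_rooting(self):
        for text in (WOESE, EOCYTE):
            t = parse_newick(text)
            expected = classify_topology(t, GROUPS).label
            for leaf_name in ("e1", "y2", "c1"):
                t2 = parse_newick(text)
                t2.reroot_on_edge(t2.find_leaf(leaf_name))
                assert classify_topology(t2, GROUPS).label == expected

    def test_missing_domain_error(self):
        t = parse_newick("((b1:1,b2:1):1,(y1:1,y2:1):1);")
        with pytest.raises(DiagnosticsError, match="Eukarya"):
            classify_topology(t, GROUPS)

    def test_scrambled_eukarya_unresolved(self):
        t = parse_newick("((b1:1,b2:1):1,((e1:1,y1:1):1,((e2:1,c1:1):1,"
                         "(l1:1,(l2:1,(y2:1,c2:1):1):1):1):1):1);")
        assert classify_topology(t, GROUPS).label == "unresolved"


class TestTabulate:
    PHYLA = ("Euryarchaeota", "Crenarchaeota", "Lokiarchaeota")

    def test_empty_input_all_zero(self):
        table = tabulate_marker_trees([], GROUPS, self.PHYLA)
        for phylum in self.PHYLA:
            assert table.summary[f"monophyly_{phylum}"]["any"] == 0
        assert table.summary["archaea_monophyly_100"] == 0
        assert table.summary["loki_eukarya_sister"]["any"] == 0

    def test_handcrafted_counts(self):
        woese_sup = ("((b1:1,b2:1):1,((e1:1,e2:1):1,(((l1:1,l2:1)95:1,"
                     "(y1:1,y2:1)60:1):1,(c1:1,c2:1)100:1)100:1):1);")
        trees = [
            ("m1", parse_newick(woese_sup)),
            ("m2", parse_newick(EOCYTE)),
            ("m3", parse_newick(WOESE)),
        ]
        table = tabulate_marker_trees(trees, GROUPS, self.PHYLA)
        s = table.summary
        # Euryarchaeota monophyletic in all three; supported >50 only in m1
        assert s["monophyly_Euryarchaeota"]["any"] == 3
        assert s["monophyly_Euryarchaeota"][">50"] == 1
        assert s["monophyly_Euryarchaeota"][">80"] == 0
        assert s["monophyly_Crenarchaeota"][">80"] == 1
        assert s["monophyly_Lokiarchaeota"][">80"] == 1
        # Loki sister to Eukarya only in the eocyte tree (support 90)
        assert s["loki_eukarya_sister"]["any"] == 1
        assert s["loki_eukarya_sister"][">80"] == 1
        assert s["class_counts"] == {"woese": 2, "eocyte": 1, "unresolved": 0}

    def test_duplicate_marker_ids_error(self):
        trees = [("m1", parse_newick(WOESE)), ("m1", parse_newick(WOESE))]
        with pytest.raises(DiagnosticsError):
            tabulate_marker_trees(trees, GROUPS, self.PHYLA)

    def test_absent_phylum_not_applicable(self):
        # tree without crenarchaeotes: excluded from that denominator
        t = parse_newick("((b1:1,b2:1):1,((e1:1,e2:1):1,((l1:1,l2:1):1,"
                         "(y1:1,y2:1):1):1):1);")
        table = tabulate_marker_trees([("m1", t)], GROUPS, self.PHYLA)
        assert table.summary["monophyly_Crenarchaeota"]["n_applicable"] == 0
        assert table.summary["monophyly_Euryarchaeota"]["n_applicable"] == 1


class TestAUPartition:
    def test_rules(self):
        res = partition_markers_by_au({
            "w": (0.9, 0.01),
            "e": (0.01, 0.8),
            "u": (0.2, 0.2),
            "both": (0.01, 0.01),
        })
        assert res.woese_relevant == ("w",)
        assert res.eocyte_relevant == ("e",)
        assert set(res.unresolved) == {"u", "both"}
        assert res.both_rejected == ("both",)

    def test_invalid_p_values(self):
        with pytest.raises(DiagnosticsError):
            partition_markers_by_au({"m": (1.2, 0.5)})
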