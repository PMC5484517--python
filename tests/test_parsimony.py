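"""Fitch / Sankoff parsimony of gene-architecture characters."""

import numpy as np
import pytest

from phyloconflict.examples import (loki_ancestor_example,
                                    thaum_rooted_example,
                                    THAUM_ROOTED_STATES)
from phyloconflict.parsimony import (CharacterStateMap, FUSED, ParsimonyError,
                                     SPLIT, brute_force_min_changes,
                                     fitch_min_changes, reconstruct_events,
                                     rooting_scan)
from phyloconflict.tree import parse_newick

from conftest import random_binary_tree


class TestWorkedExamples:
    def test_thaum_rooting_needs_single_split(self):
        tree, states = thaum_rooted_example()
        assert fitch_min_changes(tree, states) == 1

    def test_single_split_placed_after_korarchaeum_divergence(self):
        tree, states = thaum_rooted_example()
        res = reconstruct_events(tree, states)
        assert len(res.events_per_mpr) == 1
        (event,) = res.events_per_mpr[0]
        assert event.kind == "split"
        assert event.edge_child_leafset == frozenset(
            {"Crenarchaeota", "Lokiarchaeota", "Euryarchaeota"})

    def test_loki_ancestor_topology_needs_four_events(self):
        tree, states = loki_ancestor_example()
        assert fitch_min_changes(tree, states) == 4

    def test_rooting_scan_prefers_thaum_branch(self):
        ingroup = parse_newick(
            "(Thaumarchaeota:0.3,Korarchaeum:0.3,(Crenarchaeota:0.3,"
            "(Lokiarchaeota:0.3,Euryarchaeota:0.3):0.2):0.2);")
        states = CharacterStateMap(
            {k: v for k, v in THAUM_ROOTED_STATES.items() if k != "Bacteria"},
            alphabet=(FUSED, SPLIT))
        scan = rooting_scan(ingroup, FUSED, states)
        assert scan.min_changes == 1
        assert frozenset({"Thaumarchaeota"}) in scan.argmin_edges
        # attachment inside the split-carrying clade costs extra
        counts = dict(scan.edge_counts)
        assert counts[frozenset({"Euryarchaeota"})] == 2


class TestFitch:
    def test_uniform_states_zero_changes(self):
        tree = parse_newick("((a,b),(c,d));")
        states = CharacterStateMap({t: FUSED for t in "abcd"},
                                   alphabet=(FUSED, SPLIT))
        assert fitch_min_changes(tree, states) == 0
        assert reconstruct_events(tree, states).events_per_mpr == [()]

    def test_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(13)
        for _ in range(40):
            tree = random_binary_tree(rng, 8)
            states = CharacterStateMap(
                {t: (FUSED if rng.random() < 0.5 else SPLIT)
                 for t in tree.leaf_names()},
                alphabet=(FUSED, SPLIT))
            tree.rooted = True
            assert fitch_min_changes(tree, states) == \
                brute_force_min_changes(tree, states)

    def test_polytomy_generalized_fitch(self):
        tree = parse_newick("(a,b,c,d,e);")
        states = CharacterStateMap(
            {"a": FUSED, "b": FUSED, "c": FUSED, "d": SPLIT, "e": SPLIT},
            alphabet=(FUSED, SPLIT))
        assert fitch_min_changes(tree, states) == \
            brute_force_min_changes(tree, states) == 2

    def test_unmapped_leaf_error(self):
        tree = parse_newick("((a,b),(c,d));")
        states = CharacterStateMap({"a": FUSED, "b": SPLIT, "c": FUSED})
        with pytest.raises(ParsimonyError):
            fitch_min_changes(tree, states)

    def test_rooting_invariance(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            tree = random_binary_tree(rng, 7)
            states = CharacterStateMap(
                {t: (FUSED if rng.random() < 0.5 else SPLIT)
                 for t in tree.leaf_names()},
                alphabet=(FUSED, SPLIT))
            counts = set()
            for leaf_name in tree.leaf_names()[:4]:
                t = tree.copy()
                t.reroot_on_edge(t.find_leaf(leaf_name))
                counts.add(fitch_min_changes(t, states))
            assert len(counts) == 1


class TestMPRs:
    def test_every_mpr_has_min_changes_events(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            tree = random_binary_tree(rng, 7)
            tree.rooted = True
            states = CharacterStateMap(
                {t: (FUSED if rng.random() < 0.5 else SPLIT)
                 for t in tree.leaf_names()},
                alphabet=(FUSED, SPLIT))
            res = reconstruct_events(tree, states)
            mc = fitch_min_changes(tree, states)
            assert res.min_changes == mc
            assert res.events_per_mpr
            for events in res.events_per_mpr:
                assert len(events) == mc

    def test_event_typing(self):
        tree = parse_newick("((a,b),(c,d));")
        states = CharacterStateMap(
            {"a": FUSED, "b": FUSED, "c": SPLIT, "d": SPLIT},
            alphabet=(FUSED, SPLIT))
        res = reconstruct_events(tree, states)
        kinds = {e.kind for events in res.events_per_mpr for e in events}
        assert kinds <= {"split", "fusion"}

    def test_truncation_flag(self):
        # a large polytomy of conflicting leaves has many MPRs
        leaves = ",".join(f"t{i}" for i in range(12))
        tree = parse_newick(f"({leaves});")
        states = CharacterStateMap(
            {f"t{i}": (FUSED if i % 2 else SPLIT) for i in range(12)},
            alphabet=(FUSED, SPLIT))
        res = reconstruct_events(tree, states, max_mprs=1)
        assert res.truncated
        assert len(res.events_per_mpr) == 1


class TestRootingScan:
    def test_min_bounded_by_each_attachment(self):
        tree, states_full = thaum_rooted_example()
        ingroup = parse_newick(
            "(Thaumarchaeota:1,Korarchaeum:1,(Crenarchaeota:1,"
            "(Lokiarchaeota:1,Euryarchaeota:1):1):1);")
        states = CharacterStateMap(
            {k: v for k, v in THAUM_ROOTED_STATES.items() if k != "Bacteria"},
            alphabet=(FUSED, SPLIT))
        scan = rooting_scan(ingroup, FUSED, states)
        assert all(c >= scan.min_changes for _, c in scan.edge_counts)

    def test_uniform_states_all_zero(self):
        ingroup = parse_newick("(a:1,b:1,(c:1,d:1):1);")
        states = CharacterStateMap({t: SPLIT for t in "abcd"},
                                   alphabet=(FUSED, SPLIT))
        scan = rooting_scan(ingroup, SPLIT, states)
        assert scan.min_changes == 0
        assert all(c == 0 for _, c in scan.edge_counts)
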