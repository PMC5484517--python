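"""Sequence simulation: stationarity, reproducibility, chimera injection."""

import numpy as np
import pytest

from phyloconflict.alignment import Alignment
from phyloconflict.model import MODEL_ALPHABET
from phyloconflict.simulate import (ChimeraSpec, SimConfig, SimulationError,
                                    ef2_like_preset, graft_on_stem,
                                    inject_anchored_insertion,
                                    inject_segment_chimera,
                                    make_conflicting_marker_set, preset_trees,
                                    scale_branches, simulate_alignment)
from phyloconflict.tree import parse_newick


class TestSimulateAlignment:
    def test_zero_branch_lengths_identical_rows(self, model):
        tree = parse_newick("((a:0,b:0):0,(c:0,d:0):0);")
        aln = simulate_alignment(tree, model, 50, seed=1)
        assert len(set(aln.rows)) == 1

    def test_stationary_frequencies(self, model):
        tree = parse_newick("(a:10,b:10);")
        aln = simulate_alignment(tree, model, 10_000, seed=2)
        pi = model.frequencies
        for row in aln.rows:
            counts = np.array([row.count(aa) for aa in MODEL_ALPHABET])
            freqs = counts / len(row)
            se = np.sqrt(pi * (1 - pi) / len(row))
            assert np.all(np.abs(freqs - pi) < 4 * se + 1e-12)

    def test_pairwise_mismatch_matches_matrix_exponential(self, model):
        t = 0.4
        tree = parse_newick(f"(a:{t / 2},b:{t / 2});")
        n = 20_000
        aln = simulate_alignment(tree, model, n, seed=3)
        p_obs = np.mean([x != y for x, y in zip(*aln.rows)])
        pi = model.frequencies
        p_exp = np.mean([
            1.0 - (pi * np.diag(model.transition_matrix(t * r))).sum()
            for r in model.category_rates
        ])
        se = np.sqrt(p_exp * (1 - p_exp) / n)
        assert abs(p_obs - p_exp) < 4 * se

    def test_bit_reproducibility(self, model):
        tree = preset_trees()["woese"]
        a1 = simulate_alignment(tree, model, 100, seed=9)
        a2 = simulate_alignment(tree, model, 100, seed=9)
        assert a1 == a2
        a3 = simulate_alignment(tree, model, 100, seed=10)
        assert a1 != a3


class TestScaleBranches:
    def test_identity_factor(self):
        tree = preset_trees()["woese"]
        scaled = scale_branches(tree, ["L3"], 1.0)
        assert str(scaled) == str(tree)

    def test_doubles_only_listed_pendants(self):
        tree = preset_trees()["woese"]
        scaled = scale_branches(tree, ["L3", "Y1"], 2.0)
        for name in tree.leaf_names():
            before = tree.find_leaf(name).length
            after = scaled.find_leaf(name).length
            assert after == (2 * before if name in ("L3", "Y1") else before)

    def test_unknown_taxon_error(self):
        with pytest.raises(SimulationError):
            scale_branches(preset_trees()["woese"], ["nope"], 2.0)

    def test_factor_below_one_rejected(self):
        with pytest.raises(SimulationError):
            scale_branches(preset_trees()["woese"], ["L3"], 0.5)


class TestInjection:
    def test_segment_outside_interval_unchanged(self, model):
        tree = preset_trees()["woese"]
        aln = simulate_alignment(tree, model, 100, seed=4)
        spec = ChimeraSpec(kind="segment", marker="m", taxon="L3",
                           donor="E1", interval=(20, 50))
        donor_row = "W" * 30
        out, entry = inject_segment_chimera(aln, spec, donor_row)
        assert out.row("L3")[20:50] == donor_row
        assert out.row("L3")[:20] == aln.row("L3")[:20]
        assert out.row("L3")[50:] == aln.row("L3")[50:]
        for t in aln.taxon_ids:
            if t != "L3":
                assert out.row(t) == aln.row(t)
        assert (entry["start"], entry["end"]) == (20, 50)

    def test_segment_width_mismatch(self, model):
        aln = simulate_alignment(preset_trees()["woese"], model, 50, seed=4)
        spec = ChimeraSpec(kind="segment", marker="m", taxon="L3",
                           donor="E1", interval=(0, 10))
        with pytest.raises(SimulationError):
            inject_segment_chimera(aln, spec, "WW")

    def test_insertion_gaps_everyone_else(self, model):
        aln = simulate_alignment(preset_trees()["woese"], model, 200, seed=5)
        spec = ChimeraSpec(kind="insertion", marker="m", taxon="L3",
                           donor="E1", position=100, length=8)
        out, entry = inject_anchored_insertion(aln, spec, "WCWHDMKL")
        assert out.n_columns == 208
        for t in out.taxon_ids:
            seg = out.row(t)[100:108]
            assert seg == ("WCWHDMKL" if t == "L3" else "-" * 8)

    def test_insertion_too_close_to_edge(self, model):
        aln = simulate_alignment(preset_trees()["woese"], model, 100, seed=5)
        spec = ChimeraSpec(kind="insertion", marker="m", taxon="L3",
                           donor="E1", position=10, length=8)
        with pytest.raises(SimulationError, match="anchor"):
            inject_anchored_insertion(aln, spec, "WCWHDMKL")


class TestMarkerSetGeneration:
    def test_truth_bookkeeping(self):
        cfg = ef2_like_preset(seed=3)
        markers, truth = make_conflicting_marker_set(cfg)
        assert [m for m, _ in markers] == [m[0] for m in cfg.markers]
        assert len(truth.chimeras) == 1
        entry = truth.chimeras[0]
        assert entry["marker"] == "M9" and entry["taxon"] == "L3"
        assert truth.marker_histories == {m[0]: "woese" for m in cfg.markers}

    def test_reproducible_from_master_seed(self):
        m1, _ = make_conflicting_marker_set(ef2_like_preset(seed=6))
        m2, _ = make_conflicting_marker_set(ef2_like_preset(seed=6))
        assert m1 == m2

    def test_single_history_markers_recover_topology(self, model):
        # strong-signal marker simulated on one history: ML tree matches it
        from phyloconflict.search import infer_ml_tree
        from phyloconflict.tree import robinson_foulds
        cfg = SimConfig(species_trees=preset_trees(),
                        markers=[("M1", 500, "eocyte")], model=model, seed=8)
        markers, _ = make_conflicting_marker_set(cfg)
        res = infer_ml_tree(markers[0][1], model)
        assert robinson_foulds(res.tree, preset_trees()["eocyte"]) <= 2

    def test_config_validation(self):
        with pytest.raises(SimulationError):
            SimConfig(species_trees=preset_trees(),
                      markers=[("M1", 100, "nope")])
        with pytest.raises(SimulationError):
            SimConfig(species_trees=preset_trees(),
                      markers=[("M1", 100, "woese"), ("M1", 100, "woese")])
        with pytest.raises(SimulationError):
            SimConfig(species_trees=preset_trees(),
                      markers=[("M1", 100, "woese")],
                      chimeras=[ChimeraSpec(kind="segment", marker="M1",
                                            taxon="L3", donor="E1",
                                            interval=(0, 10))],
                      missing={"M1": ("L3",)})

    def test_graft_on_stem_places_new_leaf(self):
        tree = preset_trees()["woese"]
        g = graft_on_stem(tree, ("E1", "E2", "E3", "E4"), "donor")
        assert "donor" in g.leaf_names()
        bips = [set(b) for b in g.bipartitions()]
        assert {"E1", "E2", "E3", "E4", "donor"} in bips
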