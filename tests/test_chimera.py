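"""Chimera screens: anchored insertions, local alignment, donor
attribution, segment-affinity breakpoints."""

import numpy as np
import pytest

from phyloconflict.alignment import Alignment
from phyloconflict.chimera import (ChimeraScanError,
                                   attribute_insertion_donor,
                                   detect_anchored_insertions, local_align,
                                   segment_affinity_scan, split_alignment_at)
from phyloconflict.simulate import (ChimeraSpec, SimConfig,
                                    inject_anchored_insertion,
                                    insertion_screen_preset,
                                    make_conflicting_marker_set,
                                    preset_trees, simulate_alignment,
                                    PRESET_GROUPS)
from phyloconflict.trim import load_similarity_matrix

B62 = load_similarity_matrix("BLOSUM62")


class TestDetectInsertions:
    def test_fully_ungapped_alignment_empty(self, model):
        aln = simulate_alignment(preset_trees()["woese"], model, 200, seed=1)
        hits = detect_anchored_insertions(aln, {"L3"},
                                          [t for t in aln.taxon_ids
                                           if t != "L3"])
        assert hits == []

    def test_injected_insertion_recovered_exactly(self, model):
        cfg = insertion_screen_preset(seed=3)
        markers, truth = make_conflicting_marker_set(cfg)
        aln = markers[0][1]
        ref = [t for t in aln.taxon_ids if t != "L3"]
        hits = detect_anchored_insertions(aln, {"L3"}, ref)
        assert len(hits) == 1
        entry = truth.chimeras[0]
        assert (hits[0].start, hits[0].end) == (entry["start"], entry["end"])

    def test_minimum_length_five_detected(self, model):
        cfg = insertion_screen_preset(seed=8)
        cfg.chimeras = [ChimeraSpec(kind="insertion", marker="M1",
                                    taxon="L3", donor="E1", position=200,
                                    length=5)]
        markers, truth = make_conflicting_marker_set(cfg)
        aln = markers[0][1]
        ref = [t for t in aln.taxon_ids if t != "L3"]
        hits = detect_anchored_insertions(aln, {"L3"}, ref, min_len=5)
        assert any(h.length == 5 for h in hits)

    def test_run_at_edge_dropped(self):
        # insertion-like run in the first columns: no left anchor possible
        rows = {"focal": "WWWWW" + "W" * 50}
        for i in range(5):
            rows[f"r{i}"] = "-----" + "W" * 50
        aln = Alignment.from_pairs(rows.items())
        hits = detect_anchored_insertions(aln, {"focal"},
                                          [t for t in aln.taxon_ids
                                           if t != "focal"],
                                          anchor_len=40)
        assert hits == []

    def test_row_order_invariance(self, model):
        cfg = insertion_screen_preset(seed=5)
        markers, _ = make_conflicting_marker_set(cfg)
        aln = markers[0][1]
        ref = [t for t in aln.taxon_ids if t != "L3"]
        hits1 = detect_anchored_insertions(aln, {"L3"}, ref)
        shuffled = Alignment.from_pairs(
            sorted(zip(aln.taxon_ids, aln.rows), reverse=True))
        hits2 = detect_anchored_insertions(shuffled, {"L3"}, ref)
        assert [(h.start, h.end) for h in hits1] == \
            [(h.start, h.end) for h in hits2]

    def test_overlapping_sets_rejected(self, toy_alignment):
        with pytest.raises(ChimeraScanError, match="overlap"):
            detect_anchored_insertions(toy_alignment, {"A"}, {"A", "B"})


def oracle_sw(query, subject, matrix, gap_open, gap_extend):
    """Three-state affine DP, plain python, max over all cells."""
    n, m = len(query), len(subject)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            H[i][j] = max(0.0,
                          H[i - 1][j - 1]
                          + matrix.score(query[i - 1], subject[j - 1]),
                          E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestLocalAlign:
    def test_self_alignment_score(self):
        seq = "WCWHDM"
        res = local_align(seq, seq, B62)
        assert res.score == sum(B62.score(a, a) for a in seq)
        assert res.identity == 1.0

    def test_all_negative_pairs_floor(self):
        # W vs P scores -4 in BLOSUM62
        res = local_align("WWW", "PPP", B62)
        assert res.score == 0.0
        assert res.aligned_pairs == ()

    def test_matches_bruteforce_oracle_on_short_pairs(self):
        rng = np.random.default_rng(77)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(150):
            q = "".join(rng.choice(aas, size=rng.integers(1, 9)))
            s = "".join(rng.choice(aas, size=rng.integers(1, 9)))
            res = local_align(q, s, B62, gap_open=5, gap_extend=1)
            assert res.score == oracle_sw(q, s, B62, 5, 1)

    def test_score_symmetry(self):
        rng = np.random.default_rng(78)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(30):
            q = "".join(rng.choice(aas, size=12))
            s = "".join(rng.choice(aas, size=15))
            assert local_align(q, s, B62).score == local_align(s, q, B62).score

    def test_matches_biopython_pairwise_aligner(self):
        from Bio import Align
        from Bio.Align import substitution_matrices
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -12.0    # open + first extend
        aligner.extend_gap_score = -1.0
        rng = np.random.default_rng(79)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(25):
            q = "".join(rng.choice(aas, size=20))
            s = "".join(rng.choice(aas, size=25))
            assert local_align(q, s, B62).score == aligner.score(q, s)

    def test_illegal_character(self):
        with pytest.raises(ChimeraScanError):
            local_align("AR-ND", "ARND", B62)


class TestDonorAttribution:
    def test_true_donor_ranks_first(self, model):
        cfg = insertion_screen_preset(seed=11)
        markers, truth = make_conflicting_marker_set(cfg)
        aln = markers[0][1]
        ref = [t for t in aln.taxon_ids if t != "L3"]
        (hit,) = detect_anchored_insertions(aln, {"L3"}, ref)
        donor_seq = truth.chimeras[0]["donor_sequence"]
        donor_sets = {
            "Eukarya_paralog": ["true_donor"],
            "Euryarchaeota": [t for t in aln.taxon_ids if t.startswith("Y")],
        }
        attr = attribute_insertion_donor(
            hit, aln, donor_sets, B62,
            donor_sequences={"true_donor": donor_seq})
        assert attr.top_label == "Eukarya_paralog"

    def test_empty_donor_set_error(self, model):
        cfg = insertion_screen_preset(seed=11)
        markers, _ = make_conflicting_marker_set(cfg)
        aln = markers[0][1]
        ref = [t for t in aln.taxon_ids if t != "L3"]
        (hit,) = detect_anchored_insertions(aln, {"L3"}, ref)
        with pytest.raises(ChimeraScanError):
            attribute_insertion_donor(hit, aln, {}, B62)


class TestSegmentScan:
    def _clades(self, aln, focal):
        out = {}
        for t in aln.taxon_ids:
            g, d = PRESET_GROUPS[t]
            if d == "Bacteria" or t == focal:
                continue
            out.setdefault(g if d == "Archaea" else d, []).append(t)
        return {k: v for k, v in out.items() if len(v) >= 2}

    def test_null_no_false_breakpoint(self, model):
        significant = 0
        for seed in range(6):
            aln = simulate_alignment(preset_trees()["woese"], model, 400,
                                     seed=100 + seed)
            prof = segment_affinity_scan(aln, "L3", self._clades(aln, "L3"),
                                         seed=seed)
            if prof.p_value < 0.05 and prof.left_clade != prof.right_clade:
                significant += 1
        assert significant <= 1

    def test_injected_breakpoint_recovered(self, model):
        # N-terminal donor segment in a taxon with close relatives: the
        # classic two-portion geometry, breakpoint at column 230 of 626
        spec = ChimeraSpec(kind="segment", marker="M1", taxon="Y3",
                           donor="E1", donor_stem=0.05, donor_pendant=0.02,
                           interval=(0, 230))
        cfg = SimConfig(species_trees=preset_trees(),
                        markers=[("M1", 626, "woese")],
                        chimeras=[spec], seed=7)
        markers, truth = make_conflicting_marker_set(cfg)
        aln = markers[0][1]
        prof = segment_affinity_scan(aln, "Y3", self._clades(aln, "Y3"),
                                     seed=1)
        assert prof.p_value < 0.05
        assert prof.left_clade == "Eukarya"
        assert abs(prof.breakpoint_column - 230) <= 10

    def test_single_window_equals_plain_distances(self, model):
        from phyloconflict.chimera import _corrected_distance
        aln = simulate_alignment(preset_trees()["woese"], model, 120, seed=9)
        clades = self._clades(aln, "L3")
        prof = segment_affinity_scan(aln, "L3", clades, window=120, step=10,
                                     n_permutations=9, seed=0)
        assert len(prof.window_starts) == 1
        for ci, label in enumerate(prof.clade_labels):
            expected = np.mean([
                _corrected_distance(aln.row("L3"), aln.row(t))
                for t in clades[label]
            ])
            assert np.isclose(prof.affinities[0, ci], expected)

    def test_window_too_wide(self, toy_alignment):
        with pytest.raises(ChimeraScanError):
            segment_affinity_scan(toy_alignment, "A",
                                  {"x": ["B", "C"], "y": ["D"]}, window=50)


class TestSplit:
    def test_round_trip(self, toy_alignment):
        left, right = split_alignment_at(toy_alignment, 2)
        assert left.n_columns + right.n_columns == toy_alignment.n_columns
        rejoined = Alignment.from_pairs(
            (t, left.row(t) + right.row(t)) for t in toy_alignment.taxon_ids)
        assert rejoined == toy_alignment

    def test_out_of_range(self, toy_alignment):
        with pytest.raises(ChimeraScanError):
            split_alignment_at(toy_alignment, 0)
        with pytest.raises(ChimeraScanError):
            split_alignment_at(toy_alignment, 6)
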