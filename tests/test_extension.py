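import math

import edlib
import numpy as np
import pytest

from tecurate.extension import (
    ExtensionState,
    MSAProfile,
    bee_iteration,
    collect_copies,
    detect_edges,
    extend_consensus,
    kimura2p_distance,
    polish_consensus,
    split_subfamilies,
)
from tecurate.models import Order
from tecurate.search import SubjectIndex, revcomp
from tecurate.simulate import FamilySpec, build_genome, make_family, mutate, random_dna


class TestCollectCopies:
    def test_planted_copies_found(self, ltr_family, ltr_genome_index):
        _, ancestor, _, truth = ltr_family
        loci = collect_copies(ancestor, ltr_genome_index)
        assert len(loci) == len(truth.insertions) == 20

    def test_absent_consensus_empty(self, ltr_genome_index, rng):
        assert collect_copies(random_dna(rng, 800), ltr_genome_index) == []

    def test_tandem_copies_stay_separate(self, rng):
        unit = random_dna(rng, 400)
        genome = {"c": random_dna(rng, 5000) + unit + random_dna(rng, 10) + unit
                  + random_dna(rng, 5000)}
        loci = collect_copies(unit, SubjectIndex(genome))
        assert len(loci) == 2

    def test_locus_coordinates_match_truth(self, ltr_family, ltr_genome_index):
        _, ancestor, _, truth = ltr_family
        loci = collect_copies(ancestor, ltr_genome_index)
        found = {(l.contig, l.s_start // 50, l.strand) for l in loci}
        expected = {(i.contig, i.start // 50, i.strand) for i in truth.insertions}
        assert found == expected


class TestBeeIteration:
    def test_fixpoint_when_done(self, ltr_genome_index, rng):
        state = ExtensionState(consensus=random_dna(rng, 500),
                               left_done=True, right_done=True)
        before = state.consensus
        after = bee_iteration(state, ltr_genome_index)
        assert after.consensus == before and after.iteration == 0

    def test_no_support_closes_both_sides(self, ltr_genome_index, rng):
        state = ExtensionState(consensus=random_dna(rng, 600))
        after = bee_iteration(state, ltr_genome_index)
        assert after.left_done and after.right_done
        assert "no genomic support" in after.notes

    def test_full_seed_done_in_one_iteration(self, ltr_family, ltr_genome_index):
        _, ancestor, _, _ = ltr_family
        state = extend_consensus(ancestor, ltr_genome_index, max_iterations=16)
        assert state.iteration == 1
        assert state.left_done and state.right_done

    def test_truncated_seed_keeps_extending(self, ltr_family, ltr_genome_index):
        _, ancestor, _, _ = ltr_family
        state = ExtensionState(consensus=ancestor[500:1500])
        state = bee_iteration(state, ltr_genome_index)
        assert not (state.left_done or state.right_done)
        assert len(state.consensus) > 1500

    def test_contig_start_clipped_without_error(self, rng):
        fam = random_dna(rng, 600)
        copies = [mutate(fam, 0.02, rng) for _ in range(5)]
        genome = {"c": copies[0] + "".join(
            random_dna(rng, 2000) + c for c in copies[1:]) + random_dna(rng, 2000)}
        state = ExtensionState(consensus=fam)
        state = bee_iteration(state, SubjectIndex(genome))
        assert state.consensus  # no crash, boundary clipped

    def test_recovers_true_element_from_half_seed(
        self, ltr_family, ltr_genome_index
    ):
        _, ancestor, _, _ = ltr_family
        state = extend_consensus(ancestor[500:1500], ltr_genome_index)
        assert state.iteration <= 16
        res = edlib.align(state.consensus, ancestor, mode="NW", task="distance")
        ident = 1 - res["editDistance"] / max(len(ancestor), len(state.consensus))
        assert ident >= 0.95
        assert len(state.consensus) >= 0.95 * len(ancestor)


class TestPolishConsensus:
    def _msa(self, rows, fl=0, fr=0):
        return MSAProfile(member_windows=[("c", 0, len(rows[0]), "+")] * len(rows),
                          aligned_rows=rows, flank_left=fl, flank_right=fr)

    def test_identical_rows_identity(self, rng):
        row = random_dna(rng, 120)
        for n in (2, 5, 9):
            assert polish_consensus(self._msa([row] * n)) == row

    def test_majority_base_wins(self):
        rows = ["AAAA", "AAAA", "AAAA", "GAAA", "GAAA"]
        assert polish_consensus(self._msa(rows)) == "AAAA"

    def test_tie_broken_by_base_order(self):
        rows = ["CAAA", "CAAA", "AAAA", "AAAA"]
        assert polish_consensus(self._msa(rows))[0] == "A"

    def test_terminal_low_depth_trimmed_interior_kept(self):
        rows = [
            "--ACGTACGT--",
            "--ACGTACGT--",
            "--ACG-ACGT--",
            "--ACGTACGT--",
            "T-ACGTACGTG-",
        ]
        out = polish_consensus(self._msa(rows))
        assert out == "ACGTACGT"  # depth-1 terminal columns dropped

    def test_all_gap_raises(self):
        with pytest.raises(ValueError):
            polish_consensus(self._msa(["----", "----"]))


class TestDetectEdges:
    def test_single_copy_always_done(self):
        msa = MSAProfile(member_windows=[("c", 0, 10, "+")],
                         aligned_rows=["ACGTACGTAC"], flank_left=3, flank_right=3)
        assert detect_edges(msa) == (True, True)

    def test_supported_flanks_not_done(self, ltr_family, ltr_genome_index):
        _, ancestor, _, _ = ltr_family
        state = ExtensionState(consensus=ancestor[500:1500])
        state = bee_iteration(state, ltr_genome_index)
        assert not state.left_done and not state.right_done

    def test_random_flanks_done(self, ltr_family, ltr_genome_index):
        _, ancestor, _, _ = ltr_family
        state = ExtensionState(consensus=ancestor)
        state = bee_iteration(state, ltr_genome_index)
        assert state.left_done and state.right_done


class TestKimura2P:
    def test_identical_rows_zero(self):
        d = kimura2p_distance("ACGTACGT", "ACGTACGT")
        assert (d.p_transitions, d.q_transversions, d.d) == (0.0, 0.0, 0.0)

    def test_known_value(self):
        # P=0.1, Q=0.05 over 1000 sites: d = -0.5 ln(0.75) - 0.25 ln(0.9)
        row_a = "A" * 1000
        row_b = "G" * 100 + "C" * 50 + "A" * 850
        d = kimura2p_distance(row_a, row_b)
        assert d.p_transitions == pytest.approx(0.1)
        assert d.q_transversions == pytest.approx(0.05)
        assert d.d == pytest.approx(0.1702, abs=1e-4)

    def test_saturation_boundary(self):
        d = kimura2p_distance("A" * 100, "G" * 50 + "A" * 50)  # P=0.5, Q=0
        assert d.saturated and math.isinf(d.d)

    def test_symmetric(self, rng):
        a = random_dna(rng, 300)
        b = mutate(a, 0.1, rng)
        assert kimura2p_distance(a, b).d == pytest.approx(kimura2p_distance(b, a).d)

    def test_gap_columns_excluded(self):
        d = kimura2p_distance("AC--GT", "ACTTGT")
        assert d.comparable_sites == 4 and d.d == 0.0

    def test_no_comparable_sites_raises(self):
        with pytest.raises(ValueError):
            kimura2p_distance("--AA", "TT--")


class TestSplitSubfamilies:
    def _rows_msa(self, rows):
        return MSAProfile(member_windows=[("c", 0, len(rows[0]), "+")] * len(rows),
                          aligned_rows=rows)

    def test_two_diverged_subfamilies_recovered(self, rng):
        anc_a = random_dna(rng, 600)
        anc_b = mutate(anc_a, 0.15, rng)
        rows = [mutate(anc_a, 0.02, rng) for _ in range(7)]
        rows += [mutate(anc_b, 0.02, rng) for _ in range(6)]
        subs = split_subfamilies(self._rows_msa(rows))
        assert len(subs) == 2
        sizes = sorted(len(s.aligned_rows) for s in subs)
        assert sizes == [6, 7]
        # the true partition: subfamily rows are contiguous by construction
        groups = [set(rows.index(r) for r in s.aligned_rows) for s in subs]
        assert sorted(groups, key=min) == [set(range(7)), set(range(7, 13))]

    def test_homogeneous_family_not_split(self, rng):
        anc = random_dna(rng, 600)
        rows = [mutate(anc, 0.01, rng) for _ in range(12)]
        assert len(split_subfamilies(self._rows_msa(rows))) == 1

    def test_too_few_rows_guard(self, rng):
        anc = random_dna(rng, 300)
        rows = [mutate(anc, 0.15, rng) for _ in range(6)]
        assert len(split_subfamilies(self._rows_msa(rows), min_members=5)) == 1

    def test_uniform_high_divergence_not_split(self, rng):
        """A star-shaped cloud near the cutoff must stay one family."""
        anc = random_dna(rng, 1500)
        rows = [mutate(anc, 0.055, rng) for _ in range(20)]
        assert len(split_subfamilies(self._rows_msa(rows))) == 1

    def test_disjoint_segments_split_as_chimera(self, rng):
        """Rows covering non-overlapping column blocks are separate families."""
        left = [mutate(random_dna(rng, 400), 0.0, rng) for _ in range(1)][0]
        right = random_dna(rng, 400)
        rows = [mutate(left, 0.03, rng) + "-" * 400 for _ in range(6)]
        rows += ["-" * 400 + mutate(right, 0.03, rng) for _ in range(6)]
        subs = split_subfamilies(self._rows_msa(rows))
        assert len(subs) == 2


class TestExtensionOnSimulatedFamilies:
    def test_consensus_length_nondecreasing_until_trim(
        self, ltr_family, ltr_genome_index
    ):
        _, ancestor, _, _ = ltr_family
        state = ExtensionState(consensus=ancestor[500:1500])
        lengths = [len(state.consensus)]
        for _ in range(16):
            trimmed_before = state.left_done or state.right_done
            state = bee_iteration(state, ltr_genome_index)
            if state.left_done and state.right_done:
                break
            if not trimmed_before:
                assert len(state.consensus) >= lengths[-1] - 5
            lengths.append(len(state.consensus))

    def test_terminal_repeats_recovered(self, ltr_family, ltr_genome_index):
        from tecurate.classify import detect_terminal_repeats

        spec, ancestor, _, _ = ltr_family
        state = extend_consensus(ancestor[500:1500], ltr_genome_index)
        features = detect_terminal_repeats(state.consensus)
        assert features.ltr is not None
        left, right, ident = features.ltr
        assert left[1] - left[0] >= 0.8 * spec.ltr_length
        assert ident >= 0.9
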