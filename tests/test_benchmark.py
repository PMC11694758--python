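import numpy as np
import pytest

from tecurate.benchmark import (
    compute_nte_lte,
    count_copies,
    count_overlapping,
    detect_chimeras,
    evaluate_family_quality,
    order_proportions,
    quality_summary,
    read_bed,
    read_repeatmasker_out,
)
from tecurate.models import (
    AnnotationRecord,
    ConsensusRecord,
    LibraryDocument,
    Order,
    TEClassification,
)
from tecurate.simulate import mutate, random_dna


def _ann(contig, start, end, cons="c1", order=Order.LTR, strand="+"):
    return AnnotationRecord(contig=contig, start=start, end=end, strand=strand,
                            consensus_id=cons, order=order)


def _lib(*records):
    return LibraryDocument(records=list(records))


class TestFamilyQuality:
    @pytest.fixture
    def reference(self, rng):
        return _lib(ConsensusRecord("ref1", random_dna(rng, 1000),
                                    TEClassification(order=Order.LTR)))

    def test_exact_copy_is_perfect(self, reference):
        test = _lib(ConsensusRecord("t1", reference.get("ref1").sequence))
        labels = evaluate_family_quality(reference, test)
        assert labels[0].label == "perfect"
        assert labels[0].n_matching_sequences == 1

    def test_two_overlapping_fragments_are_good(self, reference, rng):
        seq = reference.get("ref1").sequence
        test = _lib(
            ConsensusRecord("f1", mutate(seq[:600], 0.02, rng)),
            ConsensusRecord("f2", mutate(seq[550:], 0.02, rng)),
        )
        labels = evaluate_family_quality(reference, test)
        assert labels[0].label == "good"
        assert labels[0].n_matching_sequences == 2

    def test_85_percent_full_length_is_present(self, reference, rng):
        seq = mutate(reference.get("ref1").sequence, 0.12, rng)
        labels = evaluate_family_quality(reference, _lib(ConsensusRecord("t", seq)))
        assert labels[0].label == "present"

    def test_no_match_is_missing(self, reference, rng):
        labels = evaluate_family_quality(
            reference, _lib(ConsensusRecord("t", random_dna(rng, 1000)))
        )
        assert labels[0].label == "missing"

    def test_empty_test_library_all_missing(self, reference):
        labels = evaluate_family_quality(reference, _lib())
        assert [l.label for l in labels] == ["missing"]

    def test_self_evaluation_all_perfect(self, rng):
        lib = _lib(*[
            ConsensusRecord(f"f{i}", random_dna(rng, int(n)))
            for i, n in enumerate(rng.integers(400, 1500, 6))
        ])
        labels = evaluate_family_quality(lib, lib)
        assert quality_summary(labels)["perfect"] == 6


class TestNteLte:
    def test_worked_example(self):
        anns = [_ann("c", i * 1000, i * 1000 + L)
                for i, L in enumerate([100, 80, 60, 40, 20])]
        assert compute_nte_lte(anns, 150) == (2, 80)

    def test_single_copy(self):
        assert compute_nte_lte([_ann("c", 0, 500)], 250) == (1, 500)

    def test_uniform_lengths(self):
        anns = [_ann("c", i * 200, i * 200 + 100) for i in range(10)]
        assert compute_nte_lte(anns, 500) == (5, 100)

    def test_undefined_when_target_unreachable(self):
        assert compute_nte_lte([_ann("c", 0, 100)], 1000) == (None, None)

    def test_matches_cumulative_sum_oracle(self, rng):
        for _ in range(200):
            lengths = rng.integers(10, 5000, size=int(rng.integers(1, 40)))
            anns = [_ann("c", int(i * 6000), int(i * 6000 + L))
                    for i, L in enumerate(lengths)]
            target = int(rng.integers(1, int(lengths.sum()) + 1))
            # oracle: literal cumulative sum over the sorted lengths
            srt = sorted(lengths, reverse=True)
            cum, n50, l50 = 0, None, None
            for k, L in enumerate(srt, 1):
                cum += L
                if cum >= target:
                    n50, l50 = k, L
                    break
            assert compute_nte_lte(anns, target) == (n50, l50)

    def test_monotone_under_appending(self, rng):
        anns = [_ann("c", i * 1000, i * 1000 + int(L))
                for i, L in enumerate(rng.integers(50, 800, 10))]
        target = 2000
        n_before, l_before = compute_nte_lte(anns, target)
        more = anns + [_ann("c", 99_000, 99_900)]
        n_after, l_after = compute_nte_lte(more, target)
        assert l_after >= l_before or n_after <= n_before


class TestCopyCounts:
    def test_short_copy_threshold_strict(self):
        anns = [_ann("c", 0, 99), _ann("c", 200, 300), _ann("c", 400, 501)]
        assert count_copies(anns) == (3, 1)

    def test_empty(self):
        assert count_copies([]) == (0, 0)

    def test_all_short(self):
        anns = [_ann("c", i * 100, i * 100 + 50) for i in range(4)]
        assert count_copies(anns) == (4, 4)


class TestCountOverlapping:
    def test_two_consensus_overlap_counts(self):
        anns = [_ann("c", 100, 200, "consA"), _ann("c", 150, 250, "consB")]
        assert count_overlapping(anns) == 1

    def test_book_ended_not_merged(self):
        anns = [_ann("c", 100, 200, "consA"), _ann("c", 200, 300, "consB")]
        assert count_overlapping(anns) == 0

    def test_same_consensus_overlap_not_counted(self):
        anns = [_ann("c", 100, 200, "consA"), _ann("c", 150, 250, "consA")]
        assert count_overlapping(anns) == 0

    def test_reorder_invariant(self, rng):
        anns = []
        for i in range(50):
            start = int(rng.integers(0, 20_000))
            anns.append(_ann("c", start, start + int(rng.integers(50, 400)),
                             f"cons{int(rng.integers(0, 5))}"))
        expected = count_overlapping(anns)
        for _ in range(5):
            perm = [anns[i] for i in rng.permutation(len(anns))]
            assert count_overlapping(perm) == expected

    def test_matches_sweep_oracle(self, rng):
        def oracle(anns):
            events = sorted(anns, key=lambda a: (a.contig, a.start, a.end))
            total = 0
            by_contig = {}
            for a in events:
                by_contig.setdefault(a.contig, []).append(a)
            for _, items in sorted(by_contig.items()):
                regions = []
                for a in items:
                    if regions and a.start < regions[-1][1]:
                        regions[-1][1] = max(regions[-1][1], a.end)
                        regions[-1][2].add(a.consensus_id)
                    else:
                        regions.append([a.start, a.end, {a.consensus_id}])
                total += sum(1 for r in regions if len(r[2]) >= 2)
            return total

        for _ in range(50):
            n = int(rng.integers(1, 60))
            anns = [
                _ann(f"chr{int(rng.integers(1, 4))}", s, s + int(rng.integers(1, 500)),
                     f"cons{int(rng.integers(0, 6))}")
                for s in rng.integers(0, 30_000, n)
            ]
            assert count_overlapping(anns) == oracle(anns)


class TestOrderProportions:
    def test_single_copy_fraction(self):
        anns = [_ann("c", 0, 500, order=Order.LTR)]
        assert order_proportions(anns, 10_000) == {"LTR": 0.05}

    def test_same_order_overlap_counted_once(self):
        anns = [_ann("c", 0, 100, "a", Order.TIR), _ann("c", 50, 150, "b", Order.TIR)]
        assert order_proportions(anns, 1000) == {"TIR": 0.15}

    def test_empty_annotations(self):
        assert order_proportions([], 1000) == {}


class TestDetectChimeras:
    @pytest.fixture
    def refdb(self, rng):
        return _lib(
            ConsensusRecord("copia", random_dna(rng, 1200),
                            TEClassification(order=Order.LTR, superfamily="Copia")),
            ConsensusRecord("gypsy", random_dna(rng, 1300),
                            TEClassification(order=Order.LTR, superfamily="Gypsy")),
            ConsensusRecord("hat", random_dna(rng, 900),
                            TEClassification(order=Order.TIR, superfamily="hAT")),
        )

    def test_cross_order_concatenation_flagged(self, refdb):
        chim = refdb.get("copia").sequence + refdb.get("hat").sequence
        out = detect_chimeras(_lib(ConsensusRecord("x", chim)), refdb)
        assert len(out) == 1
        assert out[0][1] == {Order.LTR, Order.TIR}

    def test_pure_record_not_flagged(self, refdb, rng):
        pure = mutate(refdb.get("copia").sequence, 0.05, rng)
        assert detect_chimeras(_lib(ConsensusRecord("x", pure)), refdb) == []

    def test_same_order_pair_not_flagged(self, refdb):
        chim = refdb.get("copia").sequence + refdb.get("gypsy").sequence
        assert detect_chimeras(_lib(ConsensusRecord("x", chim)), refdb) == []


class TestAnnotationIO:
    def test_bed_round(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t600\tfam1#LTR/Copia\t0\t+\n"
                     "chr2\t0\t99\tfam2#TIR\t0\t-\n")
        anns = read_bed(p)
        assert anns[0].start == 100 and anns[0].end == 600
        assert anns[0].order is Order.LTR and anns[0].consensus_id == "fam1"
        assert anns[1].strand == "-" and anns[1].length == 99

    def test_repeatmasker_out_coordinates_converted(self, tmp_path):
        p = tmp_path / "a.out"
        p.write_text(
            "   SW  perc perc perc  query     position in query  matching repeat\n"
            "score  div. del. ins.  sequence  begin  end  (left) repeat  class/family\n"
            "\n"
            " 1000  5.0  0.0  0.0  chr1  101  600  (0)  +  fam1  LTR/Copia  1 500 (0) 1\n"
            "  900  6.0  0.0  0.0  chr1  701  800  (0)  C  fam2  DNA/hAT    1 100 (0) 2\n"
        )
        anns = read_repeatmasker_out(p)
        assert (anns[0].start, anns[0].end) == (100, 600)  # 1-based -> half-open
        assert anns[0].order is Order.LTR
        assert anns[1].strand == "-"
        assert anns[1].order is Order.TIR  # DNA/hAT dialect resolved
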