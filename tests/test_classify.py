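import numpy as np
import pytest

from tecurate.classify import (
    check_structure,
    classify_unknown,
    compute_features,
    detect_polya,
    detect_terminal_repeats,
    homology_assign,
)
from tecurate.models import (
    ConsensusRecord,
    DomainHit,
    LibraryDocument,
    Order,
    ProfileRole,
    StructuralFeatureSet,
    TEClass,
    TEClassification,
)
from tecurate.profiles import back_translate, builtin_te_profiles, role_peptide
from tecurate.search import revcomp
from tecurate.simulate import mutate, random_dna


def _domain(role):
    return DomainHit(profile_name=f"{role.value}_dom", profile_role=role,
                     q_start=0, q_end=60, frame=1, evalue=1e-30)


class TestDetectTerminalRepeats:
    def test_constructed_ltr_element(self, rng):
        ltr = random_dna(rng, 300)
        seq = ltr + random_dna(rng, 1400) + ltr
        f = detect_terminal_repeats(seq)
        assert f.ltr is not None
        (l0, l1), (r0, r1), ident = f.ltr
        assert (l0, l1) == (0, 300) and (r0, r1) == (1700, 2000)
        assert ident == 1.0

    def test_constructed_tir_element(self, rng):
        tir = random_dna(rng, 25)
        seq = tir + random_dna(rng, 800) + revcomp(tir)
        f = detect_terminal_repeats(seq)
        assert f.tir is not None
        (l0, l1), (r0, r1), ident = f.tir
        assert l0 == 0 and l1 == 25 and ident == 1.0
        assert r1 == len(seq)

    def test_random_sequence_has_neither(self):
        """Exhaustive end-vs-end oracle agrees: nothing above threshold."""
        for seed in range(10):
            seq = random_dna(np.random.default_rng(900 + seed), 2000)
            f = detect_terminal_repeats(seq)
            assert f.ltr is None and f.tir is None

    def test_revcomp_finds_same_tir_and_mirrored_ltr(self, rng):
        ltr = random_dna(rng, 150)
        tir = random_dna(rng, 25)
        ltr_el = ltr + random_dna(rng, 900) + ltr
        tir_el = tir + random_dna(rng, 600) + revcomp(tir)
        for seq in (ltr_el, tir_el):
            f_fwd = detect_terminal_repeats(seq)
            f_rev = detect_terminal_repeats(revcomp(seq))
            assert (f_fwd.ltr is None) == (f_rev.ltr is None)
            assert (f_fwd.tir is None) == (f_rev.tir is None)

    def test_diverged_ltr_still_detected(self, rng):
        ltr = random_dna(rng, 250)
        seq = ltr + random_dna(rng, 1000) + mutate(ltr, 0.05, rng)
        f = detect_terminal_repeats(seq)
        assert f.ltr is not None and f.ltr[2] >= 0.9


class TestDetectPolya:
    def test_terminal_run_found(self, rng):
        seq = random_dna(rng, 900) + "A" * 12
        hit = detect_polya(seq)
        assert hit is not None
        (start, end), purity = hit
        assert end >= len(seq) - 1 and purity >= 0.9

    def test_impure_tail_detected(self, rng):
        seq = random_dna(rng, 400) + "AAAAAGAAAAAA"
        hit = detect_polya(seq)
        assert hit is not None
        assert hit[1] == pytest.approx(11 / 12)

    def test_interior_run_ignored(self, rng):
        seq = random_dna(rng, 400) + "A" * 15 + random_dna(rng, 400)
        assert detect_polya(seq) is None


class TestHomologyAssign:
    @pytest.fixture
    def refdb(self, rng):
        return LibraryDocument(records=[
            ConsensusRecord("copia1", random_dna(rng, 1500),
                            TEClassification(order=Order.LTR, superfamily="Copia")),
            ConsensusRecord("hat1", random_dna(rng, 900),
                            TEClassification(order=Order.TIR, superfamily="hAT")),
            ConsensusRecord("gypsy1", random_dna(rng, 1600),
                            TEClassification(order=Order.LTR, superfamily="Gypsy")),
        ])

    def test_near_identical_match_donates_classification(self, refdb, rng):
        rec = ConsensusRecord("q", mutate(refdb.get("copia1").sequence, 0.01, rng))
        d = homology_assign(rec, refdb)
        assert d is not None and d.step == "homology_80"
        assert d.final.order is Order.LTR and d.final.superfamily == "Copia"

    def test_85_percent_match_passes_80_rule(self, refdb, rng):
        rec = ConsensusRecord("q", mutate(refdb.get("hat1").sequence, 0.12, rng))
        d = homology_assign(rec, refdb)
        assert d is not None and d.final.superfamily == "hAT"

    def test_75_percent_match_fails_80_but_passes_70(self, refdb, rng):
        rec = ConsensusRecord("q", mutate(refdb.get("gypsy1").sequence, 0.24, rng))
        assert homology_assign(rec, refdb, rule=(80, 0.80, 0.80)) is None
        d = homology_assign(rec, refdb, rule=(70, 0.70, 0.70))
        assert d is not None and d.final.superfamily == "Gypsy"
        assert d.step == "unknown_homology_70"

    def test_unrelated_query_no_decision(self, refdb, rng):
        rec = ConsensusRecord("q", random_dna(rng, 1200))
        assert homology_assign(rec, refdb) is None


class TestCheckStructure:
    def _rec(self, order, length=1500, superfamily=""):
        return ConsensusRecord("x", "A" * length,
                               TEClassification(order=order, superfamily=superfamily))

    def test_ltr_with_tr_and_domains_passes(self):
        f = StructuralFeatureSet(ltr=((0, 300), (1200, 1500), 1.0),
                                 domains=[_domain(ProfileRole.RT)])
        d = check_structure(self._rec(Order.LTR), f)
        assert d.step == "structural_pass"

    def test_ltr_without_evidence_fails_inc(self):
        rec = self._rec(Order.LTR)
        d = check_structure(rec, StructuralFeatureSet())
        assert d.step == "structural_fail_inc"
        assert d.final.order is Order.LTR  # order never changed

    def test_line_with_polya_only_passes(self):
        f = StructuralFeatureSet(polya=((1480, 1500), 1.0))
        assert check_structure(self._rec(Order.LINE), f).step == "structural_pass"

    def test_line_with_direct_tr_fails(self):
        f = StructuralFeatureSet(polya=((1480, 1500), 1.0),
                                 ltr=((0, 200), (1300, 1500), 0.95))
        assert check_structure(self._rec(Order.LINE), f).step == "structural_fail_inc"

    def test_tir_with_transposase_only_passes(self):
        f = StructuralFeatureSet(domains=[_domain(ProfileRole.TRANSPOSASE)])
        assert check_structure(self._rec(Order.TIR), f).step == "structural_pass"

    def test_mite_length_and_coding_limits(self):
        f = StructuralFeatureSet(tir=((0, 25), (475, 500), 1.0))
        assert check_structure(self._rec(Order.MITE, 500), f).step == "structural_pass"
        assert (
            check_structure(self._rec(Order.MITE, 2000), f).step
            == "structural_fail_inc"
        )
        f_coding = StructuralFeatureSet(tir=((0, 25), (475, 500), 1.0),
                                        domains=[_domain(ProfileRole.TRANSPOSASE)])
        assert (
            check_structure(self._rec(Order.MITE, 500), f_coding).step
            == "structural_fail_inc"
        )

    def test_helitron_requires_helicase(self):
        ok = StructuralFeatureSet(domains=[_domain(ProfileRole.HELICASE)])
        bad = StructuralFeatureSet(domains=[_domain(ProfileRole.RT)])
        assert check_structure(self._rec(Order.HELITRON), ok).step == "structural_pass"
        assert (
            check_structure(self._rec(Order.HELITRON), bad).step
            == "structural_fail_inc"
        )

    def test_inc_suffix_applied_via_record(self):
        rec = self._rec(Order.LTR)
        d = check_structure(rec, StructuralFeatureSet())
        assert d.step == "structural_fail_inc"
        rec.mark_incomplete("classification", "missing features")
        assert rec.id.endswith("_inc")


class TestClassifyUnknown:
    @pytest.fixture
    def empty_db(self):
        return LibraryDocument()

    def _unknown(self, seq):
        return ConsensusRecord("u", seq)

    def test_step1_homology_70(self, rng):
        db = LibraryDocument(records=[
            ConsensusRecord("gypsy1", random_dna(rng, 1400),
                            TEClassification(order=Order.LTR, superfamily="Gypsy")),
        ])
        rec = self._unknown(mutate(db.get("gypsy1").sequence, 0.25, rng))
        d = classify_unknown(rec, db, StructuralFeatureSet())
        assert d.step == "unknown_homology_70"
        assert d.final.order is Order.LTR and d.final.superfamily == "Gypsy"

    def test_step2_rt_without_tr_or_polya_is_generic_class1(self, empty_db, rng):
        f = StructuralFeatureSet(domains=[_domain(ProfileRole.RT)])
        d = classify_unknown(self._unknown(random_dna(rng, 1000)), empty_db, f)
        assert d.step == "unknown_domains"
        assert d.final.is_generic_class()
        assert d.final.te_class is TEClass.CLASS_I
        assert d.final.label == "ClassI"

    def test_step2_rt_with_ltr_is_ltr_order(self, empty_db, rng):
        f = StructuralFeatureSet(domains=[_domain(ProfileRole.RT)],
                                 ltr=((0, 200), (800, 1000), 0.95))
        d = classify_unknown(self._unknown(random_dna(rng, 1000)), empty_db, f)
        assert d.final.order is Order.LTR

    def test_step2_rt_with_polya_no_tr_is_line(self, empty_db, rng):
        f = StructuralFeatureSet(domains=[_domain(ProfileRole.RT)],
                                 polya=((980, 1000), 1.0))
        d = classify_unknown(self._unknown(random_dna(rng, 1000)), empty_db, f)
        assert d.final.order is Order.LINE

    def test_step2_transposase_with_tir_is_tir(self, empty_db, rng):
        f = StructuralFeatureSet(domains=[_domain(ProfileRole.TRANSPOSASE)],
                                 tir=((0, 25), (975, 1000), 1.0))
        d = classify_unknown(self._unknown(random_dna(rng, 1000)), empty_db, f)
        assert d.final.order is Order.TIR

    def test_step2_helicase_is_helitron(self, empty_db, rng):
        f = StructuralFeatureSet(domains=[_domain(ProfileRole.HELICASE)])
        d = classify_unknown(self._unknown(random_dna(rng, 1000)), empty_db, f)
        assert d.final.order is Order.HELITRON

    def test_step2_transposase_alone_generic_class2(self, empty_db, rng):
        f = StructuralFeatureSet(domains=[_domain(ProfileRole.TRANSPOSASE)])
        d = classify_unknown(self._unknown(random_dna(rng, 1000)), empty_db, f)
        assert d.final.is_generic_class()
        assert d.final.te_class is TEClass.CLASS_II
        assert d.final.label == "ClassII"

    def test_step3_trs_alone(self, empty_db, rng):
        d_ltr = classify_unknown(
            self._unknown(random_dna(rng, 1000)), empty_db,
            StructuralFeatureSet(ltr=((0, 200), (800, 1000), 0.95)),
        )
        assert d_ltr.step == "unknown_tr" and d_ltr.final.order is Order.LTR
        d_tir = classify_unknown(
            self._unknown(random_dna(rng, 1000)), empty_db,
            StructuralFeatureSet(tir=((0, 20), (980, 1000), 1.0)),
        )
        assert d_tir.step == "unknown_tr" and d_tir.final.order is Order.TIR

    def test_no_signal_still_unclassified(self, empty_db, rng):
        d = classify_unknown(
            self._unknown(random_dna(rng, 1000)), empty_db, StructuralFeatureSet()
        )
        assert d.step == "still_unclassified"
        assert d.final.order is Order.UNCLASSIFIED


class TestComputeFeatures:
    def test_planted_domain_and_structure_detected(self, rng):
        """An element carrying an LTR pair and an RT back-translation yields
        the full feature set from one call."""
        ltr = random_dna(rng, 200)
        rt_nt = back_translate(role_peptide(ProfileRole.RT.value))
        seq = ltr + rt_nt + random_dna(rng, 700) + ltr
        rec = ConsensusRecord("x", seq)
        f = compute_features(rec, builtin_te_profiles())
        assert f.ltr is not None
        assert ProfileRole.RT in f.roles()
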