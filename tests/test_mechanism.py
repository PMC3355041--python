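"""TSD exchange, TE annotation, inverted duplications, dating, classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from invbreak.mechanism import (
    DuplicationBlock,
    TeAnnotation,
    annotate_te_fragments,
    classify_junctions,
    classify_mechanism,
    detect_exchanged_tsd,
    detect_inverted_duplications,
    estimate_inversion_age,
    find_tsds,
    principal_te,
    reverse_complement,
    TsdCandidates,
    TsdEvidence,
)
from invbreak.simulate import (
    MechanismSpec,
    junction_windows,
    evolve_sequences,
    _random_seq,
)


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("AAGGCAAGT", "ACTTGCCTT"),
            ("ATTATACAG", "CTGTATAAT"),
            ("", ""),
        ],
    )
    def test_known_words(self, seq, expected):
        assert reverse_complement(seq) == expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTNacgtn", max_size=60))
    def test_involution_preserves_length(self, seq):
        rc = reverse_complement(seq)
        assert len(rc) == len(seq)
        assert reverse_complement(rc) == seq.upper()

    def test_rejects_other_characters(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGU")


class TestAnnotateTeFragments:
    def test_planted_full_copy(self, te_library):
        rng = np.random.default_rng(3)
        left, right = _random_seq(rng, 2_000), _random_seq(rng, 2_000)
        seq = left + te_library["BuT5"] + right
        anns = annotate_te_fragments(seq, te_library)
        full = [a for a in anns if a.kind == "full_copy"]
        assert len(full) == 1
        assert full[0].te_id == "BuT5"
        assert abs(full[0].start - 2_000) <= 2
        assert abs(full[0].end - (2_000 + 981)) <= 2

    def test_composite_footprint_from_both_termini(self, te_library):
        rng = np.random.default_rng(4)
        te = te_library["BuT5"]
        footprint = te[:12] + te[-15:]
        seq = _random_seq(rng, 5_000) + footprint + _random_seq(rng, 5_000)
        anns = annotate_te_fragments(seq, te_library, min_match=12)
        comps = [a for a in anns if a.kind == "composite_footprint"]
        assert len(comps) == 1
        assert comps[0].end - comps[0].start == 27
        assert comps[0].end_composition == (12, 15)

    def test_random_sequence_has_no_annotations_at_default(self, te_library):
        seq = _random_seq(np.random.default_rng(5), 10_000)
        assert annotate_te_fragments(seq, te_library) == []

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            annotate_te_fragments("ACGT" * 100, {})


class TestFindTsds:
    def make(self, rng, tsd_left, tsd_right, te_len=100, at_edge=False):
        te = _random_seq(rng, te_len)
        left = "" if at_edge else _random_seq(rng, 50) + tsd_left
        seq = left + te + tsd_right + _random_seq(rng, 50)
        ann = TeAnnotation("T", len(left), len(left) + te_len, "+", "full_copy")
        return seq, ann

    def test_flanks_returned_at_each_length(self):
        rng = np.random.default_rng(6)
        seq, ann = self.make(rng, "AAGGCAAGT", "CTGTATAAT")
        cands = find_tsds(seq, ann, (4, 12))
        assert cands.left[9] == "AAGGCAAGT"
        assert cands.right[9] == "CTGTATAAT"
        assert set(cands.left) == set(range(4, 13))

    def test_fixed_length_gives_single_pair(self):
        rng = np.random.default_rng(7)
        seq, ann = self.make(rng, "AAGGCAAGT", "CTGTATAAT")
        cands = find_tsds(seq, ann, (9, 9))
        assert list(cands.left) == [9] and list(cands.right) == [9]

    def test_te_at_edge_flags_one_sided(self):
        rng = np.random.default_rng(8)
        seq, ann = self.make(rng, "", "CTGTATAAT", at_edge=True)
        cands = find_tsds(seq, ann, (4, 12))
        assert cands.left == {}
        assert cands.edge_flags[0]


class TestDetectExchangedTsd:
    def test_reference_configuration_detected(self):
        distal = TsdCandidates(left={9: "AAGGCAAGT"}, right={9: "CTGTATAAT"})
        proximal = TsdCandidates(left={9: "ACTTGCCTT"}, right={9: "ATTATACAG"})
        ev = detect_exchanged_tsd(distal, proximal)
        assert ev.exchanged
        assert ev.distal_left == "AAGGCAAGT"

    def test_identical_flanks_not_exchanged(self):
        same = TsdCandidates(left={9: "AAGGCAAGT"}, right={9: "AAGGCAAGT"})
        assert not detect_exchanged_tsd(same, same).exchanged

    def test_simulated_junctions(self, te_library):
        mech = MechanismSpec("te_ectopic", tsd_length=9, te_id="BuT5")
        jw = junction_windows(mech, seed=30, flank=3_000, te_library=te_library)
        te_ac = principal_te(annotate_te_fragments(jw.ac, te_library))
        te_bd = principal_te(annotate_te_fragments(jw.bd, te_library))
        ev = detect_exchanged_tsd(
            find_tsds(jw.ac, te_ac, (4, 12)), find_tsds(jw.bd, te_bd, (4, 12))
        )
        assert ev.exchanged


class TestDetectInvertedDuplications:
    def test_planted_inverted_copy(self):
        rng = np.random.default_rng(9)
        dup = _random_seq(rng, 1_000)
        ac = _random_seq(rng, 2_000) + dup + _random_seq(rng, 2_000)
        bd = _random_seq(rng, 1_500) + reverse_complement(dup) + _random_seq(rng, 1_500)
        blocks = detect_inverted_duplications(ac, bd)
        inv = [b for b in blocks if b.orientation == "inverted"]
        assert len(inv) == 1
        assert abs(inv[0].length - 1_000) < 30

    def test_deleted_copy_chains_into_one_segment(self):
        # 7.1-kb duplication, one copy eroded to ~40%
        mech = MechanismSpec(
            "staggered_ssb", dup_length_distal=7_100, deletion_fraction=0.6
        )
        jw = junction_windows(mech, seed=31, flank=9_000)
        inv = [
            b
            for b in detect_inverted_duplications(jw.ac, jw.bd)
            if b.orientation == "inverted"
        ]
        assert len(inv) == 1
        span = inv[0].ac_end - inv[0].ac_start
        assert span <= 7_150
        assert inv[0].length >= 1_000

    def test_unrelated_sequences_give_nothing(self):
        rng = np.random.default_rng(10)
        assert (
            detect_inverted_duplications(_random_seq(rng, 3_000), _random_seq(rng, 3_000))
            == []
        )


class TestEstimateInversionAge:
    def test_declared_formula(self):
        blk = DuplicationBlock(0, 1000, 0, 1000, "inverted", 1000, 100.0, 0.0)
        assert estimate_inversion_age([blk], 0.0111) == 0.0
        # raw p-distance 0.0222 -> age 1.0 without the JC correction
        blk2 = DuplicationBlock(0, 1000, 0, 1000, "inverted", 1000, 97.78, 0.0)
        assert estimate_inversion_age([blk2], 0.0111, jukes_cantor=False) == pytest.approx(
            1.0, abs=0.01
        )

    def test_zero_aligned_sites_is_error(self):
        with pytest.raises(ValueError):
            estimate_inversion_age([], 0.0111)

    def test_parameter_recovery_at_reference_age(self):
        # two copies of >=5 kb diverging 4.4 myr each at the neutral rate
        estimates = []
        for seed in range(6):
            mech = MechanismSpec("staggered_ssb", dup_length_distal=5_500)
            jw = junction_windows(mech, seed=40 + seed, flank=7_000, age_myr=4.4)
            inv = [
                b
                for b in detect_inverted_duplications(jw.ac, jw.bd)
                if b.orientation == "inverted"
            ]
            estimates.append(estimate_inversion_age(inv, 0.0111))
        err = np.abs(np.array(estimates) - 4.4)
        # p ~ 0.098 over 5.5 kb: 2 binomial SEs on the age scale is ~0.5 myr
        assert np.median(err) < 0.5


class TestClassifyMechanism:
    def test_exchanged_tsds_take_precedence(self):
        ev = TsdEvidence("A" * 9, "C" * 9, "T" * 9, "G" * 9, exchanged=True)
        call = classify_mechanism(ev, [], preexisting_dup=True)
        assert call.label == "ectopic_recombination"

    def test_inverted_dups_without_parent_copy(self):
        blk = DuplicationBlock(0, 1000, 0, 1000, "inverted", 1000, 98.0, 0.0)
        call = classify_mechanism(None, [blk], preexisting_dup=False)
        assert call.label == "staggered_ssb_nhej"
        assert call.age_myr is not None

    def test_preexisting_duplication_blocks_staggered_call(self):
        blk = DuplicationBlock(0, 1000, 0, 1000, "inverted", 1000, 98.0, 0.0)
        call = classify_mechanism(None, [blk], preexisting_dup=True)
        assert call.label == "undetermined"
        assert call.preexisting_duplication

    def test_no_evidence_is_undetermined(self):
        assert classify_mechanism(None, []).label == "undetermined"

    def test_preexisting_duplication_detected_in_parent(self, te_library):
        # a duplication present in the parental windows is not mechanism
        # evidence: plant the same inverted pair in parent and derived
        rng = np.random.default_rng(11)
        dup = _random_seq(rng, 800)
        a, b = _random_seq(rng, 1_500), _random_seq(rng, 1_500)
        c, d = _random_seq(rng, 1_500), _random_seq(rng, 1_500)
        ab = a + dup + b
        cd = c + reverse_complement(dup) + d
        ac = a + dup + reverse_complement(c) + dup[:0]
        bd = reverse_complement(b) + reverse_complement(dup) + d
        call = classify_junctions(ac, bd, None, ab, cd)
        assert call.label == "undetermined"
        assert call.preexisting_duplication
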