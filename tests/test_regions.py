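"""Breakpoint-region delimitation, pairing, narrowing, refinement, RBH."""

import numpy as np
import pytest

from invbreak.regions import (
    BreakpointRegion,
    initial_regions,
    narrow_by_outgroup,
    pair_breakpoints,
    reciprocal_best_hit,
    refine_by_orthologs,
)
from invbreak.rearrangement import Reversal, SignedPermutation, sorting_scenario
from invbreak.segmentation import SyntenicSegment
from invbreak.simulate import (
    GeneModel,
    MechanismSpec,
    junction_windows,
    two_lineage_permutation,
    _random_seq,
)


def seg(i, start, end, sign=1):
    return SyntenicSegment(i, sign, start, end, 10, (10 * i, 10 * i + 9))


class TestInitialRegions:
    def test_region_per_adjacent_pair(self):
        assert len(initial_regions([seg(1, 0, 100), seg(2, 200, 300)])) == 1
        segs = [seg(i, i * 1000, i * 1000 + 500) for i in range(1, 21)]
        assert len(initial_regions(segs)) == 19

    def test_interval_is_marker_to_marker(self):
        (r,) = initial_regions([seg(1, 0, 100), seg(2, 250, 300)])
        assert (r.start, r.end) == (100, 250)
        assert r.initial_size == 150

    def test_abutting_segments_flag_zero_length(self):
        (r,) = initial_regions([seg(1, 0, 100), seg(2, 100, 300)])
        assert r.zero_length and r.initial_size == 0

    def test_overlap_is_error(self):
        with pytest.raises(ValueError):
            initial_regions([seg(1, 0, 100), seg(2, 50, 300)])


class TestPairBreakpoints:
    def test_single_interior_inversion(self):
        # target (1, -2, 3): one inverted middle segment
        p = SignedPermutation((1, -2, 3))
        segs = [seg(i, i * 1000, i * 1000 + 500) for i in range(1, 4)]
        regions = initial_regions(segs)
        scen = sorting_scenario(p)
        paired = pair_breakpoints(regions, scen, p)
        assert paired[0].inversion_ids == paired[1].inversion_ids != ()
        assert paired[1].side == "distal_AC"
        assert paired[0].side == "proximal_BD"

    def test_inconsistent_scenario_rejected(self):
        p = SignedPermutation((1, -2, 3))
        segs = [seg(i, i * 1000, i * 1000 + 500) for i in range(1, 4)]
        with pytest.raises(ValueError):
            pair_breakpoints(initial_regions(segs), [Reversal(1, 1)], p)

    def test_simulated_seven_inversion_pairing(self):
        scen = two_lineage_permutation(2)
        p = scen.arrangement_a  # 7 inversions, 14 independent breakpoints
        # collapse preserved adjacencies into blocks to obtain 15 segments
        from invbreak.rearrangement import reversal_distance

        segs = [seg(i, i * 10_000, i * 10_000 + 5_000) for i in range(1, p.n + 1)]
        regions = initial_regions(segs)
        paired = pair_breakpoints(regions, sorting_scenario(p), p)
        by_inv = {}
        for r in paired:
            for inv in r.inversion_ids:
                by_inv.setdefault(inv, []).append(r.region_id)
        assert len(by_inv) == reversal_distance(p) == 7
        # each inversion's endpoints map to exactly two regions
        assert all(len(v) == 2 for v in by_inv.values())

    def test_reused_breakpoint_carries_two_inversion_ids(self):
        scen = two_lineage_permutation(4)
        p = scen.arrangement_b.inverse()  # tandem pair visible from ancestor
        segs = [seg(i, i * 10_000, i * 10_000 + 5_000) for i in range(1, p.n + 1)]
        paired = pair_breakpoints(
            initial_regions(segs), sorting_scenario(p), p
        )
        multi = [r for r in paired if len(r.inversion_ids) == 2]
        assert len(multi) == 1


class TestNarrowByOutgroup:
    def test_inserted_junction_is_recovered(self):
        rng = np.random.default_rng(0)
        flank_a = _random_seq(rng, 3000)
        flank_b = _random_seq(rng, 3000)
        insert = _random_seq(rng, 500)
        region = flank_a + insert + flank_b
        s, e, narrowed = narrow_by_outgroup(region, flank_a + flank_b, _random_seq(rng, 2000))
        assert narrowed
        assert abs(s - 3000) < 60 and abs(e - 3500) < 60

    def test_full_similarity_collapses_region(self):
        rng = np.random.default_rng(1)
        region = _random_seq(rng, 4000)
        s, e, narrowed = narrow_by_outgroup(region, region, _random_seq(rng, 2000))
        assert narrowed
        assert e - s < 120

    def test_no_similarity_warns_unchanged(self):
        rng = np.random.default_rng(2)
        region = _random_seq(rng, 1500)
        with pytest.warns(UserWarning):
            s, e, narrowed = narrow_by_outgroup(
                region, _random_seq(rng, 1500), _random_seq(rng, 1500)
            )
        assert (s, e, narrowed) == (0, 1500, False)

    @pytest.mark.parametrize(
        "kind",
        ["te_ectopic", "staggered_ssb", "clean_dsb"],
    )
    def test_narrowed_interval_contains_true_junction(self, kind, te_library):
        if kind == "te_ectopic":
            mech = MechanismSpec(kind, tsd_length=9, te_id="BuT5")
        elif kind == "staggered_ssb":
            mech = MechanismSpec(kind, dup_length_distal=1_000, dup_length_proximal=2_000)
        else:
            mech = MechanismSpec(kind)
        hits = 0
        n = 10
        ratios = []
        for i in range(n):
            jw = junction_windows(
                mech, seed=100 + i, flank=5_000, te_library=te_library, age_myr=1.0
            )
            for region, junction in ((jw.ac, jw.junction_ac), (jw.bd, jw.junction_bd)):
                s, e, _ = narrow_by_outgroup(region, jw.ab, jw.cd, te_library=te_library)
                if s - 50 <= junction <= e + 50:
                    hits += 1
                ratios.append((e - s) / len(region))
        assert hits >= int(0.95 * 2 * n)
        assert np.mean(ratios) < 0.25  # narrowing is substantial


class TestRefineByOrthologs:
    @staticmethod
    def region(start=1000, end=5000):
        return BreakpointRegion(region_id=1, start=start, end=end)

    @staticmethod
    def gene(gid, start, end, n_exons=2):
        step = (end - start) // (2 * n_exons - 1)
        exons = tuple(
            (start + 2 * k * step, start + (2 * k + 1) * step) for k in range(n_exons)
        )
        return GeneModel(gid, start, end, "+", exons)

    def orthologs(self):
        from invbreak.regions import OrthologPair

        return [OrthologPair("gA", "gB", 500.0, mutual=True)]

    def test_no_overlapping_genes_unchanged(self):
        r = refine_by_orthologs(self.region(), [self.gene("gA", 6000, 8000)], self.orthologs())
        assert (r.narrowed_start, r.narrowed_end) == (1000, 5000)

    def test_conserved_ortholog_excised_from_edge(self):
        g = self.gene("gA", 500, 3000)
        partner = {"gB": self.gene("gB", 100, 2600)}
        r = refine_by_orthologs(self.region(), [g], self.orthologs(), partner)
        assert r.narrowed_start == 3000
        assert r.refined

    def test_non_conserved_gene_not_excised(self):
        g = self.gene("gA", 500, 3000, n_exons=2)
        partner = {"gB": self.gene("gB", 100, 2600, n_exons=4)}  # exon count differs
        r = refine_by_orthologs(self.region(), [g], self.orthologs(), partner)
        assert r.narrowed_start == 1000 and not r.refined

    def test_gene_spanning_region_left_unchanged(self):
        g = self.gene("gA", 500, 6000)
        partner = {"gB": self.gene("gB", 100, 5600)}
        r = refine_by_orthologs(self.region(), [g], self.orthologs(), partner)
        assert (r.narrowed_start, r.narrowed_end) == (1000, 5000)

    def test_idempotent(self):
        g = self.gene("gA", 500, 3000)
        partner = {"gB": self.gene("gB", 100, 2600)}
        r1 = refine_by_orthologs(self.region(), [g], self.orthologs(), partner)
        r2 = refine_by_orthologs(r1, [g], self.orthologs(), partner)
        assert (r1.narrowed_start, r1.narrowed_end) == (r2.narrowed_start, r2.narrowed_end)
        assert r1.narrowed_size <= r1.initial_size


PROT_A = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQ"
PROT_B = "MSSSSWLLLSLVAVTAAQSTIEEQAKTFLDKFNHEAEDLFYQSSLASWNYNTNITEENVQNMNNAG"


class TestReciprocalBestHit:
    def test_identical_sets_give_identity_mapping(self):
        a = {"g1": PROT_A, "g2": PROT_B}
        b = {"h1": PROT_A, "h2": PROT_B}
        pairs = reciprocal_best_hit(a, b)
        assert {(p.gene_id_a, p.gene_id_b) for p in pairs} == {("g1", "h1"), ("g2", "h2")}
        assert all(p.mutual for p in pairs)

    def test_paralog_resolved_to_mutual_best(self):
        # h1 is an exact copy, h2 a decayed paralog of the same protein
        decayed = PROT_A[:30] + "G" * 10 + PROT_A[40:]
        pairs = reciprocal_best_hit({"g1": PROT_A}, {"h1": PROT_A, "h2": decayed})
        assert [(p.gene_id_a, p.gene_id_b) for p in pairs] == [("g1", "h1")]

    def test_empty_input(self):
        assert reciprocal_best_hit({}, {"h1": PROT_A}) == []
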