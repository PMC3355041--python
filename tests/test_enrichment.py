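"""Duplicate adjacency detection and 2x2 contingency statistics."""

import math
import random

import numpy as np
import pytest
from scipy import stats as sstats

from invbreak.config import ConfigDefaults
from invbreak.enrichment import (
    ContingencyTable,
    ProteinRecord,
    align_protein_pair,
    chi2_2x2,
    enrichment_report,
    find_duplicate_adjacencies,
    fisher_exact_2x2,
    two_sample_t,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n):
    return "".join(rng.choice(list(AA), size=n))


class TestAlignProteinPair:
    def test_identical_proteins(self):
        rng = np.random.default_rng(0)
        seq = random_protein(rng, 100)
        identity, length, score = align_protein_pair(seq, seq)
        assert identity == 100.0
        assert length == 100
        assert score > 0

    def test_unrelated_proteins_below_duplicate_cutoff(self):
        from invbreak.alignment import protein_score_threshold

        rng = np.random.default_rng(1)
        a, b = random_protein(rng, 200), random_protein(rng, 200)
        _, _, score = align_protein_pair(a, b)
        assert score < protein_score_threshold(1e-30, 200, 200)

    def test_constructed_half_identity(self):
        rng = np.random.default_rng(2)
        a = random_protein(rng, 120)
        # mutate every second residue of the middle block
        b = list(a)
        for i in range(30, 90, 2):
            b[i] = "A" if a[i] != "A" else "G"
        identity, length, _ = align_protein_pair(a, "".join(b))
        assert 55 <= identity <= 90  # ~75% overall with a 50%-identity block

    def test_bad_characters_rejected(self):
        with pytest.raises(ValueError):
            align_protein_pair("MKT1", "MKT")


class TestFindDuplicateAdjacencies:
    def test_intergenic_count_is_genes_minus_one(self):
        rng = np.random.default_rng(3)
        prots = [
            ProteinRecord(f"g{i}", i + 1, random_protein(rng, 60)) for i in range(25)
        ]
        flagged, _ = find_duplicate_adjacencies(prots)
        assert flagged <= set(range(1, 25))

    def test_adjacent_identical_proteins_flagged(self):
        rng = np.random.default_rng(4)
        seq = random_protein(rng, 150)
        prots = [
            ProteinRecord("g1", 1, seq),
            ProteinRecord("g2", 2, seq),
            ProteinRecord("g3", 3, random_protein(rng, 150)),
        ]
        flagged, pairs = find_duplicate_adjacencies(prots)
        assert flagged == {1}
        assert pairs[0].gene_id_a == "g1"

    def test_planted_duplicates_exactly_recovered(self):
        rng = np.random.default_rng(5)
        n = 120
        seqs = [random_protein(rng, 90) for _ in range(n)]
        planted = set()
        k = 1
        while len(planted) < 10:
            planted.add(int(rng.integers(1, n - 1)))
        for idx in planted:
            seqs[idx] = seqs[idx - 1]  # rank idx+1 duplicates rank idx
        prots = [ProteinRecord(f"g{i}", i + 1, s) for i, s in enumerate(seqs)]
        flagged, _ = find_duplicate_adjacencies(prots)
        assert flagged == planted

    def test_duplicate_ranks_rejected(self):
        rng = np.random.default_rng(6)
        prots = [
            ProteinRecord("g1", 1, random_protein(rng, 50)),
            ProteinRecord("g2", 1, random_protein(rng, 50)),
        ]
        with pytest.raises(ValueError):
            find_duplicate_adjacencies(prots)


class TestChi2:
    @pytest.mark.parametrize(
        "table, yates, expected",
        [
            ((4, 10, 215, 3191), False, 11.526),
            ((4, 10, 215, 3191), True, 8.111),
            ((3, 25, 69, 3338), False, 10.22),
            ((3, 25, 69, 3338), True, 6.42),
        ],
    )
    def test_reference_statistics(self, table, yates, expected):
        res = chi2_2x2(ContingencyTable(*table), yates=yates)
        assert res.statistic == pytest.approx(expected, abs=5e-3)

    def test_proportional_table(self):
        res = chi2_2x2(ContingencyTable(5, 10, 10, 20))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_zero_margin_is_error(self):
        with pytest.raises(ValueError):
            chi2_2x2(ContingencyTable(0, 0, 5, 5))

    def test_invariances_and_yates_ordering(self):
        rng = random.Random(1)
        for _ in range(100):
            a, b, c, d = (rng.randint(1, 40) for _ in range(4))
            t = ContingencyTable(a, b, c, d)
            plain = chi2_2x2(t).statistic
            yates = chi2_2x2(t, yates=True).statistic
            assert plain >= yates
            for variant in [(c, d, a, b), (b, a, d, c), (a, c, b, d)]:
                assert chi2_2x2(ContingencyTable(*variant)).statistic == pytest.approx(
                    plain
                )

    def test_against_scipy(self):
        rng = random.Random(2)
        for _ in range(50):
            a, b, c, d = (rng.randint(1, 60) for _ in range(4))
            ours = chi2_2x2(ContingencyTable(a, b, c, d), yates=True)
            ref = sstats.chi2_contingency([[a, b], [c, d]], correction=True)
            assert ours.statistic == pytest.approx(ref.statistic)
            assert ours.p_value == pytest.approx(ref.pvalue)


class TestFisher:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((4, 10, 215, 3191), 0.0098),
            ((3, 25, 69, 3338), 0.0199),
        ],
    )
    def test_reference_p_values(self, table, expected):
        res = fisher_exact_2x2(ContingencyTable(*table))
        assert res.p_value == pytest.approx(expected, abs=5e-5)

    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2(ContingencyTable(1, 1, 1, 1)).p_value == pytest.approx(
            1.0
        )

    def test_matches_scipy_convention(self):
        rng = random.Random(3)
        for _ in range(200):
            a, b, c, d = (rng.randint(0, 15) for _ in range(4))
            t = ContingencyTable(a, b, c, d)
            try:
                ours = fisher_exact_2x2(t).p_value
            except ValueError:
                continue
            assert ours == pytest.approx(
                sstats.fisher_exact([[a, b], [c, d]]).pvalue, abs=1e-9
            )

    def test_type_one_error_under_hypergeometric_null(self):
        rng = np.random.default_rng(7)
        n, r1, c1 = 60, 25, 20
        rejections = 0
        trials = 10_000
        for _ in range(trials):
            a = rng.hypergeometric(r1, n - r1, c1)
            t = ContingencyTable(int(a), r1 - int(a), c1 - int(a), n - r1 - c1 + int(a))
            if fisher_exact_2x2(t).p_value <= 0.05:
                rejections += 1
        assert rejections / trials <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / trials)


class TestTwoSampleT:
    def test_identical_groups(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_degenerate_two_point_groups(self):
        # zero within-group variance: separated means cannot be scored
        with pytest.raises(ValueError):
            two_sample_t([0.0, 0.0], [1.0, 1.0])
        res = two_sample_t([0.0, 1.0], [2.0, 3.0])
        assert math.isfinite(res.statistic) and res.p_value < 0.2

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            x = rng.normal(0, 1, size=20)
            y = rng.normal(0.5, 1.3, size=25)
            ours = two_sample_t(x, y)
            ref = sstats.ttest_ind(x, y, equal_var=True)
            assert ours.statistic == pytest.approx(ref.statistic)
            assert ours.p_value == pytest.approx(ref.pvalue)

    def test_power_matches_closed_form(self):
        # means 0 vs 1, sd 1, n=100/group: analytic power at alpha=0.05
        rng = np.random.default_rng(9)
        n, delta, alpha, trials = 100, 1.0, 0.05, 400
        rejections = sum(
            two_sample_t(rng.normal(0, 1, n), rng.normal(delta, 1, n)).p_value < alpha
            for _ in range(trials)
        )
        df = 2 * n - 2
        ncp = delta / math.sqrt(2.0 / n)
        crit = sstats.t.ppf(1 - alpha / 2, df)
        power = 1 - sstats.nct.cdf(crit, df, ncp) + sstats.nct.cdf(-crit, df, ncp)
        se = math.sqrt(power * (1 - power) / trials)
        assert abs(rejections / trials - power) < 4 * se


class TestEnrichmentReport:
    def test_reference_table_construction(self):
        rep = enrichment_report(4, 14, 215, 3406, 3, 28, 69, 3407)
        dup = rep["duplication"]["table"]
        assert (dup.a, dup.b, dup.c, dup.d) == (4, 10, 215, 3191)
        tr = rep["transposition"]["table"]
        assert (tr.a, tr.b, tr.c, tr.d) == (3, 25, 69, 3338)
        assert rep["duplication"]["chi2"].statistic == pytest.approx(11.526, abs=5e-3)
        assert rep["transposition"]["fisher"].p_value == pytest.approx(0.0199, abs=5e-5)

    def test_exclusive_comparison_group(self):
        rep = enrichment_report(4, 14, 215, 3406, exclusive=True)
        dup = rep["duplication"]["table"]
        assert (dup.a, dup.b, dup.c, dup.d) == (4, 10, 211, 3181)

    def test_zero_breakpoint_hits_reports_no_enrichment(self):
        rep = enrichment_report(0, 14, 215, 3406)
        assert "note" in rep["duplication"]
        assert rep["duplication"]["table"].a == 0

    def test_inconsistent_totals_rejected(self):
        with pytest.raises(ValueError):
            enrichment_report(15, 14, 215, 3406)
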