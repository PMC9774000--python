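import numpy as np
import pytest

from strainrank import (
    DataError,
    MetricRow,
    ShiftEntry,
    ShiftTable,
    TorsionEntry,
    TorsionTable,
    delta_alphabeta,
    match_residues,
    rank_structures,
    secondary_shifts,
    sigma_a,
    sigma_cs,
    sigma_psiphi,
)
from strainrank.tables import SecondaryShiftEntry, SecondaryShiftProfile

from .conftest import random_paired_shift_tables, random_paired_torsion_tables
from .oracles import brute_sigma_a, brute_sigma_cs, brute_sigma_psiphi


def shift_table(rows, label="NMR"):
    return ShiftTable([ShiftEntry(*r) for r in rows], source_label=label)


@pytest.fixture()
def toy_pair():
    """Two residues with CA diffs 0.5/1.0 ppm and CB diffs 0.25/0.25 ppm."""
    nmr = shift_table([(1, "V", "CA", 60.0), (1, "V", "CB", 34.0),
                       (2, "K", "CA", 55.0), (2, "K", "CB", 33.0)])
    cal = shift_table([(1, "V", "CA", 60.5), (1, "V", "CB", 34.25),
                       (2, "K", "CA", 56.0), (2, "K", "CB", 32.75)], "Cal:toy")
    return nmr, cal


class TestMatchResidues:
    def test_intersection_of_coverage(self):
        nmr = shift_table([(n, "V", "CA", 60.0) for n in range(309, 329)])
        cal = shift_table([(n, "V", "CA", 60.0) for n in range(306, 325)], "Cal:x")
        matched = match_residues(nmr, cal)
        assert matched.cs_ca() == list(range(309, 325))

    def test_glycine_contributes_ca_but_not_sign_metric(self, rc):
        nmr = shift_table([(1, "G", "CA", 45.0), (2, "V", "CA", 60.0), (2, "V", "CB", 34.0)])
        cal = shift_table([(1, "G", "CA", 45.5), (2, "V", "CA", 60.0), (2, "V", "CB", 34.0)], "Cal:x")
        matched = match_residues(nmr, cal)
        assert 1 in matched.cs_ca()
        assert matched.a_eligible() == [2]
        val, n = sigma_cs(nmr, cal, matched)
        assert val == pytest.approx(0.5)
        assert n == 2

    def test_ambiguous_exclude_policy_drops_groups(self):
        nmr = shift_table([(n, "A", "CA", 52.0) for n in range(330, 370)])
        cal = shift_table([(n, "A", "CA", 52.0) for n in range(330, 370)], "Cal:x")
        groups = ((332, 335), (364, 367))
        matched = match_residues(nmr, cal, ambiguous_policy="exclude", ambiguous_groups=groups)
        banned = set(range(332, 336)) | set(range(364, 368))
        assert not banned & set(matched.residues())
        both = match_residues(nmr, cal, ambiguous_policy="both", ambiguous_groups=groups)
        assert banned <= set(both.residues())

    def test_empty_intersection_raises(self):
        nmr = shift_table([(1, "A", "CA", 52.0)])
        cal = shift_table([(9, "A", "CA", 52.0)], "Cal:x")
        with pytest.raises(DataError):
            match_residues(nmr, cal)


class TestSigmaCS:
    def test_identity_is_zero(self, toy_pair):
        nmr, _ = toy_pair
        matched = match_residues(nmr, nmr)
        assert sigma_cs(nmr, nmr, matched) == (0.0, 2)

    def test_toy_value_and_per_residue_decomposition(self, toy_pair):
        nmr, cal = toy_pair
        matched = match_residues(nmr, cal)
        val, n = sigma_cs(nmr, cal, matched)
        assert val == pytest.approx(2.0)
        assert n == 2
        dab = delta_alphabeta(nmr, cal, matched)
        assert dab[1] == pytest.approx(0.75)
        assert dab[2] == pytest.approx(1.25)

    def test_partial_vs_strict_atom_modes(self):
        nmr = shift_table([(1, "V", "CA", 60.0), (2, "K", "CA", 55.0), (2, "K", "CB", 33.0)])
        cal = shift_table([(1, "V", "CA", 61.0), (1, "V", "CB", 34.0),
                           (2, "K", "CA", 55.5), (2, "K", "CB", 33.5)], "Cal:x")
        matched = match_residues(nmr, cal)
        assert sigma_cs(nmr, cal, matched, partial_atoms=True) == (pytest.approx(2.0), 2)
        # strict mode drops residue 1 (CB missing on the NMR side)
        assert sigma_cs(nmr, cal, matched, partial_atoms=False) == (pytest.approx(1.0), 1)

    def test_common_offset_cancels(self, toy_pair):
        nmr, cal = toy_pair
        shifted = ShiftTable(
            [ShiftEntry(e.residue_number, e.residue_type, e.atom_name, e.shift + 3.7)
             for e in nmr.entries]
        )
        shifted_cal = ShiftTable(
            [ShiftEntry(e.residue_number, e.residue_type, e.atom_name, e.shift + 3.7)
             for e in cal.entries], "Cal:toy"
        )
        matched = match_residues(nmr, cal)
        assert sigma_cs(shifted, shifted_cal, matched)[0] == pytest.approx(
            sigma_cs(nmr, cal, matched)[0]
        )


def profile(values):
    return SecondaryShiftProfile(
        [SecondaryShiftEntry(num, s, 0.0, s) for num, s in values.items()]
    )


class TestSigmaA:
    def test_identical_profiles_score_zero(self):
        p = profile({1: -2.0, 2: 1.5, 3: -0.5})
        nmr = shift_table(
            [(n, "V", "CA", 60.0) for n in (1, 2, 3)]
            + [(n, "V", "CB", 34.0) for n in (1, 2, 3)]
        )
        matched = match_residues(nmr, nmr)
        assert sigma_a(p, p, matched) == (0, 3)

    def test_hand_counted_sign_flips(self):
        # Cal = (+1, -2, -1), NMR = (-1, -2, +0.5): flips at residues 1 and 3
        cal = profile({1: 1.0, 2: -2.0, 3: -1.0})
        nmr_p = profile({1: -1.0, 2: -2.0, 3: 0.5})
        table = shift_table(
            [(n, "V", "CA", 60.0) for n in (1, 2, 3)]
            + [(n, "V", "CB", 34.0) for n in (1, 2, 3)]
        )
        matched = match_residues(table, table)
        assert sigma_a(nmr_p, cal, matched) == (2, 3)

    def test_zero_product_counts_as_agreement(self):
        cal = profile({1: 0.0, 2: -3.0})
        nmr_p = profile({1: -3.0, 2: -3.0})
        table = shift_table(
            [(n, "V", "CA", 60.0) for n in (1, 2)]
            + [(n, "V", "CB", 34.0) for n in (1, 2)]
        )
        matched = match_residues(table, table)
        assert sigma_a(nmr_p, cal, matched) == (0, 2)


class TestSigmaPsiPhi:
    def test_identity_is_zero(self):
        t = TorsionTable([TorsionEntry(1, "V", -135.0, 135.0)])
        table = shift_table([(1, "V", "CA", 60.0)])
        matched = match_residues(table, table, t, t)
        assert sigma_psiphi(t, t, matched) == (0.0, 1)

    def test_wraparound_circular_vs_naive(self):
        nmr_t = TorsionTable([TorsionEntry(1, "V", -170.0, 100.0)])
        cal_t = TorsionTable([TorsionEntry(1, "V", 170.0, 100.0)], "Cal:x")
        table = shift_table([(1, "V", "CA", 60.0)])
        matched = match_residues(table, table, nmr_t, cal_t)
        assert sigma_psiphi(nmr_t, cal_t, matched, circular=True)[0] == pytest.approx(20.0)
        assert sigma_psiphi(nmr_t, cal_t, matched, circular=False)[0] == pytest.approx(340.0)


class TestMetricProperties:
    """Identity, symmetry, bounds and oracle equivalence on random tables."""

    def test_oracle_equivalence_on_random_paired_tables(self, rc):
        rng = np.random.default_rng(42)
        for _ in range(50):
            nmr, cal, nmr_view, cal_view, residues = random_paired_shift_tables(rng, rc)
            matched = match_residues(nmr, cal)
            got_cs = sigma_cs(nmr, cal, matched)
            exp_cs = brute_sigma_cs(nmr_view, cal_view, residues)
            assert got_cs[1] == exp_cs[1]
            assert got_cs[0] == pytest.approx(exp_cs[0], abs=1e-9)

            p_n = secondary_shifts(nmr, rc)
            p_c = secondary_shifts(cal, rc)
            got_a = sigma_a(p_n, p_c, matched)
            exp_a = brute_sigma_a(p_n.s_values(), p_c.s_values(), residues)
            assert got_a == exp_a

            t_n, t_c, tv_n, tv_c, t_res = random_paired_torsion_tables(rng)
            cover = shift_table([(r, "A", "CA", 52.0) for r in t_res])
            m2 = match_residues(cover, cover, t_n, t_c)
            got_pp = sigma_psiphi(t_n, t_c, m2)
            exp_pp = brute_sigma_psiphi(tv_n, tv_c, t_res)
            assert got_pp[1] == exp_pp[1]
            assert got_pp[0] == pytest.approx(exp_pp[0], abs=1e-9)

    def test_symmetry_in_arguments(self, rc):
        rng = np.random.default_rng(3)
        nmr, cal, *_ = random_paired_shift_tables(rng, rc)
        matched = match_residues(nmr, cal)
        assert sigma_cs(nmr, cal, matched)[0] == pytest.approx(sigma_cs(cal, nmr, matched)[0])
        p_n, p_c = secondary_shifts(nmr, rc), secondary_shifts(cal, rc)
        assert sigma_a(p_n, p_c, matched) == sigma_a(p_c, p_n, matched)
        t_n, t_c, _, _, t_res = random_paired_torsion_tables(rng)
        cover = shift_table([(r, "A", "CA", 52.0) for r in t_res])
        m2 = match_residues(cover, cover, t_n, t_c)
        assert sigma_psiphi(t_n, t_c, m2)[0] == pytest.approx(sigma_psiphi(t_c, t_n, m2)[0])

    def test_sigma_a_bounded_by_n(self, rc):
        rng = np.random.default_rng(8)
        for _ in range(20):
            nmr, cal, *_ = random_paired_shift_tables(rng, rc)
            matched = match_residues(nmr, cal)
            val, n = sigma_a(secondary_shifts(nmr, rc), secondary_shifts(cal, rc), matched)
            assert 0 <= val <= n

    def test_delta_ab_sums_to_sigma_cs(self, rc):
        rng = np.random.default_rng(21)
        for _ in range(20):
            nmr, cal, *_ = random_paired_shift_tables(rng, rc)
            matched = match_residues(nmr, cal)
            dab = delta_alphabeta(nmr, cal, matched)
            assert sum(dab.values()) == pytest.approx(sigma_cs(nmr, cal, matched)[0], abs=1e-12)


class TestRanking:
    def test_single_structure_all_ranks_one(self):
        report = rank_structures([MetricRow("solo", 1.0, 5, 0, 5, 10.0, 5)])
        row = report.frame.iloc[0]
        assert (row.rank_cs, row.rank_a, row.rank_psiphi) == (1, 1, 1)

    def test_published_style_panel_ranks(self):
        # per-metric minima each belong to a different structure
        rows = [
            MetricRow("7p6d", 65.8414, 40, 4, 40, 3648.0, 40, "AGD"),
            MetricRow("7qjv", 73.6912, 40, 4, 40, 3361.0, 40, "AD"),
            MetricRow("7mkg", 62.9429, 40, 5, 40, 2848.0, 40, "AD"),
            MetricRow("5o3o", 74.1779, 40, 5, 40, 3146.0, 40, "AD"),
            MetricRow("7p6c", 69.0672, 40, 7, 40, 2661.0, 40, "LNT"),
        ]
        report = rank_structures(rows)
        assert report.best("sigma_cs") == "7mkg"
        assert report.best("sigma_psiphi") == "7p6c"
        # table sorted by sigma_a; 4-4 tie broken by ascending sigma_psiphi
        assert list(report.frame.structure_id[:2]) == ["7qjv", "7p6d"]
        assert report.frame.loc[report.frame.structure_id == "7qjv", "rank_a"].item() == 1
        assert report.frame.loc[report.frame.structure_id == "7p6d", "rank_a"].item() == 1

    def test_three_way_tie_follows_documented_tiebreak(self):
        rows = [
            MetricRow("c", 1.0, 5, 2, 9, 50.0, 5),
            MetricRow("a", 1.0, 5, 2, 9, 50.0, 5),
            MetricRow("b", 1.0, 5, 2, 9, 40.0, 5),
        ]
        report = rank_structures(rows)
        assert list(report.frame.structure_id) == ["b", "a", "c"]
        assert list(report.frame.rank_a) == [1, 1, 1]
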