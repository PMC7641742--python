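"""Restraint generation: class windows, per-fold counts, bookkeeping."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qdhfold import restraints as R
from qdhfold import topology as T


class TestClassifyNoe:
    @pytest.mark.parametrize(
        "cls, exch, target, lower, upper",
        [
            ("strong", False, 2.7, 1.9, 3.5),
            ("medium", False, 3.8, 2.9, 4.7),
            ("weak", False, 5.5, 3.8, 7.2),
            ("strong", True, 4.0, 3.0, 5.0),
            ("medium", True, 4.8, 3.4, 6.2),
            ("weak", True, 5.5, 3.8, 7.2),
        ],
    )
    def test_intensity_class_windows(self, cls, exch, target, lower, upper):
        r = R.classify_noe(cls, exch, False, (1, "H8"), (2, "H1'"))
        assert (r.target, r.lower, r.upper) == pytest.approx((target, lower, upper))
        assert r.exchangeable is exch

    def test_thymine_methyl_redirected_and_loosened(self):
        r = R.classify_noe("weak", False, True, (5, "H71"), (2, "H6"))
        assert r.atom_a == (5, "C7")
        assert r.atom_b == (2, "H6")
        assert (r.lower, r.upper) == pytest.approx((3.3, 7.7))

    def test_origin_inferred_from_residues(self):
        intra = R.classify_noe("medium", False, False, (3, "H8"), (3, "H1'"))
        inter = R.classify_noe("medium", False, False, (3, "H8"), (4, "H1'"))
        assert intra.origin == "intra-residue"
        assert inter.origin == "inter-residue"

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="intensity class"):
            R.classify_noe("huge", False, False, (1, "H8"), (2, "H6"))

    def test_window_invariants(self):
        with pytest.raises(ValueError):
            R.DistanceRestraint((1, "H8"), (2, "H6"), 0.5, 0.8, 0.8, "strong")


class TestHbondRestraints:
    def test_form1_count(self, form1):
        assert len(R.hbond_restraints(form1)) == 66  # 3*16 + 3*6

    def test_form2_count(self, form2):
        assert len(R.hbond_restraints(form2)) == 56  # 2*16 + 4*6

    def test_single_pair_topology(self):
        t = T.QDHTopology(
            "pair", "GC",
            (T.ResidueSpec(1, "G"), T.ResidueSpec(2, "C")),
            pairs=(T.BasePairSpec(1, 2),),
        )
        rs = R.hbond_restraints(t)
        assert len(rs) == 6
        assert {(r.target, r.minus) for r in rs} == {(2.0, 0.2), (2.9, 0.3)}

    def test_hoogsteen_edges_follow_member_order(self, form1):
        rs = R.hbond_restraints(form1)
        tet = form1.tetrads[0].members
        # donor 3 -> acceptor 25 (next in cyclic order)
        edge = [r for r in rs if r.atom_a[0] == tet[0] and r.atom_b[0] == tet[1]]
        assert {(r.atom_a[1], r.atom_b[1]) for r in edge} == {
            ("H21", "N7"), ("N2", "N7"), ("H1", "O6"), ("N1", "O6")
        }

    def test_non_g_member_rejected(self, form1):
        bad = dataclasses.replace(
            form1, tetrads=(T.TetradSpec((6, 25, 22, 7)),) + form1.tetrads[1:]
        )
        with pytest.raises(ValueError, match="not G"):
            R.hbond_restraints(bad)

    @given(
        n_tetrads=st.integers(min_value=0, max_value=3),
        n_pairs=st.integers(min_value=0, max_value=3),
    )
    @settings(max_examples=16, deadline=None)
    def test_count_closed_form(self, n_tetrads, n_pairs):
        # 16 restraints per G-tetrad + 6 per WC pair for any valid topology
        seq = "G" * (4 * n_tetrads) + "GC" * n_pairs
        if not seq:
            seq = "G"
        residues = tuple(T.ResidueSpec(i + 1, b) for i, b in enumerate(seq))
        tetrads = tuple(
            T.TetradSpec(tuple(range(4 * k + 1, 4 * k + 5)))
            for k in range(n_tetrads)
        )
        base = 4 * n_tetrads
        pairs = tuple(
            T.BasePairSpec(base + 2 * k + 1, base + 2 * k + 2)
            for k in range(n_pairs)
        )
        t = T.QDHTopology("synthetic", seq, residues, tetrads, pairs)
        assert len(R.hbond_restraints(t)) == 16 * n_tetrads + 6 * n_pairs


class TestDihedralRestraints:
    def test_form1_count_includes_syn_terminal(self, form1):
        rs = R.dihedral_restraints(form1)
        assert len(rs) == 19  # 12 tetrad G + 6 stem G/C + syn G1
        assert any(r.residue == 1 for r in rs)

    def test_form2_count(self, form2):
        assert len(R.dihedral_restraints(form2)) == 16  # 8 + 4 GCGC + 4 stem

    def test_syn_window_loose(self, form1):
        (g1,) = [r for r in R.dihedral_restraints(form1) if r.residue == 1]
        assert (g1.center, g1.halfwidth) == (60.0, 70.0)
        assert g1.atoms == ("O4'", "C1'", "N9", "C4")

    def test_tight_flag_narrows_all(self, form2):
        assert all(r.halfwidth == 40.0 for r in R.dihedral_restraints(form2, tight=True))

    def test_anti_center(self, form1):
        anti = [r for r in R.dihedral_restraints(form1) if r.residue == 19]
        assert anti[0].center == 240.0

    def test_cytosine_quartet(self, form1):
        (c10,) = [r for r in R.dihedral_restraints(form1) if r.residue == 10]
        assert c10.atoms == ("O4'", "C1'", "N1", "C2")


class TestPlanarityRestraints:
    def test_form1_units(self, form1):
        units = R.planarity_restraints(form1)
        assert len(units) == 6  # 3 tetrads + 3 pairs
        assert sum(len(u.members) == 4 for u in units) == 3

    def test_form2_units_exclude_gcgc_member_pairs(self, form2):
        units = R.planarity_restraints(form2)
        assert len(units) == 5  # 2 G-tetrads + 1 GCGC + 2 stand-alone pairs
        assert sum(len(u.members) == 4 for u in units) == 3

    def test_empty_topology(self):
        t = T.QDHTopology("empty", "G", (T.ResidueSpec(1, "G"),))
        assert R.planarity_restraints(t) == []


class TestSummaryAndSerialization:
    def test_form_summaries(self, form1, form2):
        for t, expect in ((form1, (66, 19, 6)), (form2, (56, 16, 5))):
            s = R.restraint_summary(
                [], R.hbond_restraints(t), R.dihedral_restraints(t),
                R.planarity_restraints(t),
            )
            assert (s.hydrogen_bond, s.dihedral_angle, s.planarity) == expect

    def test_empty_summary_zeros(self):
        s = R.restraint_summary([], [], [], [])
        assert all(getattr(s, f) == 0 for f in s.__dataclass_fields__)

    def test_noe_partition_by_origin_and_solvent(self):
        noe = [
            R.classify_noe("strong", False, False, (1, "H8"), (1, "H1'")),
            R.classify_noe("medium", False, False, (1, "H8"), (2, "H1'")),
            R.classify_noe("strong", True, False, (1, "H1"), (2, "H1")),
        ]
        s = R.restraint_summary(noe, [], [], [])
        assert (s.intra_residue_d2o, s.inter_residue_d2o, s.inter_residue_h2o) \
            == (1, 1, 1)

    def test_tsv_round_trip_is_deterministic(self, form1):
        rs = R.hbond_restraints(form1)
        text = R.restraints_to_tsv(rs)
        assert text == R.restraints_to_tsv(R.restraints_from_tsv(text))

    def test_xplor_writer_format(self, form1):
        text = R.restraints_to_xplor(R.hbond_restraints(form1)[:1])
        assert text.startswith("assign (residue 3 and name H21)")
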