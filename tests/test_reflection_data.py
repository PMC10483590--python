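"""Unit cell, hkl I/O and symmetry-equivalence grouping."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from edsigma import (
    Measurement,
    SymmetrySetting,
    UnitCell,
    d_star,
    group_equivalents,
    read_hkl,
    write_hkl,
)
from edsigma.reflection_data import LAUE_CLASSES, canonical_index, laue_operators


class TestUnitCell:
    def test_rejects_nonpositive_lengths_and_bad_angles(self):
        with pytest.raises(ValueError):
            UnitCell(-1, 10, 10)
        with pytest.raises(ValueError):
            UnitCell(10, 10, 10, alpha=180.0)

    def test_degenerate_cell_rejected(self):
        # alpha + beta + gamma constraints violated -> non-positive-definite metric
        with pytest.raises(ValueError):
            UnitCell(10, 10, 10, 10.0, 170.0, 90.0)


class TestDStar:
    def test_cubic_axis(self):
        assert d_star(UnitCell(10, 10, 10), (1, 0, 0)) == pytest.approx(0.1)

    def test_zero_index(self):
        assert d_star(UnitCell(7, 8, 9, 80, 95, 100), (0, 0, 0)) == 0.0

    def test_orthorhombic_zeolite_cell(self):
        cell = UnitCell(18.2872, 18.6661, 6.6222)
        assert d_star(cell, (0, 0, 2)) == pytest.approx(2 / 6.6222, rel=1e-12)

    @given(
        h=st.integers(-8, 8), k=st.integers(-8, 8), l=st.integers(-8, 8),
        a=st.floats(3, 50), b=st.floats(3, 50), c=st.floats(3, 50),
    )
    def test_orthorhombic_closed_form(self, h, k, l, a, b, c):
        cell = UnitCell(a, b, c)
        expected = np.sqrt((h / a) ** 2 + (k / b) ** 2 + (l / c) ** 2)
        assert d_star(cell, (h, k, l)) == pytest.approx(expected, rel=1e-12, abs=1e-15)

    def test_triclinic_agrees_with_gemmi(self):
        gemmi = pytest.importorskip("gemmi")
        cell = UnitCell(8.1, 9.2, 11.3, 83.0, 99.5, 104.0)
        g = gemmi.UnitCell(8.1, 9.2, 11.3, 83.0, 99.5, 104.0)
        for hkl in [(1, 0, 0), (1, 2, 3), (-2, 1, 4)]:
            assert d_star(cell, hkl) == pytest.approx(1.0 / g.calculate_d(hkl), rel=1e-9)


class TestLaueOperators:
    def test_group_orders(self):
        orders = {name: len(laue_operators(name)) for name in LAUE_CLASSES}
        assert orders == {
            "-1": 1, "2/m": 2, "mmm": 4, "4/m": 4, "4/mmm": 8,
            "-3": 3, "-3m": 6, "6/m": 6, "6/mmm": 12, "m-3": 12, "m-3m": 24,
        }

    @pytest.mark.parametrize("name", LAUE_CLASSES)
    def test_closure_and_identity(self, name):
        ops = laue_operators(name)
        keys = {op.tobytes() for op in ops}
        assert np.eye(3, dtype=int).tobytes() in keys
        for a in ops:
            for b in ops:
                assert (a @ b).astype(int).tobytes() in keys

    def test_orbits_match_gemmi(self):
        """Orbit partition agrees with gemmi space-group operators."""
        gemmi = pytest.importorskip("gemmi")
        for laue, sg in [("mmm", "P m m m"), ("2/m", "P 2/m"), ("4/mmm", "P 4/m m m")]:
            ops = SymmetrySetting(laue_class=laue, add_friedel=True).matrices()
            gops = gemmi.find_spacegroup_by_name(sg).operations()
            for hkl in [(1, 2, 3), (0, 1, 5), (2, 0, 0)]:
                mine = {tuple(int(x) for x in op @ np.array(hkl)) for op in ops}
                theirs = {
                    tuple(int(x) for x in np.array(op.rot).reshape(3, 3).T @ np.array(hkl) // op.DEN)
                    for op in gops
                }
                assert mine == theirs


class TestGrouping:
    def test_mirror_equivalence_mmm(self):
        ms = [Measurement((1, 2, 3), 10, 1), Measurement((-1, 2, 3), 12, 1)]
        groups = group_equivalents(ms, SymmetrySetting(laue_class="mmm"))
        assert len(groups) == 1 and groups[0].n == 2

    def test_friedel_switch(self):
        ms = [Measurement((1, 2, 3), 10, 1), Measurement((-1, -2, -3), 12, 1)]
        no_friedel = group_equivalents(ms, SymmetrySetting("-1", add_friedel=False))
        with_friedel = group_equivalents(ms, SymmetrySetting("-1", add_friedel=True))
        assert len(no_friedel) == 2
        assert len(with_friedel) == 1

    def test_full_orbit_mmm(self):
        ms = [
            Measurement((sh * 1, sk * 2, sl * 3), 5, 1)
            for sh in (1, -1) for sk in (1, -1) for sl in (1, -1)
        ]
        groups = group_equivalents(ms, SymmetrySetting(laue_class="mmm"))
        assert len(groups) == 1
        assert groups[0].n == 8
        assert groups[0].canonical_hkl == (1, 2, 3)

    def test_group_statistics(self):
        ms = [Measurement((1, 2, 3), i, 1.0) for i in (2.0, 4.0, 9.0)]
        (g,) = group_equivalents(ms, SymmetrySetting(laue_class="-1"))
        assert g.mean_intensity == pytest.approx(5.0)
        assert g.max_intensity == pytest.approx(9.0)
        assert g.sample_std == pytest.approx(np.std([2, 4, 9], ddof=1))

    @given(st.lists(st.tuples(st.integers(-4, 4), st.integers(-4, 4), st.integers(-4, 4))
                    .filter(lambda t: t != (0, 0, 0)), min_size=1, max_size=25))
    def test_conservation_and_permutation_invariance(self, hkls):
        sym = SymmetrySetting(laue_class="mmm")
        ms = [Measurement(h, float(i), 1.0) for i, h in enumerate(hkls)]
        groups = group_equivalents(ms, sym)
        assert sum(g.n for g in groups) == len(ms)
        rev = group_equivalents(ms[::-1], sym)
        assert [g.canonical_hkl for g in groups] == [g.canonical_hkl for g in rev]
        assert [sorted(m.intensity for m in g.members) for g in groups] == [
            sorted(m.intensity for m in g.members) for g in rev
        ]

    def test_regrouping_is_idempotent(self):
        sym = SymmetrySetting(laue_class="4/m")
        ms = [Measurement(h, 1.0, 1.0) for h in [(1, 2, 3), (-2, 1, 3), (1, -2, 3), (3, 1, 0)]]
        once = group_equivalents(ms, sym)
        flat = [m for g in once for m in g.members]
        twice = group_equivalents(flat, sym)
        assert [g.canonical_hkl for g in once] == [g.canonical_hkl for g in twice]
        assert [g.n for g in once] == [g.n for g in twice]

    def test_canonical_is_orbit_maximum(self):
        ops = SymmetrySetting(laue_class="m-3m").matrices()
        assert canonical_index((-3, 1, -2), ops) == (3, 2, 1)


class TestHklIO:
    def test_fixed_width_parse(self, tmp_path):
        p = tmp_path / "a.hkl"
        p.write_text("   1   2   3  100.00    5.00\n")
        (m,) = read_hkl(p, "shelx_fixed")
        assert m.hkl == (1, 2, 3)
        assert m.intensity == pytest.approx(100.0)
        assert m.sigma == pytest.approx(5.0)

    def test_free_parse_with_trailing_columns(self, tmp_path):
        p = tmp_path / "a.hkl"
        p.write_text("-1 -5 -9 250.5 12.1 extra 7\n")
        (m,) = read_hkl(p, "free")
        assert m.hkl == (-1, -5, -9)
        assert (m.intensity, m.sigma) == (pytest.approx(250.5), pytest.approx(12.1))

    def test_nonpositive_sigma_rejected_with_report(self, tmp_path, caplog):
        p = tmp_path / "a.hkl"
        p.write_text("1 2 3 10.0 0.0\n1 2 4 10.0 2.0\n")
        with caplog.at_level("WARNING"):
            ms = read_hkl(p, "free")
        assert len(ms) == 1
        assert "rejected 1" in caplog.text

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "a.hkl"
        p.write_text("1 2 3 10.0 1.0\n1 2 oops 1 1\n")
        with pytest.raises(ValueError, match="line 2"):
            read_hkl(p, "free")

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "a.hkl"
        p.write_text("")
        with pytest.raises(ValueError):
            read_hkl(p, "free")

    def test_zero_index_terminates(self, tmp_path):
        p = tmp_path / "a.hkl"
        p.write_text("1 2 3 10.0 1.0\n0 0 0 0.0 0.0\n4 5 6 9.0 1.0\n")
        assert len(read_hkl(p, "free")) == 1

    @pytest.mark.parametrize("dialect", ["shelx_fixed", "free"])
    def test_round_trip(self, tmp_path, dialect):
        ms = [
            Measurement((1, 2, 3), 100.0, 5.0),
            Measurement((-9, 0, 12), -3.25, 0.75),
        ]
        p = tmp_path / "rt.hkl"
        write_hkl(ms, p, dialect)
        back = read_hkl(p, dialect)
        for orig, rt in zip(ms, back):
            assert rt.hkl == orig.hkl
            assert rt.intensity == pytest.approx(orig.intensity, abs=0.01)
            assert rt.sigma == pytest.approx(orig.sigma, abs=0.01)

    def test_empty_write_errors(self, tmp_path):
        with pytest.raises(ValueError):
            write_hkl([], tmp_path / "x.hkl", "free")

    def test_merged_record_keeps_multiplicity_column(self, tmp_path):
        from edsigma import MergedReflection

        rec = MergedReflection((1, 2, 3), 10.0, 1.0, n=4, observed=True)
        p = tmp_path / "m.hkl"
        write_hkl([rec], p, "free")
        assert p.read_text().split() == ["1", "2", "3", "10", "1", "4"]
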