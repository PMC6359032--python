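import numpy as np
import pytest

from reactikit import units
from reactikit.core_io import (AtomRecord, ContractError, FormatError,
                               GridField, MediumError, MoleculeGeometry,
                               SchemaError, UnitError, read_cube,
                               read_summary_tables, read_xyz, resolve_medium,
                               write_cube, write_xyz)
from reactikit.synthetic import toy_geometry


def test_unit_converters_are_mutually_consistent():
    # 1 hartree = 27.2114 eV = 627.509 kcal/mol = 2625.50 kJ/mol
    assert units.hartree_to_ev(1.0) == pytest.approx(27.2114)
    assert units.hartree_to_kcal(1.0) == pytest.approx(627.509)
    assert units.hartree_to_kj(1.0) == pytest.approx(2625.50)
    assert units.angstrom_to_bohr(0.529177) == pytest.approx(1.0, rel=1e-12)
    for there, back in [(units.hartree_to_ev, units.ev_to_hartree),
                        (units.hartree_to_kcal, units.kcal_to_hartree),
                        (units.hartree_to_kj, units.kj_to_hartree),
                        (units.angstrom_to_bohr, units.bohr_to_angstrom),
                        (units.kcal_to_kj, units.kj_to_kcal)]:
        for x in (1e-6, 1.0, 13.37, 1e6):
            assert back(there(x)) == pytest.approx(x, rel=1e-12)


class TestXYZ:
    def test_minimal_file(self, tmp_path):
        p = tmp_path / "o.xyz"
        p.write_text("1\n\nO 0.0 0.0 0.0\n")
        g = read_xyz(p)
        assert len(g) == 1
        assert g.atoms[0].element == "O"
        assert np.allclose(g.atoms[0].position, 0.0)

    def test_round_trip_identity(self, tmp_path):
        g = toy_geometry("hbonded_dimer", seed=3)
        p = tmp_path / "dimer.xyz"
        write_xyz(g, p)
        g2 = read_xyz(p)
        assert g2.elements() == g.elements()
        assert np.abs(g2.positions_angstrom() - g.positions_angstrom()).max() < 1e-6
        assert [a.index for a in g2.atoms] == [a.index for a in g.atoms]

    def test_declared_count_mismatch(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("3\n\nO 0 0 0\nH 1 0 0\n")
        with pytest.raises(FormatError):
            read_xyz(p)

    def test_unparseable_coordinate_reports_line(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("1\n\nO 0.0 zero 0.0\n")
        with pytest.raises(FormatError, match="line 3"):
            read_xyz(p)


class TestCube:
    def test_constant_field_round_trip(self, tmp_path):
        field = GridField(np.zeros(3), [0.5, 0.5, 0.5], (2, 2, 2),
                          np.ones(8), "rho")
        geom = toy_geometry("intramolecular_chain", seed=0)
        p = tmp_path / "c.cube"
        write_cube(field, geom, p)
        f2, g2 = read_cube(p)
        assert f2.values.size == 8
        assert np.allclose(f2.values, 1.0)
        assert g2.elements() == geom.elements()
        assert np.abs(g2.positions_angstrom()
                      - geom.positions_angstrom()).max() < 1e-5

    def test_field_round_trip_tolerance(self, tmp_path, toy_h_model,
                                        h2_pair_2bohr):
        from reactikit.igm import molecular_grid, promolecular_field, rdg_field

        spec = molecular_grid(h2_pair_2bohr, spacing=0.5, padding=2.0)
        ft = promolecular_field(h2_pair_2bohr, toy_h_model, spec.points())
        s = np.nan_to_num(rdg_field(ft.rho, ft.grad))
        field = spec.field(s, "rdg")
        p = tmp_path / "rdg.cube"
        write_cube(field, h2_pair_2bohr, p)
        f2, _ = read_cube(p)
        scale = np.maximum(np.abs(field.values), 1.0)
        assert (np.abs(f2.values - field.values) / scale).max() < 1e-5

    def test_empty_geometry_nonempty_field(self, tmp_path):
        field = GridField(np.zeros(3), [1, 1, 1], (2, 1, 1), [1.0, 2.0], "rho")
        geom = MoleculeGeometry("empty", [])
        p = tmp_path / "e.cube"
        write_cube(field, geom, p)
        assert p.read_text().splitlines()[2].split()[0] == "0"
        f2, g2 = read_cube(p)
        assert len(g2) == 0
        assert np.allclose(f2.values.ravel(), [1.0, 2.0])

    def test_dims_values_mismatch(self):
        with pytest.raises(ContractError):
            GridField(np.zeros(3), [1, 1, 1], (2, 2, 2), np.ones(7), "rho")


SUMMARY = """\
# units.orbitals = eV
# units.enthalpies = kcal/mol
# medium.brine.dielectric = 70.0
# medium.brine.h_hydrogen_atom = -314.55
# medium.brine.h_electron = -25.27
# medium.brine.h_proton = -252.66

[orbitals]
molecule,medium,E_HOMO,E_LUMO
Neu5Gc,Gas,-8.900,0.753
Neu5Gc,Water,-8.731,0.988

[enthalpies]
molecule,medium,site,H_ROH,H_cation,H_radical,H_anion
mol,brine,O7-H,-1000.0,-850.0,-590.0,-680.0
"""


class TestSummaryTables:
    def test_typed_records(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text(SUMMARY)
        t = read_summary_tables(p)
        assert len(t.orbitals) == 2
        assert t.orbitals[0].E_LUMO == pytest.approx(0.753)
        assert t.orbitals[1].medium == "water"
        assert len(t.enthalpies) == 1
        assert t.media["brine"].has_references

    def test_empty_file_header_only(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("# units.orbitals = eV\n[orbitals]\n"
                     "molecule,medium,E_HOMO,E_LUMO\n")
        t = read_summary_tables(p)
        assert t.orbitals == [] and t.enthalpies == []

    def test_missing_column_names_it(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("# units.orbitals = eV\n[orbitals]\n"
                     "molecule,medium,E_HOMO\nNeu5Gc,Gas,-8.9\n")
        with pytest.raises(SchemaError, match="E_LUMO"):
            read_summary_tables(p)

    def test_missing_unit_declaration(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("[orbitals]\nmolecule,medium,E_HOMO,E_LUMO\n"
                     "Neu5Gc,Gas,-8.9,0.75\n")
        with pytest.raises(UnitError):
            read_summary_tables(p)

    def test_enthalpies_need_reference_enthalpies(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("# units.enthalpies = kcal/mol\n[enthalpies]\n"
                     "molecule,medium,site,H_ROH,H_cation,H_radical,H_anion\n"
                     "mol,water,O7-H,-1000,-850,-590,-680\n")
        # water is a known medium but ships without reference enthalpies
        with pytest.raises(MediumError):
            read_summary_tables(p)

    def test_unknown_medium_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("# units.orbitals = eV\n[orbitals]\n"
                     "molecule,medium,E_HOMO,E_LUMO\nm,plasma,-8.9,0.75\n")
        with pytest.raises(MediumError):
            read_summary_tables(p)


def test_medium_names_match_case_insensitively():
    assert resolve_medium("  Gas Phase ").name == "gas"
    assert resolve_medium("WATER").dielectric == pytest.approx(78.35)
    assert resolve_medium("gas").cycle_constant == pytest.approx(314.53)


def test_fragments_must_not_overlap():
    atoms = [AtomRecord("H", np.array([float(i), 0, 0]), i + 1)
             for i in range(3)]
    with pytest.raises(ContractError, match="overlap"):
        MoleculeGeometry("m", atoms, {"a": (1, 2), "b": (2, 3)})
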