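"""Unit cell algebra, CIF/symmetry parsing, environment expansion, molecules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crystalcontacts import (
    AtomSite,
    CifParseError,
    CrystalStructure,
    GeometryError,
    UnitCell,
    cart_to_frac,
    detect_molecules,
    expand_environment,
    frac_to_cart,
    parse_cif,
    parse_symop,
    read_xyz,
    write_cif,
    write_xyz,
)
from crystalcontacts.crystal_io import bond_matrix, distance

MINIMAL_P1 = """
data_min
_cell_length_a 10.0
_cell_length_b 10.0
_cell_length_c 10.0
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
  C1 C 0.1 0.2 0.3
"""

STRUCTURE1_CELL = UnitCell(4.286, 12.704, 14.187, 90.0, 93.458, 90.0)


class TestUnitCell:
    def test_bromooxindole_cell_volume(self):
        # monoclinic cell of the 6-bromooxindole structure
        assert STRUCTURE1_CELL.volume == pytest.approx(771.2, abs=0.5)

    def test_volume_matches_triclinic_closed_form(self, rng):
        for _ in range(50):
            a, b, c = rng.uniform(3, 20, 3)
            al, be, ga = rng.uniform(60, 120, 3)
            cell = UnitCell(a, b, c, al, be, ga)
            det = np.linalg.det(cell.orthogonalization_matrix)
            assert abs(det) == pytest.approx(cell.volume, rel=1e-4)

    @pytest.mark.parametrize("kwargs", [
        dict(a=-1, b=1, c=1), dict(a=1, b=1, c=1, alpha=0),
        dict(a=1, b=1, c=1, alpha=185),
    ])
    def test_invalid_cells_rejected(self, kwargs):
        with pytest.raises(GeometryError):
            UnitCell(**kwargs)


class TestCoordinates:
    def test_orthogonal_cell_is_simple_scaling(self):
        cell = UnitCell(10, 10, 10)
        assert frac_to_cart(cell, [0.5, 0.5, 0.5]) == pytest.approx([5, 5, 5])

    def test_a_axis_length_of_structure_1(self):
        vec = frac_to_cart(STRUCTURE1_CELL, [1, 0, 0])
        assert np.linalg.norm(vec) == pytest.approx(4.286, abs=1e-9)

    def test_distance_agrees_with_metric_tensor_oracle(self, rng):
        # oracle: d^2 = dx^T (A^T A) dx evaluated directly on fractional vectors
        for _ in range(1000):
            cell = UnitCell(*rng.uniform(3, 20, 3), 90.0, rng.uniform(60, 120), 90.0)
            fi, fj = rng.uniform(-1, 2, (2, 3))
            g = cell.metric_tensor()
            d_oracle = float(np.sqrt((fj - fi) @ g @ (fj - fi)))
            assert distance(cell, fi, fj) == pytest.approx(d_oracle, abs=1e-8)

    def test_frac_cart_round_trip(self, rng):
        for _ in range(100):
            cell = UnitCell(*rng.uniform(3, 20, 3), *rng.uniform(60, 120, 3))
            frac = rng.uniform(-1, 2, 3)
            back = cart_to_frac(cell, frac_to_cart(cell, frac))
            assert np.allclose(back, frac, atol=1e-10)


class TestSymOp:
    def test_identity(self):
        op = parse_symop("x,y,z")
        assert np.array_equal(op.rot, np.eye(3))
        assert np.allclose(op.tran, 0)

    @pytest.mark.parametrize("code,point,expected", [
        ("2 − x, −y, 1 − z", (0.1, 0.2, 0.3), (1.9, -0.2, 0.7)),
        ("1 − x, 0.5 + y, 1.5 − z", (0, 0, 0), (1.0, 0.5, 1.5)),
    ])
    def test_crystallographic_codes(self, code, point, expected):
        assert parse_symop(code).apply(point) == pytest.approx(expected)

    @given(st.sampled_from(["x,y,z", "-x,-y,-z", "-x,1/2+y,1/2-z",
                            "x,1/2-y,1/2+z", "2-x,-y,1-z"]),
           st.tuples(*[st.floats(-2, 2, allow_nan=False) for _ in range(3)]))
    @settings(deadline=None)
    def test_op_then_inverse_is_identity(self, code, point):
        op = parse_symop(code)
        assert round(abs(np.linalg.det(op.rot))) == 1
        back = op.inverse().apply(op.apply(point))
        assert np.allclose(back, point, atol=1e-9)

    def test_malformed_code_names_token(self):
        with pytest.raises(CifParseError, match="2q-x"):
            parse_symop("2q-x, -y, z")


class TestParseCif:
    def test_minimal_p1(self):
        s = parse_cif(MINIMAL_P1)
        assert len(s.symops) == 1 and len(s.sites) == 1
        assert s.sites[0].element == "C"

    def test_uncertainty_suffix_stripped(self):
        text = MINIMAL_P1.replace("_cell_length_a 10.0", "_cell_length_a 4.286(2)")
        assert parse_cif(text).cell.a == pytest.approx(4.286)

    def test_spacegroup_name_resolved_via_symmetry_tables(self):
        text = MINIMAL_P1.replace(
            "loop_", "_space_group_name_H-M_alt 'P 21/c'\nloop_", 1)
        assert len(parse_cif(text).symops) == 4

    def test_missing_cell_block(self):
        bad = "\n".join(l for l in MINIMAL_P1.splitlines() if "_cell_length_a" not in l)
        with pytest.raises(CifParseError, match="_cell_length_a"):
            parse_cif(bad)

    def test_missing_atom_loop(self):
        bad = MINIMAL_P1.split("loop_")[0]
        with pytest.raises(CifParseError, match="atom_site"):
            parse_cif(bad)

    def test_unknown_element_names_label(self):
        bad = MINIMAL_P1.replace("C1 C", "Xx1 Xx")
        with pytest.raises(CifParseError, match="Xx1"):
            parse_cif(bad)

    def test_cif_writer_round_trips(self, nho_crystal):
        cif_text, _ = nho_crystal
        s = parse_cif(cif_text)
        assert parse_cif(write_cif(s)).sites[0].label == s.sites[0].label


class TestXyz:
    def test_round_trip(self, rng):
        els = ["C", "N", "O", "H"]
        coords = rng.uniform(-5, 5, (4, 3))
        els2, coords2, comment = read_xyz(write_xyz(els, coords, "probe"))
        assert els2 == els and comment == "probe"
        assert np.allclose(coords2, coords, atol=1e-5)

    def test_truncated_document_rejected(self):
        with pytest.raises(CifParseError):
            read_xyz("3\ncomment\nC 0 0 0\n")


def _p1_structure(cell, atoms):
    return CrystalStructure(cell=cell, symops=[parse_symop("x,y,z")],
                            sites=[AtomSite(f"{el}{i}", el, np.array(f))
                                   for i, (el, f) in enumerate(atoms, 1)])


class TestExpandEnvironment:
    def test_single_atom_small_radius(self):
        s = _p1_structure(UnitCell(10, 10, 10), [("C", (0.5, 0.5, 0.5))])
        images = expand_environment(s, radius=4.0)
        assert len(images) == 1 and images[0].is_original

    def test_inversion_pair_reported_with_symcode(self):
        cell = UnitCell(12, 12, 12)
        s = CrystalStructure(cell=cell,
                             symops=[parse_symop("x,y,z"), parse_symop("-x,-y,-z")],
                             sites=[AtomSite("Br1", "Br", np.array([0.125, 0, 0]))])
        images = expand_environment(s, radius=5.0)
        codes = {img.symcode(s) for img in images}
        assert "-x,-y,-z" in codes
        d = np.linalg.norm(images[0].cart - [im for im in images if not im.is_original][0].cart)
        assert d == pytest.approx(3.0, abs=1e-9)

    def test_matches_brute_force_enumeration(self, nho_crystal):
        cif_text, _ = nho_crystal
        s = parse_cif(cif_text)
        radius = 6.0
        images = expand_environment(s, radius)
        got = {(im.site_index, tuple(np.round(im.frac, 5))) for im in images}
        # oracle: exhaustive enumeration over every op and +-2 lattice shifts
        m = s.cell.orthogonalization_matrix
        asym = np.array([site.frac for site in s.sites]) @ m.T
        expected = set()
        for op in s.symops:
            for i, site in enumerate(s.sites):
                for sa in range(-2, 3):
                    for sb in range(-2, 3):
                        for sc in range(-2, 3):
                            frac = op.apply(site.frac) + np.array([sa, sb, sc])
                            cart = m @ frac
                            if np.min(np.linalg.norm(asym - cart, axis=1)) <= radius:
                                expected.add((i, tuple(np.round(frac, 5))))
        assert got == expected

    def test_symmetry_closure(self, nho_crystal):
        # applying any symop maps the expanded set into itself modulo shifts
        cif_text, _ = nho_crystal
        s = parse_cif(cif_text)
        images = expand_environment(s, 6.0)
        by_site = {}
        for im in images:
            by_site.setdefault(im.site_index, []).append(np.mod(np.round(im.frac, 6), 1.0))
        for op in s.symops:
            for im in images:
                mapped = np.mod(np.round(op.apply(im.frac), 6), 1.0)
                pool = by_site[im.site_index]
                assert any(np.allclose(mapped, f, atol=1e-5) for f in pool)

    def test_radius_guards(self):
        s = _p1_structure(UnitCell(10, 10, 10), [("C", (0, 0, 0))])
        with pytest.raises(GeometryError):
            expand_environment(s, radius=20.0)
        with pytest.raises(GeometryError):
            expand_environment(s, radius=-1.0)


# hand-built 17-atom oxindole-like skeleton: fused 5- and 6-ring + exocyclic
# O and Br + three hydrogens, coordinates chosen so the oracle bond list below
# is exactly the set of pairs within covalent reach
_OXINDOLE_LIKE = {
    "atoms": [
        ("N", (0.00, 0.00, 0.0)), ("C", (1.35, 0.00, 0.0)), ("C", (2.10, 1.20, 0.0)),
        ("C", (1.30, 2.35, 0.0)), ("C", (-0.05, 2.05, 0.0)), ("C", (-0.75, 0.95, 0.0)),
        ("C", (1.95, 3.60, 0.0)), ("C", (1.20, 4.75, 0.0)), ("C", (-0.15, 4.70, 0.0)),
        ("C", (-0.85, 3.40, 0.0)), ("O", (1.95, -1.05, 0.0)), ("Br", (3.95, 1.25, 0.0)),
        ("H", (-0.55, -0.80, 0.0)), ("H", (3.00, 3.65, 0.0)), ("H", (1.75, 5.68, 0.0)),
        ("H", (-0.70, 5.60, 0.0)), ("H", (-1.93, 3.35, 0.0)),
    ],
    "bonds": {(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 5), (3, 6), (6, 7),
              (7, 8), (8, 9), (4, 9), (1, 10), (2, 11), (0, 12), (6, 13),
              (7, 14), (8, 15), (9, 16)},
}


class TestDetectMolecules:
    def test_far_atoms_are_separate_molecules(self):
        s = _p1_structure(UnitCell(30, 30, 30),
                          [("C", (0.1, 0.1, 0.1)), ("C", (0.1 + 1 / 3, 0.1, 0.1))])
        assert detect_molecules(s) == [0, 1]

    def test_oxindole_like_fragment_is_one_molecule(self):
        cell = UnitCell(25, 25, 25)
        atoms = [(el, tuple(np.array(x) / 25.0)) for el, x in _OXINDOLE_LIKE["atoms"]]
        s = _p1_structure(cell, atoms)
        adj = bond_matrix(cell, s.sites)
        got_bonds = {(i, j) for i, j in zip(*np.nonzero(adj)) if i < j}
        assert got_bonds == _OXINDOLE_LIKE["bonds"]
        assert set(detect_molecules(s)) == {0}

    def test_two_unique_molecules_in_asymmetric_unit(self, rng):
        # mimics an asymmetric unit holding two complete independent molecules
        from crystalcontacts.synthetic import _amide_dimer_sites
        cell = UnitCell(24, 24, 24)
        _, carts = _amide_dimer_sites(1.92)
        atoms = [(el, tuple((np.array(c) + off) / 24.0))
                 for off, tag in (((4, 4, 4), "a"), ((14, 14, 14), "b"))
                 for el, c in zip("NHCO", carts)]
        s = _p1_structure(cell, atoms)
        ids = detect_molecules(s)
        assert ids == [0, 0, 0, 0, 1, 1, 1, 1]
        assert [site.molecule_id for site in s.sites] == ids
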