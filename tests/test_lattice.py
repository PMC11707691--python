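"""Cells, scattering vectors, Niggli reduction, cell comparison, counting."""

import math

import numpy as np
import pytest

gemmi = pytest.importorskip("gemmi")

from serialindex.lattice import (
    UnitCell,
    cell_from_parameters,
    check_cell,
    count_unique_reflections,
    g6_vector,
    niggli_reduce,
    read_cell,
    scattering_vector,
    write_cell,
)


def random_cell(rng):
    while True:
        p = [rng.uniform(5, 100) for _ in range(3)] + [rng.uniform(60, 120) for _ in range(3)]
        try:
            return cell_from_parameters(*p), p
        except ValueError:
            continue


def random_unimodular(rng):
    while True:
        T = rng.integers(-2, 3, size=(3, 3))
        if abs(round(np.linalg.det(T))) == 1:
            return T


def trig_scattering_vector(params, h, k, l):
    """Independent oracle: reciprocal basis from the trigonometric formulas."""
    a, b, c, al, be, ga = params
    al, be, ga = map(math.radians, (al, be, ga))
    ca, cb, cg = math.cos(al), math.cos(be), math.cos(ga)
    sg = math.sin(ga)
    V = a * b * c * math.sqrt(1 - ca**2 - cb**2 - cg**2 + 2 * ca * cb * cg)
    # direct basis in the canonical orientation
    av = np.array([a, 0, 0])
    bv = np.array([b * cg, b * sg, 0])
    cv = np.array([c * cb, c * (ca - cb * cg) / sg, V / (a * b * sg)])
    astar = np.cross(bv, cv) / V
    bstar = np.cross(cv, av) / V
    cstar = np.cross(av, bv) / V
    return h * astar + k * bstar + l * cstar


class TestUnitCell:
    def test_orthogonal_volume_closed_form(self, lysozyme_cell):
        assert lysozyme_cell.volume == pytest.approx(79.2 * 79.2 * 38.0, rel=1e-12)

    def test_cubic_identity_basis(self):
        c = cell_from_parameters(1, 1, 1, 90, 90, 90)
        assert np.allclose(c.basis, np.eye(3), atol=1e-12)
        assert c.volume == pytest.approx(1.0)

    def test_parameter_round_trip(self, rng):
        for _ in range(20):
            _, p = random_cell(rng)
            cell = cell_from_parameters(*p)
            assert np.allclose(cell.parameters, p, rtol=1e-9, atol=1e-9)

    def test_reciprocal_matrix_inverts_basis(self, rng):
        cell, _ = random_cell(rng)
        assert np.allclose(cell.reciprocal_matrix.T @ cell.basis, np.eye(3), atol=1e-10)

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValueError):
            cell_from_parameters(10, 10, 10, 60, 60, 170)
        with pytest.raises(ValueError):
            cell_from_parameters(-1, 10, 10, 90, 90, 90)

    def test_left_handed_basis_rejected(self):
        with pytest.raises(ValueError):
            UnitCell(np.diag([1.0, 1.0, -1.0]))


class TestScatteringVector:
    def test_zero_index(self, lysozyme_cell):
        assert np.allclose(scattering_vector(lysozyme_cell, 0, 0, 0), 0.0)

    def test_cubic_closed_form(self):
        c = cell_from_parameters(10, 10, 10, 90, 90, 90)
        assert np.linalg.norm(scattering_vector(c, 1, 0, 0)) == pytest.approx(0.1)

    def test_matches_trigonometric_oracle(self, rng):
        worst = 0.0
        for _ in range(100):
            cell, p = random_cell(rng)
            h, k, l = rng.integers(-8, 9, size=3)
            got = scattering_vector(cell, h, k, l)
            exp = trig_scattering_vector(p, h, k, l)
            worst = max(worst, float(np.abs(got - exp).max()))
        assert worst < 1e-10


class TestNiggliReduction:
    def test_idempotent_on_cubic(self):
        c = cell_from_parameters(10, 10, 10, 90, 90, 90)
        r = niggli_reduce(c)
        assert np.allclose(r.parameters, c.parameters, atol=1e-9)
        r2 = niggli_reduce(r)
        assert np.allclose(r2.parameters, r.parameters, atol=1e-9)

    def test_shear_invariance(self, lysozyme_cell):
        T = np.array([[1, 1, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        sheared = UnitCell(lysozyme_cell.basis @ T)
        assert np.allclose(
            niggli_reduce(sheared).parameters, niggli_reduce(lysozyme_cell).parameters, atol=1e-6
        )

    def test_c_centring_halves_volume(self):
        # primitive setting of a C-centred orthorhombic cell via the
        # standard centring transform (a+b)/2, (a-b)/2, c
        cell = cell_from_parameters(7.0, 11.0, 5.0, 90, 90, 90)
        P = np.array([[0.5, 0.5, 0], [0.5, -0.5, 0], [0, 0, 1]]).T
        prim = cell.basis @ P
        if np.linalg.det(prim) < 0:
            prim = prim[:, [1, 0, 2]]
        red = niggli_reduce(UnitCell(prim))
        assert red.volume == pytest.approx(cell.volume / 2, rel=1e-9)

    def test_unimodular_invariance_matches_gemmi(self, rng):
        """Reduced parameters are a lattice invariant; gemmi is the oracle."""
        for _ in range(60):
            cell, p = random_cell(rng)
            T = random_unimodular(rng)
            B2 = cell.basis @ T
            if np.linalg.det(B2) < 0:
                B2 = B2[:, [1, 0, 2]]
            mine = niggli_reduce(UnitCell(B2)).parameters
            gv = gemmi.GruberVector(gemmi.UnitCell(*p), None)
            gv.niggli_reduce()
            ref = gv.cell_parameters()
            assert np.allclose(sorted(mine[:3]), sorted(ref[:3]), rtol=1e-4)
            assert np.allclose(sorted(mine[3:]), sorted(ref[3:]), atol=0.05)

    def test_degenerate_basis_rejected(self):
        with pytest.raises(ValueError):
            niggli_reduce(UnitCell(np.diag([1.0, 1.0, 1e-18])))


class TestCheckCell:
    def test_identical_cells_match(self, lysozyme_cell):
        m = check_cell(lysozyme_cell, lysozyme_cell)
        assert m.matched and m.length_reldev == 0.0 and m.angle_dev == 0.0

    def test_doubled_axis_rejected(self, lysozyme_cell):
        other = cell_from_parameters(79.2, 79.2, 76.0, 90, 90, 90)
        assert not check_cell(other, lysozyme_cell).matched

    def test_unimodular_representation_matches(self, lysozyme_cell, rng):
        for _ in range(20):
            T = random_unimodular(rng)
            B2 = lysozyme_cell.basis @ T
            if np.linalg.det(B2) < 0:
                B2 = B2[:, [1, 0, 2]]
            assert check_cell(UnitCell(B2), lysozyme_cell).matched

    def test_symmetric(self, lysozyme_cell):
        other = cell_from_parameters(79.5, 79.0, 38.2, 90, 90, 90)
        m1 = check_cell(other, lysozyme_cell)
        m2 = check_cell(lysozyme_cell, other)
        assert m1.matched == m2.matched
        assert m1.length_reldev == pytest.approx(m2.length_reldev)

    def test_g6_diagnostics(self, lysozyme_cell):
        m = check_cell(lysozyme_cell, lysozyme_cell)
        assert np.allclose(m.g6_candidate, m.g6_reference)
        assert np.allclose(sorted(m.g6_candidate[:3]), [38.0**2, 79.2**2, 79.2**2])

    def test_g6_vector_definition(self):
        c = cell_from_parameters(3, 4, 5, 90, 90, 60)
        g6 = g6_vector(c)
        assert g6[:3] == pytest.approx([9, 16, 25])
        assert g6[5] == pytest.approx(2 * 3 * 4 * 0.5)  # 2ab cos(gamma)


class TestUniqueReflections:
    def test_cubic_hand_enumeration(self):
        # a=10, Laue -1, 100-5 A: h^2+k^2+l^2 <= 4, origin excluded,
        # Friedel merged: 32 lattice points -> 16 classes
        c = cell_from_parameters(10, 10, 10, 90, 90, 90)
        assert count_unique_reflections(c, "-1", 100.0, 5.0) == 16

    def test_empty_window(self):
        c = cell_from_parameters(10, 10, 10, 90, 90, 90)
        assert count_unique_reflections(c, "-1", 4.9, 4.5) == 0

    def test_monotone_in_resolution(self, lysozyme_cell):
        counts = [
            count_unique_reflections(lysozyme_cell, "4/mmm", None, d)
            for d in (6.0, 4.0, 3.0, 2.5)
        ]
        assert counts == sorted(counts)

    def test_triclinic_count_bounds_tetragonal(self, lysozyme_cell):
        lo = count_unique_reflections(lysozyme_cell, "4/mmm", None, 5.0)
        hi = count_unique_reflections(lysozyme_cell, "-1", None, 5.0)
        assert hi >= lo

    def test_matches_gemmi_asu_count(self, lysozyme_cell):
        """Class count cross-checked against gemmi's reciprocal ASU mapping.

        P43212 has Laue class 4/mmm, so mapping every in-range index to
        gemmi's ASU representative and counting distinct representatives is
        an independent oracle (absences included, Friedel merged).
        """
        d_min = 3.0
        mine = count_unique_reflections(lysozyme_cell, "4/mmm", None, d_min)
        sg = gemmi.SpaceGroup("P 43 21 2")
        cell = gemmi.UnitCell(79.2, 79.2, 38.0, 90, 90, 90)
        gops = sg.operations()
        asu = gemmi.ReciprocalAsu(sg)
        seen = set()
        for h in range(-27, 28):
            for k in range(-27, 28):
                for l in range(-13, 14):
                    if (h, k, l) == (0, 0, 0):
                        continue
                    if cell.calculate_d((h, k, l)) < d_min * (1 - 1e-9):
                        continue
                    rep, _ = asu.to_asu((h, k, l), gops)
                    seen.add(tuple(rep))
        assert mine == len(seen)

    def test_unsupported_group_rejected(self, lysozyme_cell):
        with pytest.raises(ValueError):
            count_unique_reflections(lysozyme_cell, "m-3m", None, 2.0)


class TestCellFile:
    def test_round_trip(self, tmp_path, lysozyme_cell):
        p = tmp_path / "cell.txt"
        write_cell(p, lysozyme_cell)
        cell2 = read_cell(p)
        assert np.allclose(cell2.parameters, lysozyme_cell.parameters, atol=1e-9)

    def test_cryst1_line(self, tmp_path):
        p = tmp_path / "cryst.txt"
        p.write_text("CRYST1 79.200 79.200 38.000 90.00 90.00 90.00 P 43 21 2\n")
        cell = read_cell(p)
        assert np.allclose(cell.parameters, (79.2, 79.2, 38.0, 90, 90, 90))
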