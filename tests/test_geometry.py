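"""Internal-coordinate math: measurement, placement, torsion round trips."""

import math

import numpy as np
import pytest

from idealize.errors import ChainBreakError, DegenerateGeometryError, IdealizeError
from idealize.fixtures import make_ideal_peptide, uniform_torsions
from idealize.geometry import (
    IdealGeometryTable,
    TorsionSet,
    bond_angle,
    bond_length,
    build_from_torsions,
    dihedral,
    extract_torsions,
    place_cb,
    place_next_atom,
    rebuild_dependent_atoms,
    wrap_deg,
)
from idealize.pdb_io import Structure


def law_of_cosines_angle(a, b, c):
    ab = np.linalg.norm(np.subtract(a, b))
    cb = np.linalg.norm(np.subtract(c, b))
    ac = np.linalg.norm(np.subtract(a, c))
    return math.degrees(math.acos((ab**2 + cb**2 - ac**2) / (2 * ab * cb)))


def praxeolitic_dihedral(p0, p1, p2, p3):
    """Independent dihedral formulation: project bond vectors onto the
    plane normal to the central bond and take the signed planar angle."""
    p0, p1, p2, p3 = map(np.asarray, (p0, p1, p2, p3))
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return -math.degrees(math.atan2(y, x))


@pytest.mark.parametrize("pts,expected", [
    (((0, 0, 0), (1, 0, 0)), 1.0),
    (((1, 2, 3), (1, 2, 5)), 2.0),
])
def test_bond_length_trivial(pts, expected):
    assert bond_length(*pts) == pytest.approx(expected)


def test_bond_angle_right_angle():
    assert bond_angle((1, 0, 0), (0, 0, 0), (0, 1, 0)) == pytest.approx(90.0)


def test_measurement_oracles_random():
    rng = np.random.default_rng(0)
    for _ in range(200):
        a, b, c, d = rng.normal(size=(4, 3))
        assert bond_angle(a, b, c) == pytest.approx(
            law_of_cosines_angle(a, b, c), abs=1e-9)
        assert wrap_deg(dihedral(a, b, c, d) - praxeolitic_dihedral(a, b, c, d)) \
            == pytest.approx(0.0, abs=1e-9)


def test_dihedral_planar_conventions():
    assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)) == pytest.approx(0.0)
    assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)) == pytest.approx(180.0)


def test_degenerate_inputs_raise():
    with pytest.raises(DegenerateGeometryError):
        bond_length((0, 0, 0), (0, 0, 0))
    with pytest.raises(DegenerateGeometryError):
        dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))
    with pytest.raises(DegenerateGeometryError):
        place_next_atom((0, 0, 0), (1, 0, 0), (2, 0, 0), 1.5, 109.0, 60.0)


def test_place_next_atom_planar_cases():
    d0 = place_next_atom((-1, 1, 0), (-1, 0, 0), (0, 0, 0), 1.0, 90.0, 0.0)
    assert np.allclose(d0, (0, 1, 0), atol=1e-12)
    d180 = place_next_atom((-1, 1, 0), (-1, 0, 0), (0, 0, 0), 1.0, 90.0, 180.0)
    assert np.allclose(d180, (0, -1, 0), atol=1e-12)


def test_place_measure_round_trip_and_equivariance():
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(1)
    for _ in range(100):
        a, b, c = rng.normal(size=(3, 3))
        L = rng.uniform(1.0, 1.8)
        ang = rng.uniform(60.0, 150.0)
        tau = rng.uniform(-179.9, 180.0)
        d = place_next_atom(a, b, c, L, ang, tau)
        assert bond_length(c, d) == pytest.approx(L, abs=1e-6)
        assert bond_angle(b, c, d) == pytest.approx(ang, abs=1e-6)
        assert wrap_deg(dihedral(a, b, c, d) - tau) == pytest.approx(0.0, abs=1e-6)
        # rigid-motion equivariance
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(size=3)
        d2 = place_next_atom(a @ rot.T + shift, b @ rot.T + shift,
                             c @ rot.T + shift, L, ang, tau)
        assert np.allclose(d2, d @ rot.T + shift, atol=1e-9)


def test_build_extract_helix_round_trip():
    ts = uniform_torsions(6, -57.0, -47.0)
    st = build_from_torsions(["ALA"] * 6, ts)
    out = extract_torsions(st)
    assert out.phi[0] is None and out.psi[-1] is None and out.omega[-1] is None
    assert np.allclose(out.phi[1:], -57.0, atol=1e-9)
    assert np.allclose(out.psi[:-1], -47.0, atol=1e-9)
    assert np.allclose(out.omega[:-1], 180.0, atol=1e-9)


def test_build_extract_random_round_trip():
    rng = np.random.default_rng(7)
    n = 5
    ts = TorsionSet(
        phi=[None] + list(rng.uniform(-179, 179, n - 1)),
        psi=list(rng.uniform(-179, 179, n - 1)) + [None],
        omega=list(rng.uniform(-179, 179, n - 1)) + [None],
    )
    seq = ["ALA", "GLY", "SER", "PRO", "LEU"]
    st = build_from_torsions(seq, ts)
    out = extract_torsions(st)
    for i in range(1, n):
        assert out.phi[i] == pytest.approx(ts.phi[i], abs=1e-6)
        assert out.psi[i - 1] == pytest.approx(ts.psi[i - 1], abs=1e-6)
        assert out.omega[i - 1] == pytest.approx(ts.omega[i - 1], abs=1e-6)
    # rebuilding from the same anchor reproduces coordinates
    anchor = st.backbone_coords()[:3]
    st2 = build_from_torsions(seq, out, anchor=anchor)
    assert np.abs(st2.backbone_coords() - st.backbone_coords()).max() < 1e-4


def test_every_built_bond_and_angle_is_ideal(ideal_table):
    """The defining property of an idealized structure."""
    st = make_ideal_peptide("AGPSA", (-70.0, 120.0))
    tab = ideal_table
    seq = st.sequence
    for i in range(1, 6):
        res = seq[i - 1]
        n, ca, c = (st.coord(i, x) for x in ("N", "CA", "C"))
        assert bond_length(n, ca) == pytest.approx(tab.bond("N-CA", res), abs=1e-6)
        assert bond_length(ca, c) == pytest.approx(tab.bond("CA-C", res), abs=1e-6)
        assert bond_angle(n, ca, c) == pytest.approx(tab.angle("N-CA-C", res), abs=1e-6)
        if i < 5:
            nn = st.coord(i + 1, "N")
            nres = seq[i]
            assert bond_length(c, nn) == pytest.approx(tab.bond("C-N", nres), abs=1e-6)
            assert bond_angle(ca, c, nn) == pytest.approx(
                tab.angle("CA-C-N", res), abs=1e-6)


def test_cis_peptide_geometry():
    ts = TorsionSet(phi=[None, -75.0], psi=[150.0, None], omega=[0.0, None])
    st = build_from_torsions(["ALA", "PRO"], ts)
    om = extract_torsions(st).omega[0]
    assert om == pytest.approx(0.0, abs=1e-9)
    # cis: consecutive CA atoms on the same side of the peptide bond
    ca1, ca2 = st.coord(1, "CA"), st.coord(2, "CA")
    c1, n2 = st.coord(1, "C"), st.coord(2, "N")
    axis = n2 - c1
    v1 = ca1 - c1 - np.dot(ca1 - c1, axis) / np.dot(axis, axis) * axis
    v2 = ca2 - n2 - np.dot(ca2 - n2, axis) / np.dot(axis, axis) * axis
    assert np.dot(v1, v2) > 0


def test_rebuild_dependent_atoms(ideal_table):
    st = make_ideal_peptide("AGPA")
    names = {(a.residue_index, a.name) for a in st.atoms}
    assert (2, "CB") not in names          # Gly has no CB
    assert (3, "H") not in names           # Pro has no amide H
    assert (1, "CB") in names and (3, "CB") in names
    i = 2  # check in-plane trans carbonyl for an interior residue
    o, c = st.coord(i, "O"), st.coord(i, "C")
    ca, nn = st.coord(i, "CA"), st.coord(i + 1, "N")
    assert bond_length(c, o) == pytest.approx(ideal_table.bond("C-O"), abs=1e-6)
    assert bond_angle(ca, c, o) == pytest.approx(
        ideal_table.angle("CA-C-O"), abs=1e-6)
    assert abs(dihedral(nn, ca, c, o)) == pytest.approx(180.0, abs=1e-6)


def test_rebuild_requires_gapless_chain(helix8):
    broken = Structure([a for a in helix8.atoms if a.residue_index not in (4,)])
    # renumber to keep indices contiguous in identity but break geometry
    with pytest.raises((ChainBreakError, ValueError)):
        rebuild_dependent_atoms(broken.select(("N", "CA", "C")))


def test_cb_reconstruction_on_jittered_fixture(jittered_peptide, ideal_table):
    """Rebuilt ideal CB stays within 0.25 A of a realistically jittered CB."""
    for i in range(1, jittered_peptide.n_residues + 1):
        n, ca, c = (jittered_peptide.coord(i, x) for x in ("N", "CA", "C"))
        cb = place_cb(n, ca, c, ideal_table, jittered_peptide.sequence[i - 1])
        dep = jittered_peptide.coord(i, "CB")
        assert np.linalg.norm(cb - dep) < 0.25


def test_cb_chirality_is_L(helix8):
    for i in range(1, 9):
        n, ca, c, cb = (helix8.coord(i, x) for x in ("N", "CA", "C", "CB"))
        assert np.dot(np.cross(n - ca, c - ca), cb - ca) > 0


def test_ideal_table_validation():
    with pytest.raises(IdealizeError):
        IdealGeometryTable({"N-CA": 1.458}, {})
    with pytest.raises(IdealizeError):
        IdealGeometryTable(
            {k: 1.4 for k in IdealGeometryTable.REQUIRED_BONDS} | {"X-Y": 5.0},
            {k: 115.0 for k in IdealGeometryTable.REQUIRED_ANGLES},
        )


def test_table_overrides(ideal_table):
    assert ideal_table.bond("N-CA", "GLY") != ideal_table.bond("N-CA")
    assert ideal_table.bond("N-CA", "SER") == ideal_table.bond("N-CA")
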