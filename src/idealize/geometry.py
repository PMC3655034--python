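"""Internal-coordinate mathematics.

Measure and impose bond lengths, bond angles and dihedral angles; rebuild
the dependent backbone atoms (carbonyl O, amide H, C-beta) from an N/CA/C
trace; convert between Cartesian coordinates and torsion angles.  All
elementary operations broadcast over leading array dimensions, which is
what lets the dynamic program score candidate batches without Python loops.

A structure built by :func:`build_from_torsions` has *every* bond length
and bond angle equal to its tabulated mean ("ideal") value; its
conformation is therefore fully determined by dihedral angles plus the
rigid-body frame of the first three atoms.  That property is the working
definition of an idealized structure throughout the package.

Torsion sign convention is IUPAC: looking down b->c, the far bond c->d
rotated clockwise from the near bond b->a gives a positive angle.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import ChainBreakError, DegenerateGeometryError, IdealizeError
from .pdb_io import Structure, structure_from_arrays
from .residues import CHI_ATOMS

_EPS = 1e-12


def wrap_deg(x):
    """Wrap angles in degrees to the interval (-180, 180]."""
    x = np.asarray(x, dtype=float)
    w = -((-x + 180.0) % 360.0 - 180.0)
    return w if w.ndim else float(w)


def _unit(v, name="vector"):
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n < _EPS):
        raise DegenerateGeometryError(f"zero-length {name}")
    return v / n


def bond_length(a, b):
    """Euclidean distance |a-b| in Angstrom."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    d = np.linalg.norm(b - a, axis=-1)
    if np.any(d < _EPS):
        raise DegenerateGeometryError("coincident points")
    return d if d.ndim else float(d)


def bond_angle(a, b, c):
    """Interior angle at b, in degrees within [0, 180]."""
    u = _unit(np.asarray(a, float) - np.asarray(b, float), "b->a")
    v = _unit(np.asarray(c, float) - np.asarray(b, float), "b->c")
    cosang = np.clip(np.sum(u * v, axis=-1), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    return ang if ang.ndim else float(ang)


def dihedral(a, b, c, d):
    """Signed torsion angle a-b-c-d in degrees, in (-180, 180]."""
    a, b, c, d = (np.asarray(x, float) for x in (a, b, c, d))
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.any(np.linalg.norm(n1, axis=-1) < _EPS) or np.any(
        np.linalg.norm(n2, axis=-1) < _EPS
    ):
        raise DegenerateGeometryError("collinear points in dihedral")
    m = np.cross(n1, _unit(b2))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m * n2, axis=-1)
    ang = wrap_deg(np.degrees(np.arctan2(y, x)))
    return ang if np.ndim(ang) else float(ang)


def place_next_atom(a, b, c, length, angle, torsion):
    """Place atom d with |c-d| = length, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (degrees).  NeRF construction; broadcasts
    over leading dimensions of the coordinates and of ``torsion``.
    """
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    theta = np.radians(np.asarray(angle, float))
    tau = np.radians(np.asarray(torsion, float))
    bc = _unit(c - b, "b->c")
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n, axis=-1, keepdims=True)
    if np.any(nn < _EPS):
        raise DegenerateGeometryError("collinear reference atoms")
    n = n / nn
    m = np.cross(n, bc)
    L = np.asarray(length, float)
    d2 = (
        -np.cos(theta)[..., None] * bc
        + (np.sin(theta) * np.cos(tau))[..., None] * m
        - (np.sin(theta) * np.sin(tau))[..., None] * n
    )
    return c + L[..., None] * d2 if L.ndim else c + L * d2


# -- ideal parameter table -------------------------------------------------

@dataclass
class IdealGeometryTable:
    """Mean ("ideal") bond lengths (A) and angles (deg) by covalent type,
    with optional per-residue-type overrides (keys like ``N-CA@PRO``)."""

    bond_lengths: dict[str, float]
    bond_angles: dict[str, float]

    REQUIRED_BONDS = ("N-CA", "CA-C", "C-N", "C-O", "CA-CB", "N-H")
    REQUIRED_ANGLES = (
        "N-CA-C", "CA-C-N", "C-N-CA", "CA-C-O", "C-N-H", "CA-N-H",
        "N-CA-CB", "C-CA-CB",
    )

    def __post_init__(self):
        for key in self.REQUIRED_BONDS:
            if key not in self.bond_lengths:
                raise IdealizeError(f"ideal table missing bond {key}")
        for key in self.REQUIRED_ANGLES:
            if key not in self.bond_angles:
                raise IdealizeError(f"ideal table missing angle {key}")
        for k, v in self.bond_lengths.items():
            if not 0.8 < v < 2.0:
                raise IdealizeError(f"implausible bond length {k}={v}")
        for k, v in self.bond_angles.items():
            if not 90.0 < v < 180.0:
                raise IdealizeError(f"implausible bond angle {k}={v}")

    def bond(self, kind: str, residue_type: str | None = None) -> float:
        if residue_type and f"{kind}@{residue_type}" in self.bond_lengths:
            return self.bond_lengths[f"{kind}@{residue_type}"]
        return self.bond_lengths[kind]

    def angle(self, kind: str, residue_type: str | None = None) -> float:
        if residue_type and f"{kind}@{residue_type}" in self.bond_angles:
            return self.bond_angles[f"{kind}@{residue_type}"]
        return self.bond_angles[kind]

    @classmethod
    def from_file(cls, path_or_text) -> "IdealGeometryTable":
        if hasattr(path_or_text, "read"):
            text = path_or_text.read()
        else:
            with open(path_or_text) as fh:
                text = fh.read()
        bonds, angles = {}, {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            kind, key, value = line.split()
            {"bond": bonds, "angle": angles}[kind][key] = float(value)
        return cls(bonds, angles)


@functools.lru_cache(maxsize=1)
def default_ideal_table() -> IdealGeometryTable:
    """The packaged Engh & Huber style parameter table."""
    ref = resources.files("idealize.data") / "ideal_geometry.txt"
    return IdealGeometryTable.from_file(ref.open())


# -- torsions --------------------------------------------------------------

@dataclass
class TorsionSet:
    """Backbone and side-chain torsions per residue (degrees; None where
    undefined: phi of the first residue, psi/omega of the last)."""

    phi: list[float | None]
    psi: list[float | None]
    omega: list[float | None]
    chi: list[list[float]] = field(default_factory=list)

    @property
    def n_residues(self) -> int:
        return len(self.phi)


def check_gapless(s: Structure, cutoff: float = 2.0) -> None:
    for i in range(1, s.n_residues):
        c, n = s.coord(i, "C"), s.coord(i + 1, "N")
        if c is None or n is None or np.linalg.norm(c - n) > cutoff:
            raise ChainBreakError(f"chain break after residue {i}")


def extract_torsions(s: Structure) -> TorsionSet:
    """Measure phi/psi/omega (and chi where side-chain atoms are present)."""
    n = s.n_residues
    bb = {(i, nm): s.coord(i, nm) for i in range(1, n + 1) for nm in ("N", "CA", "C")}
    phi: list = [None] * n
    psi: list = [None] * n
    omega: list = [None] * n
    for i in range(1, n + 1):
        if i > 1:
            phi[i - 1] = dihedral(bb[i - 1, "C"], bb[i, "N"], bb[i, "CA"], bb[i, "C"])
        if i < n:
            psi[i - 1] = dihedral(bb[i, "N"], bb[i, "CA"], bb[i, "C"], bb[i + 1, "N"])
            omega[i - 1] = dihedral(bb[i, "CA"], bb[i, "C"], bb[i + 1, "N"], bb[i + 1, "CA"])
    chis: list[list[float]] = []
    seq = s.sequence
    for i in range(1, n + 1):
        res_chis = []
        for quad in CHI_ATOMS.get(seq[i - 1], []):
            pts = [s.coord(i, nm) for nm in quad]
            if any(p is None for p in pts):
                break
            res_chis.append(dihedral(*pts))
        chis.append(res_chis)
    return TorsionSet(phi, psi, omega, chis)


def default_anchor(sequence: list[str], ideal: IdealGeometryTable) -> np.ndarray:
    """Canonical frame: N1 at the origin, CA1 on +x, C1 in the xy plane."""
    r0 = sequence[0]
    n1 = np.zeros(3)
    ca1 = np.array([ideal.bond("N-CA", r0), 0.0, 0.0])
    th = np.radians(ideal.angle("N-CA-C", r0))
    c1 = ca1 + ideal.bond("CA-C", r0) * np.array([-np.cos(th), np.sin(th), 0.0])
    return np.stack([n1, ca1, c1])


def build_from_torsions(
    sequence: list[str],
    torsions: TorsionSet,
    ideal: IdealGeometryTable | None = None,
    anchor: np.ndarray | None = None,
) -> Structure:
    """Chain an N/CA/C backbone from torsions with exactly ideal geometry.

    ``anchor`` fixes the coordinates of the first three atoms (defaults to
    the canonical frame at the origin).  Mid-chain torsions must all be
    defined.  Returns a backbone-only Structure; use
    :func:`rebuild_dependent_atoms` to add O, H and CB.
    """
    ideal = ideal or default_ideal_table()
    n = len(sequence)
    if torsions.n_residues != n:
        raise IdealizeError("sequence/torsion length mismatch")
    if anchor is None:
        anchor = default_anchor(sequence, ideal)
    coords = [np.asarray(anchor[0], float), np.asarray(anchor[1], float),
              np.asarray(anchor[2], float)]
    for i in range(2, n + 1):
        res, prev = sequence[i - 1], sequence[i - 2]
        psi, om, phi = torsions.psi[i - 2], torsions.omega[i - 2], torsions.phi[i - 1]
        if psi is None or om is None or phi is None:
            raise IdealizeError(f"undefined mid-chain torsion at residue {i}")
        pn, pca, pc = coords[-3], coords[-2], coords[-1]
        ni = place_next_atom(pn, pca, pc, ideal.bond("C-N", res),
                             ideal.angle("CA-C-N", prev), psi)
        cai = place_next_atom(pca, pc, ni, ideal.bond("N-CA", res),
                              ideal.angle("C-N-CA", res), om)
        ci = place_next_atom(pc, ni, cai, ideal.bond("CA-C", res),
                             ideal.angle("N-CA-C", res), phi)
        coords.extend([ni, cai, ci])
    triples = []
    for i in range(1, n + 1):
        for j, nm in enumerate(("N", "CA", "C")):
            triples.append((i, nm, coords[3 * (i - 1) + j]))
    return structure_from_arrays(list(sequence), triples)


# -- dependent atoms -------------------------------------------------------

def place_cb(n, ca, c, ideal: IdealGeometryTable, residue_type: str) -> np.ndarray:
    """C-beta from the backbone frame: ideal N-CA-CB and C-CA-CB angles,
    chirality chosen to give an L-amino acid.  Broadcasts."""
    n, ca, c = (np.asarray(x, float) for x in (n, ca, c))
    u = _unit(n - ca)
    v = _unit(c - ca)
    cos_a = np.cos(np.radians(ideal.angle("N-CA-CB", residue_type)))
    cos_b = np.cos(np.radians(ideal.angle("C-CA-CB", residue_type)))
    uv = np.sum(u * v, axis=-1, keepdims=True)
    e2 = _unit(v - uv * u)
    e3 = np.cross(u, e2)
    y = (cos_b - cos_a * uv[..., 0]) / np.sum(v * e2, axis=-1)
    z2 = 1.0 - cos_a**2 - y**2
    # On a heavily distorted (non-ideal) frame both target angles can be
    # unreachable (z2 < 0); fall back to the nearest in-plane direction.
    # Ideal frames, as built by the generator, always have z2 > 0.
    z = np.sqrt(np.clip(z2, 0.0, None))
    # positive component along (N-CA)x(C-CA) gives the L configuration
    d = cos_a * u + y[..., None] * e2 + z[..., None] * e3
    d = d / np.linalg.norm(d, axis=-1, keepdims=True)
    return ca + ideal.bond("CA-CB", residue_type) * d


def place_carbonyl_o(n_i, ca_i, c_i, n_next, ideal, residue_type, psi=None):
    """Carbonyl O off C, in the peptide plane, trans to the next N."""
    if psi is None:
        psi = dihedral(n_i, ca_i, c_i, n_next)
    return place_next_atom(n_i, ca_i, c_i, ideal.bond("C-O"),
                           ideal.angle("CA-C-O", residue_type), wrap_deg(psi + 180.0))


def place_amide_h(ca_prev, c_prev, n_i, ca_i, ideal, omega=None):
    """Amide H off N, in the peptide plane, anti to the chain (trans to CA)."""
    if omega is None:
        omega = dihedral(ca_prev, c_prev, n_i, ca_i)
    return place_next_atom(ca_prev, c_prev, n_i, ideal.bond("N-H"),
                           ideal.angle("C-N-H"), wrap_deg(omega + 180.0))


def rebuild_dependent_atoms(
    backbone: Structure, ideal: IdealGeometryTable | None = None,
    max_gap: float = 2.5,
) -> Structure:
    """Add O, amide H and CB to an N/CA/C trace.

    O lies in the peptide plane trans to the following N; H lies in the
    peptide plane anti to the following CA; CB is built from the N/CA/C
    frame with L chirality.  Gly gets no CB, Pro no amide H.  Terminal
    rule: the N-terminal H and C-terminal O are placed in the frame of the
    only available neighbor at torsion 180.
    """
    ideal = ideal or default_ideal_table()
    check_gapless(backbone, cutoff=max_gap)
    n = backbone.n_residues
    seq = backbone.sequence
    triples = []
    for i in range(1, n + 1):
        res = seq[i - 1]
        ni, cai, ci = (backbone.coord(i, nm) for nm in ("N", "CA", "C"))
        for nm, xyz in (("N", ni), ("CA", cai), ("C", ci)):
            triples.append((i, nm, xyz))
        if i < n:
            o = place_carbonyl_o(ni, cai, ci, backbone.coord(i + 1, "N"), ideal, res)
        else:
            o = place_next_atom(ni, cai, ci, ideal.bond("C-O"),
                                ideal.angle("CA-C-O", res), 180.0)
        triples.append((i, "O", o))
        if res != "GLY":
            triples.append((i, "CB", place_cb(ni, cai, ci, ideal, res)))
        if res != "PRO":
            if i > 1:
                h = place_amide_h(backbone.coord(i - 1, "CA"),
                                  backbone.coord(i - 1, "C"), ni, cai, ideal)
            else:
                h = place_next_atom(ci, cai, ni, ideal.bond("N-H"),
                                    ideal.angle("CA-N-H"), 180.0)
            triples.append((i, "H", h))
    out = structure_from_arrays(seq, triples, chain_id=backbone.chain_id)
    out.renumbering = dict(backbone.renumbering)
    return out
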