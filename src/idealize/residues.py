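"""Amino-acid residue definitions: names, chi-angle atom quadruples, and
ideal internal-coordinate topology for building side chains past C-beta.

Side-chain atoms are defined Z-matrix style: each atom is placed from three
previously built atoms by an ideal bond length, an ideal bond angle, and a
torsion that is either a searchable chi angle, a fixed offset from a chi
(branches such as CG2 or ring closures), or an outright constant (planar
groups).  Lengths/angles are mean values of the Engh & Huber style
stereochemical tabulations used for refinement restraints.
"""

from __future__ import annotations

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_RESIDUES = frozenset(THREE_TO_ONE)

#: chi dihedral definitions (atom-name quadruples), in chi1..chi4 order
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ALA": [],
    "GLY": [],
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}


def n_chi(res: str) -> int:
    """Number of searchable chi torsions of a residue type."""
    return len(CHI_ATOMS[res])


# torsion specs: ("chi", k)            -> the k-th chi angle (1-based)
#                ("chi+", k, offset)   -> chi_k + offset degrees (branches)
#                ("fixed", value)      -> constant torsion (rings, planar ends)
# entry: (atom, (a, b, c), bond length A, bond angle b-c-atom deg, torsion a-b-c-atom)
SIDECHAIN_TOPOLOGY: dict[str, list[tuple]] = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", ("N", "CA", "CB"), 1.417, 110.8, ("chi", 1))],
    "CYS": [("SG", ("N", "CA", "CB"), 1.808, 113.8, ("chi", 1))],
    "THR": [("OG1", ("N", "CA", "CB"), 1.433, 109.6, ("chi", 1)),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi+", 1, -120.0))],
    "VAL": [("CG1", ("N", "CA", "CB"), 1.527, 110.5, ("chi", 1)),
            ("CG2", ("N", "CA", "CB"), 1.527, 110.5, ("chi+", 1, 122.0))],
    "LEU": [("CG", ("N", "CA", "CB"), 1.530, 116.3, ("chi", 1)),
            ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, ("chi", 2)),
            ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, ("chi+", 2, 122.0))],
    "ILE": [("CG1", ("N", "CA", "CB"), 1.530, 110.4, ("chi", 1)),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi+", 1, -122.0)),
            ("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, ("chi", 2))],
    "MET": [("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1)),
            ("SD", ("CA", "CB", "CG"), 1.803, 112.7, ("chi", 2)),
            ("CE", ("CB", "CG", "SD"), 1.791, 100.9, ("chi", 3))],
    "ASP": [("CG", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 1)),
            ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 2)),
            ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, ("chi+", 2, 180.0))],
    "ASN": [("CG", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 1)),
            ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, ("chi", 2)),
            ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, ("chi+", 2, 180.0))],
    "GLU": [("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1)),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 2)),
            ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 3)),
            ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, ("chi+", 3, 180.0))],
    "GLN": [("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1)),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 2)),
            ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, ("chi", 3)),
            ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, ("chi+", 3, 180.0))],
    "LYS": [("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1)),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 2)),
            ("CE", ("CB", "CG", "CD"), 1.520, 111.3, ("chi", 3)),
            ("NZ", ("CG", "CD", "CE"), 1.489, 111.9, ("chi", 4))],
    # Arg N-eta torsions about CZ are rounded to exactly 0/180: the
    # guanidinium group is planar, so they are not searched.
    "ARG": [("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1)),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 2)),
            ("NE", ("CB", "CG", "CD"), 1.460, 112.0, ("chi", 3)),
            ("CZ", ("CG", "CD", "NE"), 1.329, 124.2, ("chi", 4)),
            ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, ("fixed", 0.0)),
            ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, ("fixed", 180.0))],
    "HIS": [("CG", ("N", "CA", "CB"), 1.497, 113.8, ("chi", 1)),
            ("ND1", ("CA", "CB", "CG"), 1.371, 122.7, ("chi", 2)),
            ("CD2", ("CA", "CB", "CG"), 1.356, 129.1, ("chi+", 2, 180.0)),
            ("CE1", ("CB", "CG", "ND1"), 1.319, 109.3, ("fixed", 180.0)),
            ("NE2", ("CG", "ND1", "CE1"), 1.374, 108.4, ("fixed", 0.0))],
    "PHE": [("CG", ("N", "CA", "CB"), 1.502, 113.8, ("chi", 1)),
            ("CD1", ("CA", "CB", "CG"), 1.384, 120.7, ("chi", 2)),
            ("CD2", ("CA", "CB", "CG"), 1.384, 120.7, ("chi+", 2, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.384, 120.7, ("fixed", 180.0)),
            ("CE2", ("CB", "CG", "CD2"), 1.384, 120.7, ("fixed", 180.0)),
            ("CZ", ("CG", "CD1", "CE1"), 1.382, 120.0, ("fixed", 0.0))],
    "TYR": [("CG", ("N", "CA", "CB"), 1.512, 113.9, ("chi", 1)),
            ("CD1", ("CA", "CB", "CG"), 1.389, 120.8, ("chi", 2)),
            ("CD2", ("CA", "CB", "CG"), 1.389, 120.8, ("chi+", 2, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.382, 121.2, ("fixed", 180.0)),
            ("CE2", ("CB", "CG", "CD2"), 1.382, 121.2, ("fixed", 180.0)),
            ("CZ", ("CG", "CD1", "CE1"), 1.378, 119.6, ("fixed", 0.0)),
            ("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, ("fixed", 180.0))],
    "TRP": [("CG", ("N", "CA", "CB"), 1.498, 113.6, ("chi", 1)),
            ("CD1", ("CA", "CB", "CG"), 1.365, 126.9, ("chi", 2)),
            ("CD2", ("CA", "CB", "CG"), 1.433, 126.8, ("chi+", 2, 180.0)),
            ("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, ("fixed", 180.0)),
            ("CE2", ("CB", "CG", "CD2"), 1.409, 107.2, ("fixed", 180.0)),
            ("CE3", ("CB", "CG", "CD2"), 1.398, 133.9, ("fixed", 0.0)),
            ("CZ2", ("CG", "CD2", "CE2"), 1.394, 122.4, ("fixed", 180.0)),
            ("CZ3", ("CG", "CD2", "CE3"), 1.382, 118.6, ("fixed", 180.0)),
            ("CH2", ("CD2", "CE2", "CZ2"), 1.368, 117.5, ("fixed", 0.0))],
    "PRO": [("CG", ("N", "CA", "CB"), 1.492, 104.5, ("chi", 1)),
            ("CD", ("CA", "CB", "CG"), 1.503, 106.1, ("chi", 2))],
}

#: canonical within-residue atom order used on output
_BACKBONE_ORDER = ("N", "CA", "C", "O", "CB")


def atom_sort_key(residue_type: str, atom_name: str) -> tuple[int, int]:
    """Sort key giving the conventional PDB atom order within a residue:
    backbone (N CA C O CB), then side chain outward, then the amide H."""
    if atom_name in _BACKBONE_ORDER:
        return (0, _BACKBONE_ORDER.index(atom_name))
    if atom_name == "H":
        return (2, 0)
    topo = SIDECHAIN_TOPOLOGY.get(residue_type, [])
    for i, entry in enumerate(topo):
        if entry[0] == atom_name:
            return (1, i)
    return (1, 99)


def element_of(atom_name: str) -> str:
    """Element symbol from a (heavy-atom or amide H) PDB atom name."""
    return atom_name[0]
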