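"""PDB reading/writing and working-chain selection.

Parsing and serialization stand on :mod:`gemmi`; this module adapts gemmi
models to the package's flat :class:`Structure` container, resolves
alternate locations, drops hydrogens/heteroatoms, and extracts the longest
gapless backbone fragment renumbered to a clean 1..n index.  For files with
several models/chains (NMR ensembles) the default policy keeps the first
chain of the first model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .errors import FormatError, InputTooShortError
from .residues import STANDARD_RESIDUES, atom_sort_key, element_of

log = logging.getLogger(__name__)

#: maximum C(i)-N(i+1) distance still counted as a peptide bond (A)
PEPTIDE_BOND_CUTOFF = 2.0


@dataclass
class AtomRecord:
    """One atom: identity plus Cartesian coordinate in Angstrom."""

    serial: int
    name: str
    element: str
    residue_index: int
    residue_type: str
    coord: np.ndarray

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"bad coordinate for atom {self.name}: {self.coord}")


@dataclass
class Structure:
    """An ordered list of atoms for a single chain, residues numbered 1..n.

    Within each residue atoms follow the conventional order
    N, CA, C, O, CB, side chain outward, amide H.
    """

    atoms: list[AtomRecord] = field(default_factory=list)
    chain_id: str = "A"
    source_model: int = 1
    #: original (auth) residue numbering, index -> label, kept for reports
    renumbering: dict[int, str] = field(default_factory=dict)

    # -- container conveniences -------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return max((a.residue_index for a in self.atoms), default=0)

    @property
    def sequence(self) -> list[str]:
        seq: dict[int, str] = {}
        for a in self.atoms:
            seq[a.residue_index] = a.residue_type
        return [seq[i] for i in sorted(seq)]

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    def atom(self, residue_index: int, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.residue_index == residue_index and a.name == name:
                return a
        return None

    def coord(self, residue_index: int, name: str) -> np.ndarray | None:
        a = self.atom(residue_index, name)
        return None if a is None else a.coord

    def select(self, names: tuple[str, ...]) -> "Structure":
        """Sub-structure keeping only the given atom names (order preserved)."""
        kept = [replace(a) for a in self.atoms if a.name in names]
        return Structure(kept, self.chain_id, self.source_model)

    def backbone_coords(self) -> np.ndarray:
        """(3n, 3) array of N, CA, C coordinates in chain order."""
        out = []
        for i in range(1, self.n_residues + 1):
            for name in ("N", "CA", "C"):
                c = self.coord(i, name)
                if c is None:
                    raise ValueError(f"residue {i} missing backbone atom {name}")
                out.append(c)
        return np.array(out, dtype=float)

    def sorted_copy(self) -> "Structure":
        atoms = sorted(
            self.atoms,
            key=lambda a: (a.residue_index, atom_sort_key(a.residue_type, a.name)),
        )
        atoms = [replace(a, serial=i + 1) for i, a in enumerate(atoms)]
        return Structure(atoms, self.chain_id, self.source_model, dict(self.renumbering))


def structure_from_arrays(
    sequence: list[str], names_coords: list[tuple[int, str, np.ndarray]], chain_id: str = "A"
) -> Structure:
    """Assemble a Structure from (residue_index, atom_name, coord) triples."""
    atoms = []
    for k, (ri, name, xyz) in enumerate(names_coords):
        atoms.append(
            AtomRecord(k + 1, name, element_of(name), ri, sequence[ri - 1], np.asarray(xyz, float))
        )
    return Structure(atoms, chain_id=chain_id).sorted_copy()


# -- reading ---------------------------------------------------------------

def _pick(policy, items, kind):
    if policy in ("first", None):
        return items[0]
    for it in items:
        label = it.name if kind == "model" else it.name
        if str(label) == str(policy):
            return it
    raise FormatError(f"no {kind} matching policy {policy!r}")


def read_structure(path, model_policy="first", chain_policy="first") -> Structure:
    """Read a PDB file and return the selected model/chain as a Structure.

    Alternate locations are resolved to the highest-occupancy (then
    alphabetically first) conformer; hydrogens, waters and heteroatoms are
    dropped; residues missing any of N/CA/C are reported and the longest
    gapless fragment (peptide C-N bond under 2 A) is returned, renumbered
    1..n with the original numbering kept in ``Structure.renumbering``.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    st.remove_hydrogens()
    st.remove_waters()
    if len(st) == 0:
        raise InputTooShortError(f"{path}: no models")
    model = _pick(model_policy, list(st), "model")
    chains = [ch for ch in model if len(ch) > 0]
    if not chains:
        raise InputTooShortError(f"{path}: empty model")
    chain = _pick(chain_policy, chains, "chain")

    residues = []
    for res in chain:
        if res.name not in STANDARD_RESIDUES:
            if res.het_flag != "H":
                log.warning("skipping non-standard residue %s %s", res.name, res.seqid)
            continue
        names = {a.name for a in res}
        if not {"N", "CA", "C"} <= names:
            log.warning("residue %s%s lacks full backbone; skipped", res.name, res.seqid.num)
            continue
        residues.append(res)
    if len(residues) < 2:
        raise InputTooShortError(f"{path}: fewer than 2 complete residues")

    # split into gapless fragments at broken peptide bonds
    fragments, current = [], [residues[0]]
    for prev, res in zip(residues, residues[1:]):
        c = np.array(prev["C"][0].pos.tolist())
        n = np.array(res["N"][0].pos.tolist())
        if np.linalg.norm(c - n) <= PEPTIDE_BOND_CUTOFF:
            current.append(res)
        else:
            fragments.append(current)
            current = [res]
    fragments.append(current)
    best = max(fragments, key=len)
    if len(best) < 2:
        raise InputTooShortError(f"{path}: no gapless residue pair")
    if len(fragments) > 1:
        log.warning(
            "%d chain fragments; keeping longest with %d residues", len(fragments), len(best)
        )

    out = Structure(chain_id=chain.name, source_model=1)
    serial = 0
    for idx, res in enumerate(best, start=1):
        out.renumbering[idx] = f"{res.seqid.num}{(res.seqid.icode or '').strip()}"
        # resolve altLocs: highest occupancy wins, ties alphabetically
        by_name: dict[str, gemmi.Atom] = {}
        for atom in res:
            if atom.element.is_hydrogen:
                continue
            prev = by_name.get(atom.name)
            if prev is None or (atom.occ, -ord(atom.altloc or "A")) > (
                prev.occ, -ord(prev.altloc or "A")
            ):
                by_name[atom.name] = atom
        for atom in by_name.values():
            serial += 1
            out.atoms.append(
                AtomRecord(
                    serial=serial,
                    name=atom.name,
                    element=atom.element.name or element_of(atom.name),
                    residue_index=idx,
                    residue_type=res.name,
                    coord=np.array(atom.pos.tolist()),
                )
            )
    return out.sorted_copy()


# -- writing ---------------------------------------------------------------

def write_structure(s: Structure, path) -> None:
    """Write plain ATOM/TER records (occupancy 1.00, B 0.00) via gemmi."""
    if not s.atoms:
        raise ValueError("refusing to write an empty Structure")
    st = gemmi.Structure()
    st.name = "idealized"
    model = gemmi.Model(1)
    chain = gemmi.Chain(s.chain_id or "A")
    ordered = s.sorted_copy()
    current = None
    for a in ordered.atoms:
        if current is None or current.seqid.num != a.residue_index:
            current = gemmi.Residue()
            current.name = a.residue_type
            current.seqid = gemmi.SeqId(a.residue_index, " ")
            chain.add_residue(current)
            current = chain[-1]
        atom = gemmi.Atom()
        atom.name = a.name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*a.coord)
        atom.occ = 1.0
        atom.b_iso = 0.0
        current.add_atom(atom)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string(gemmi.PdbWriteOptions(minimal=True))
    with open(path, "w") as fh:
        fh.write(doc)
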