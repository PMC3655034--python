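"""Deterministic synthetic structures and toy probability tables.

Everything here is a pure function of its arguments (and an explicit seed
where randomness is involved), so every module of the package is testable
with no downloads: idealized poly-peptides with prescribed torsions,
Gaussian coordinate perturbations of them (a "target" whose ideal
ancestor is known), and toy Ramachandran tables trained on synthetic
torsion samples concentrated in the helix and sheet basins.
"""

from __future__ import annotations

import numpy as np

from .geometry import (
    TorsionSet,
    build_from_torsions,
    default_ideal_table,
    rebuild_dependent_atoms,
)
from .pdb_io import AtomRecord, Structure
from .rama_stats import N_BINS, RamachandranTable, RotamerTable, fallback_rotamer_table
from .residues import ONE_TO_THREE, STANDARD_RESIDUES, n_chi
from .sidechain import build_sidechain

#: canonical basin centers (phi, psi), degrees
ALPHA_HELIX = (-57.0, -47.0)
BETA_STRAND = (-120.0, 130.0)


def parse_sequence(sequence) -> list[str]:
    if isinstance(sequence, str):
        return [ONE_TO_THREE[ch] for ch in sequence]
    seq = list(sequence)
    if any(r not in STANDARD_RESIDUES for r in seq):
        raise ValueError(f"non-standard residue in {seq}")
    return seq


def uniform_torsions(n: int, phi: float, psi: float, omega: float = 180.0) -> TorsionSet:
    return TorsionSet(
        phi=[None] + [phi] * (n - 1),
        psi=[psi] * (n - 1) + [None],
        omega=[omega] * (n - 1) + [None],
    )


def make_ideal_peptide(sequence, torsions: TorsionSet | tuple = ALPHA_HELIX,
                       chis: list | None = None) -> Structure:
    """Idealized peptide with prescribed torsions, anchored at the origin.

    ``torsions`` may be a full TorsionSet or a (phi, psi) pair applied
    uniformly with trans peptides.  If ``chis`` (list of per-residue chi
    lists) is given, ideal side chains are attached; otherwise rotamer-mean
    side chains can be added later by the side-chain module.
    """
    seq = parse_sequence(sequence)
    if not isinstance(torsions, TorsionSet):
        phi, psi = torsions
        torsions = uniform_torsions(len(seq), phi, psi)
    ideal = default_ideal_table()
    bb = build_from_torsions(seq, torsions, ideal)
    full = rebuild_dependent_atoms(bb, ideal)
    if chis is not None:
        triples = [(a.residue_index, a.name, a.coord) for a in full.atoms]
        for i, res in enumerate(seq, start=1):
            if n_chi(res) == 0 or not chis[i - 1]:
                continue
            bbs = {nm: full.coord(i, nm) for nm in ("N", "CA", "C")}
            for nm, xyz in build_sidechain(res, bbs, chis[i - 1], ideal).items():
                if nm != "CB":
                    triples.append((i, nm, xyz))
        from .pdb_io import structure_from_arrays

        full = structure_from_arrays(seq, triples)
    return full


def perturb(s: Structure, sigma: float, seed: int) -> Structure:
    """Add i.i.d. Gaussian noise (stddev ``sigma`` A per coordinate) to
    every atom; deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=(len(s.atoms), 3)) if sigma > 0 else 0.0
    atoms = []
    for j, a in enumerate(s.atoms):
        xyz = a.coord + (noise[j] if sigma > 0 else 0.0)
        atoms.append(AtomRecord(a.serial, a.name, a.element, a.residue_index,
                                a.residue_type, xyz))
    return Structure(atoms, s.chain_id, s.source_model, dict(s.renumbering))


def make_toy_tables(seed: int, n_samples: int = 20000,
                    pseudocount: float = 1.0) -> tuple[RamachandranTable, RotamerTable]:
    """Toy tables for self-contained runs: a Ramachandran table trained on
    synthetic (phi, psi) samples (65% helix basin, 35% strand basin,
    shared across residue types) and the packaged coarse rotamer table."""
    rng = np.random.default_rng(seed)
    in_helix = rng.random(n_samples) < 0.65
    phi = np.where(in_helix,
                   rng.normal(ALPHA_HELIX[0], 8.0, n_samples),
                   rng.normal(BETA_STRAND[0], 14.0, n_samples))
    psi = np.where(in_helix,
                   rng.normal(ALPHA_HELIX[1], 8.0, n_samples),
                   rng.normal(BETA_STRAND[1], 14.0, n_samples))
    from .rama_stats import angle_bin

    counts = np.zeros((N_BINS, N_BINS))
    np.add.at(counts, (angle_bin(phi), angle_bin(psi)), 1.0)
    counts += pseudocount
    grid = counts / counts.sum()
    rama = RamachandranTable({aa: grid.copy() for aa in STANDARD_RESIDUES},
                             pseudocount, f"toy basins, seed={seed}")
    return rama, fallback_rotamer_table()
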