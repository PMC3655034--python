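"""Side-chain idealization by exhaustive chi-grid search.

With the idealized backbone held rigid, side-chain conformations of
different residues are independent, so each residue is searched
exhaustively and independently: for every rotamer of the residue's
backbone bin, each chi torsion is sampled on a grid (default 10 degrees)
within a window of 3 sigma around the rotamer mean, the side chain is
rebuilt with ideal bond lengths and angles for every chi tuple, and the
tuple maximizing S_SC is kept.  The two arginine N-eta torsions are
rounded to exactly 0/180 (planar guanidinium) and are not searched, which
caps the search dimension at four.  No inter-residue clash term is
evaluated -- that is the independence assumption.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .errors import IdealizeError
from .geometry import (
    IdealGeometryTable,
    default_ideal_table,
    extract_torsions,
    place_cb,
    place_next_atom,
    wrap_deg,
)
from .pdb_io import Structure, structure_from_arrays
from .rama_stats import Rotamer, RotamerTable
from .residues import CHI_ATOMS, SIDECHAIN_TOPOLOGY, n_chi
from .scoring import score_sidechain_parts, sidechain_atoms

log = logging.getLogger(__name__)


@dataclass
class ChiGrid:
    """Chi search grid: samples every ``step`` degrees within
    ``window_sigmas`` standard deviations of the rotamer mean."""

    step: float = 10.0
    window_sigmas: float = 3.0

    def scaled(self, factor: float) -> "ChiGrid":
        """Refinement schedule: window and step shrink together, so the
        sample count per chi dimension stays constant."""
        return ChiGrid(self.step * factor, self.window_sigmas * factor)

    def samples(self, mean: float, sigma: float) -> np.ndarray:
        half = int(np.floor(self.window_sigmas * sigma / self.step))
        offs = self.step * np.arange(-half, half + 1)
        return wrap_deg(mean + offs)


def enumerate_chi(res: str, rotamer: Rotamer, grid: ChiGrid) -> np.ndarray:
    """All chi tuples of one rotamer: the Cartesian product of
    per-dimension grids (2*floor(3 sigma/step)+1 samples each)."""
    k = n_chi(res)
    if k == 0:
        return np.empty((0, 0))
    axes = [grid.samples(rotamer.means[j], rotamer.sigmas[j]) for j in range(k)]
    return np.array(list(itertools.product(*axes)))


def build_sidechain(
    res: str,
    backbone_atoms: dict[str, np.ndarray],
    chis,
    ideal: IdealGeometryTable | None = None,
) -> dict[str, np.ndarray]:
    """Ideal-geometry side-chain coordinates (CB outward) for given chis.

    ``backbone_atoms`` must hold N, CA, C.  Atoms are chained Z-matrix
    style from the topology table, so every bond length and angle equals
    its tabulated value exactly; only the chi torsions vary.
    """
    ideal = ideal or default_ideal_table()
    if res not in SIDECHAIN_TOPOLOGY:
        raise IdealizeError(f"unknown residue type {res!r}")
    pos = dict(backbone_atoms)
    if res != "GLY" and "CB" not in pos:
        pos["CB"] = place_cb(pos["N"], pos["CA"], pos["C"], ideal, res)
    chis = list(np.atleast_1d(np.asarray(chis, float))) if n_chi(res) else []
    out = {} if res == "GLY" else {"CB": pos["CB"]}
    for name, parents, length, angle, tors in SIDECHAIN_TOPOLOGY[res]:
        if tors[0] == "chi":
            tau = chis[tors[1] - 1]
        elif tors[0] == "chi+":
            tau = wrap_deg(chis[tors[1] - 1] + tors[2])
        else:
            tau = tors[1]
        a, b, c = (pos[p] for p in parents)
        pos[name] = place_next_atom(a, b, c, length, angle, tau)
        out[name] = pos[name]
    return out


def idealize_sidechains(
    backbone: Structure,
    target: Structure,
    table: RotamerTable,
    grid: ChiGrid | None = None,
    weights: tuple[float, float] = (1.0, 1.0),
    ideal: IdealGeometryTable | None = None,
) -> Structure:
    """Attach the best-scoring ideal side chain to every residue.

    For each residue the full rotamer x chi-grid enumeration is scored
    with S_SC against the target's side chain (distance terms are dropped
    for residues whose target side chain is absent) and the argmax kept;
    ties go to the earliest enumerated tuple.  Residue results are
    independent of each other and of processing order.
    """
    grid = grid or ChiGrid()
    ideal = ideal or default_ideal_table()
    tors = extract_torsions(backbone)
    n = backbone.n_residues
    seq = backbone.sequence
    triples = []
    for a in backbone.atoms:
        triples.append((a.residue_index, a.name, a.coord))
    targ_tors = extract_torsions(target) if target is not None else None
    for i in range(1, n + 1):
        res = seq[i - 1]
        k = n_chi(res)
        if k == 0:
            continue
        bb = {nm: backbone.coord(i, nm) for nm in ("N", "CA", "C")}
        targ_sc = sidechain_atoms(target, i) if target is not None else {}
        chis_t = None
        if targ_tors is not None and len(targ_tors.chi) >= i:
            chis_t = targ_tors.chi[i - 1] or None
        phi, psi = tors.phi[i - 1], tors.psi[i - 1]
        best_score, best_atoms = -np.inf, None
        for rot in table.rotamers_for(res, phi, psi):
            for chis in enumerate_chi(res, rot, grid):
                cand = build_sidechain(res, bb, chis, ideal)
                if targ_sc or chis_t:
                    s = score_sidechain_parts(
                        res, list(chis), cand, targ_sc, chis_t, table,
                        phi, psi, weights)
                else:
                    from .rama_stats import chi_log_odds

                    s = chi_log_odds(table, res, phi, psi, chis)
                if s > best_score:
                    best_score, best_atoms = s, cand
        for nm, xyz in best_atoms.items():
            if nm != "CB" or backbone.coord(i, "CB") is None:
                triples.append((i, nm, xyz))
    out = structure_from_arrays(seq, triples, chain_id=backbone.chain_id)
    out.renumbering = dict(backbone.renumbering)
    return out
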