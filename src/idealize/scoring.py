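"""Scoring functions for backbone and side-chain idealization.

The backbone score of a candidate structure P against the target P0 is

    S_BB(P) = S_f(P) - w1*D_alpha - w2*D_beta - w3*D_H - w4*D_PhiPsi

where S_f is the summed Ramachandran log-odds of interior residues and the
D terms are frame-fixed RMSDs (no superposition -- candidates are built in
the target's coordinate frame): over CA atoms, over CB atoms, over the
amide H / carbonyl O atoms participating in the target's hydrogen bonds,
and over wrapped (Phi,Psi) differences.

Every term is carried as a (sum of squares, count) pair plus a log-odds
sum in :class:`ScoreBreakdown`, which makes the score additive over
disjoint contiguous atom segments: sums and counts add, and the combined
RMSD is sqrt((r1^2*n1 + r2^2*n2)/(n1+n2)).  That additivity is what the
tail-grid dynamic program relies on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import IdealizeError
from .geometry import (
    extract_torsions,
    place_cb,
    rebuild_dependent_atoms,
    wrap_deg,
)
from .pdb_io import Structure
from .rama_stats import RamachandranTable, RotamerTable, chi_log_odds, rama_log_odds
from .residues import CHI_ATOMS

log = logging.getLogger(__name__)

BACKBONE_NAMES = ("N", "CA", "C", "O", "H")
#: Kabsch-Sander electrostatic model: q1*q2*332 kcal/mol*A
KS_COUPLING = 0.084 * 332.0
#: hydrogen bond energy threshold, kcal/mol
KS_CUTOFF = -0.5
#: minimal sequence separation |i-j| of donor and acceptor
KS_MIN_SEP = 2


# -- elementary distances --------------------------------------------------

def _matched_coords(p: Structure, q: Structure, names=None):
    keyed_q = {(a.residue_index, a.name): a for a in q.atoms}
    P, Q = [], []
    for a in p.atoms:
        if names is not None and a.name not in names:
            continue
        b = keyed_q.get((a.residue_index, a.name))
        if b is None:
            raise IdealizeError(f"atom {a.residue_index}:{a.name} unmatched")
        P.append(a.coord)
        Q.append(b.coord)
    return np.array(P), np.array(Q)


def bottleneck_distance(p: Structure, q: Structure) -> float:
    """Maximum over matched atoms of the Euclidean distance."""
    if len(p) != len(q):
        raise IdealizeError("structures have different atom counts")
    P, Q = _matched_coords(p, q)
    return float(np.max(np.linalg.norm(P - Q, axis=1)))


def rmsd_no_fit(p: Structure, q: Structure, atom_selector=None) -> float:
    """Frame-fixed RMSD (no superposition) over the selected matched atoms.

    ``atom_selector`` is a tuple of atom names or a predicate on
    AtomRecord; an empty selection is defined as 0 (with a warning).
    """
    if callable(atom_selector):
        sel = tuple({a.name for a in p.atoms if atom_selector(a)})
    else:
        sel = atom_selector
    P, Q = _matched_coords(p, q, names=sel)
    if len(P) == 0:
        log.warning("empty atom selection in RMSD; defined as 0")
        return 0.0
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))


# -- hydrogen bonds --------------------------------------------------------

@dataclass
class HydrogenBondSet:
    """Backbone hydrogen bonds detected on the target structure."""

    pairs: list[tuple[int, int]]  # (donor residue, acceptor residue)

    @property
    def donor_residues(self) -> set[int]:
        return {d for d, _ in self.pairs}

    @property
    def acceptor_residues(self) -> set[int]:
        return {a for _, a in self.pairs}

    def participating_atoms(self) -> set[tuple[int, str]]:
        out = set()
        for d, a in self.pairs:
            out.add((d, "H"))
            out.add((a, "O"))
        return out


def kabsch_sander_energy(o, c, h, n) -> float:
    """Electrostatic H-bond energy (kcal/mol) of donor N-H vs acceptor C=O."""
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -math.inf  # atoms on top of each other: count as bonded
    return KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def detect_hbonds(target: Structure) -> HydrogenBondSet:
    """Kabsch-Sander detection of backbone hydrogen bonds.

    Donors are amide N-H groups of residues 2..n (Pro has none; the
    N-terminal amine is excluded); acceptors are carbonyl C=O of residues
    1..n-1 (the terminal carboxylate is excluded).  Pairs with energy
    below -0.5 kcal/mol and |i-j| >= 2 are kept.
    """
    n = target.n_residues
    seq = target.sequence
    missing = [i for i in range(1, n + 1)
               if target.coord(i, "O") is None and i < n]
    if missing or all(target.coord(i, "H") is None
                      for i in range(2, n + 1) if seq[i - 1] != "PRO"):
        raise IdealizeError("detect_hbonds needs rebuilt O and H atoms")
    pairs = []
    for d in range(2, n + 1):
        if seq[d - 1] == "PRO":
            continue
        h, nn = target.coord(d, "H"), target.coord(d, "N")
        if h is None:
            continue
        best = None
        for a in range(1, n):
            if abs(d - a) < KS_MIN_SEP:
                continue
            o, c = target.coord(a, "O"), target.coord(a, "C")
            if o is None:
                continue
            e = kabsch_sander_energy(o, c, h, nn)
            if e < KS_CUTOFF:
                pairs.append((d, a))
    return HydrogenBondSet(sorted(pairs))


# -- score breakdown -------------------------------------------------------

_METRICS = ("alpha", "beta", "hbond", "phipsi")


@dataclass
class ScoreBreakdown:
    """Additive representation of S_BB: a log-odds sum plus, per distance
    metric, the sum of squared deviations and the item count."""

    logodds_sum: float = 0.0
    sq: dict[str, float] = field(default_factory=lambda: {m: 0.0 for m in _METRICS})
    n: dict[str, int] = field(default_factory=lambda: {m: 0 for m in _METRICS})
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    span: tuple[int, int] | None = None  # atom index range (1-based, inclusive)

    def rmsd(self, metric: str) -> float:
        cnt = self.n[metric]
        return math.sqrt(self.sq[metric] / cnt) if cnt else 0.0

    def total(self) -> float:
        return self.logodds_sum - sum(
            w * self.rmsd(m) for w, m in zip(self.weights, _METRICS)
        )

    def copy(self) -> "ScoreBreakdown":
        return replace(self, sq=dict(self.sq), n=dict(self.n))


def combine(a: ScoreBreakdown, b: ScoreBreakdown) -> ScoreBreakdown:
    """The additive operator: log-odds sums add, squared sums and counts
    add, so combined RMSDs follow sqrt((r1^2 n1 + r2^2 n2)/(n1+n2))."""
    if a.weights != b.weights:
        raise IdealizeError("cannot combine breakdowns with different weights")
    span = None
    if a.span is not None and b.span is not None:
        if a.span[1] >= b.span[0] and b.span[1] >= a.span[0]:
            raise IdealizeError(f"overlapping segments {a.span} and {b.span}")
        lo, hi = min(a.span, b.span), max(a.span, b.span)
        if lo[1] + 1 != hi[0]:
            raise IdealizeError(f"non-contiguous segments {a.span} and {b.span}")
        span = (lo[0], hi[1])
    return ScoreBreakdown(
        a.logodds_sum + b.logodds_sum,
        {m: a.sq[m] + b.sq[m] for m in _METRICS},
        {m: a.n[m] + b.n[m] for m in _METRICS},
        a.weights,
        span,
    )


def backbone_score(b: ScoreBreakdown) -> float:
    """S_BB = S_f - sum_a w_a D_a, recovered from the breakdown fields."""
    return b.total()


# -- target context & monolithic scoring ----------------------------------

@dataclass
class ScoringContext:
    """Everything about the target that scoring needs, computed once.

    Reference CB positions come from the target's own CB atoms where
    deposited and are rebuilt from the target backbone otherwise; amide H
    and carbonyl O references are always rebuilt on the target backbone,
    and the hydrogen-bond pair set is detected there and then held fixed.
    """

    target: Structure
    rama: RamachandranTable
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self):
        from .geometry import default_ideal_table

        ideal = default_ideal_table()
        t = self.target
        self.n = t.n_residues
        self.sequence = t.sequence
        self.bb0 = t.backbone_coords()
        self.ca0 = self.bb0[1::3]
        # noisy pseudo-structure targets can stretch a peptide bond well
        # past covalent range; references still need to be buildable
        rebuilt = rebuild_dependent_atoms(t.select(("N", "CA", "C")), ideal,
                                          max_gap=6.0)
        self.rebuilt_target = rebuilt
        # CB reference: deposited if present, rebuilt otherwise; none for GLY
        self.cb_ref = np.zeros((self.n, 3))
        self.cb_mask = np.zeros(self.n, dtype=bool)
        for i in range(1, self.n + 1):
            if self.sequence[i - 1] == "GLY":
                continue
            cb = t.coord(i, "CB")
            if cb is None:
                cb = rebuilt.coord(i, "CB")
            self.cb_ref[i - 1] = cb
            self.cb_mask[i - 1] = True
        self.h_ref = np.full((self.n, 3), np.nan)
        self.o_ref = np.full((self.n, 3), np.nan)
        for i in range(1, self.n + 1):
            h = rebuilt.coord(i, "H")
            o = rebuilt.coord(i, "O")
            if h is not None:
                self.h_ref[i - 1] = h
            if o is not None:
                self.o_ref[i - 1] = o
        self.hbonds = detect_hbonds(rebuilt)
        participating = self.hbonds.participating_atoms()
        self.h_mask = np.array([(i, "H") in participating for i in range(1, self.n + 1)])
        self.o_mask = np.array([(i, "O") in participating for i in range(1, self.n + 1)])
        tors = extract_torsions(t)
        self.phi0 = np.array([math.nan if x is None else x for x in tors.phi])
        self.psi0 = np.array([math.nan if x is None else x for x in tors.psi])
        self.omega0 = np.array([math.nan if x is None else x for x in tors.omega])
        self.ideal = ideal

    # interior residues scored by the Ramachandran term
    def scored_residues(self) -> range:
        return range(2, self.n)

    def breakdown_of(self, candidate: Structure) -> ScoreBreakdown:
        """Monolithic S_BB breakdown of a candidate backbone against the
        target; independent of the DP's incremental bookkeeping."""
        if candidate.n_residues != self.n:
            raise IdealizeError("candidate/target residue count mismatch")
        b = ScoreBreakdown(weights=self.weights, span=(1, 3 * self.n))
        rebuilt = rebuild_dependent_atoms(candidate.select(("N", "CA", "C")), self.ideal)

        def dep(i, nm):  # candidate's own atom if deposited, else rebuilt
            c = candidate.coord(i, nm)
            return c if c is not None else rebuilt.coord(i, nm)

        tors = extract_torsions(candidate)
        for i in range(1, self.n + 1):
            ca = candidate.coord(i, "CA")
            b.sq["alpha"] += float(np.sum((ca - self.ca0[i - 1]) ** 2))
            b.n["alpha"] += 1
            if self.cb_mask[i - 1]:
                b.sq["beta"] += float(np.sum((dep(i, "CB") - self.cb_ref[i - 1]) ** 2))
                b.n["beta"] += 1
            if self.h_mask[i - 1]:
                b.sq["hbond"] += float(np.sum((dep(i, "H") - self.h_ref[i - 1]) ** 2))
                b.n["hbond"] += 1
            if self.o_mask[i - 1]:
                b.sq["hbond"] += float(np.sum((dep(i, "O") - self.o_ref[i - 1]) ** 2))
                b.n["hbond"] += 1
        for i in self.scored_residues():
            phi, psi = tors.phi[i - 1], tors.psi[i - 1]
            b.logodds_sum += rama_log_odds(self.rama, self.sequence[i - 1], phi, psi)
            # angular deviations enter in radians, commensurate with the
            # Angstrom-scale distance terms
            dphi = math.radians(wrap_deg(phi - self.phi0[i - 1]))
            dpsi = math.radians(wrap_deg(psi - self.psi0[i - 1]))
            b.sq["phipsi"] += float(dphi**2 + dpsi**2)
            b.n["phipsi"] += 2
        return b


# -- side chains -----------------------------------------------------------

def sidechain_atoms(s: Structure, residue_index: int) -> dict[str, np.ndarray]:
    """Non-hydrogen side-chain atoms (CB outward) of one residue."""
    out = {}
    for a in s.atoms:
        if a.residue_index == residue_index and a.name not in BACKBONE_NAMES:
            if not a.name.startswith("H"):
                out[a.name] = a.coord
    return out


def sidechain_score(
    candidate: Structure,
    target: Structure,
    residue_index: int,
    table: RotamerTable,
    phi: float | None = None,
    psi: float | None = None,
    weights: tuple[float, float] = (1.0, 1.0),
) -> float:
    """S_SC = S_f(chi log-odds) - w1*(RMSD of non-H side-chain atoms)
    - w2*(RMSD of wrapped chi differences), frame-fixed.

    Distance terms use only the atoms/chis present in the target (missing
    target side chains leave the free-energy term alone).
    """
    res = candidate.sequence[residue_index - 1]
    chis_c = _residue_chis(candidate, residue_index, res)
    if chis_c is None or len(CHI_ATOMS[res]) == 0:
        return 0.0
    return score_sidechain_parts(
        res, chis_c, sidechain_atoms(candidate, residue_index),
        sidechain_atoms(target, residue_index),
        _residue_chis(target, residue_index, res), table, phi, psi, weights,
    )


def score_sidechain_parts(res, chis_c, cand_sc, targ_sc, chis_t, table,
                          phi, psi, weights=(1.0, 1.0)) -> float:
    """S_SC from pre-extracted parts (shared by the chi-grid search)."""
    sf = chi_log_odds(table, res, phi, psi, chis_c)
    common = sorted(set(cand_sc) & set(targ_sc))
    d_h = 0.0
    if common:
        d2 = [np.sum((cand_sc[nm] - targ_sc[nm]) ** 2) for nm in common]
        d_h = math.sqrt(float(np.mean(d2)))
    d_chi = 0.0
    if chis_t:
        kk = min(len(chis_c), len(chis_t))
        diffs = np.radians(wrap_deg(np.asarray(chis_c[:kk]) - np.asarray(chis_t[:kk])))
        d_chi = math.sqrt(float(np.mean(diffs**2)))
    return sf - weights[0] * d_h - weights[1] * d_chi


def _residue_chis(s: Structure, residue_index: int, res: str):
    from .geometry import dihedral

    chis = []
    for quad in CHI_ATOMS[res]:
        pts = [s.coord(residue_index, nm) for nm in quad]
        if any(p is None for p in pts):
            return chis if chis else None
        chis.append(dihedral(*pts))
    return chis
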