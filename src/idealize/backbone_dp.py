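"""Tail-grid dynamic program over idealized backbone candidates.

Candidates are grown atom by atom (N, CA, C, N, ...) with exactly ideal
bond lengths and angles, so the only freedom at each step is a torsion:

* the first atom ranges over an eps-spaced lattice within radius r of the
  target's first N (the radius constrains the first atom only; later atoms
  are constrained implicitly through chain geometry);
* the second atom samples the ideal-bond-length sphere at ~eps arc spacing;
* every subsequent N and C sweeps its ideal-geometry circle at ~eps arc
  spacing (a free Psi or Phi torsion);
* every CA is fixed by rounding the peptide Omega to 180 (trans) or 0
  (cis) -- cis is tried for proline always, and for other residues only
  when the target's own Omega is near 0.

Prefixes are scored incrementally with the additive ScoreBreakdown; two
prefixes whose last k atoms (default 5, enough to cover a complete
(Phi,Psi) pair) fall in the same eps-lattice cells are interchangeable, so
only the best one is kept per tail signature, and an additional top-m
filter keeps the beam bounded.  Coordinates are exact ideal-geometry
points; the lattice (anchored at the target's first N) is used only
for keying and deduplication.

All ties are broken lexicographically (tail key, then generation order),
so identical inputs give bit-identical outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import IdealizeError
from .geometry import (
    IdealGeometryTable,
    default_ideal_table,
    dihedral,
    place_cb,
    place_next_atom,
    rebuild_dependent_atoms,
)
from .pdb_io import Structure, structure_from_arrays
from .rama_stats import RamachandranTable, angle_bin
from .scoring import ScoreBreakdown, ScoringContext

log = logging.getLogger(__name__)

_METRIC_IDX = {"alpha": 1, "beta": 2, "hbond": 3, "phipsi": 4}


@dataclass
class DPParams:
    """Search-space and beam parameters (defaults per the method)."""

    r: float = 1.6
    eps: float = 0.32
    m: int | None = 50_000
    k: int = 5
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    cis_window: float = 30.0
    exact_tails: bool = False

    def __post_init__(self):
        if self.r < self.eps:
            raise IdealizeError("search radius r must be >= grid size eps")
        if self.k < 5 and not self.exact_tails:
            raise IdealizeError("tail length k must be >= 5")


@dataclass
class BeamEntry:
    """One DP state: a generated prefix, its score breakdown, and the
    grid-cell signature of its last k atoms."""

    coords: np.ndarray
    breakdown: ScoreBreakdown
    tail_key: tuple


def sweep_count(length: float, angle: float, eps: float) -> int:
    """Number of arc-spacing ~eps samples on the ideal-geometry circle of
    radius length*sin(angle)."""
    rho = length * math.sin(math.radians(angle))
    return max(int(math.ceil(2.0 * math.pi * rho / eps)), 2)


def _sweep(length: float, angle: float, eps: float) -> np.ndarray:
    c = sweep_count(length, angle, eps)
    return -180.0 + 360.0 * np.arange(c) / c


def step_spec(sequence, t: int, ideal: IdealGeometryTable, eps: float,
              target_omega=None, cis_window: float = 30.0):
    """(bond length, bond angle, torsion grid) for backbone atom t >= 4.

    t indexes N1,CA1,C1,N2,... (1-based).  N and C steps sweep the full
    circle; CA steps take Omega in {180} or {0, 180}.
    """
    i = (t + 2) // 3
    kind = (t - 1) % 3  # 0=N, 1=CA, 2=C
    res, prev = sequence[i - 1], sequence[i - 2]
    if kind == 0:
        L, ang = ideal.bond("C-N", res), ideal.angle("CA-C-N", prev)
        return L, ang, _sweep(L, ang, eps)
    if kind == 1:
        L, ang = ideal.bond("N-CA", res), ideal.angle("C-N-CA", res)
        torsions = [180.0]
        om0 = None if target_omega is None else target_omega[i - 2]
        if res == "PRO" or (om0 is not None and np.isfinite(om0) and abs(om0) <= cis_window):
            torsions = [0.0, 180.0]
        return L, ang, np.array(torsions)
    L, ang = ideal.bond("CA-C", res), ideal.angle("N-CA-C", res)
    return L, ang, _sweep(L, ang, eps)


def extend_candidates(prefix_coords: np.ndarray, sequence, t: int,
                      ideal: IdealGeometryTable, eps: float,
                      target_omega=None, cis_window: float = 30.0) -> np.ndarray:
    """Candidate coordinates for atom t given prefixes of t-1 atoms.

    ``prefix_coords`` is (..., t-1, 3); returns (..., C, 3) where C is the
    torsion-grid size of the step.  Every candidate satisfies the ideal
    bond length and angle by construction.
    """
    prefix_coords = np.asarray(prefix_coords, float)
    single = prefix_coords.ndim == 2
    if single:
        prefix_coords = prefix_coords[None]
    L, ang, torsions = step_spec(sequence, t, ideal, eps, target_omega, cis_window)
    a = prefix_coords[:, -3][:, None]
    b = prefix_coords[:, -2][:, None]
    c = prefix_coords[:, -1][:, None]
    out = place_next_atom(a, b, c, L, ang, torsions[None, :])
    return out[0] if single else out


# -- seeding ---------------------------------------------------------------

def lattice_points_in_ball(center: np.ndarray, anchor: np.ndarray,
                           r: float, eps: float) -> np.ndarray:
    """All eps-lattice points (anchored at ``anchor``) within r of center."""
    lo = np.floor((center - r - anchor) / eps).astype(int)
    hi = np.ceil((center + r - anchor) / eps).astype(int)
    axes = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    pts = anchor + eps * grid
    keep = np.linalg.norm(pts - center, axis=1) <= r
    pts = pts[keep]
    if len(pts) == 0:  # degenerate r ~ eps: fall back to the nearest point
        nearest = anchor + eps * np.round((center - anchor) / eps)
        pts = nearest[None]
    return pts


def fibonacci_sphere(n: int) -> np.ndarray:
    """n deterministic, nearly uniform unit vectors."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=-1)


def _circle_dirs(axis_unit: np.ndarray, angle: float, torsions: np.ndarray) -> np.ndarray:
    """Directions making ``angle`` with axis_unit, swept around it."""
    g = np.array([1.0, 1.0, 1.0]) / math.sqrt(3.0)
    if abs(float(np.dot(axis_unit, g))) > 0.99:
        g = np.array([1.0, 0.0, 0.0])
    f1 = np.cross(axis_unit, g)
    f1 /= np.linalg.norm(f1)
    f2 = np.cross(axis_unit, f1)
    th = math.radians(angle)
    tau = np.radians(torsions)
    return (math.cos(th) * axis_unit[None]
            + math.sin(th) * (np.cos(tau)[:, None] * f1[None]
                              + np.sin(tau)[:, None] * f2[None]))


def seed_candidates(target: Structure, r: float, eps: float,
                    ideal: IdealGeometryTable | None = None) -> np.ndarray:
    """Enumerate all 3-atom prefixes (N1, CA1, C1): lattice ball x ideal
    sphere x ideal circle.  Returns (K, 3, 3).  Intended for coarse eps;
    the DP interleaves pruning instead of calling this."""
    ideal = ideal or default_ideal_table()
    if r < eps:
        raise IdealizeError("r must be >= eps")
    res1 = target.sequence[0]
    anchor = np.asarray(target.coord(1, "N"), float)
    n1 = target.coord(1, "N")
    p1 = lattice_points_in_ball(n1, anchor, r, eps)
    L2 = ideal.bond("N-CA", res1)
    dirs = fibonacci_sphere(max(int(math.ceil(4.0 * math.pi * (L2 / eps) ** 2)), 2))
    p2 = p1[:, None, :] + L2 * dirs[None]  # (K1, K2, 3)
    L3, ang3 = ideal.bond("CA-C", res1), ideal.angle("N-CA-C", res1)
    torsions = _sweep(L3, ang3, eps)
    prefixes = []
    for i in range(p2.shape[0]):
        for j in range(p2.shape[1]):
            axis = (p1[i] - p2[i, j]) / L2
            d3 = p2[i, j] + L3 * _circle_dirs(axis, ang3, torsions)
            for c3 in d3:
                prefixes.append((p1[i], p2[i, j], c3))
    return np.array(prefixes)


# -- the dynamic program ---------------------------------------------------

class _Beam:
    """Vectorized beam state: coords (M,t,3), accumulator (M,5)
    [logodds, sq_alpha, sq_beta, sq_hbond, sq_phipsi], tail cells (M,k,3)."""

    def __init__(self, coords, acc, counts, anchor, eps, k, exact):
        self.coords = coords
        self.acc = acc
        self.counts = counts  # dict metric -> int, shared by all entries
        self.anchor = anchor
        self.eps = eps
        self.k = k
        self.exact = exact

    def scores(self, weights) -> np.ndarray:
        s = self.acc[:, 0].copy()
        for m_name, col in _METRIC_IDX.items():
            cnt = self.counts[m_name]
            if cnt:
                s -= weights[col - 1] * np.sqrt(self.acc[:, col] / cnt)
        return s

    def tail_cells(self) -> np.ndarray:
        t = self.coords.shape[1]
        tail = self.coords[:, -min(self.k, t):]
        return np.floor((tail - self.anchor) / self.eps).astype(np.int64)


def _radius_filter(coords, acc, center_atom, r):
    """Generation constraint: drop candidates whose newest atom lies more
    than r from the generation center's corresponding atom.  Falls back to
    the nearest candidate if the bound would empty the beam."""
    dev = np.linalg.norm(coords[:, -1] - center_atom, axis=1)
    keep = dev <= r
    if not np.any(keep):
        log.warning("radius bound %.2f A empty; keeping nearest candidate", r)
        keep = dev == dev.min()
    return coords[keep], acc[keep]


def _select(coords, acc, counts, anchor, eps, k, weights, m, exact):
    """Deduplicate by tail key (unless exact) and keep the top-m entries.

    Ordering rules: per key, highest score wins, ties to the earliest
    generated; the beam cut orders by score, then key, then order.
    """
    M = coords.shape[0]
    t = coords.shape[1]
    tail = np.floor((coords[:, -min(k, t):] - anchor) / eps).astype(np.int64)
    keys = tail.reshape(M, -1)
    score = np.zeros(M)
    score += acc[:, 0]
    for m_name, col in _METRIC_IDX.items():
        cnt = counts[m_name]
        if cnt:
            score -= weights[col - 1] * np.sqrt(acc[:, col] / cnt)
    order = np.arange(M)
    if not exact:
        sort_keys = (order, -score) + tuple(keys[:, j] for j in range(keys.shape[1] - 1, -1, -1))
        idx = np.lexsort(sort_keys)
        sk = keys[idx]
        first = np.ones(len(idx), dtype=bool)
        first[1:] = np.any(sk[1:] != sk[:-1], axis=1)
        idx = idx[first]
        coords, acc, keys, score, order = (
            coords[idx], acc[idx], keys[idx], score[idx], order[idx])
    if m is not None and coords.shape[0] > m:
        sort_keys = (order,) + tuple(keys[:, j] for j in range(keys.shape[1] - 1, -1, -1)) + (-score,)
        idx = np.lexsort(sort_keys)[:m]
        coords, acc, score = coords[idx], acc[idx], score[idx]
    return coords, acc, score


def dp_idealize(
    target: Structure,
    rama: RamachandranTable,
    params: DPParams | None = None,
    seed_center: Structure | None = None,
) -> tuple[Structure, ScoreBreakdown]:
    """Find an approximately optimal idealized backbone for ``target``.

    Scoring is always against ``target``; ``seed_center`` (for the
    refinement loop) recenters candidate generation -- the first-atom ball
    and the cis/trans decision -- on a different structure.  Returns the
    traceback of the best final beam entry with O/H/CB rebuilt, plus its
    score breakdown.
    """
    params = params or DPParams()
    if target.n_residues < 2:
        raise IdealizeError("need at least 2 residues")
    ctx = ScoringContext(target, rama, params.weights)
    center = seed_center if seed_center is not None else target
    seq = ctx.sequence
    n = ctx.n
    ideal = ctx.ideal
    eps, k, weights = params.eps, params.k, params.weights
    anchor = np.asarray(target.coord(1, "N"), float)
    from .geometry import extract_torsions as _ext

    omega_gen = np.array(
        [math.nan if x is None else x for x in _ext(center).omega]
    )
    lo_grids = {aa: rama.log_odds_grid(aa) for aa in set(seq)}
    counts = {m: 0 for m in _METRIC_IDX}

    center_bb = center.backbone_coords()

    # --- seed: atom 1 (N1 lattice ball around the generation center) ---
    p1 = lattice_points_in_ball(center.coord(1, "N"), anchor, params.r, eps)
    coords = p1[:, None, :]
    acc = np.zeros((len(p1), 5))
    coords, acc, _ = _select(coords, acc, counts, anchor, eps, k, weights,
                             params.m, params.exact_tails)

    def grow(coords, acc, new_pts, new_terms):
        """Cross entries with candidates: (M,t,3)x(M,C,3) -> (M*C,t+1,3)."""
        M, C = new_pts.shape[:2]
        t = coords.shape[1]
        rep = np.repeat(coords, C, axis=0)
        ext = new_pts.reshape(M * C, 1, 3)
        out = np.concatenate([rep, ext], axis=1)
        acc2 = np.repeat(acc, C, axis=0)
        for col, vals in new_terms:
            acc2[:, col] += vals.reshape(M * C)
        return out, acc2

    # --- seed: atom 2 (CA1 on the ideal sphere) ---
    res1 = seq[0]
    L2 = ideal.bond("N-CA", res1)
    dirs = fibonacci_sphere(max(int(math.ceil(4.0 * math.pi * (L2 / eps) ** 2)), 2))
    cand = coords[:, 0][:, None, :] + L2 * dirs[None]
    d2 = np.sum((cand - ctx.ca0[0]) ** 2, axis=-1)
    coords, acc = grow(coords, acc, cand, [(1, d2)])
    coords, acc = _radius_filter(coords, acc, center_bb[1], params.r)
    counts["alpha"] += 1
    coords, acc, _ = _select(coords, acc, counts, anchor, eps, k, weights,
                             params.m, params.exact_tails)

    # --- seed: atom 3 (C1 on the ideal circle) ---
    L3, ang3 = ideal.bond("CA-C", res1), ideal.angle("N-CA-C", res1)
    torsions3 = _sweep(L3, ang3, eps)
    axis = (coords[:, 0] - coords[:, 1]) / L2
    cand = np.stack(
        [coords[i, 1] + L3 * _circle_dirs(axis[i], ang3, torsions3)
         for i in range(coords.shape[0])]
    )
    terms = []
    if ctx.cb_mask[0]:
        cb = place_cb(coords[:, 0][:, None], coords[:, 1][:, None], cand, ideal, res1)
        terms.append((2, np.sum((cb - ctx.cb_ref[0]) ** 2, axis=-1)))
        counts["beta"] += 1
    coords, acc = grow(coords, acc, cand, terms)
    coords, acc = _radius_filter(coords, acc, center_bb[2], params.r)
    coords, acc, _ = _select(coords, acc, counts, anchor, eps, k, weights,
                             params.m, params.exact_tails)

    # --- main sweep: atoms 4 .. 3n ---
    for t in range(4, 3 * n + 1):
        i = (t + 2) // 3
        kind = (t - 1) % 3
        res, prev = seq[i - 1], seq[i - 2]
        L, ang, torsions = step_spec(seq, t, ideal, eps, omega_gen, params.cis_window)
        a = coords[:, -3][:, None]
        b = coords[:, -2][:, None]
        c = coords[:, -1][:, None]
        cand = place_next_atom(a, b, c, L, ang, torsions[None, :])
        M, C = cand.shape[:2]
        terms = []
        if kind == 0:
            if ctx.o_mask[i - 2]:
                # carbonyl O of residue i-1 becomes defined: torsion is Psi_{i-1}
                o = place_next_atom(a, b, c, ideal.bond("C-O"),
                                    ideal.angle("CA-C-O", prev),
                                    (torsions[None, :] + 180.0))
                terms.append((3, np.sum((o - ctx.o_ref[i - 2]) ** 2, axis=-1)))
                counts["hbond"] += 1
            if 2 <= i - 1 <= n - 1:
                # the sweep torsion IS Psi_{i-1}: both its deviation term
                # and the (Phi,Psi) log-odds of residue i-1 (Phi is already
                # fixed in the prefix) are emitted here, at the atom that
                # completes the pair -- zero-latency feedback for the beam
                dpsi = np.radians((torsions - ctx.psi0[i - 2] + 180.0) % 360.0 - 180.0)
                terms.append((4, np.broadcast_to(dpsi[None, :] ** 2, (M, C))))
                counts["phipsi"] += 1
                phi = np.atleast_1d(dihedral(coords[:, t - 5], coords[:, t - 4],
                                             coords[:, t - 3], coords[:, t - 2]))
                lo = lo_grids[seq[i - 2]][angle_bin(phi)[:, None],
                                          angle_bin(torsions)[None, :]]
                terms.append((0, np.broadcast_to(lo, (M, C))))
        elif kind == 1:
            d2 = np.sum((cand - ctx.ca0[i - 1]) ** 2, axis=-1)
            terms.append((1, d2))
            counts["alpha"] += 1
            if ctx.h_mask[i - 1]:
                # amide H of residue i: torsion is Omega + 180
                h = place_next_atom(a, b, c, ideal.bond("N-H"),
                                    ideal.angle("C-N-H"),
                                    (torsions[None, :] + 180.0))
                terms.append((3, np.sum((h - ctx.h_ref[i - 1]) ** 2, axis=-1)))
                counts["hbond"] += 1
        elif kind == 2:
            if ctx.cb_mask[i - 1]:
                cb = place_cb(coords[:, t - 3][:, None], coords[:, t - 2][:, None],
                              cand, ideal, res)
                terms.append((2, np.sum((cb - ctx.cb_ref[i - 1]) ** 2, axis=-1)))
                counts["beta"] += 1
            if 2 <= i <= n - 1:
                # the sweep torsion IS Phi_i
                dphi = np.radians((torsions - ctx.phi0[i - 1] + 180.0) % 360.0 - 180.0)
                terms.append((4, np.broadcast_to(dphi[None, :] ** 2, (M, C))))
                counts["phipsi"] += 1
        coords, acc = grow(coords, acc, cand, terms)
        coords, acc = _radius_filter(coords, acc, center_bb[t - 1], params.r)
        coords, acc, score = _select(coords, acc, counts, anchor, eps, k,
                                     weights, params.m, params.exact_tails)
        if coords.shape[0] == 0:
            raise IdealizeError(f"beam exhausted at atom {t}")

    # --- traceback: the stored prefix of the best final entry ---
    score = _Beam(coords, acc, counts, anchor, eps, k, params.exact_tails).scores(weights)
    tail = np.floor((coords[:, -min(k, coords.shape[1]):] - anchor) / eps)
    keys = tail.reshape(coords.shape[0], -1).astype(np.int64)
    order = np.arange(coords.shape[0])
    idx = np.lexsort((order,) + tuple(keys[:, j] for j in range(keys.shape[1] - 1, -1, -1))
                     + (-score,))[0]
    best = coords[idx]
    triples = []
    for i in range(1, n + 1):
        for j, nm in enumerate(("N", "CA", "C")):
            triples.append((i, nm, best[3 * (i - 1) + j]))
    bb = structure_from_arrays(list(seq), triples, chain_id=target.chain_id)
    out = rebuild_dependent_atoms(bb, ideal)
    breakdown = ScoreBreakdown(
        logodds_sum=float(acc[idx, 0]),
        sq={m_name: float(acc[idx, col]) for m_name, col in _METRIC_IDX.items()},
        n=dict(counts),
        weights=weights,
        span=(1, 3 * n),
    )
    return out, breakdown
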