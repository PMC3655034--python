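"""Probability tables behind the free-energy scores.

Two tables are served here:

* :class:`RamachandranTable` -- one 360x360 grid of (Phi,Psi) bin
  probabilities per amino-acid type (1-degree bins over (-180,180]^2,
  pseudocounted so every bin has positive mass).  The backbone free-energy
  term is the natural-log odds of the observed bin against a uniform null
  of 1/129600 per bin.

* :class:`RotamerTable` -- side-chain chi statistics: per residue type
  (optionally conditioned on a 10-degree backbone (Phi,Psi) bin, as in
  Dunbrack-style backbone-dependent libraries) a list of rotamers, each
  with per-chi mean, per-chi sigma and a probability.  The side-chain
  free-energy term is the log of the matched rotamer's probability times
  its per-chi Gaussian densities, against a uniform null density per chi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import IdealizeError
from .geometry import extract_torsions, wrap_deg
from .residues import STANDARD_RESIDUES, n_chi

N_BINS = 360
N_CELLS = N_BINS * N_BINS  # 129600


def angle_bin(x) -> np.ndarray:
    """1-degree half-open bin index: angle in [k, k+1) -> k + 180."""
    x = np.asarray(wrap_deg(x), dtype=float)
    # wrap_deg maps to (-180, 180]; fold the single point +180 onto -180
    x = np.where(x >= 180.0, -180.0, x)
    return np.floor(x).astype(int) + 180


@dataclass
class RamachandranTable:
    """Per-amino-acid (Phi,Psi) bin probabilities."""

    grids: dict[str, np.ndarray]
    pseudocount: float = 1.0
    description: str = ""
    _log_odds: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def grid(self, aa: str) -> np.ndarray:
        if aa not in self.grids:
            raise IdealizeError(f"no Ramachandran grid for {aa!r}")
        return self.grids[aa]

    def log_odds_grid(self, aa: str) -> np.ndarray:
        """ln(P / (1/129600)) for every bin; cached per type."""
        if aa not in self._log_odds:
            self._log_odds[aa] = np.log(self.grid(aa) * N_CELLS)
        return self._log_odds[aa]

    def validate(self) -> None:
        for aa, g in self.grids.items():
            if g.shape != (N_BINS, N_BINS):
                raise IdealizeError(f"{aa}: bad grid shape {g.shape}")
            if not np.all(g > 0):
                raise IdealizeError(f"{aa}: non-positive probability")
            if abs(float(g.sum()) - 1.0) > 1e-9:
                raise IdealizeError(f"{aa}: grid sums to {g.sum()}")

    def save(self, path) -> None:
        np.savez(path, pseudocount=self.pseudocount, description=self.description,
                 **{f"grid_{aa}": g for aa, g in self.grids.items()})

    @classmethod
    def load(cls, path) -> "RamachandranTable":
        with np.load(path, allow_pickle=False) as z:
            grids = {k[5:]: z[k].copy() for k in z.files if k.startswith("grid_")}
            return cls(grids, float(z["pseudocount"]), str(z["description"]))


def uniform_rama_table() -> RamachandranTable:
    """Every bin 1/129600 for every standard residue type (null model)."""
    g = np.full((N_BINS, N_BINS), 1.0 / N_CELLS)
    return RamachandranTable({aa: g.copy() for aa in STANDARD_RESIDUES},
                             description="uniform")


def build_rama_table(structures, pseudocount: float = 1.0,
                     description: str = "") -> RamachandranTable:
    """Count interior-residue (Phi,Psi) pairs per amino-acid type and
    normalize with ``pseudocount`` added to every bin.

    Types with zero observations get the pseudocount-only (uniform) grid.
    """
    structures = list(structures)
    if not structures:
        raise IdealizeError("no structures to train on")
    counts = {aa: np.zeros((N_BINS, N_BINS)) for aa in STANDARD_RESIDUES}
    n_obs = 0
    for s in structures:
        tors = extract_torsions(s)
        seq = s.sequence
        for i in range(s.n_residues):
            if tors.phi[i] is None or tors.psi[i] is None:
                continue
            counts[seq[i]][angle_bin(tors.phi[i]), angle_bin(tors.psi[i])] += 1
            n_obs += 1
    if n_obs == 0:
        raise IdealizeError("no defined (Phi,Psi) pair in the training set")
    grids = {}
    for aa, c in counts.items():
        c = c + pseudocount
        grids[aa] = c / c.sum()
    return RamachandranTable(grids, pseudocount, description)


def rama_log_odds(table: RamachandranTable, aa: str, phi, psi):
    """ln P_aa(bin(phi,psi)) - ln(1/129600).  Broadcasts over angles."""
    phi, psi = np.asarray(phi, float), np.asarray(psi, float)
    if np.any(~np.isfinite(phi)) or np.any(~np.isfinite(psi)):
        raise IdealizeError("undefined (Phi,Psi) passed to rama_log_odds")
    lo = table.log_odds_grid(aa)[angle_bin(phi), angle_bin(psi)]
    return lo if np.ndim(lo) else float(lo)


# -- rotamers --------------------------------------------------------------

@dataclass
class Rotamer:
    means: tuple[float, ...]
    sigmas: tuple[float, ...]
    probability: float


@dataclass
class RotamerTable:
    """Rotamer lists per residue type, optionally per 10-degree (Phi,Psi)
    backbone bin (key ``None`` holds backbone-independent entries)."""

    entries: dict[str, dict[tuple[int, int] | None, list[Rotamer]]]
    backbone_dependent: bool = False
    description: str = ""

    def rotamers_for(self, aa: str, phi: float | None = None,
                     psi: float | None = None) -> list[Rotamer]:
        if aa not in self.entries:
            raise IdealizeError(f"no rotamers for residue type {aa!r}")
        table = self.entries[aa]
        if self.backbone_dependent and phi is not None and psi is not None:
            key = (_bb_bin(phi), _bb_bin(psi))
            if key in table:
                return table[key]
        if None in table:
            return table[None]
        # backbone-dependent table queried without angles: fall back to the
        # probability-weighted pool of the (-60,-40) helical bin, else any
        return table.get((-60, -40)) or next(iter(table.values()))

    def validate(self) -> None:
        for aa, by_bin in self.entries.items():
            k = n_chi(aa)
            for key, rots in by_bin.items():
                total = sum(r.probability for r in rots)
                if abs(total - 1.0) > 1e-6:
                    raise IdealizeError(f"{aa}{key}: probabilities sum to {total}")
                for r in rots:
                    if len(r.means) < k or any(s <= 0 for s in r.sigmas):
                        raise IdealizeError(f"{aa}{key}: bad rotamer {r}")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# rotamer table: {self.description}\n")
            fh.write(f"backbone_dependent {int(self.backbone_dependent)}\n")
            for aa, by_bin in sorted(self.entries.items()):
                for key, rots in sorted(by_bin.items(), key=lambda kv: (kv[0] is not None, kv[0])):
                    for r in rots:
                        bin_s = "-" if key is None else f"{key[0]},{key[1]}"
                        ms = " ".join(repr(x) for pair in zip(r.means, r.sigmas) for x in pair)
                        fh.write(f"{aa} {bin_s} {r.probability!r} {ms}\n")

    @classmethod
    def load(cls, path_or_text) -> "RotamerTable":
        if hasattr(path_or_text, "read"):
            lines = path_or_text.read().splitlines()
        else:
            with open(path_or_text) as fh:
                lines = fh.read().splitlines()
        entries: dict = {}
        bbdep = False
        for line in lines:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("backbone_dependent"):
                bbdep = bool(int(line.split()[1]))
                continue
            parts = line.split()
            aa, bin_s, prob = parts[0], parts[1], float(parts[2])
            vals = [float(x) for x in parts[3:]]
            key = None if bin_s == "-" else tuple(int(x) for x in bin_s.split(","))
            rot = Rotamer(tuple(vals[0::2]), tuple(vals[1::2]), prob)
            entries.setdefault(aa, {}).setdefault(key, []).append(rot)
        return cls(entries, bbdep)


def _bb_bin(angle: float) -> int:
    """Nearest multiple of 10 degrees, folded into [-180, 170]."""
    b = int(round(wrap_deg(angle) / 10.0)) * 10
    return -180 if b >= 180 else b


def fallback_rotamer_table() -> RotamerTable:
    """The packaged coarse backbone-independent rotamer table."""
    from importlib import resources

    ref = resources.files("idealize.data") / "rotamers_fallback.txt"
    table = RotamerTable.load(ref.open())
    table.description = "packaged coarse backbone-independent table"
    return table


def read_rotamer_library(path) -> RotamerTable:
    """Read a backbone-dependent rotamer library in the Dunbrack text
    format (columns: residue, phi, psi, count, r1-r4, probability, four
    chi means, four chi sigmas; '#' comments)."""
    entries: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 17:
                raise IdealizeError(f"short Dunbrack record: {line!r}")
            aa = parts[0].upper()
            if aa not in STANDARD_RESIDUES:
                continue
            phi, psi = int(float(parts[1])), int(float(parts[2]))
            prob = float(parts[8])
            means = tuple(float(x) for x in parts[9:13])
            sigmas = tuple(max(float(x), 1e-6) for x in parts[13:17])
            k = n_chi(aa)
            key = (_bb_bin(phi), _bb_bin(psi))
            entries.setdefault(aa, {}).setdefault(key, []).append(
                Rotamer(means[:k], sigmas[:k], prob)
            )
    if not entries:
        raise IdealizeError(f"no rotamer records found in {path}")
    # renormalize probabilities within each conditioning bin
    for by_bin in entries.values():
        for rots in by_bin.values():
            total = sum(r.probability for r in rots)
            if total > 0:
                for r in rots:
                    r.probability /= total
    return RotamerTable(entries, backbone_dependent=True, description=str(path))


def match_rotamer(rotamers: list[Rotamer], chis) -> Rotamer:
    """Nearest rotamer by summed squared wrapped distance of chi means."""
    chis = np.asarray(chis, float)
    best, best_d = None, math.inf
    for r in rotamers:
        d = float(np.sum(wrap_deg(chis - np.asarray(r.means[: len(chis)])) ** 2))
        if d < best_d:
            best, best_d = r, d
    return best


def chi_log_odds(table: RotamerTable, aa: str, phi, psi, chis) -> float:
    """ln( P(rotamer) * prod_j Normal(chi_j; mean_j, sigma_j) / null ),
    null = uniform density (1/360 per degree) per chi.  Rotamer matching is
    nearest-per-chi-mean under wrapped distance.  No-chi residues score 0.
    """
    from .residues import CHI_ATOMS

    if aa not in CHI_ATOMS:
        raise IdealizeError(f"unknown residue type {aa!r}")
    k = n_chi(aa)
    if k == 0:
        return 0.0
    chis = np.asarray(chis, float)
    if chis.size < k:
        raise IdealizeError(f"{aa} needs {k} chi angles, got {chis.size}")
    chis = chis[:k]
    r = match_rotamer(table.rotamers_for(aa, phi, psi), chis)
    log_dens = 0.0
    for x, mu, sig in zip(chis, r.means, r.sigmas):
        d = wrap_deg(x - mu)
        log_dens += -0.5 * (d / sig) ** 2 - math.log(sig * math.sqrt(2 * math.pi))
    return math.log(r.probability) + log_dens - k * math.log(1.0 / 360.0)
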