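# Methods

## Model

An *idealized* structure is one in which every covalent bond length and
bond angle equals its tabulated mean value, so the conformation is fully
determined by dihedral angles plus the rigid-body frame of the first
three atoms.  The packaged parameter table (`data/ideal_geometry.txt`)
transcribes the Engh & Huber stereochemical means with Gly/Pro overrides;
the amide N–H length (1.020 Å) is the conventional neutron-derived value
since X-ray surveys do not observe it.  Users may supply their own table;
every builder takes it as an argument.

Torsions follow the IUPAC sign convention in degrees: Φ = C–N–Cα–C,
Ψ = N–Cα–C–N, Ω = Cα–C–N–Cα, with Φ of the first and Ψ/Ω of the last
residue undefined.  Dependent atoms are deterministic functions of the
N/Cα/C trace: the carbonyl O in the peptide plane trans to the next N,
the amide H in the peptide plane anti to the next Cα (none for Pro), and
Cβ from the backbone frame with ideal N–Cα–Cβ / C–Cα–Cβ angles and
L-chirality (positive scalar triple product (N−Cα)×(C−Cα)·(Cβ−Cα)).
Terminal O and H are placed with the same in-plane rule at torsion 180°
using the only available neighbor; no OXT is built.  On heavily distorted
frames where both Cβ angles are unreachable, the nearest in-plane
direction is used — this arises only when rebuilding references on noisy
*targets*, never on generated candidates.

## Backbone score

S_BB = S_f − Σₐ wₐ·Dₐ with all weights 1.0 by default.

* **S_f** — for each interior residue, ln P_aa(Φ,Ψ) − ln(1/129600) on a
  per-amino-acid 360×360 grid of 1° bins (half-open, [k, k+1)°, with
  +180° folded onto −180°).  Natural log; any other base would rescale
  uniformly and be absorbed by the weights.  Grids are pseudocounted
  (default 1 per bin) so every bin has positive mass; types with no
  observations degrade to the uniform null and score ≈ 0.
* **D_α, D_β** — frame-fixed RMSDs (no superposition; candidates are
  generated in the target's frame, and superposition would break the
  additivity below) over Cα and Cβ atoms.  The reference Cβ is the
  target's own atom where deposited, rebuilt from its backbone otherwise;
  Gly contributes nothing.
* **D_H** — hydrogen bonds are detected once on the target (rebuilt O/H)
  with the Kabsch–Sander electrostatic model,
  E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, keeping
  pairs with E < −0.5 and |i−j| ≥ 2.  Donors are amide N–H of residues
  2..n (Pro excluded; the N-terminal amine is chemically an NH₃⁺, not an
  amide), acceptors carbonyl C=O of residues 1..n−1 (the terminal
  carboxylate is excluded).  The participating H/O atom set is then held
  fixed and D_H is the frame-fixed RMSD of the candidate's corresponding
  rebuilt atoms against the target's — comparing a fixed atom set keeps
  the term additive; re-detecting bonds per candidate would not be.
* **D_{Φ,Ψ}** — RMSD of wrapped (Φ, Ψ) differences over interior
  residues, **in radians**.  The unit is a deliberate modeling choice: in
  degrees the angle term (tens of units on any realistic target) would
  dominate every Å-scale term and the log-odds, pinning the optimum to
  the target's exact torsions and making it impossible for idealization
  to move angles toward favored Ramachandran regions — behavior the
  method is expected to show on poor structures.  Radians put the term on
  the same numeric scale as the distance metrics.  Reports print degrees
  alongside.  An empty selection (e.g. no hydrogen bonds) contributes 0,
  the neutral element of the sum.

Every term is carried as (sum of squares, count) plus a log-odds sum
(`ScoreBreakdown`), making the score additive over disjoint contiguous
segments: sums and counts add and the combined RMSD is
√((r₁²n₁ + r₂²n₂)/(n₁+n₂)).  The suite verifies the additive path against
monolithic scoring to 1e-9.

## The dynamic program

Candidates are grown atom by atom (N, Cα, C, N, …) with exactly ideal
geometry, so each step's only freedom is one torsion:

* atom 1: ε-lattice points (lattice anchored at the target's first N, so
  that atom is itself a candidate) within radius r of the generation
  center's first N;
* atom 2: a deterministic Fibonacci sampling of the ideal-bond-length
  sphere at ~ε arc spacing;
* N and C atoms: the ideal-geometry circle swept at ~ε arc spacing
  (⌈2πρ/ε⌉ samples, ρ = ℓ·sin of the bond angle) — these torsions *are*
  Ψ and Φ;
* Cα atoms: Ω rounded to 180°, plus 0° for proline or when the target's
  own Ω is within 30° of cis (unrestricted cis doubling would waste
  beam).

Every placed atom additionally respects the generation bound
‖Pᵗ − P₀ᵗ‖ ≤ r against the generation center (nearest candidate kept if
a step would otherwise empty).  Enforcing the bound for *all* atoms, not
just the first, is what makes the shrinking refinement a trust region:
without it the fine-grid iterations trade ~1–2 Å of positional drift for
log-odds and move away from the target.

Score terms are emitted at the step that fixes them, so the beam cut is
never made on stale information: the Ψ deviation and the (Φ,Ψ) log-odds
at the N step that completes the pair (Φ is already in the prefix; Ψ is
the sweep torsion, so the grid lookup vectorizes over entries ×
candidates), the Φ deviation at the C step, the Cα deviation and the
H-bond H term at the Cα step, the H-bond O term at the following N step,
and the Cβ term at the C step.  All items needed live within the last
six atoms, which is why tails of k = 5 atoms — the minimum that spans a
complete (Φ,Ψ) pair — suffice.

Two prefixes whose last k atoms fall in the same ε-lattice cells are
interchangeable up to ε per atom; the DP keeps the best-scoring prefix
per tail-cell signature, then prunes to the top-m beam.  Coordinates are
never snapped to the lattice — it is purely a keying device; snapping
would destroy the ideal-geometry invariant.  All ties break
lexicographically (tail key, then generation order), making runs
bit-identical.  With pruning disabled (`exact_tails=True, m=None`) the
DP is an exhaustive enumeration and provably attains the brute-force
optimum; the suite checks this on 2-residue instances at coarse ε.

The implementation stores full prefix coordinates per beam entry
(vectorized as one (m, t, 3) array), which is simple and exact at the
problem sizes this package targets (tens of residues, m ≤ a few
thousand); a traceback table would be needed for m = 50 000 on
200-residue chains.

## Side chains

With the backbone fixed, residues are independent (no inter-residue
clash term — that is the method's independence assumption, and its known
cost).  Per residue, every rotamer of the backbone (Φ,Ψ) bin contributes
a χ grid: mean ± 3σ in 10° steps per dimension (2⌊3σ/step⌋+1 samples).
Side-chain atoms are chained Z-matrix style from a per-residue topology
table with ideal lengths/angles; branch atoms ride their parent χ at
fixed offsets, ring and planar-group torsions are constants, and
arginine's Nη torsions are rounded to exactly 0°/180° (planar
guanidinium), capping the search dimension at four.  Candidates score
S_SC = S_f − w₁·D_H′ − w₂·D_χ with S_f the rotamer log-odds (matched
rotamer probability times per-χ Gaussian densities against a uniform
1/360-per-degree null per χ; nearest-mean matching under wrapped
distance), D_H′ the frame-fixed RMSD of non-hydrogen side-chain atoms
present in both candidate and target, and D_χ the wrapped-χ RMSD in
radians.  Missing target side chains drop the distance terms.  The
packaged backbone-independent rotamer table is a coarse round-number
summary of canonical gauche/trans preferences so the tool runs with no
download; a Dunbrack-format backbone-dependent library is read natively
and takes precedence when supplied.

## Refinement

Iteration j runs the backbone DP with (r, ε)·0.5^{j−1}, generation
centered on the previous iterate but *scored against the original
target* (the method's goal is similarity to the target, not to the
incumbent).  Because the shrunken, re-centered grids do not literally
contain the incumbent, monotonicity of S_BB is enforced explicitly: an
iteration that fails to improve by more than 1e-6 leaves the incumbent
in place and stops.  Side chains are idealized once after the final
backbone pass, with the χ window and step shrunk by the last accepted
factor (shrinking both together keeps the per-dimension sample count
constant).  Defaults: 3 iterations, factor 0.5.

## Synthetic data

The fixture generator provides the study conditions for all tests:
idealized poly-peptides at prescribed torsions (canonical helix
(−57, −47) and strand (−120, 130) presets), i.i.d. Gaussian coordinate
noise of σ = 0.3 Å (seeded) as the noisy "target" whose ideal ancestor
is known, and toy Ramachandran tables histogrammed from 20 000 sampled
(Φ,Ψ) pairs (65% helix basin with 8° spread, 35% strand basin with 14°,
matching observed basin widths; shared across residue types).  What this
emulates: coordinate-level noise of a pseudo-structure and a concentrated
torsion prior.  What it does not: sequence-specific Ramachandran
differences, correlated/anisotropic experimental error, secondary-
structure-dependent rotamer statistics, and crystallographic packing.
Passing tests therefore demonstrate the machinery (geometry invariants,
DP optimality, denoising under isotropic noise), not accuracy on real
crystal structures — for that, train a table with
`idealize stats build-rama` and supply a real rotamer library.

## Numerical choices and degenerate inputs

* Bin convention: half-open 1° bins, +180° folded onto −180°; the score
  is piecewise constant within a bin.
* Collinear/coincident frames raise a degenerate-geometry error rather
  than returning NaN; candidate generation cannot produce them (ideal
  angles are bounded away from 0/180°).
* Chain-gap tolerance: 2.0 Å C–N for splitting deposited files into
  fragments, 2.5 Å for rebuild sanity, 6.0 Å when rebuilding references
  on noisy pseudo-structure targets (σ = 0.3 Å noise stretches an
  occasional peptide bond past covalent range without implying a real
  break).
* The radius bound keeps the nearest candidate if it would empty a step,
  guaranteeing the DP always returns a structure.
* PDB output carries 0.001 Å precision; reports recomputed from written
  files can shift a bin-boundary log-odds term accordingly.
* Problem sizes in tests and the acceptance script (≤ 8 residues,
  m ≤ 2000, 2-residue exhaustive oracles at ε ≥ 1 Å) are chosen so each
  check runs in seconds while remaining non-trivial; the defaults
  r = 1.6 Å, ε = r/5, m = 50 000, k = 5, 10° χ grid, 3σ window and ×0.5
  schedule are the method's standard operating point.

## Known limitations

* No inter-residue side-chain packing or clash detection.
* cis/trans decisions follow the target; a genuinely mis-assigned Ω in
  the input will be reproduced.
* The k-atom-tail interchangeability is an approximation; counter-
  examples exist but are rare, and none is detected at run time.
* The divide-and-conquer/tree-decomposition variant and B-factor-
  dependent per-atom radii are not implemented.
* External free-energy programs (e.g. dDFIRE) and PROCHECK-style
  classification are out of scope; `evaluate` reports the package's own
  metrics only.
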