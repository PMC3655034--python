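# idealize — protein structure idealization in torsion space

High-resolution surveys show that covalent bond lengths and angles in
proteins cluster tightly around type-specific means (spreads of ~0.02 Å
and ~1.5–2.7°).  Fixing every bond length and angle at its mean ("ideal")
value leaves the dihedral angles as the only degrees of freedom: a
backbone is then fully described by (Φ, Ψ) with Ω rounded to 0°/180°, and
a side chain by up to four χ angles.  `idealize` answers the practical
question *how closely can a given structure be reproduced under that
constraint* — useful for structure-quality work, for refining
pseudo-structures (e.g. NMR models with poor Ramachandran statistics),
and for building torsion-space fragment or rotamer libraries.  It is
aimed at structural bioinformaticians comfortable with PDB files and
backbone dihedral conventions.

## The method

Given a target structure P₀, the tool searches for the idealized
structure P maximizing

```
S_BB(P) = S_f(P) − w₁·D_α(P,P₀) − w₂·D_β(P,P₀) − w₃·D_H(P,P₀) − w₄·D_{Φ,Ψ}(P,P₀)
```

where S_f is a Ramachandran log-odds free-energy term
(Σ ln P_aa(Φ,Ψ)/P_null over interior residues, on per-amino-acid 360×360
grids with a uniform null of 1/129600 per bin), and the D terms are
frame-fixed RMSDs against the target: over Cα atoms, over Cβ atoms, over
the amide H / carbonyl O atoms participating in the target's
Kabsch–Sander hydrogen bonds, and over wrapped (Φ, Ψ) differences (in
radians, commensurate with the Å-scale terms).  All weights default to
1.0.

The optimizer is a dynamic program over candidate backbones grown atom by
atom with exactly ideal geometry: the first atom ranges over an ε-lattice
ball of radius r around the target's first N, each subsequent N/C sweeps
its ideal-geometry circle at ~ε arc spacing, each Cα is fixed by Ω
rounding, and every atom respects the generation bound ‖Pᵗ − P₀ᵗ‖ ≤ r.
Because every score term is additive over chain segments, two prefixes
whose last k = 5 atoms share ε-lattice cells are interchangeable; the DP
keeps the best prefix per tail signature and prunes to the top-m beam
(defaults r = 1.6 Å, ε = r/5, m = 50 000).  Side chains are then searched
exhaustively per residue on a 10° χ grid within 3σ of each rotamer mean
(arginine's planar Nη torsions are fixed at 0°/180°), scored with the
analogous S_SC.  A refinement loop repeats the whole search with r, ε and
the χ grid halved each iteration, scoring always against the original
target.

## Worked example

Idealize a synthetic noisy helix (all three commands are provided by the
package, so this runs with no external data):

```sh
idealize fixtures make-peptide AAAAAAAA helix.pdb        # ideal α-helix
idealize fixtures perturb helix.pdb noisy.pdb --sigma 0.3 --seed 42
idealize run noisy.pdb ideal.pdb --beam 2000 --no-sidechains
idealize evaluate noisy.pdb ideal.pdb
```

The `run` step prints the score breakdown of its result against the
noisy target:

```
S_f     16.0964
D_alpha 0.7268
D_beta  0.7931
D_hbond 1.2299
D_phipsi        0.7001
S_BB    12.6465
iteration_scores        12.646484       12.646484
```

S_f ≈ 16.1 means the model's interior (Φ, Ψ) pairs sit in well-populated
Ramachandran bins (about e^{16.1/6} ≈ 15× enrichment over uniform per
residue), while staying within 0.73 Å Cα-RMSD of the noisy input.
`evaluate` reports the same distances plus torsion and hydrogen-bond
comparisons (the small S_f shift comes from re-reading coordinates at
PDB's 0.001 Å precision):

```
ca_rmsd_A       0.7267
all_atom_rmsd_A 0.7995
mean_abs_dphipsi_deg    35.5284
hbonds_reference        2
hbonds_candidate        5
hbonds_conserved        2
```

Both of the noisy target's hydrogen bonds survive idealization, and the
idealized model actually has *more* detected bonds than the noisy input —
idealization regularized the helix.  A Ramachandran table trained on real
structures can be supplied with `--rama` (build one with
`idealize stats build-rama DIR out.npz`); without it a synthetic
helix/strand basin prior is used.

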