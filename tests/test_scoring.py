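"""Score function: distance metrics, the additive combine, H-bond
detection, and side-chain scoring."""

import math

import numpy as np
import pytest

from idealize.errors import IdealizeError
from idealize.fixtures import make_ideal_peptide, make_toy_tables, perturb
from idealize.geometry import extract_torsions, rebuild_dependent_atoms
from idealize.pdb_io import structure_from_arrays
from idealize.rama_stats import Rotamer, RotamerTable, chi_log_odds
from idealize.scoring import (
    ScoreBreakdown,
    ScoringContext,
    backbone_score,
    bottleneck_distance,
    combine,
    detect_hbonds,
    rmsd_no_fit,
    sidechain_score,
)


def test_bottleneck_trivial(helix8):
    assert bottleneck_distance(helix8, helix8) == 0.0
    moved = perturb(helix8, 0.0, 0)
    moved.atoms[5].coord = moved.atoms[5].coord + np.array([0.5, 0.0, 0.0])
    assert bottleneck_distance(helix8, moved) == pytest.approx(0.5)


def test_bottleneck_brute_force_oracle(helix8):
    rng = np.random.default_rng(3)
    q = perturb(helix8, 0.2, 9)
    expected = max(
        np.linalg.norm(a.coord - b.coord) for a, b in zip(helix8.atoms, q.atoms)
    )
    assert bottleneck_distance(helix8, q) == pytest.approx(expected)
    with pytest.raises(IdealizeError):
        bottleneck_distance(helix8, make_ideal_peptide("AAA"))


def test_rmsd_no_fit_hand_arithmetic():
    seq = ["ALA", "ALA"]
    p = structure_from_arrays(seq, [(1, "CA", (0, 0, 0)), (2, "CA", (5, 0, 0))])
    q = structure_from_arrays(seq, [(1, "CA", (1, 0, 0)), (2, "CA", (5, 2, 0))])
    assert rmsd_no_fit(p, q) == pytest.approx(math.sqrt(2.5))


def test_rmsd_is_frame_fixed(helix8):
    translated = perturb(helix8, 0.0, 0)
    for a in translated.atoms:
        a.coord = a.coord + np.array([1.0, 0.0, 0.0])
    assert rmsd_no_fit(helix8, translated) == pytest.approx(1.0)


def test_rmsd_empty_selection_is_zero(helix8):
    assert rmsd_no_fit(helix8, helix8, ("XX",)) == 0.0


def _random_breakdown(rng, n_items):
    b = ScoreBreakdown(logodds_sum=float(rng.normal()))
    for m in b.sq:
        b.n[m] = int(rng.integers(0, n_items))
        b.sq[m] = float(rng.uniform(0, 5)) if b.n[m] else 0.0
    return b


def test_combine_hand_value():
    a = ScoreBreakdown(sq={"alpha": 3.0, "beta": 0, "hbond": 0, "phipsi": 0},
                       n={"alpha": 3, "beta": 0, "hbond": 0, "phipsi": 0})
    b = ScoreBreakdown(sq={"alpha": 4.0, "beta": 0, "hbond": 0, "phipsi": 0},
                       n={"alpha": 1, "beta": 0, "hbond": 0, "phipsi": 0})
    assert a.rmsd("alpha") == pytest.approx(1.0)
    assert b.rmsd("alpha") == pytest.approx(2.0)
    assert combine(a, b).rmsd("alpha") == pytest.approx(math.sqrt(1.75))


def test_combine_identity_and_associativity():
    rng = np.random.default_rng(4)
    empty = ScoreBreakdown()
    for _ in range(30):
        a, b, c = (_random_breakdown(rng, 6) for _ in range(3))
        assert combine(a, empty).total() == pytest.approx(a.total(), abs=1e-12)
        left = combine(combine(a, b), c)
        right = combine(a, combine(b, c))
        assert left.total() == pytest.approx(right.total(), abs=1e-12)
        for m in left.sq:
            assert left.sq[m] == pytest.approx(right.sq[m], abs=1e-12)


def test_combine_rejects_overlap():
    a = ScoreBreakdown(span=(1, 10))
    b = ScoreBreakdown(span=(5, 12))
    with pytest.raises(IdealizeError):
        combine(a, b)
    c = ScoreBreakdown(span=(12, 20))
    with pytest.raises(IdealizeError):
        combine(a, c)  # non-contiguous
    assert combine(a, ScoreBreakdown(span=(11, 20))).span == (1, 20)


def test_backbone_score_arithmetic():
    b = ScoreBreakdown(logodds_sum=3.2)
    assert backbone_score(b) == pytest.approx(3.2)
    b.sq["alpha"], b.n["alpha"] = 0.25, 1
    assert backbone_score(b) == pytest.approx(3.2 - 0.5)
    rng = np.random.default_rng(5)
    for _ in range(20):
        x = _random_breakdown(rng, 8)
        expected = x.logodds_sum - sum(
            math.sqrt(x.sq[m] / x.n[m]) if x.n[m] else 0.0
            for m in ("alpha", "beta", "hbond", "phipsi"))
        assert backbone_score(x) == pytest.approx(expected)


def test_helix_hbond_pattern():
    """An ideal alpha helix donates i -> i-4 hydrogen bonds."""
    helix = make_ideal_peptide("AAAAAAAAAAAA")
    hb = detect_hbonds(helix)
    pairs = set(hb.pairs)
    for d in range(6, 11):  # interior donors
        assert (d, d - 4) in pairs
    assert all(abs(d - a) >= 2 for d, a in pairs)


def test_extended_strand_has_no_hbonds():
    strand = make_ideal_peptide("AAAAAA", (-135.0, 135.0))
    assert detect_hbonds(strand).pairs == []


def test_proline_never_donates():
    helix = make_ideal_peptide("AAAAPAAAAAAA")
    hb = detect_hbonds(helix)
    assert 5 not in hb.donor_residues


def test_terminal_groups_excluded():
    helix = make_ideal_peptide("AAAAAAAAAAAA")
    hb = detect_hbonds(helix)
    assert 1 not in hb.donor_residues
    assert helix.n_residues not in hb.acceptor_residues


def test_dphipsi_wraps_across_the_branch_cut(toy_tables):
    """Angles straddling +-180 count as their small wrapped difference."""
    rama, _ = toy_tables
    target = make_ideal_peptide("AAAA", (-150.0, 179.5))
    cand = make_ideal_peptide("AAAA", (-150.0, -179.5))
    ctx = ScoringContext(target, rama)
    bd = ctx.breakdown_of(cand)
    # two interior residues, psi off by 1 degree each (wrapped), phi exact
    assert bd.sq["phipsi"] == pytest.approx(2 * math.radians(1.0) ** 2, rel=1e-6)
    from idealize.geometry import wrap_deg

    for theta in (-523.0, 197.0, 360.0, 179.5):
        assert wrap_deg(theta) == pytest.approx(wrap_deg(theta - 360.0))
        assert wrap_deg(theta) == pytest.approx(wrap_deg(theta + 360.0))


def test_additivity_matches_monolithic(perturbed8, toy_tables):
    """Summing per-segment contributions reproduces the monolithic score."""
    rama, _ = toy_tables
    ctx = ScoringContext(perturbed8, rama)
    cand = make_ideal_peptide("AAAAAAAA")
    whole = ctx.breakdown_of(cand)
    # split the items by residue into two segments and recombine
    a = ScoreBreakdown(span=(1, 12))
    b = ScoreBreakdown(span=(13, 24))
    rebuilt = rebuild_dependent_atoms(cand.select(("N", "CA", "C")))
    tors = extract_torsions(cand)
    for i in range(1, 9):
        part = a if i <= 4 else b
        part.sq["alpha"] += float(np.sum((cand.coord(i, "CA") - ctx.ca0[i - 1]) ** 2))
        part.n["alpha"] += 1
        if ctx.cb_mask[i - 1]:
            part.sq["beta"] += float(np.sum(
                (rebuilt.coord(i, "CB") - ctx.cb_ref[i - 1]) ** 2))
            part.n["beta"] += 1
        if ctx.h_mask[i - 1]:
            part.sq["hbond"] += float(np.sum(
                (rebuilt.coord(i, "H") - ctx.h_ref[i - 1]) ** 2))
            part.n["hbond"] += 1
        if ctx.o_mask[i - 1]:
            part.sq["hbond"] += float(np.sum(
                (rebuilt.coord(i, "O") - ctx.o_ref[i - 1]) ** 2))
            part.n["hbond"] += 1
        if 2 <= i <= 7:
            from idealize.rama_stats import rama_log_odds
            from idealize.geometry import wrap_deg

            part.logodds_sum += rama_log_odds(rama, "ALA", tors.phi[i - 1],
                                              tors.psi[i - 1])
            part.sq["phipsi"] += float(
                math.radians(wrap_deg(tors.phi[i - 1] - ctx.phi0[i - 1])) ** 2
                + math.radians(wrap_deg(tors.psi[i - 1] - ctx.psi0[i - 1])) ** 2)
            part.n["phipsi"] += 2
    merged = combine(a, b)
    assert merged.total() == pytest.approx(whole.total(), abs=1e-9)
    for m in merged.sq:
        assert merged.sq[m] == pytest.approx(whole.sq[m], abs=1e-9)


def test_distance_terms_nonnegative_so_sbb_below_sf(perturbed8, toy_tables):
    rama, _ = toy_tables
    ctx = ScoringContext(perturbed8, rama)
    for seed in range(5):
        bd = ctx.breakdown_of(perturb(make_ideal_peptide("AAAAAAAA"), 0.1, seed))
        assert bd.total() <= bd.logodds_sum + 1e-12


SER_TABLE = RotamerTable({"SER": {None: [Rotamer((-65.0,), (10.0,), 1.0)]}})


def _ser_peptide(chi1):
    return make_ideal_peptide("ASA", chis=[[], [chi1], []])


def test_sidechain_score_self_is_free_energy_only():
    st = _ser_peptide(-65.0)
    got = sidechain_score(st, st, 2, SER_TABLE)
    assert got == pytest.approx(chi_log_odds(SER_TABLE, "SER", None, None, [-65.0]))


def test_sidechain_chi_wrap():
    cand, targ = _ser_peptide(175.0), _ser_peptide(-175.0)
    s = sidechain_score(cand, targ, 2, SER_TABLE, weights=(0.0, 1.0))
    sf = chi_log_odds(SER_TABLE, "SER", None, None, [175.0])
    assert sf - s == pytest.approx(math.radians(10.0))  # 350 wraps to 10 deg


def test_sidechain_score_brute_recompute():
    rng = np.random.default_rng(8)
    for _ in range(10):
        chi_c, chi_t = rng.uniform(-180, 180, 2)
        cand, targ = _ser_peptide(chi_c), _ser_peptide(chi_t)
        got = sidechain_score(cand, targ, 2, SER_TABLE)
        og = cand.coord(2, "OG"), targ.coord(2, "OG")
        cb = cand.coord(2, "CB"), targ.coord(2, "CB")
        d_h = math.sqrt((np.sum((og[0] - og[1]) ** 2) + np.sum((cb[0] - cb[1]) ** 2)) / 2)
        from idealize.geometry import wrap_deg

        d_chi = abs(math.radians(wrap_deg(chi_c - chi_t)))
        sf = chi_log_odds(SER_TABLE, "SER", None, None, [chi_c])
        assert got == pytest.approx(sf - d_h - d_chi, abs=1e-9)


def test_sidechain_score_no_sidechain_residue(helix8):
    assert sidechain_score(helix8, helix8, 1, SER_TABLE) == 0.0
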