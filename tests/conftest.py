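import numpy as np
import pytest

from idealize.fixtures import make_ideal_peptide, make_toy_tables, perturb
from idealize.geometry import default_ideal_table, place_next_atom


@pytest.fixture(scope="session")
def ideal_table():
    return default_ideal_table()


@pytest.fixture(scope="session")
def toy_tables():
    return make_toy_tables(seed=1)


@pytest.fixture(scope="session")
def helix8():
    return make_ideal_peptide("AAAAAAAA")


@pytest.fixture(scope="session")
def perturbed8(helix8):
    return perturb(helix8, 0.3, seed=42)


@pytest.fixture(scope="session")
def jittered_peptide(ideal_table):
    """Synthetic stand-in for a high-resolution crystal structure: a
    peptide chained with bond lengths/angles jittered by realistic
    crystallographic spreads (0.02 A, 1.5 deg) around the ideal values,
    including jittered C-beta placements."""
    rng = np.random.default_rng(11)
    seq = ["ALA", "LEU", "SER", "VAL", "ALA", "PHE"]
    tab = ideal_table
    coords = [np.zeros(3), np.array([tab.bond("N-CA"), 0.0, 0.0])]
    th = np.radians(tab.angle("N-CA-C") + rng.normal(0, 1.5))
    coords.append(coords[1] + (tab.bond("CA-C") + rng.normal(0, 0.02))
                  * np.array([-np.cos(th), np.sin(th), 0.0]))
    phi, psi = -63.0, -42.0
    for i in range(1, len(seq)):
        for kind, L, ang, tau in (
            ("N", tab.bond("C-N"), tab.angle("CA-C-N"), psi + rng.normal(0, 6)),
            ("CA", tab.bond("N-CA"), tab.angle("C-N-CA"), 180.0 + rng.normal(0, 3)),
            ("C", tab.bond("CA-C"), tab.angle("N-CA-C"), phi + rng.normal(0, 6)),
        ):
            coords.append(place_next_atom(
                coords[-3], coords[-2], coords[-1],
                L + rng.normal(0, 0.02), ang + rng.normal(0, 1.5), tau))
    triples = []
    for i in range(len(seq)):
        for j, nm in enumerate(("N", "CA", "C")):
            triples.append((i + 1, nm, coords[3 * i + j]))
        n_, ca_, c_ = coords[3 * i], coords[3 * i + 1], coords[3 * i + 2]
        # jittered CB, placed like a real residue's
        cb = place_next_atom(n_, c_, ca_, tab.bond("CA-CB") + rng.normal(0, 0.02),
                             tab.angle("C-CA-CB") + rng.normal(0, 1.5),
                             -122.0 + rng.normal(0, 3))
        triples.append((i + 1, "CB", cb))
    from idealize.pdb_io import structure_from_arrays

    return structure_from_arrays(seq, triples)
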