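"""Shared fixtures: small molecule files and the self-verified toy systems."""

from __future__ import annotations

import numpy as np
import pytest

from modock.fixtures import make_conflict_system, make_harmonic_pocket
from modock.molecules import Atom, Bond, Ligand

ETHANE_MOL2 = """@<TRIPOS>MOLECULE
ethane
8 7 0 0 0
SMALL
USER_CHARGES
@<TRIPOS>ATOM
1 C1 0.000 0.000 0.000 C.3 1 ETH -0.060
2 C2 1.540 0.000 0.000 C.3 1 ETH -0.060
3 H1 -0.400 0.950 0.300 H 1 ETH 0.020
4 H2 -0.400 -0.600 0.800 H 1 ETH 0.020
5 H3 -0.400 -0.400 -0.950 H 1 ETH 0.020
6 H4 1.940 0.950 -0.300 H 1 ETH 0.020
7 H5 1.940 -0.600 -0.800 H 1 ETH 0.020
8 H6 1.940 -0.400 0.950 H 1 ETH 0.020
@<TRIPOS>BOND
1 1 2 1
2 1 3 1
3 1 4 1
4 1 5 1
5 2 6 1
6 2 7 1
7 2 8 1
"""

BUTANE_MOL2 = """@<TRIPOS>MOLECULE
n-butane
14 13 0 0 0
SMALL
USER_CHARGES
@<TRIPOS>ATOM
1 C1 0.000 0.000 0.000 C.3 1 BUT -0.060
2 C2 1.540 0.000 0.000 C.3 1 BUT -0.040
3 C3 2.100 1.430 0.000 C.3 1 BUT -0.040
4 C4 3.640 1.430 0.000 C.3 1 BUT -0.060
5 H1 -0.400 0.500 0.880 H 1 BUT 0.020
6 H2 -0.400 0.500 -0.880 H 1 BUT 0.020
7 H3 -0.400 -1.020 0.000 H 1 BUT 0.020
8 H4 1.910 -0.530 0.880 H 1 BUT 0.020
9 H5 1.910 -0.530 -0.880 H 1 BUT 0.020
10 H6 1.730 1.960 0.880 H 1 BUT 0.020
11 H7 1.730 1.960 -0.880 H 1 BUT 0.020
12 H8 4.040 0.930 0.880 H 1 BUT 0.020
13 H9 4.040 0.930 -0.880 H 1 BUT 0.020
14 H10 4.040 2.450 0.000 H 1 BUT 0.020
@<TRIPOS>BOND
1 1 2 1
2 2 3 1
3 3 4 1
4 1 5 1
5 1 6 1
6 1 7 1
7 2 8 1
8 2 9 1
9 3 10 1
10 3 11 1
11 4 12 1
12 4 13 1
13 4 14 1
"""

BENZENE_MOL2 = """@<TRIPOS>MOLECULE
benzene
12 12 0 0 0
SMALL
USER_CHARGES
@<TRIPOS>ATOM
1 C1 1.396 0.000 0.000 C.ar 1 BNZ -0.062
2 C2 0.698 1.209 0.000 C.ar 1 BNZ -0.062
3 C3 -0.698 1.209 0.000 C.ar 1 BNZ -0.062
4 C4 -1.396 0.000 0.000 C.ar 1 BNZ -0.062
5 C5 -0.698 -1.209 0.000 C.ar 1 BNZ -0.062
6 C6 0.698 -1.209 0.000 C.ar 1 BNZ -0.062
7 H1 2.480 0.000 0.000 H 1 BNZ 0.062
8 H2 1.240 2.148 0.000 H 1 BNZ 0.062
9 H3 -1.240 2.148 0.000 H 1 BNZ 0.062
10 H4 -2.480 0.000 0.000 H 1 BNZ 0.062
11 H5 -1.240 -2.148 0.000 H 1 BNZ 0.062
12 H6 1.240 -2.148 0.000 H 1 BNZ 0.062
@<TRIPOS>BOND
1 1 2 ar
2 2 3 ar
3 3 4 ar
4 4 5 ar
5 5 6 ar
6 6 1 ar
7 1 7 1
8 2 8 1
9 3 9 1
10 4 10 1
11 5 11 1
12 6 12 1
"""

# N-methylacetamide: CH3-C(=O)-NH-CH3; the central C-N bond is an amide
NMA_MOL2 = """@<TRIPOS>MOLECULE
N-methylacetamide
12 11 0 0 0
SMALL
USER_CHARGES
@<TRIPOS>ATOM
1 C1 -1.520 0.000 0.000 C.3 1 NMA -0.100
2 C2 0.000 0.000 0.000 C.2 1 NMA 0.500
3 O1 0.600 1.060 0.000 O.2 1 NMA -0.500
4 N1 0.650 -1.170 0.000 N.am 1 NMA -0.400
5 C3 2.100 -1.250 0.000 C.3 1 NMA -0.050
6 H1 -1.900 0.510 0.890 H 1 NMA 0.050
7 H2 -1.900 0.510 -0.890 H 1 NMA 0.050
8 H3 -1.900 -1.030 0.000 H 1 NMA 0.050
9 H4 0.130 -2.040 0.000 H 1 NMA 0.250
10 H5 2.480 -0.740 0.890 H 1 NMA 0.050
11 H6 2.480 -0.740 -0.890 H 1 NMA 0.050
12 H7 2.480 -2.280 0.000 H 1 NMA 0.050
@<TRIPOS>BOND
1 1 2 1
2 2 3 2
3 2 4 am
4 4 5 1
5 1 6 1
6 1 7 1
7 1 8 1
8 4 9 1
9 5 10 1
10 5 11 1
11 5 12 1
"""

TOY_PDB = """ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      7  C   GLY A   2       5.504   2.693   0.000  1.00  0.00           C
ATOM      8  N   SER A   3       6.191   3.830   0.000  1.00  0.00           N
ATOM      9  CA  SER A   3       7.646   3.830   0.000  1.00  0.00           C
ATOM     10  OG  SER A   3       8.150   5.160   0.000  1.00  0.00           O
ATOM     11  O   HOH A  90      20.000  20.000  20.000  1.00  0.00           O
HETATM   12 MG   MG  A  91      22.000  22.000  22.000  1.00  0.00          MG
END
"""

ALTLOC_PDB = """ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.50  0.00           C
ATOM      2  CA BALA A   1       0.300   0.000   0.000  0.50  0.00           C
ATOM      3  CB  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture(scope="session")
def harmonic_system():
    """Shared-minimum pocket, grid-verified once per session."""
    return make_harmonic_pocket(seed=0, verify=True)


@pytest.fixture(scope="session")
def conflict_system():
    """Separated-minima system, grid-verified once per session."""
    return make_conflict_system(seed=0, verify=True)


def random_chain_ligand(rng: np.random.Generator, n_heavy: int = 6) -> Ligand:
    """A random heavy-atom chain with hydrogens: torsions guaranteed."""
    elements = rng.choice(["C", "N", "O"], size=n_heavy)
    coords = [np.zeros(3)]
    for _ in range(1, n_heavy):
        step = rng.normal(size=3)
        step = 1.5 * step / np.linalg.norm(step)
        coords.append(coords[-1] + step)
    atoms = [Atom(i + 1, el, f"{el}.3", c, round(rng.uniform(-0.3, 0.3), 3))
             for i, (el, c) in enumerate(zip(elements, coords))]
    bonds = [Bond(i, i + 1) for i in range(n_heavy - 1)]
    # one hydrogen on each chain end so no bond is bare-terminal by accident
    for end in (0, n_heavy - 1):
        h = coords[end] + np.array([0.0, 0.0, 1.1])
        atoms.append(Atom(len(atoms) + 1, "H", "H", h, 0.05))
        bonds.append(Bond(end, len(atoms) - 1))
    return Ligand(atoms=atoms, bonds=bonds, name="CHAIN")
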