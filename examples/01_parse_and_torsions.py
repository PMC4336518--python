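"""Parse a ligand from MOL2 text and inspect its rotatable bonds.

n-Butane has three C-C bonds, but only the central one is a torsional
degree of freedom: the two outer bonds only spin terminal methyl groups.
"""

from modock.molecules import read_mol2

BUTANE = """@<TRIPOS>MOLECULE
n-butane
4 3 0 0 0
SMALL
USER_CHARGES
@<TRIPOS>ATOM
1 C1 0.000 0.000 0.000 C.3 1 BUT -0.06
2 C2 1.540 0.000 0.000 C.3 1 BUT -0.04
3 C3 2.100 1.430 0.000 C.3 1 BUT -0.04
4 C4 3.640 1.430 0.000 C.3 1 BUT -0.06
@<TRIPOS>BOND
1 1 2 1
2 2 3 1
3 3 4 1
"""

lig = read_mol2(BUTANE)
print(f"{lig.name}: {len(lig.atoms)} atoms, {len(lig.bonds)} bonds")
print(f"rotatable bonds: {lig.n_torsions}")
for bi in lig.rotatable_bonds:
    b = lig.bonds[bi]
    moved = lig.torsion_tree[bi]
    print(f"  bond C{b.atom_a + 1}-C{b.atom_b + 1}: rotating it moves atoms "
          f"{[i + 1 for i in moved]}")
# Expected: exactly one rotatable bond (C2-C3); the moved set is the distal
# side relative to the torsion-tree root near the molecular centroid.
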