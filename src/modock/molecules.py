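"""Molecular containers and I/O for docking.

Receptors arrive as PDB text, ligands as TRIPOS MOL2 with partial charges
already assigned (charge assignment, protonation and hydrogen placement are
preparation steps outside this package).  The ligand additionally carries a
bond graph from which rotatable bonds and a torsion tree are derived; the
receptor is reduced to an active site around a reference ligand position
before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "Atom",
    "Bond",
    "Ligand",
    "Receptor",
    "ActiveSite",
    "MoleculeError",
    "read_mol2",
    "write_mol2",
    "read_pdb",
    "extract_active_site",
    "detect_rotatable_bonds",
]

_WATER_RESNAMES = {"HOH", "WAT"}

BOND_ORDERS = {"1": "single", "2": "double", "3": "triple",
               "ar": "aromatic", "am": "amide"}


class MoleculeError(ValueError):
    """Malformed molecular input or an invariant violation."""


@dataclass
class Atom:
    """A single atom: index, element, SYBYL-ish type, coordinates (A), charge (e)."""

    serial: int
    element: str
    atom_type: str
    coords: np.ndarray
    charge: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise MoleculeError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        if not np.isfinite(self.charge):
            raise MoleculeError(f"atom {self.serial}: charges required (got non-finite charge)")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Bond:
    """Edge of the covalent graph; atom ids are 0-based indices into the atom list."""

    atom_a: int
    atom_b: int
    order: str = "single"

    def __post_init__(self) -> None:
        if self.atom_a == self.atom_b:
            raise MoleculeError("bond endpoints must differ")
        if self.order not in set(BOND_ORDERS.values()):
            raise MoleculeError(f"unknown bond order {self.order!r}")


@dataclass
class Ligand:
    """Flexible small molecule: atoms, bonds, rotatable bonds and torsion tree.

    ``rotatable_bonds`` is an ordered list of bond indices; ``torsion_tree``
    maps each rotatable bond index to the (sorted tuple of) atom ids moved
    when that torsion turns, i.e. the atoms on the distal side of the bond
    relative to ``root_atom``.
    """

    atoms: list[Atom]
    bonds: list[Bond]
    name: str = "LIG"
    rotatable_bonds: list[int] = field(default_factory=list)
    torsion_tree: dict[int, tuple[int, ...]] = field(default_factory=dict)
    root_atom: int = 0

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.atom_a < n and 0 <= b.atom_b < n):
                raise MoleculeError("bond references a missing atom id")
        g = self.graph()
        if n > 1 and not nx.is_connected(g):
            raise MoleculeError("ligand bond graph must be connected")
        if not self.rotatable_bonds and not self.torsion_tree:
            self._build_torsions()

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from((b.atom_a, b.atom_b) for b in self.bonds)
        return g

    def _build_torsions(self) -> None:
        self.root_atom = _centroid_root(self)
        self.rotatable_bonds = detect_rotatable_bonds(self)
        g = self.graph()
        tree: dict[int, tuple[int, ...]] = {}
        for bi in self.rotatable_bonds:
            b = self.bonds[bi]
            tree[bi] = _distal_atoms(g, b.atom_a, b.atom_b, self.root_atom)
        self.torsion_tree = tree
        # order root -> leaves: proximal atoms closer to the root rotate first
        depth = nx.single_source_shortest_path_length(g, self.root_atom) if self.atoms else {}
        self.rotatable_bonds.sort(
            key=lambda bi: (min(depth[self.bonds[bi].atom_a], depth[self.bonds[bi].atom_b]),
                            self.bonds[bi].atom_a, self.bonds[bi].atom_b)
        )

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    @property
    def n_torsions(self) -> int:
        return len(self.rotatable_bonds)


@dataclass
class Receptor:
    """Rigid receptor: atoms plus a map atom id -> (chain, resname, resnum)."""

    atoms: list[Atom]
    residue_of: dict[int, tuple[str, str, int]]

    def __post_init__(self) -> None:
        for i in range(len(self.atoms)):
            if i not in self.residue_of:
                raise MoleculeError(f"receptor atom {i} has no residue assignment")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class ActiveSite:
    """Receptor atoms near the reference ligand, with the docking search box."""

    atom_ids: list[int]
    box_lo: np.ndarray
    box_hi: np.ndarray

    def __post_init__(self) -> None:
        self.box_lo = np.asarray(self.box_lo, dtype=float)
        self.box_hi = np.asarray(self.box_hi, dtype=float)
        if not np.all(self.box_lo < self.box_hi):
            raise MoleculeError("active-site box must have box_lo < box_hi componentwise")


def _centroid_root(lig: Ligand) -> int:
    """Atom closest to the heavy-atom centroid (all-atom centroid if no heavies)."""
    xyz = lig.coords
    mask = lig.heavy_mask
    center = xyz[mask].mean(axis=0) if mask.any() else xyz.mean(axis=0)
    return int(np.argmin(np.linalg.norm(xyz - center, axis=1)))


def _distal_atoms(g: nx.Graph, a: int, b: int, root: int) -> tuple[int, ...]:
    """Atoms moved by rotating bond a-b: the side not containing the root."""
    h = g.copy()
    h.remove_edge(a, b)
    comp_a = nx.node_connected_component(h, a)
    if root in comp_a:
        moved = nx.node_connected_component(h, b)
    else:
        moved = comp_a
    return tuple(sorted(moved))


def detect_rotatable_bonds(ligand: Ligand) -> list[int]:
    """Indices of rotatable bonds: single, acyclic, non-amide, non-terminal.

    A bond is terminal when either side's moved set contains no heavy atom
    other than the bond atom itself (rotating it only spins hydrogens or a
    bare end atom), in which case the torsion is not a meaningful degree of
    freedom.  Order is deterministic: sorted by (atom_a, atom_b).
    """
    g = ligand.graph()
    bridges = set(frozenset(e) for e in nx.bridges(g)) if g.number_of_edges() else set()
    out: list[int] = []
    for bi, b in enumerate(ligand.bonds):
        if b.order != "single":
            continue
        if frozenset((b.atom_a, b.atom_b)) not in bridges:  # in a ring
            continue
        if _is_amide(ligand, b):
            continue
        if _is_terminal(ligand, g, b):
            continue
        out.append(bi)
    out.sort(key=lambda i: (min(ligand.bonds[i].atom_a, ligand.bonds[i].atom_b),
                            max(ligand.bonds[i].atom_a, ligand.bonds[i].atom_b)))
    return out


def _is_amide(lig: Ligand, bond: Bond) -> bool:
    """C-N single bond where the carbon carries a double-bonded O (or MOL2 'am')."""
    ea = lig.atoms[bond.atom_a].element.upper()
    eb = lig.atoms[bond.atom_b].element.upper()
    if {ea, eb} != {"C", "N"}:
        return False
    carbon = bond.atom_a if ea == "C" else bond.atom_b
    for other in lig.bonds:
        if other.order != "double":
            continue
        ends = (other.atom_a, other.atom_b)
        if carbon in ends:
            partner = ends[1] if ends[0] == carbon else ends[0]
            if lig.atoms[partner].element.upper() == "O":
                return True
    return False


def _is_terminal(lig: Ligand, g: nx.Graph, bond: Bond) -> bool:
    h = g.copy()
    h.remove_edge(bond.atom_a, bond.atom_b)
    for end in (bond.atom_a, bond.atom_b):
        side = nx.node_connected_component(h, end)
        heavies = [i for i in side if i != end and lig.atoms[i].is_heavy]
        if not heavies:
            return True
    return False


# ---------------------------------------------------------------------------
# TRIPOS MOL2
# ---------------------------------------------------------------------------

def read_mol2(text: str) -> Ligand:
    """Parse a TRIPOS MOL2 document into a :class:`Ligand`.

    MOLECULE, ATOM and BOND sections are required; the per-atom charge column
    is mandatory (inputs must arrive with charges assigned).  Atom order is
    preserved from the file; serials are kept for reporting but internal atom
    ids are 0-based positions.
    """
    sections: dict[str, list[tuple[int, str]]] = {}
    current: str | None = None
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("@<TRIPOS>"):
            current = line[len("@<TRIPOS>"):].upper()
            sections.setdefault(current, [])
            continue
        if current is not None and line and not line.startswith("#"):
            sections[current].append((ln, line))

    for need in ("MOLECULE", "ATOM", "BOND"):
        if need not in sections:
            raise MoleculeError(f"MOL2 missing @<TRIPOS>{need} section")

    name = sections["MOLECULE"][0][1] if sections["MOLECULE"] else "LIG"

    atoms: list[Atom] = []
    serial_to_idx: dict[int, int] = {}
    for ln, line in sections["ATOM"]:
        parts = line.split()
        if len(parts) < 9:
            raise MoleculeError(
                f"MOL2 line {ln}: ATOM record needs 9 fields "
                "(id name x y z type subst_id subst_name charge); charges required"
            )
        try:
            serial = int(parts[0])
            xyz = [float(parts[2]), float(parts[3]), float(parts[4])]
            atype = parts[5]
            charge = float(parts[8])
        except ValueError as exc:
            raise MoleculeError(f"MOL2 line {ln}: malformed ATOM record ({exc})") from None
        element = atype.split(".")[0]
        try:
            atom = Atom(serial=serial, element=element, atom_type=atype,
                        coords=np.array(xyz), charge=charge)
        except MoleculeError as exc:
            raise MoleculeError(f"MOL2 line {ln}: {exc}") from None
        serial_to_idx[serial] = len(atoms)
        atoms.append(atom)

    bonds: list[Bond] = []
    for ln, line in sections["BOND"]:
        parts = line.split()
        if len(parts) < 4:
            raise MoleculeError(f"MOL2 line {ln}: BOND record needs 4 fields")
        try:
            a, b = int(parts[1]), int(parts[2])
        except ValueError:
            raise MoleculeError(f"MOL2 line {ln}: malformed BOND record") from None
        order = BOND_ORDERS.get(parts[3].lower())
        if order is None:
            raise MoleculeError(f"MOL2 line {ln}: unknown bond type {parts[3]!r}")
        if a not in serial_to_idx or b not in serial_to_idx:
            raise MoleculeError(f"MOL2 line {ln}: bond references unknown atom serial")
        bonds.append(Bond(serial_to_idx[a], serial_to_idx[b], order))

    return Ligand(atoms=atoms, bonds=bonds, name=name.split()[0] if name else "LIG")


_ORDER_TO_MOL2 = {v: k for k, v in BOND_ORDERS.items()}


def write_mol2(lig: Ligand, coords: np.ndarray | None = None) -> str:
    """Serialize a ligand (optionally with replacement coordinates) to MOL2 text."""
    xyz = lig.coords if coords is None else np.asarray(coords, dtype=float)
    if xyz.shape != (len(lig.atoms), 3):
        raise MoleculeError("coordinate array shape mismatch")
    lines = ["@<TRIPOS>MOLECULE", lig.name,
             f"{len(lig.atoms)} {len(lig.bonds)} 0 0 0", "SMALL", "USER_CHARGES",
             "@<TRIPOS>ATOM"]
    for i, a in enumerate(lig.atoms):
        lines.append(
            f"{i + 1:>7d} {a.element}{i + 1:<3d} {xyz[i, 0]:>12.6f} {xyz[i, 1]:>12.6f} "
            f"{xyz[i, 2]:>12.6f} {a.atom_type:<8s} 1 {lig.name:<8s} {a.charge:>10.6f}"
        )
    lines.append("@<TRIPOS>BOND")
    for i, b in enumerate(lig.bonds):
        lines.append(f"{i + 1:>6d} {b.atom_a + 1:>5d} {b.atom_b + 1:>5d} "
                     f"{_ORDER_TO_MOL2[b.order]:>4s}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb(text: str) -> Receptor:
    """Parse fixed-column PDB ATOM records into a :class:`Receptor`.

    HETATM records, waters (HOH/WAT) and alternate locations other than
    '' or 'A' are skipped — the receptor is the bare protein.  Element is
    taken from columns 77-78 when present, else inferred from the atom name.
    Receptor partial charges are not part of the PDB format and default to 0;
    they may be overwritten by the caller before scoring.
    """
    atoms: list[Atom] = []
    residue_of: dict[int, tuple[str, str, int]] = {}
    for ln, line in enumerate(text.splitlines(), start=1):
        if not line.startswith("ATOM"):
            continue
        if len(line) < 54:
            raise MoleculeError(f"PDB line {ln}: truncated ATOM record")
        altloc = line[16].strip()
        if altloc not in ("", "A"):
            continue
        resname = line[17:20].strip()
        if resname in _WATER_RESNAMES:
            continue
        try:
            serial = int(line[6:11])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError:
            raise MoleculeError(f"PDB line {ln}: malformed ATOM record") from None
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            name = line[12:16].strip()
            element = next((c for c in name if c.isalpha()), "C")
        chain = line[21].strip()
        try:
            resnum = int(line[22:26])
        except ValueError:
            raise MoleculeError(f"PDB line {ln}: bad residue number") from None
        idx = len(atoms)
        atoms.append(Atom(serial=serial, element=element.capitalize(),
                          atom_type=element.capitalize(), coords=np.array([x, y, z]),
                          charge=0.0))
        residue_of[idx] = (chain, resname, resnum)
    if not atoms:
        raise MoleculeError("PDB contains no usable ATOM records (empty receptor)")
    return Receptor(atoms=atoms, residue_of=residue_of)


def extract_active_site(receptor: Receptor,
                        reference_coords: np.ndarray,
                        radius: float = 6.5) -> ActiveSite:
    """Residues with any atom within ``radius`` of any reference coordinate.

    Whole residues are kept (a residue qualifies through any one atom).  The
    search box is the axis-aligned bounding box of the reference coordinates
    padded by ``radius`` on every side; it bounds the translational design
    variables during docking.
    """
    ref = np.atleast_2d(np.asarray(reference_coords, dtype=float))
    if ref.size == 0:
        raise MoleculeError("reference coordinates required")
    if radius <= 0:
        raise MoleculeError("radius must be positive")
    xyz = receptor.coords
    d2 = ((xyz[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
    near = d2.min(axis=1) <= radius ** 2
    keep_res = {receptor.residue_of[i] for i in np.flatnonzero(near)}
    if not keep_res:
        raise MoleculeError(f"no receptor residue within {radius} A of the reference")
    atom_ids = [i for i in range(len(receptor.atoms))
                if receptor.residue_of[i] in keep_res]
    return ActiveSite(atom_ids=atom_ids,
                      box_lo=ref.min(axis=0) - radius,
                      box_hi=ref.max(axis=0) + radius)
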