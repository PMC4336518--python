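"""Design vector and kinematics for the flexible ligand.

A pose is encoded as X = (Tx, Ty, Tz, Rx, Ry, Rz, Tb1..Tbn): the target
position of the ligand's heavy-atom centroid, rigid-body Euler angles, and
one torsion per rotatable bond.  Applying X torsions first (root to leaves),
then rotates rigidly about the heavy-atom centroid (intrinsic Z-Y-X), then
translates the centroid to (Tx, Ty, Tz) — so X = (centroid, 0, 0, 0...) is
the identity.  Angles are periodic and wrapped into [-pi, pi].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .molecules import Ligand

__all__ = ["ConformationVector", "Bounds", "apply_conformation",
           "constraint_values", "random_conformation", "wrap_angle"]


def wrap_angle(a):
    """Wrap angle(s) into [-pi, pi)."""
    return np.mod(np.asarray(a, dtype=float) + np.pi, 2 * np.pi) - np.pi


@dataclass
class ConformationVector:
    """The design vector: 3 translations (A), 3 Euler angles, n torsions (rad)."""

    tx: float
    ty: float
    tz: float
    rx: float
    ry: float
    rz: float
    torsions: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.torsions = np.atleast_1d(np.asarray(self.torsions, dtype=float))

    @classmethod
    def from_array(cls, x: np.ndarray) -> "ConformationVector":
        x = np.asarray(x, dtype=float)
        if x.size < 6:
            raise ValueError("conformation vector needs at least 6 entries")
        return cls(*x[:6], torsions=x[6:])

    def to_array(self) -> np.ndarray:
        return np.concatenate([[self.tx, self.ty, self.tz,
                                self.rx, self.ry, self.rz], self.torsions])

    def __len__(self) -> int:
        return 6 + len(self.torsions)


@dataclass
class Bounds:
    """Box limits on the design variables.

    Translations are bounded by the active-site box; all angular variables
    (Euler angles and torsions) live on the fixed periodic interval [-pi, pi].
    """

    t_lo: np.ndarray
    t_hi: np.ndarray

    def __post_init__(self) -> None:
        self.t_lo = np.asarray(self.t_lo, dtype=float)
        self.t_hi = np.asarray(self.t_hi, dtype=float)
        if self.t_lo.shape != (3,) or self.t_hi.shape != (3,):
            raise ValueError("translation bounds must be 3-vectors")
        if not np.all(self.t_lo < self.t_hi):
            raise ValueError("t_lo must be < t_hi componentwise")

    def lo_hi(self, n_torsions: int) -> tuple[np.ndarray, np.ndarray]:
        """Full (lo, hi) arrays for a 6+n design vector."""
        n_ang = 3 + n_torsions
        lo = np.concatenate([self.t_lo, np.full(n_ang, -np.pi)])
        hi = np.concatenate([self.t_hi, np.full(n_ang, np.pi)])
        return lo, hi


def apply_conformation(ligand: Ligand, x: ConformationVector) -> np.ndarray:
    """Coordinates of ``ligand`` posed according to ``x``; the input is unchanged.

    Order of operations: torsion rotations about each rotatable bond's axis
    (root-to-leaves), then rigid rotation about the heavy-atom centroid by
    intrinsic Z-Y-X Euler angles (rz, ry, rx), then translation of the
    centroid to (tx, ty, tz).
    """
    if len(x) != 6 + ligand.n_torsions:
        raise ValueError(
            f"conformation vector length {len(x)} does not match ligand "
            f"6 + {ligand.n_torsions} torsions"
        )
    xyz = ligand.coords.copy()

    for angle, bi in zip(x.torsions, ligand.rotatable_bonds):
        if angle == 0.0:
            continue
        bond = ligand.bonds[bi]
        moved = list(ligand.torsion_tree[bi])
        # axis points from the proximal end toward the distal set
        a, b = bond.atom_a, bond.atom_b
        if a in ligand.torsion_tree[bi]:
            a, b = b, a
        axis = xyz[b] - xyz[a]
        norm = np.linalg.norm(axis)
        if norm == 0:
            continue
        rot = Rotation.from_rotvec(axis / norm * angle)
        xyz[moved] = rot.apply(xyz[moved] - xyz[a]) + xyz[a]

    heavy = ligand.heavy_mask
    center = xyz[heavy].mean(axis=0) if heavy.any() else xyz.mean(axis=0)
    rig = Rotation.from_euler("ZYX", [x.rz, x.ry, x.rx])
    xyz = rig.apply(xyz - center) + np.array([x.tx, x.ty, x.tz])
    return xyz


def constraint_values(x: ConformationVector, b: Bounds) -> np.ndarray:
    """Box constraints in g_j(X) <= 0 form: (lo - v) and (v - hi) per variable.

    Returns 2*(6+n) residuals; a residual is negative strictly inside the
    box, zero on its boundary, positive when violated.
    """
    v = x.to_array()
    lo, hi = b.lo_hi(len(x.torsions))
    return np.concatenate([lo - v, v - hi])


def random_conformation(b: Bounds, n_torsions: int,
                        rng: np.random.Generator) -> ConformationVector:
    """Uniform draw within bounds; deterministic for a fixed generator state."""
    lo, hi = b.lo_hi(n_torsions)
    return ConformationVector.from_array(rng.uniform(lo, hi))
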