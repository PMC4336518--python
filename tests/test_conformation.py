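"""Design-vector kinematics: identity, isometry, torsion locality."""

import numpy as np
import pytest

from modock.conformation import (Bounds, ConformationVector, apply_conformation,
                                 constraint_values, random_conformation)
from modock.molecules import read_mol2

from conftest import BUTANE_MOL2, random_chain_ligand


def identity_vector(lig):
    cen = lig.coords[lig.heavy_mask].mean(axis=0)
    return ConformationVector(*cen, 0.0, 0.0, 0.0,
                              torsions=np.zeros(lig.n_torsions))


def test_identity_reproduces_input():
    lig = read_mol2(BUTANE_MOL2)
    out = apply_conformation(lig, identity_vector(lig))
    np.testing.assert_allclose(out, lig.coords, atol=1e-10)


def test_pure_translation_displaces_uniformly():
    lig = read_mol2(BUTANE_MOL2)
    x = identity_vector(lig)
    shifted = ConformationVector(x.tx + 2.0, x.ty - 1.0, x.tz + 0.5,
                                 0.0, 0.0, 0.0, torsions=x.torsions)
    out = apply_conformation(lig, shifted)
    np.testing.assert_allclose(out - lig.coords,
                               np.tile([2.0, -1.0, 0.5], (len(lig.atoms), 1)),
                               atol=1e-9)


def test_half_turn_composition_returns_to_start():
    """pi followed by -pi about the same torsion is the identity."""
    lig = read_mol2(BUTANE_MOL2)
    assert lig.n_torsions == 1
    x_pi = identity_vector(lig)
    x_pi.torsions = np.array([np.pi])
    mid = apply_conformation(lig, x_pi)

    lig2 = read_mol2(BUTANE_MOL2)
    for a, c in zip(lig2.atoms, mid):
        a.coords = c
    cen2 = mid[lig2.heavy_mask].mean(axis=0)
    x_back = ConformationVector(*cen2, 0, 0, 0, torsions=np.array([-np.pi]))
    out = apply_conformation(lig2, x_back)
    np.testing.assert_allclose(out, lig.coords, atol=1e-8)


def test_rigid_motion_is_isometry():
    rng = np.random.default_rng(11)
    for _ in range(20):
        lig = random_chain_ligand(rng)
        d0 = np.linalg.norm(lig.coords[:, None] - lig.coords[None], axis=-1)
        x = ConformationVector(*rng.uniform(-5, 5, 3), *rng.uniform(-np.pi, np.pi, 3),
                               torsions=np.zeros(lig.n_torsions))
        out = apply_conformation(lig, x)
        d1 = np.linalg.norm(out[:, None] - out[None], axis=-1)
        np.testing.assert_allclose(d1, d0, atol=1e-8)


def test_torsion_leaves_fixed_side_internally_rigid():
    """A single torsion changes nothing on its fixed side beyond the common
    re-anchoring translation: all fixed-side atoms share one displacement,
    and every fixed-fixed interatomic distance is preserved exactly."""
    rng = np.random.default_rng(7)
    for _ in range(10):
        lig = random_chain_ligand(rng)
        if lig.n_torsions == 0:
            continue
        for k, bi in enumerate(lig.rotatable_bonds):
            x = identity_vector(lig)
            x.torsions = np.zeros(lig.n_torsions)
            x.torsions[k] = rng.uniform(0.3, 2.5)
            out = apply_conformation(lig, x)
            moved = set(lig.torsion_tree[bi])
            fixed = [i for i in range(len(lig.atoms)) if i not in moved]
            shifts = out[fixed] - lig.coords[fixed]
            np.testing.assert_allclose(shifts - shifts[0], np.zeros_like(shifts),
                                       atol=1e-9)
            d_in = np.linalg.norm(lig.coords[fixed][:, None]
                                  - lig.coords[fixed][None], axis=-1)
            d_out = np.linalg.norm(out[fixed][:, None] - out[fixed][None], axis=-1)
            np.testing.assert_allclose(d_out, d_in, atol=1e-9)
            # and the moved side really did move (nonzero torsion)
            assert np.abs(out[list(moved)] - lig.coords[list(moved)]
                          - shifts[0]).max() > 1e-6


def _reference_kinematics(lig, x):
    """Independent matrix-chain implementation with hand-built rotations."""
    def rot_about_axis(axis, angle):
        axis = axis / np.linalg.norm(axis)
        ux, uy, uz = axis
        c, s = np.cos(angle), np.sin(angle)
        return np.array([
            [c + ux * ux * (1 - c), ux * uy * (1 - c) - uz * s, ux * uz * (1 - c) + uy * s],
            [uy * ux * (1 - c) + uz * s, c + uy * uy * (1 - c), uy * uz * (1 - c) - ux * s],
            [uz * ux * (1 - c) - uy * s, uz * uy * (1 - c) + ux * s, c + uz * uz * (1 - c)],
        ])

    xyz = lig.coords.copy()
    for angle, bi in zip(x.torsions, lig.rotatable_bonds):
        b = lig.bonds[bi]
        a_id, b_id = b.atom_a, b.atom_b
        if a_id in lig.torsion_tree[bi]:
            a_id, b_id = b_id, a_id
        rot = rot_about_axis(xyz[b_id] - xyz[a_id], angle)
        for i in lig.torsion_tree[bi]:
            xyz[i] = rot @ (xyz[i] - xyz[a_id]) + xyz[a_id]
    heavy = lig.heavy_mask
    cen = xyz[heavy].mean(axis=0)
    rz = rot_about_axis(np.array([0.0, 0, 1]), x.rz)
    ry = rot_about_axis(np.array([0.0, 1, 0]), x.ry)
    rx = rot_about_axis(np.array([1.0, 0, 0]), x.rx)
    big = rz @ ry @ rx          # intrinsic Z-Y-X
    return (big @ (xyz - cen).T).T + np.array([x.tx, x.ty, x.tz])


def test_matches_independent_matrix_chain():
    rng = np.random.default_rng(3)
    for _ in range(20):
        lig = random_chain_ligand(rng)
        x = ConformationVector(*rng.uniform(-4, 4, 3), *rng.uniform(-np.pi, np.pi, 3),
                               torsions=rng.uniform(-np.pi, np.pi, lig.n_torsions))
        np.testing.assert_allclose(apply_conformation(lig, x),
                                   _reference_kinematics(lig, x), atol=1e-8)


def test_length_mismatch_rejected():
    lig = read_mol2(BUTANE_MOL2)
    bad = ConformationVector(0, 0, 0, 0, 0, 0, torsions=np.zeros(5))
    with pytest.raises(ValueError, match="length"):
        apply_conformation(lig, bad)


# ---------------------------------------------------------------------------
# constraints and sampling
# ---------------------------------------------------------------------------

def test_constraint_values_signs():
    b = Bounds(t_lo=np.zeros(3), t_hi=np.full(3, 10.0))
    mid = ConformationVector(5, 5, 5, 0, 0, 0, torsions=np.zeros(2))
    g = constraint_values(mid, b)
    assert g.shape == (2 * 8,)
    assert np.all(g < 0)

    at_hi = ConformationVector(10.0, 5, 5, 0, 0, 0, torsions=np.zeros(2))
    g = constraint_values(at_hi, b)
    assert g[8] == pytest.approx(0.0)             # tx - hi residual

    beyond = ConformationVector(11.0, 5, 5, 0, 0, 0, torsions=np.zeros(2))
    assert constraint_values(beyond, b)[8] == pytest.approx(1.0)


def test_random_conformation_deterministic_and_bounded():
    b = Bounds(t_lo=np.array([-2.0, 0.0, 1.0]), t_hi=np.array([3.0, 4.0, 2.0]))
    a = random_conformation(b, 3, np.random.default_rng(5))
    c = random_conformation(b, 3, np.random.default_rng(5))
    np.testing.assert_array_equal(a.to_array(), c.to_array())
    assert len(a) == 9

    rng = np.random.default_rng(0)
    draws = np.array([random_conformation(b, 2, rng).to_array()
                      for _ in range(2000)])
    lo, hi = b.lo_hi(2)
    assert np.all(draws >= lo) and np.all(draws <= hi)
    assert random_conformation(b, 0, rng).to_array().shape == (6,)
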