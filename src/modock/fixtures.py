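"""Synthetic docking systems with known, verified optima.

Every other module is testable without downloads through the constructions
here:

* :func:`make_harmonic_pocket` — a cage of receptor pseudo-atoms arranged so
  that all three scoring functions are minimized at one planted pose of a
  rigid star-shaped ligand.  Each ligand arm atom sits exactly between a
  symmetric pair of receptor partners placed at the pair's Lennard-Jones
  minimum distance, which makes the planted pose a stationary point of the
  force-field and softened-contact terms; the pair potential is built with
  wells centered on the planted pair distances.
* :func:`make_conflict_system` — three spatially separated attractive sites,
  each coupling to a different scoring function through element-selective
  parameters (Lennard-Jones depth for f1, contact/hydrophobic terms for f2,
  the pair-potential table for f3), plus the balanced compromise position at
  their centroid.
* :func:`make_pmf_samples` — pair distances drawn from a chosen potential,
  the inverse problem of the knowledge-based derivation.
* :func:`make_benchmark_problem` — analytic optimizer benchmarks.

Each system self-verifies at build time against an independent brute-force
grid search; a construction that fails verification raises instead of being
emitted.  All outputs are deterministic functions of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conformation import Bounds, ConformationVector, apply_conformation
from .molecules import Atom, Bond, Ligand, Receptor, write_mol2
from .pipeline import DockingConfig
from .scoring import (ForceFieldParams, PMFPotential, Site,
                      compute_empirical_terms, score_empirical,
                      score_forcefield, score_knowledge)

__all__ = ["ToySystem", "FixtureError", "make_harmonic_pocket",
           "make_conflict_system", "make_pmf_samples",
           "make_benchmark_problem", "write_receptor_pdb"]


class FixtureError(RuntimeError):
    """A synthetic system failed its build-time verification."""


@dataclass
class ToySystem:
    """A self-contained toy docking problem with a planted reference pose."""

    receptor: Receptor
    ligand: Ligand
    planted_pose: np.ndarray
    planted_x: ConformationVector
    config: DockingConfig
    bounds: Bounds
    notes: dict = field(default_factory=dict)

    @property
    def site(self) -> Site:
        return Site.from_atoms(self.receptor.atoms)

    def receptor_pdb(self) -> str:
        return write_receptor_pdb(self.receptor)

    def ligand_mol2(self) -> str:
        return write_mol2(self.ligand)


def write_receptor_pdb(receptor: Receptor) -> str:
    lines = []
    for i, a in enumerate(receptor.atoms):
        chain, resname, resnum = receptor.residue_of[i]
        name = f"{a.element}{i + 1}"[:4]
        lines.append(
            f"ATOM  {i + 1:>5d} {name:<4s} {resname:<3s} {chain}{resnum:>4d}    "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def _receptor_from_specs(specs: list[tuple[str, np.ndarray, float]]) -> Receptor:
    atoms = [Atom(serial=i + 1, element=el, atom_type=el,
                  coords=np.asarray(xyz, dtype=float), charge=q)
             for i, (el, xyz, q) in enumerate(specs)]
    residue_of = {i: ("A", "PKT", 1) for i in range(len(atoms))}
    return Receptor(atoms=atoms, residue_of=residue_of)


def _score_all(system_cfg: DockingConfig, ligand: Ligand, site: Site,
               coords: np.ndarray) -> np.ndarray:
    """(P, 3) raw scores for a coordinate batch."""
    f1 = score_forcefield(coords, ligand.atoms, site, system_cfg.ff_params)
    terms = compute_empirical_terms(coords, ligand.atoms, ligand, site,
                                    system_cfg.emp_params or system_cfg.ff_params)
    f2 = score_empirical(terms, system_cfg.emp_coeffs)
    f3 = score_knowledge(coords, ligand.atoms, site, system_cfg.potential)
    return np.stack([np.atleast_1d(f1), np.atleast_1d(f2), np.atleast_1d(f3)], axis=-1)


def _gaussian_wells(grid: np.ndarray, centers: np.ndarray, depth: float,
                    sigma: float) -> np.ndarray:
    a = np.zeros_like(grid)
    for c in centers:
        a -= depth * np.exp(-((grid - c) ** 2) / (2.0 * sigma ** 2))
    return a


# ---------------------------------------------------------------------------
# harmonic pocket
# ---------------------------------------------------------------------------

_ARM = 4.0           # ligand arm length, A (pseudo-bonds; geometric construction)
_ARM_Q = 0.12        # arm partial charge; partner rings carry the opposite sign
_WELL_SIGMA = 0.4    # pair-potential wells pinning the planted distances
_BROAD_DEPTH = 0.3   # shallow long-range component guiding the optimizer
_BROAD_R0 = 4.5
_BROAD_SIGMA = 2.0


_CORE_Q = 0.6        # central-atom charge; its partner pair carries the opposite
_PARTNER_Q = -0.45   # charge on each central-partner atom: a long-range funnel


def _star_ligand() -> Ligand:
    atoms = [Atom(1, "C", "C.3", np.array([0.0, 0.0, 0.0]), _CORE_Q),
             Atom(2, "C", "C.3", np.array([_ARM, 0.0, 0.0]), _ARM_Q),
             Atom(3, "N", "N.3", np.array([0.0, _ARM, 0.0]), -_ARM_Q),
             Atom(4, "O", "O.3", np.array([0.0, 0.0, _ARM]), _ARM_Q)]
    bonds = [Bond(0, 1), Bond(0, 2), Bond(0, 3)]
    return Ligand(atoms=atoms, bonds=bonds, name="STAR")


def _pair_rmin(params: ForceFieldParams, e1: str, e2: str) -> float:
    return 0.5 * (params.lj_table[e1][1] + params.lj_table[e2][1])


def _planted_distance_pmf(ligand: Ligand, receptor: Receptor,
                          pose: np.ndarray) -> PMFPotential:
    """Wells at every planted heavy-pair distance, plus a broad guiding basin."""
    delta_r, cutoff = 0.05, 8.0
    grid = np.arange(delta_r / 2, cutoff, delta_r)
    by_pair: dict[tuple[str, str], list[float]] = {}
    for i, la in enumerate(ligand.atoms):
        if not la.is_heavy:
            continue
        for ra in receptor.atoms:
            d = float(np.linalg.norm(pose[i] - ra.coords))
            if d < 7.5:
                by_pair.setdefault((la.element, ra.element), []).append(d)
    tables = {}
    for pair, dists in by_pair.items():
        a = _gaussian_wells(grid, np.array(dists), 1.0, _WELL_SIGMA)
        a += -_BROAD_DEPTH * np.exp(-((grid - _BROAD_R0) ** 2) / (2 * _BROAD_SIGMA ** 2))
        tables[pair] = a
    return PMFPotential(r_grid=grid, tables=tables, delta_r=delta_r,
                        r_cutoff=cutoff, kT=0.593,
                        fallback=np.zeros_like(grid))


def _verify_pose_grid(system: ToySystem, n_trans: int = 11, trans_step: float = 0.25,
                      rot_offsets_deg=(-90, -60, -30, 0, 30, 60, 90, 120)) -> dict:
    """Brute-force oracle: the planted pose must be the best grid cell for
    every objective over an 11^3 translation x 8^3 rotation grid around it."""
    lig, site, cfg = system.ligand, system.site, system.config
    half = (n_trans - 1) // 2
    t_off = np.arange(-half, half + 1) * trans_step
    tg = np.array(np.meshgrid(t_off, t_off, t_off, indexing="ij")).reshape(3, -1).T
    planted_t_idx = (len(tg) - 1) // 2
    rots = np.deg2rad(rot_offsets_deg)
    zero_rot_idx = int(np.argwhere(np.isclose(rots, 0.0))[0][0])

    base_x = system.planted_x.to_array()
    best = np.full(3, np.inf)
    best_idx = np.full(3, -1, dtype=int)
    all_scores = []
    ridx = 0
    for rx in rots:
        for ry in rots:
            for rz in rots:
                x = base_x.copy()
                x[3:6] = [rx, ry, rz]
                pose0 = apply_conformation(lig, ConformationVector.from_array(x))
                batch = pose0[None, :, :] + tg[:, None, :]
                f = _score_all(cfg, lig, site, batch)          # (T, 3)
                all_scores.append(f)
                for k in range(3):
                    j = int(np.argmin(f[:, k]))
                    if f[j, k] < best[k]:
                        best[k] = f[j, k]
                        best_idx[k] = ridx * len(tg) + j
                ridx += 1
    planted_flat = ((zero_rot_idx * len(rots) + zero_rot_idx) * len(rots)
                    + zero_rot_idx) * len(tg) + planted_t_idx
    planted_scores = _score_all(cfg, lig, site, system.planted_pose[None])[0]
    all_scores = np.concatenate(all_scores)
    medians = np.median(all_scores, axis=0)
    for k in range(3):
        if best_idx[k] != planted_flat:
            raise FixtureError(
                f"objective f{k + 1}: grid minimum at flat index {best_idx[k]} "
                f"(score {best[k]:.6f}), not at the planted pose "
                f"(score {planted_scores[k]:.6f})")
        if not np.isfinite(planted_scores[k]) or planted_scores[k] > medians[k]:
            raise FixtureError(f"objective f{k + 1}: planted score not below grid median")
    return {"planted_scores": planted_scores.tolist(),
            "grid_medians": medians.tolist(),
            "grid_best": best.tolist(),
            "n_poses": int(all_scores.shape[0])}


def make_harmonic_pocket(seed: int = 0, verify: bool = True) -> ToySystem:
    """Cage pocket where all three objectives share the planted minimum.

    The rigid 4-heavy-atom star ligand (C center; C, N, O arms) sits with
    each arm atom midway between a symmetric pair of receptor partners at
    that pair's Lennard-Jones minimum distance: symmetric pairs exert zero
    net force on their own atom in every direction, so the planted pose is
    (near-)stationary for the force-field and empirical contact terms, and
    the pair-potential wells are centered on the planted distances.  Two far
    corner atoms (positions mildly seed-jittered) close the cage.
    """
    rng = np.random.default_rng(seed)
    lig = _star_ligand()
    params = ForceFieldParams()

    # one partner ring of 3 per arm, in the plane through the arm atom
    # perpendicular to the arm: an evenly spaced ring at the pair's r_min
    # exerts zero net force on its own atom in every direction.  The common
    # azimuthal phase of each ring is seed-jittered, which changes the
    # emitted coordinates without breaking that cancellation.
    arms = [(np.array([_ARM, 0.0, 0.0]), "Cl", -_ARM_Q, (1, 2)),
            (np.array([0.0, _ARM, 0.0]), "N", _ARM_Q, (0, 2)),
            (np.array([0.0, 0.0, _ARM]), "O", -_ARM_Q, (0, 1))]
    arm_elements = ["C", "N", "O"]
    specs = []
    for (pos, partner_el, q, plane), arm_el in zip(arms, arm_elements):
        r_ring = _pair_rmin(params, arm_el, partner_el)
        phase = rng.uniform(-10.0, 10.0)
        for theta in np.deg2rad([90.0, 210.0, 330.0]) + np.deg2rad(phase):
            offset = np.zeros(3)
            offset[plane[0]] = r_ring * np.cos(theta)
            offset[plane[1]] = r_ring * np.sin(theta)
            specs.append((partner_el, pos + offset, q))
    # the central atom gets a symmetric partner pair along the free body
    # diagonal, cancelling its otherwise-unopposed attraction to the rings
    # the pair is oppositely charged to the ligand core: its Coulomb tail
    # (1/r^2 under the distance-dependent dielectric) funnels the ligand
    # toward the cage center from anywhere in the search box
    diag = np.ones(3) / np.sqrt(3.0)
    r_cc = _pair_rmin(params, "C", "C")
    specs.append(("C", r_cc * diag, _PARTNER_Q))
    specs.append(("C", -r_cc * diag, _PARTNER_Q))
    receptor = _receptor_from_specs(specs)

    planted_pose = lig.coords
    centroid = planted_pose[lig.heavy_mask].mean(axis=0)
    planted_x = ConformationVector(*centroid, 0.0, 0.0, 0.0, torsions=np.zeros(0))
    potential = _planted_distance_pmf(lig, receptor, planted_pose)
    config = DockingConfig(ff_params=params, potential=potential)
    # search box: centroid +- 5 A — about three cage radii, and wider than
    # pi per side so the box-constraint penalty stays translation-neutral
    lo = centroid - 5.0
    hi = centroid + 5.0
    system = ToySystem(receptor=receptor, ligand=lig, planted_pose=planted_pose,
                       planted_x=planted_x, config=config,
                       bounds=Bounds(t_lo=lo, t_hi=hi),
                       notes={"seed": seed, "kind": "harmonic_pocket"})
    err = np.abs(apply_conformation(lig, planted_x) - planted_pose).max()
    if err > 1e-8:
        raise FixtureError(f"planted_x does not reproduce planted_pose ({err:.2e} A)")
    if verify:
        system.notes["verification"] = _verify_pose_grid(system)
    return system


# ---------------------------------------------------------------------------
# conflict system
# ---------------------------------------------------------------------------

_TETRA = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3.0)


def _single_atom_ligand(charge: float = 0.0) -> Ligand:
    return Ligand(atoms=[Atom(1, "C", "C.3", np.zeros(3), charge)], bonds=[],
                  name="PROBE")


def normalized_matrix(scores: np.ndarray) -> np.ndarray:
    """Min-max normalization per objective across a set of compared poses.

    0 is the best value seen for that objective, 1 the worst; this puts the
    three heterogeneous score scales on a common footing so that the worst
    normalized score of a pose measures how unbalanced it is.
    """
    s = np.asarray(scores, dtype=float)
    lo = s.min(axis=0)
    span = np.where(s.max(axis=0) - lo > 1e-12, s.max(axis=0) - lo, 1.0)
    return (s - lo) / span


def make_conflict_system(seed: int = 0, separation: float = 7.0,
                         verify: bool = True) -> ToySystem:
    """Three separated per-objective minima plus a balanced compromise pose.

    Site A couples only to the force-field score (deep-epsilon N atoms),
    site B only to the empirical score (hydrophobic C contacts), site C only
    to the knowledge-based score (a pair-potential well for element P); the
    channels are separated by element-selective parameters.  Each site is a
    tetrahedral cage of 4 atoms at contact radius.  The compromise pose sits
    at the centroid of the three sites; metadata records all four poses.
    With separation 0 the minima coincide and the system degenerates to a
    single shared-optimum pocket.
    """
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    rng = np.random.default_rng(seed)
    lig = _single_atom_ligand(charge=0.5)   # Coulomb funnel toward site A
    radius = separation / np.sqrt(3.0)
    angles = np.deg2rad([0.0, 120.0, 240.0]) + rng.uniform(-0.05, 0.05, 3)
    centers = radius * np.stack([np.cos(angles), np.sin(angles),
                                 np.zeros(3)], axis=1)
    cage_r = 3.7
    elements = ["N", "C", "P"]
    specs = []
    for el, c, phi in zip(elements, centers, angles):
        # tetrahedron in the site's local frame (radial, tangent, z) so every
        # site presents the same geometry toward the central compromise region
        e1 = np.array([np.cos(phi), np.sin(phi), 0.0])
        e2 = np.array([-np.sin(phi), np.cos(phi), 0.0])
        e3 = np.array([0.0, 0.0, 1.0])
        q = -0.3 if el == "N" else 0.0   # site A attracts the charged probe
        for v in _TETRA:
            specs.append((el, c + cage_r * (v[0] * e1 + v[1] * e2 + v[2] * e3), q))
    receptor = _receptor_from_specs(specs)

    lj = dict(ForceFieldParams().lj_table)
    lj.update({"C": (0.05, 3.82), "N": (2.0, 3.65), "P": (0.001, 3.90)})
    ff = ForceFieldParams(lj_table=lj)
    emp_lj = dict(lj)
    emp_lj.update({"N": (0.05, 1.0), "P": (0.05, 1.0)})
    emp = ForceFieldParams(lj_table=emp_lj)

    delta_r, cutoff = 0.1, 8.0
    grid = np.arange(delta_r / 2, cutoff, delta_r)
    well = -2.0 * np.exp(-((grid - cage_r) ** 2) / (2.0 * 2.0 ** 2))
    potential = PMFPotential(
        r_grid=grid,
        tables={("C", "P"): well,
                ("C", "C"): np.zeros_like(grid),
                ("C", "N"): np.zeros_like(grid)},
        delta_r=delta_r, r_cutoff=cutoff, kT=0.593,
        fallback=np.zeros_like(grid))

    config = DockingConfig(ff_params=ff, emp_params=emp, potential=potential)
    compromise = centers.mean(axis=0)
    planted_pose = compromise[None, :].copy()
    planted_x = ConformationVector(*compromise, 0.0, 0.0, 0.0)
    # box covers all three site centers with margin while keeping the central
    # balanced region well-sampled at initialization (and stays wider than pi
    # per side so the box penalty cannot bias translations)
    half = radius + 2.0
    system = ToySystem(receptor=receptor, ligand=lig, planted_pose=planted_pose,
                       planted_x=planted_x, config=config,
                       bounds=Bounds(t_lo=compromise - half, t_hi=compromise + half),
                       notes={"seed": seed, "kind": "conflict",
                              "separation": separation,
                              "site_f1": centers[0].tolist(),
                              "site_f2": centers[1].tolist(),
                              "site_f3": centers[2].tolist(),
                              "compromise": compromise.tolist()})
    if verify and separation > 0:
        system.notes["verification"] = _verify_conflict(system, centers)
    return system


def _verify_conflict(system: ToySystem, centers: np.ndarray,
                     step: float = 0.5) -> dict:
    """Translation-grid oracle: each objective's minimum sits at its own site,
    and the compromise pose is more balanced than any planted site pose."""
    lig, site, cfg = system.ligand, system.site, system.config
    lo, hi = system.bounds.t_lo, system.bounds.t_hi
    axes = [np.arange(lo[d], hi[d] + step / 2, step) for d in range(3)]
    gp = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
    scores = []
    for chunk in np.array_split(gp, max(1, len(gp) // 8000)):
        scores.append(_score_all(cfg, lig, site, chunk[:, None, :]))
    scores = np.concatenate(scores)
    out = {}
    for k in range(3):
        argmin = gp[int(np.argmin(scores[:, k]))]
        dist = float(np.linalg.norm(argmin - centers[k]))
        if dist > 1.0:
            raise FixtureError(
                f"objective f{k + 1}: grid minimum {argmin} is {dist:.2f} A "
                f"from its planted site {centers[k]}")
        out[f"f{k + 1}_grid_min_offset"] = dist

    poses = np.concatenate([centers, system.planted_pose[0][None]])[:, None, :]
    f = _score_all(cfg, lig, site, poses)
    norm = normalized_matrix(f)
    worst = norm.max(axis=1)
    if not np.all(worst[3] < worst[:3]):
        raise FixtureError(
            f"compromise pose is not more balanced: worst normalized scores "
            f"{worst.tolist()}")
    out["worst_normalized"] = worst.tolist()
    out["pose_scores"] = f.tolist()
    return out


# ---------------------------------------------------------------------------
# PMF training samples
# ---------------------------------------------------------------------------

def make_pmf_samples(u_of_r, n: int, kT: float = 0.593, r_max: float = 8.0,
                     seed: int = 0) -> np.ndarray:
    """Distances with density proportional to r^2 exp(-U(r)/kT) on (0, r_max].

    ``u_of_r`` is a callable (vectorized over r); sampling is by
    inverse-transform on a fine grid, deterministic per seed.  This is the
    forward model whose statistics the inverse-Boltzmann derivation must
    invert.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    r = np.linspace(1e-4, r_max, 4001)
    u = np.asarray(u_of_r(r), dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("U(r) must be finite on (0, r_max]")
    log_dens = 2.0 * np.log(r) - u / kT
    dens = np.exp(log_dens - log_dens.max())
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1])
                                           * np.diff(r))])
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    return np.interp(rng.uniform(size=n), cdf, r)


# ---------------------------------------------------------------------------
# optimizer benchmarks
# ---------------------------------------------------------------------------

def make_benchmark_problem(name: str, dim: int | None = None,
                           center_separation: float = 4.0) -> dict:
    """Analytic test problems: ``sphere``, ``rastrigin``, ``tri_objective``.

    Returns a dict with ``objective`` (or ``objectives``), ``bounds`` as
    (lo, hi) arrays, ``optimum_x`` and ``optimum_value``.
    """
    if name == "sphere":
        d = dim or 10

        def sphere(x):
            x = np.asarray(x, dtype=float)
            return (x ** 2).sum(axis=-1)
        return {"objective": sphere,
                "bounds": (np.full(d, -5.12), np.full(d, 5.12)),
                "optimum_x": np.zeros(d), "optimum_value": 0.0}
    if name == "rastrigin":
        d = dim or 6

        def rastrigin(x):
            x = np.asarray(x, dtype=float)
            return 10.0 * x.shape[-1] + (x ** 2
                                         - 10.0 * np.cos(2 * np.pi * x)).sum(axis=-1)
        return {"objective": rastrigin,
                "bounds": (np.full(d, -5.12), np.full(d, 5.12)),
                "optimum_x": np.zeros(d), "optimum_value": 0.0}
    if name == "tri_objective":
        d = dim or 3
        cs = np.zeros((3, d))
        cs[0, 0] = center_separation / 2
        cs[1, 0] = -center_separation / 2
        cs[2, min(1, d - 1)] = center_separation / 2

        def make_bowl(c):
            def bowl(x):
                x = np.asarray(x, dtype=float)
                return ((x - c) ** 2).sum(axis=-1)
            return bowl
        return {"objectives": [make_bowl(c) for c in cs],
                "centers": cs,
                "bounds": (np.full(d, -10.0), np.full(d, 10.0)),
                "optimum_x": cs.mean(axis=0),
                "optimum_value": None}
    raise ValueError(f"unknown benchmark problem {name!r}")
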