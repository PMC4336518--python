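"""The three docking objectives sharing one call contract.

* ``score_forcefield`` (f1) — AMBER-style nonbonded energy: 12-6 Lennard-Jones
  plus Coulomb electrostatics with the 332.0 kcal/mol conversion factor,
  summed over ligand x active-site atom pairs.
* ``score_empirical`` (f2) — an X-Score-style regression of interpretable
  terms (softened van der Waals, hydrogen bonds, rotor penalty, three
  hydrophobic variants), averaged over the three hydrophobic formulations and
  negated so that minimization improves predicted affinity.
* ``score_knowledge`` (f3) — a potential-of-mean-force sum over heavy-atom
  pairs, with the potential derived from pair-distance statistics by the
  inverse Boltzmann relation.

All scorers accept either a single pose ``(n_lig, 3)`` or a batch
``(P, n_lig, 3)`` of poses (returning a ``(P,)`` array), which keeps
population evaluation and grid-search verification cheap.  Distances below
``r_min_clamp`` (0.5 A) are evaluated at the clamp so that scores stay finite
in the steric-clash region the optimizer must cross.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .molecules import ActiveSite, Atom, Ligand, Receptor

__all__ = [
    "ParameterizationError", "Site", "ForceFieldParams", "EmpiricalCoefficients",
    "EmpiricalTerms", "PMFPotential", "score_forcefield",
    "compute_empirical_terms", "score_empirical", "derive_pmf",
    "score_knowledge", "read_potential_table", "write_potential_table",
    "COULOMB_FACTOR", "R_MIN_CLAMP", "DEFAULT_LJ_TABLE",
]

COULOMB_FACTOR = 332.0   # converts e^2/A to kcal/mol
R_MIN_CLAMP = 0.5        # A; pair distances are floored here in f1 and f3
HYDROPHOBIC_ELEMENTS = frozenset({"C", "S"})
POLAR_ELEMENTS = frozenset({"N", "O"})

# per-element Lennard-Jones well depth (kcal/mol) and homonuclear-pair
# minimum-energy distance (A); "X" is the generic fallback type
DEFAULT_LJ_TABLE: dict[str, tuple[float, float]] = {
    "C": (0.086, 3.82), "N": (0.170, 3.65), "O": (0.210, 3.44),
    "S": (0.250, 4.00), "P": (0.200, 4.20), "H": (0.015, 2.00),
    "F": (0.061, 3.50), "Cl": (0.265, 3.94), "Br": (0.320, 4.22),
    "I": (0.400, 4.46), "X": (0.100, 3.80),
}


class ParameterizationError(KeyError):
    """An atom-type pair has no parameters and no fallback is configured."""


@dataclass
class Site:
    """Active-site atoms flattened to arrays for vectorized scoring."""

    coords: np.ndarray          # (m, 3)
    elements: list[str]
    charges: np.ndarray         # (m,)
    is_heavy: np.ndarray        # (m,) bool

    @classmethod
    def from_atoms(cls, atoms: list[Atom]) -> "Site":
        return cls(coords=np.array([a.coords for a in atoms], dtype=float),
                   elements=[a.element for a in atoms],
                   charges=np.array([a.charge for a in atoms], dtype=float),
                   is_heavy=np.array([a.is_heavy for a in atoms], dtype=bool))

    @classmethod
    def from_receptor(cls, receptor: Receptor, site: ActiveSite) -> "Site":
        return cls.from_atoms([receptor.atoms[i] for i in site.atom_ids])

    def __len__(self) -> int:
        return len(self.elements)


@dataclass
class ForceFieldParams:
    """Lennard-Jones and dielectric parameters for the force-field objective.

    Per-element (epsilon, r_min) rows are combined Lorentz-Berthelot style:
    eps_ij = sqrt(eps_i * eps_j), rmin_ij = (rmin_i + rmin_j)/2, then
    A_ij = eps_ij * rmin_ij**12 and B_ij = 2 * eps_ij * rmin_ij**6, so each
    pair term has its minimum -eps_ij at rmin_ij.  The dielectric is either
    constant D or distance-dependent D = k * r (default k = 4).
    """

    lj_table: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LJ_TABLE))
    dielectric_model: str = "distance_dependent"   # or "constant"
    dielectric_value: float = 4.0                  # k for D=k*r, or D itself
    coulomb_factor: float = COULOMB_FACTOR
    r_min_clamp: float = R_MIN_CLAMP

    def _row(self, element: str) -> tuple[float, float]:
        if element in self.lj_table:
            return self.lj_table[element]
        if "X" in self.lj_table:
            return self.lj_table["X"]
        raise ParameterizationError(
            f"no Lennard-Jones parameters for element {element!r} and no "
            "generic 'X' fallback in the table")

    def ab_matrices(self, lig_elements: list[str],
                    site_elements: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """A_ij, B_ij arrays of shape (n_lig, n_site)."""
        le = np.array([self._row(e) for e in lig_elements])
        se = np.array([self._row(e) for e in site_elements])
        eps = np.sqrt(le[:, 0, None] * se[None, :, 0])
        rmin = 0.5 * (le[:, 1, None] + se[None, :, 1])
        a = eps * rmin ** 12
        b = 2.0 * eps * rmin ** 6
        return a, b


def _pair_distances(lig_coords: np.ndarray, site: Site) -> tuple[np.ndarray, bool]:
    """Distance array (P, n, m) plus a flag for whether input was batched."""
    xyz = np.asarray(lig_coords, dtype=float)
    batched = xyz.ndim == 3
    if not batched:
        xyz = xyz[None]
    diff = xyz[:, :, None, :] - site.coords[None, None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1)), batched


def score_forcefield(lig_coords: np.ndarray, lig_atoms: list[Atom],
                     site: Site, params: ForceFieldParams | None = None):
    """Force-field objective f1 in kcal/mol (scalar, or (P,) for a pose batch).

    f1 = sum_i sum_j [ A_ij/r^12 - B_ij/r^6 + 332.0 q_i q_j / (D r) ] over
    ligand atoms i and active-site atoms j.
    """
    params = params or ForceFieldParams()
    if len(site) == 0:
        r, batched = _pair_distances(lig_coords, Site(np.zeros((0, 3)), [], np.zeros(0), np.zeros(0, bool)))
        return np.zeros(r.shape[0]) if batched else 0.0
    r, batched = _pair_distances(lig_coords, site)
    r = np.maximum(r, params.r_min_clamp)
    a, b = params.ab_matrices([x.element for x in lig_atoms], site.elements)
    inv6 = r ** -6
    lj = a * inv6 ** 2 - b * inv6
    qq = np.array([x.charge for x in lig_atoms])[:, None] * site.charges[None, :]
    if params.dielectric_model == "distance_dependent":
        elec = params.coulomb_factor * qq / (params.dielectric_value * r ** 2)
    elif params.dielectric_model == "constant":
        elec = params.coulomb_factor * qq / (params.dielectric_value * r)
    else:
        raise ValueError(f"unknown dielectric model {params.dielectric_model!r}")
    total = (lj + elec).sum(axis=(1, 2))
    return total if batched else float(total[0])


# ---------------------------------------------------------------------------
# Empirical objective
# ---------------------------------------------------------------------------

@dataclass
class EmpiricalCoefficients:
    """Regression weights: three rows of (C0, C1, C2, C3, C4).

    Row i weights (intercept, E_vdw, E_hb, E_def, E_hyd_i) in the i-th
    affinity estimate; the published weights are regression data external to
    the method, so the shipped default is the unit-weight row (0, 1, 1, 1, 1).
    """

    rows: np.ndarray = field(
        default_factory=lambda: np.array([[0.0, 1, 1, 1, 1]] * 3, dtype=float))

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.shape != (3, 5):
            raise ValueError("need exactly three rows of five coefficients")


@dataclass
class EmpiricalTerms:
    """Interpretable interaction terms feeding the empirical regression.

    Fields are scalars for a single pose or (P,) arrays for a batch.
    """

    e_vdw: np.ndarray | float
    e_hb: np.ndarray | float
    e_def: float
    e_hyd_1: np.ndarray | float
    e_hyd_2: np.ndarray | float
    e_hyd_3: np.ndarray | float


HB_R_ON = 2.6    # A: switch is 1 at or below
HB_R_OFF = 3.2   # A: switch is 0 at or beyond
HYD_CONTACT_R = 4.5       # A: hydrophobic contact cutoff
HYD_SATURATION = 6        # neighbor count at which the surface proxy saturates


def _hb_switch(r: np.ndarray) -> np.ndarray:
    return np.clip((HB_R_OFF - r) / (HB_R_OFF - HB_R_ON), 0.0, 1.0)


def _ligand_donor_mask(ligand: Ligand) -> np.ndarray:
    """Polar ligand heavy atoms (N, O) carrying at least one bonded hydrogen."""
    has_h = np.zeros(len(ligand.atoms), dtype=bool)
    for b in ligand.bonds:
        ea = ligand.atoms[b.atom_a].element.upper()
        eb = ligand.atoms[b.atom_b].element.upper()
        if ea == "H":
            has_h[b.atom_b] = True
        if eb == "H":
            has_h[b.atom_a] = True
    polar = np.array([a.element.upper() in POLAR_ELEMENTS for a in ligand.atoms])
    return polar & has_h


def compute_empirical_terms(lig_coords: np.ndarray, lig_atoms: list[Atom],
                            ligand: Ligand, site: Site,
                            params: ForceFieldParams | None = None) -> EmpiricalTerms:
    """Evaluate the empirical interaction terms for one pose or a batch.

    e_vdw   softened 8-4 contact potential, positive at ideal contact
            (sum of 2 (d0/r)^4 - (d0/r)^8 with d0 the pair r_min);
    e_hb    donor-acceptor distance switch, 1 at <= 2.6 A, 0 at >= 3.2 A;
    e_def   rotatable-bond count (conformation-independent rotor penalty);
    e_hyd_1 hydrophobic pair-contact count (C/S x C/S within 4.5 A);
    e_hyd_2 hydrophobic-surface proxy (saturating neighbor counts);
    e_hyd_3 hydrophobic-matching count (nearest site atom is hydrophobic).
    """
    params = params or ForceFieldParams()
    r, batched = _pair_distances(lig_coords, site)
    rc = np.maximum(r, params.r_min_clamp)

    _, b_mat = params.ab_matrices([x.element for x in lig_atoms], site.elements)
    le = np.array([params._row(x.element) for x in lig_atoms])
    se = np.array([params._row(e) for e in site.elements])
    d0 = 0.5 * (le[:, 1, None] + se[None, :, 1])
    frac4 = (d0 / rc) ** 4
    e_vdw = (2.0 * frac4 - frac4 ** 2).sum(axis=(1, 2))

    lig_polar = np.array([a.element.upper() in POLAR_ELEMENTS for a in lig_atoms])
    lig_donor = _ligand_donor_mask(ligand)[:len(lig_atoms)]
    site_el = np.array([e.upper() for e in site.elements])
    site_acceptor = np.isin(site_el, list(POLAR_ELEMENTS))
    site_donor = site_el == "N"   # receptor bonds are unknown; N taken donor-capable
    hb_pair = (lig_donor[:, None] & site_acceptor[None, :]) | \
              (lig_polar[:, None] & site_donor[None, :])
    e_hb = (_hb_switch(r) * hb_pair[None]).sum(axis=(1, 2))

    e_def = float(ligand.n_torsions)

    lig_hyd = np.array([a.element.upper() in HYDROPHOBIC_ELEMENTS and a.is_heavy
                        for a in lig_atoms])
    site_hyd = np.isin(site_el, list(HYDROPHOBIC_ELEMENTS)) & site.is_heavy
    contact = (r <= HYD_CONTACT_R) & (lig_hyd[:, None] & site_hyd[None, :])[None]
    e_hyd_1 = contact.sum(axis=(1, 2)).astype(float)

    neigh = contact.sum(axis=2)                      # (P, n_lig)
    e_hyd_2 = (np.minimum(neigh, HYD_SATURATION) / HYD_SATURATION)[:, lig_hyd].sum(axis=1)

    if site.is_heavy.any() and lig_hyd.any():
        r_heavy = np.where(site.is_heavy[None, None, :], r, np.inf)
        nearest = np.argmin(r_heavy, axis=2)         # (P, n_lig)
        e_hyd_3 = (site_hyd[nearest] & lig_hyd[None, :]).sum(axis=1).astype(float)
    else:
        e_hyd_3 = np.zeros(r.shape[0])

    if not batched:
        return EmpiricalTerms(float(e_vdw[0]), float(e_hb[0]), e_def,
                              float(e_hyd_1[0]), float(e_hyd_2[0]), float(e_hyd_3[0]))
    return EmpiricalTerms(e_vdw, e_hb, e_def, e_hyd_1, e_hyd_2, e_hyd_3)


def score_empirical(terms: EmpiricalTerms, coeffs: EmpiricalCoefficients | None = None):
    """Empirical objective f2: negated mean of the three affinity estimates.

    pKd_i = C0_i + C1_i E_vdw + C2_i E_hb + C3_i E_def + C4_i E_hyd_i; the
    mean over i is an affinity (larger = better binding), so the returned
    score is its negation — minimization then improves predicted affinity.
    """
    c = (coeffs or EmpiricalCoefficients()).rows
    hyd = [terms.e_hyd_1, terms.e_hyd_2, terms.e_hyd_3]
    pk = [c[i, 0] + c[i, 1] * terms.e_vdw + c[i, 2] * terms.e_hb
          + c[i, 3] * terms.e_def + c[i, 4] * hyd[i] for i in range(3)]
    out = -(pk[0] + pk[1] + pk[2]) / 3.0
    return out if isinstance(out, np.ndarray) else float(out)


# ---------------------------------------------------------------------------
# Knowledge-based objective (potential of mean force)
# ---------------------------------------------------------------------------

@dataclass
class PMFPotential:
    """Tabulated pair potentials A_ij(r) on a shared radial grid.

    ``tables`` maps an (element_i, element_j) pair (looked up symmetrically)
    to A values at ``r_grid`` bin centers; beyond ``r_cutoff`` the potential
    is zero.  ``fallback`` optionally supplies a table for unlisted pairs.
    """

    r_grid: np.ndarray
    tables: dict[tuple[str, str], np.ndarray]
    delta_r: float
    r_cutoff: float
    kT: float = 0.593
    fallback: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        if np.any(np.diff(self.r_grid) <= 0):
            raise ValueError("r_grid must be strictly increasing")
        for k, v in self.tables.items():
            self.tables[k] = np.asarray(v, dtype=float)
            if not np.all(np.isfinite(self.tables[k])):
                raise ValueError(f"non-finite potential values for pair {k}")

    def lookup(self, t_lig: str, t_site: str) -> np.ndarray:
        for key in ((t_lig, t_site), (t_site, t_lig)):
            if key in self.tables:
                return self.tables[key]
        if self.fallback is not None:
            return self.fallback
        raise ParameterizationError(
            f"no potential table for pair ({t_lig}, {t_site}) and no fallback")


def derive_pmf(pair_observations: dict[tuple[str, str], np.ndarray],
               bulk_density: dict[tuple[str, str], float] | float,
               delta_r: float = 0.2, r_cutoff: float = 8.0,
               kT: float = 0.593, vol_corr=None, n_structures: int = 1,
               empty_bin_ceiling_kT: float = 3.0) -> PMFPotential:
    """Inverse-Boltzmann derivation of pair potentials from distance statistics.

    For each pair type the observed distances are binned into spherical
    shells [r, r + delta_r); the shell number density
    rho_seg(r) = count / (4 pi r_c^2 delta_r) / n_structures (r_c the bin
    center) is compared with the non-interacting bulk density, and
    A(r) = -kT ln[ vol_corr(r) * rho_seg(r) / rho_bulk ].  Empty bins get a
    finite repulsive ceiling of ``empty_bin_ceiling_kT`` * kT so the table
    stays usable where statistics run out.
    """
    if delta_r <= 0:
        raise ValueError("delta_r must be positive")
    edges = np.arange(0.0, r_cutoff + delta_r / 2, delta_r)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell_vol = 4.0 * np.pi * centers ** 2 * delta_r
    corr = np.ones_like(centers) if vol_corr is None else np.asarray(
        [vol_corr(r) for r in centers], dtype=float)
    tables: dict[tuple[str, str], np.ndarray] = {}
    for pair, dists in pair_observations.items():
        dists = np.asarray(dists, dtype=float)
        if np.any(dists < 0):
            raise ValueError(f"negative distance for pair {pair}")
        rho_b = bulk_density[pair] if isinstance(bulk_density, dict) else bulk_density
        if rho_b <= 0:
            raise ValueError(f"bulk density for pair {pair} must be positive")
        counts, _ = np.histogram(dists, bins=edges)
        rho_seg = counts / shell_vol / n_structures
        with np.errstate(divide="ignore"):
            a = -kT * np.log(corr * rho_seg / rho_b)
        a[counts == 0] = empty_bin_ceiling_kT * kT
        tables[pair] = a
    return PMFPotential(r_grid=centers, tables=tables, delta_r=delta_r,
                        r_cutoff=r_cutoff, kT=kT)


def score_knowledge(lig_coords: np.ndarray, lig_atoms: list[Atom],
                    site: Site, potential: PMFPotential):
    """Knowledge-based objective f3: sum of A_ij(r) over heavy-atom pairs.

    Only heavy-atom pairs with r < r_cutoff contribute; A is linearly
    interpolated between bin centers (flat extension at the grid ends,
    distances floored at the clash clamp).
    """
    r, batched = _pair_distances(lig_coords, site)
    r = np.maximum(r, R_MIN_CLAMP)
    lig_heavy = np.array([a.is_heavy for a in lig_atoms])
    total = np.zeros(r.shape[0])
    for i, la in enumerate(lig_atoms):
        if not lig_heavy[i]:
            continue
        for j, el in enumerate(site.elements):
            if not site.is_heavy[j]:
                continue
            table = potential.lookup(la.element, el)
            rij = r[:, i, j]
            within = rij < potential.r_cutoff
            if np.any(within):
                vals = np.interp(rij[within], potential.r_grid, table)
                total[within] += vals
    return total if batched else float(total[0])


# ---------------------------------------------------------------------------
# Potential table text format
# ---------------------------------------------------------------------------

def write_potential_table(potential: PMFPotential) -> str:
    """Serialize to the plain-text table format (round-trip exact)."""
    out = io.StringIO()
    out.write(f"delta_r {potential.delta_r!r}\n")
    out.write(f"r_cutoff {potential.r_cutoff!r}\n")
    out.write(f"kT {potential.kT!r}\n")
    for (ti, tj), a in sorted(potential.tables.items()):
        for r, v in zip(potential.r_grid, a):
            out.write(f"{ti} {tj} {float(r)!r} {float(v)!r}\n")
    return out.getvalue()


def read_potential_table(text: str) -> PMFPotential:
    header: dict[str, float] = {}
    rows: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) == 2 and parts[0] in ("delta_r", "r_cutoff", "kT"):
            header[parts[0]] = float(parts[1])
            continue
        if len(parts) != 4:
            raise ValueError(f"potential table line {ln}: expected 'type_i type_j r A'")
        rows.setdefault((parts[0], parts[1]), []).append((float(parts[2]), float(parts[3])))
    for need in ("delta_r", "r_cutoff", "kT"):
        if need not in header:
            raise ValueError(f"potential table missing header field {need}")
    grid: np.ndarray | None = None
    tables: dict[tuple[str, str], np.ndarray] = {}
    for pair, pts in rows.items():
        pts.sort(key=lambda p: p[0])
        r = np.array([p[0] for p in pts])
        if grid is None:
            grid = r
        elif len(r) != len(grid) or not np.array_equal(r, grid):
            raise ValueError(f"pair {pair} uses a different radial grid")
        tables[pair] = np.array([p[1] for p in pts])
    if grid is None:
        raise ValueError("potential table contains no data rows")
    return PMFPotential(r_grid=grid, tables=tables, delta_r=header["delta_r"],
                        r_cutoff=header["r_cutoff"], kT=header["kT"])
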