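"""The three scoring functions against naive oracles and analytic cases."""

import math

import numpy as np
import pytest

from modock.molecules import Atom, Bond, Ligand
from modock.scoring import (DEFAULT_LJ_TABLE, EmpiricalCoefficients,
                            EmpiricalTerms, ForceFieldParams,
                            ParameterizationError, PMFPotential, Site,
                            compute_empirical_terms, derive_pmf,
                            read_potential_table, score_empirical,
                            score_forcefield, score_knowledge,
                            write_potential_table)
from modock.fixtures import make_pmf_samples

# ---------------------------------------------------------------------------
# naive pure-python oracles (independent of the vectorized implementations)
# ---------------------------------------------------------------------------


def naive_forcefield(lig_coords, lig_atoms, site, params):
    total = 0.0
    for i, a in enumerate(lig_atoms):
        for j in range(len(site)):
            r = max(math.dist(lig_coords[i], site.coords[j]), params.r_min_clamp)
            ei = params.lj_table.get(a.element, params.lj_table.get("X"))
            ej = params.lj_table.get(site.elements[j], params.lj_table.get("X"))
            eps = math.sqrt(ei[0] * ej[0])
            rmin = 0.5 * (ei[1] + ej[1])
            aa, bb = eps * rmin ** 12, 2 * eps * rmin ** 6
            lj = aa / r ** 12 - bb / r ** 6
            qq = a.charge * site.charges[j]
            if params.dielectric_model == "distance_dependent":
                elec = params.coulomb_factor * qq / (params.dielectric_value * r * r)
            else:
                elec = params.coulomb_factor * qq / (params.dielectric_value * r)
            total += lj + elec
    return total


def naive_knowledge(lig_coords, lig_atoms, site, pot):
    total = 0.0
    for i, a in enumerate(lig_atoms):
        if not a.is_heavy:
            continue
        for j in range(len(site)):
            if not site.is_heavy[j]:
                continue
            r = max(math.dist(lig_coords[i], site.coords[j]), 0.5)
            if r >= pot.r_cutoff:
                continue
            table = pot.lookup(a.element, site.elements[j])
            total += float(np.interp(r, pot.r_grid, table))
    return total


def random_system(rng, n_lig=8, n_site=20):
    elements = ["C", "N", "O", "S", "H"]
    lig_atoms = [Atom(i + 1, rng.choice(elements), "X",
                      rng.uniform(-3, 3, 3), rng.uniform(-0.4, 0.4))
                 for i in range(n_lig)]
    bonds = [Bond(i, i + 1) for i in range(n_lig - 1)]
    lig = Ligand(atoms=lig_atoms, bonds=bonds, name="RND")
    site_atoms = [Atom(100 + i, rng.choice(elements), "X",
                       rng.uniform(-6, 6, 3), rng.uniform(-0.4, 0.4))
                  for i in range(n_site)]
    return lig, Site.from_atoms(site_atoms)


def test_forcefield_matches_naive_oracle():
    rng = np.random.default_rng(0)
    params = ForceFieldParams()
    for _ in range(10):
        lig, site = random_system(rng)
        got = score_forcefield(lig.coords, lig.atoms, site, params)
        want = naive_forcefield(lig.coords, lig.atoms, site, params)
        assert got == pytest.approx(want, rel=1e-9)


def test_knowledge_matches_naive_oracle():
    rng = np.random.default_rng(1)
    grid = np.arange(0.1, 8.0, 0.2)
    pot = PMFPotential(r_grid=grid, tables={}, delta_r=0.2, r_cutoff=8.0,
                       fallback=np.sin(grid))
    for _ in range(10):
        lig, site = random_system(rng)
        got = score_knowledge(lig.coords, lig.atoms, site, pot)
        want = naive_knowledge(lig.coords, lig.atoms, site, pot)
        assert got == pytest.approx(want, rel=1e-9, abs=1e-12)


def test_batched_scores_equal_sequential():
    rng = np.random.default_rng(2)
    lig, site = random_system(rng)
    params = ForceFieldParams()
    batch = np.stack([lig.coords + rng.normal(0, 0.5, lig.coords.shape)
                      for _ in range(7)])
    got = score_forcefield(batch, lig.atoms, site, params)
    for p in range(7):
        assert got[p] == pytest.approx(
            score_forcefield(batch[p], lig.atoms, site, params), rel=1e-12)


# ---------------------------------------------------------------------------
# force-field analytics
# ---------------------------------------------------------------------------

def _pair_system(e1, e2, r, q1=0.0, q2=0.0):
    a = Atom(1, e1, e1, np.zeros(3), q1)
    s = Site.from_atoms([Atom(2, e2, e2, np.array([r, 0.0, 0.0]), q2)])
    return a, s


def test_coulomb_factor_332():
    a, s = _pair_system("C", "C", 1.0, 1.0, 1.0)
    params = ForceFieldParams(lj_table={"C": (0.0, 1.0)},
                              dielectric_model="constant", dielectric_value=1.0)
    assert score_forcefield(np.zeros((1, 3)), [a], s, params) == pytest.approx(332.0)


def test_lj_minimum_location_and_depth():
    params = ForceFieldParams(lj_table={"C": (0.3, 3.5)},
                              dielectric_model="constant", dielectric_value=1.0)
    A, B = params.ab_matrices(["C"], ["C"])
    A, B = float(A[0, 0]), float(B[0, 0])
    rstar = (2 * A / B) ** (1 / 6)
    a, s = _pair_system("C", "C", rstar)
    e_min = score_forcefield(np.zeros((1, 3)), [a], s, params)
    assert e_min == pytest.approx(-B ** 2 / (4 * A), rel=1e-12)
    # numerically: neighbors of r* are higher
    for dr in (-1e-3, 1e-3):
        a2, s2 = _pair_system("C", "C", rstar + dr)
        assert score_forcefield(np.zeros((1, 3)), [a2], s2, params) > e_min


def test_empty_site_scores_zero():
    a = Atom(1, "C", "C", np.zeros(3), 0.1)
    empty = Site(np.zeros((0, 3)), [], np.zeros(0), np.zeros(0, dtype=bool))
    assert score_forcefield(np.zeros((1, 3)), [a], empty) == 0.0


def test_unknown_pair_without_fallback_raises():
    table = {k: v for k, v in DEFAULT_LJ_TABLE.items() if k != "X"}
    params = ForceFieldParams(lj_table=table)
    a, s = _pair_system("C", "Zz", 3.0)
    with pytest.raises(ParameterizationError, match="Zz"):
        score_forcefield(np.zeros((1, 3)), [a], s, params)


def test_clash_region_monotone_increasing():
    """With A > 0 the pair energy rises monotonically as r drops to the clamp."""
    params = ForceFieldParams(lj_table={"C": (0.2, 3.6)},
                              dielectric_model="constant", dielectric_value=1.0)
    rs = np.linspace(0.5, 2.5, 40)
    vals = []
    for r in rs:
        a, s = _pair_system("C", "C", r)
        vals.append(score_forcefield(np.zeros((1, 3)), [a], s, params))
    assert np.all(np.diff(vals) < 0)      # decreasing with r => increasing as r -> clamp
    assert np.isfinite(vals[0])


# ---------------------------------------------------------------------------
# invariances
# ---------------------------------------------------------------------------

def _all_scores(lig, site, pot):
    f1 = score_forcefield(lig.coords, lig.atoms, site)
    terms = compute_empirical_terms(lig.coords, lig.atoms, lig, site)
    f2 = score_empirical(terms)
    f3 = score_knowledge(lig.coords, lig.atoms, site, pot)
    return np.array([f1, f2, f3])


def test_rigid_motion_of_complex_leaves_scores_unchanged():
    from scipy.spatial.transform import Rotation
    rng = np.random.default_rng(3)
    grid = np.arange(0.1, 8.0, 0.2)
    pot = PMFPotential(r_grid=grid, tables={}, delta_r=0.2, r_cutoff=8.0,
                       fallback=-np.exp(-(grid - 4) ** 2))
    for _ in range(5):
        lig, site = random_system(rng)
        before = _all_scores(lig, site, pot)
        rot = Rotation.random(rng=rng)
        shift = rng.uniform(-10, 10, 3)
        for a in lig.atoms:
            a.coords = rot.apply(a.coords) + shift
        site2 = Site(rot.apply(site.coords) + shift, site.elements,
                     site.charges, site.is_heavy)
        after = _all_scores(lig, site2, pot)
        np.testing.assert_allclose(after, before, atol=1e-8)


def test_site_permutation_invariance():
    rng = np.random.default_rng(4)
    grid = np.arange(0.1, 8.0, 0.2)
    pot = PMFPotential(r_grid=grid, tables={}, delta_r=0.2, r_cutoff=8.0,
                       fallback=np.cos(grid))
    lig, site = random_system(rng)
    before = _all_scores(lig, site, pot)
    perm = rng.permutation(len(site))
    site2 = Site(site.coords[perm], [site.elements[i] for i in perm],
                 site.charges[perm], site.is_heavy[perm])
    np.testing.assert_allclose(_all_scores(lig, site2, pot), before, atol=1e-10)


# ---------------------------------------------------------------------------
# empirical terms and regression
# ---------------------------------------------------------------------------

def test_rotor_count_term():
    lig, site = random_system(np.random.default_rng(5), n_lig=4)
    terms = compute_empirical_terms(lig.coords, lig.atoms, lig, site)
    assert terms.e_def == lig.n_torsions


def test_hbond_switch_plateau():
    # ligand N with an H at 2.0 A from a site O: full-strength hydrogen bond
    n = Atom(1, "N", "N.3", np.zeros(3), -0.4)
    h = Atom(2, "H", "H", np.array([0.0, 1.0, 0.0]), 0.3)
    lig = Ligand(atoms=[n, h], bonds=[Bond(0, 1)], name="NH")
    site = Site.from_atoms([Atom(3, "O", "O.2", np.array([2.0, 0.0, 0.0]), -0.5)])
    terms = compute_empirical_terms(lig.coords, lig.atoms, lig, site)
    assert terms.e_hb == pytest.approx(1.0)


def test_hbond_switch_is_linear_between_cutoffs():
    n = Atom(1, "N", "N.3", np.zeros(3), -0.4)
    h = Atom(2, "H", "H", np.array([0.0, 1.0, 0.0]), 0.3)
    lig = Ligand(atoms=[n, h], bonds=[Bond(0, 1)], name="NH")
    site = Site.from_atoms([Atom(3, "O", "O.2", np.array([2.9, 0.0, 0.0]), -0.5)])
    terms = compute_empirical_terms(lig.coords, lig.atoms, lig, site)
    assert terms.e_hb == pytest.approx(0.5)


def test_hydrophobic_contact_cutoff():
    c = Atom(1, "C", "C.3", np.zeros(3), 0.0)
    lig = Ligand(atoms=[c], bonds=[], name="C1")
    far = Site.from_atoms([Atom(2, "C", "C.3", np.array([10.0, 0, 0]), 0.0)])
    near = Site.from_atoms([Atom(2, "C", "C.3", np.array([4.0, 0, 0]), 0.0)])
    assert compute_empirical_terms(lig.coords, lig.atoms, lig, far).e_hyd_1 == 0
    assert compute_empirical_terms(lig.coords, lig.atoms, lig, near).e_hyd_1 == 1


@pytest.mark.parametrize("rows, terms, expected", [
    (np.zeros((3, 5)), EmpiricalTerms(5, 1, 2, 3, 4, 5), 0.0),
    (np.array([[1, 0, 0, 0, 0]] * 3), EmpiricalTerms(9, 9, 9, 9, 9, 9), -1.0),
    (np.array([[0, 1, 0, 0, 0], [0, 0, 0, 0, 0], [0, 0, 0, 0, 0]]),
     EmpiricalTerms(3.0, 0, 0, 0, 0, 0), -1.0),
])
def test_empirical_regression_hand_cases(rows, terms, expected):
    coeffs = EmpiricalCoefficients(rows)
    assert score_empirical(terms, coeffs) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# PMF derivation
# ---------------------------------------------------------------------------

def test_pmf_flat_density_gives_zero_potential():
    # rho_seg == rho_bulk in every bin => A == 0 (ln 1)
    rng = np.random.default_rng(6)
    # draw r^2-weighted distances => uniform number density
    d = make_pmf_samples(lambda r: np.zeros_like(r), n=400000, r_max=8.0, seed=6)
    rho_bulk = 400000 / (4 / 3 * np.pi * 8.0 ** 3)
    pot = derive_pmf({("C", "C"): d}, rho_bulk, delta_r=0.5, r_cutoff=8.0, kT=1.0)
    a = pot.tables[("C", "C")]
    inner = pot.r_grid > 1.5                 # small-r bins are noise-dominated
    assert np.abs(a[inner]).max() < 0.05


def test_pmf_analytic_bin():
    # a single bin with rho_seg = e * rho_bulk and kT = 1 => A = -1 there
    delta_r = 0.5
    r_lo = 2.0
    center = r_lo + delta_r / 2
    shell = 4 * np.pi * center ** 2 * delta_r
    rho_bulk = 10.0
    n = int(round(np.e * rho_bulk * shell))
    d = np.full(n, center)
    pot = derive_pmf({("C", "C"): d}, rho_bulk, delta_r=delta_r, r_cutoff=8.0, kT=1.0)
    idx = int(np.argmin(np.abs(pot.r_grid - center)))
    assert pot.tables[("C", "C")][idx] == pytest.approx(-1.0, abs=2e-3)


def test_pmf_empty_bins_get_finite_ceiling():
    pot = derive_pmf({("C", "C"): np.array([3.1])}, 1.0, delta_r=0.2,
                     r_cutoff=8.0, kT=1.0)
    a = pot.tables[("C", "C")]
    assert np.all(np.isfinite(a))
    assert a[0] == pytest.approx(3.0)        # ceiling = +3 kT


def test_pmf_zero_bulk_density_rejected():
    with pytest.raises(ValueError, match="bulk density"):
        derive_pmf({("C", "C"): np.array([1.0])}, 0.0)


def test_pmf_recovery_from_samples():
    """Inverse-Boltzmann derivation recovers the generating potential."""
    kT = 0.593
    def U(r):
        return 1.2 * np.exp(-((r - 3.5) ** 2) / 0.72) \
            - 0.8 * np.exp(-((r - 5.0) ** 2) / 1.28)
    d = make_pmf_samples(U, n=50000, kT=kT, r_max=8.0, seed=9)
    pot = derive_pmf({("C", "C"): d}, 1.0, delta_r=0.2, r_cutoff=8.0, kT=kT)
    counts, _ = np.histogram(d, bins=np.arange(0.0, 8.0 + 0.1, 0.2))
    mask = counts >= 200
    resid = pot.tables[("C", "C")][mask] - U(pot.r_grid[mask])
    resid -= np.average(resid, weights=counts[mask])
    rms = np.sqrt(np.average(resid ** 2, weights=counts[mask]))
    assert rms < 0.1 * kT


# ---------------------------------------------------------------------------
# knowledge-based lookup
# ---------------------------------------------------------------------------

def _one_pair_potential():
    grid = np.array([1.0, 2.0, 3.0, 4.0])
    return PMFPotential(r_grid=grid, tables={("C", "C"): np.array([5.0, 2.0, 4.0, 1.0])},
                        delta_r=1.0, r_cutoff=5.0)


def test_knowledge_beyond_cutoff_zero():
    pot = _one_pair_potential()
    a, s = _pair_system("C", "C", 6.0)
    assert score_knowledge(np.zeros((1, 3)), [a], s, pot) == 0.0


def test_knowledge_bin_center_exact_and_midpoint_interpolated():
    pot = _one_pair_potential()
    a, s = _pair_system("C", "C", 2.0)
    assert score_knowledge(np.zeros((1, 3)), [a], s, pot) == pytest.approx(2.0)
    a, s = _pair_system("C", "C", 2.5)
    assert score_knowledge(np.zeros((1, 3)), [a], s, pot) == pytest.approx(3.0)


def test_knowledge_uncovered_pair_raises():
    pot = _one_pair_potential()
    a, s = _pair_system("N", "N", 2.0)
    with pytest.raises(ParameterizationError):
        score_knowledge(np.zeros((1, 3)), [a], s, pot)


def test_potential_table_round_trip_exact():
    grid = np.arange(0.1, 6.0, 0.2)
    pot = PMFPotential(r_grid=grid,
                       tables={("C", "O"): np.sin(grid) * 1.7,
                               ("N", "C"): np.cos(grid) / 3.0},
                       delta_r=0.2, r_cutoff=6.0, kT=0.593)
    back = read_potential_table(write_potential_table(pot))
    assert back.delta_r == pot.delta_r
    assert back.r_cutoff == pot.r_cutoff
    assert back.kT == pot.kT
    np.testing.assert_array_equal(back.r_grid, pot.r_grid)
    for k in pot.tables:
        np.testing.assert_array_equal(back.tables[k], pot.tables[k])
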