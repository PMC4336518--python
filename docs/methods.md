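# Methods

This note documents the model implemented by `modock`, the parameters that
matter, the synthetic systems the tests run on, and the numerical and design
choices made where the method leaves room.

## Model and assumptions

The ligand is flexible only in its torsions: bond lengths, angles and ring
geometries are frozen at their input values, and the receptor is rigid. A
pose is the vector X = (T, R, Tb) of centroid translation (Å), intrinsic
Z–Y–X Euler angles, and one torsion per rotatable bond; all angular
variables live on the periodic interval [−π, π] and proposals outside it are
wrapped, never clamped. Applying X performs torsion rotations first
(root-to-leaves through the torsion tree), then the rigid rotation about the
heavy-atom centroid, then translation of that centroid to T — so
X = (centroid, 0, 0, 0, …) is the identity. Under this target-centroid
convention a torsion re-anchors the whole molecule: the operational meaning
of "a torsion moves only its distal side" is that the fixed side undergoes
no internal change (one common translation, all internal distances exact),
which is what the kinematics tests assert.

A bond is rotatable when it is single, acyclic (not on any ring, via bridge
detection on the bond graph), not an amide (C–N with a double-bonded O on
the carbon, or a MOL2 `am` bond), and not terminal — terminal meaning either
side's moved set contains no heavy atom besides the bond atom itself. The
torsion-tree root is the atom nearest the heavy-atom centroid, which keeps
torsion lever arms short; any fixed deterministic rule would do.

## The three objectives

**Force field (f1).** 12-6 Lennard-Jones plus Coulomb over ligand ×
active-site atom pairs, 332.0 kcal·mol⁻¹·Å·e⁻² conversion. Pair parameters
come from per-element (ε, r_min) rows combined Lorentz–Berthelot style
(ε_ij geometric mean, r_min_ij arithmetic mean; A = ε·r_min¹², B =
2ε·r_min⁶, so each pair bottoms out at −ε_ij at r_min_ij). The shipped
element table (C, N, O, S, P, H, halogens, generic `X`) carries plausible
magnitudes — ε of order 0.1 kcal/mol, contact distances 3.4–4.2 Å — and is
deliberately a configuration input, not a claim of fidelity to any published
force field. The dielectric is distance-dependent D = 4r by default
(constant-D selectable), a common implicit-solvent choice. All pair
distances are floored at r_min_clamp = 0.5 Å in f1 and f3 so that clash
poses, which the optimizer must traverse, score badly but finitely.

**Empirical (f2).** Three affinity rows pK_d,i = C0 + C1·E_vdw + C2·E_hb +
C3·E_def + C4·E_hyd,i differ only in the hydrophobic term; f2 is the
*negated* mean of the rows, so minimization improves predicted affinity —
an affinity is defined as a mean pK_d (larger is better) while the docking
problem minimizes, and negation reconciles the two. Term definitions:

* E_vdw — softened 8-4 contact potential, sign chosen so ideal contact is
  +1 per pair and clash is large-negative: Σ [2(d0/r)⁴ − (d0/r)⁸] with d0
  the pair r_min. With the raw (unnegated) 8-4 sign, maximizing pK_d would
  reward steric clash through the clamped repulsion wall; the chosen sign
  makes the term a bounded contact reward with a steep clash penalty.
* E_hb — distance-only switch on donor/acceptor heavy-atom distance: 1 at
  ≤ 2.6 Å, 0 at ≥ 3.2 Å, linear between. Ligand donors are N/O with a bonded
  H; receptor bonds are unknown from PDB input, so receptor N is treated as
  donor-capable and N/O as acceptors. No angular weighting (a documented
  simplification; the switch is the testable contract).
* E_def — the rotatable-bond count: a conformation-independent rotor
  penalty, the standard reading of a deformation cost absent any formula.
* E_hyd,1/2/3 — hydrophobic contact count (ligand C/S × site C/S pairs
  within 4.5 Å); a surface proxy Σ min(neighbors, 6)/6 over hydrophobic
  ligand atoms; and a matching count (hydrophobic ligand atoms whose nearest
  site atom is hydrophobic).

All empirical coefficients default to the unit-weight row (0, 1, 1, 1, 1):
the published regression weights belong to an external parameterization and
are treated as configuration data.

**Knowledge-based (f3).** A tabulated pair potential per element pair,
linearly interpolated between radial bin centers, summed over heavy-atom
pairs within r_cutoff. `derive_pmf` builds such tables from observed pair
distances by the inverse Boltzmann relation A(r) = −kT·ln[f_vol·ρ_seg(r)/
ρ_bulk], with ρ_seg the shell number density (4πr²Δr shells at bin
centers). Defaults: Δr = 0.2 Å, r_cutoff = 8 Å, kT = 0.593 kcal/mol (298 K),
volume correction ≡ 1 (ligand-volume correction factors vary by
parameterization and none is universal; a callable hook is exposed). Empty bins get a
finite ceiling of +3 kT — a repulsive default where statistics run out.
Element-based pair typing is the default; richer typing schemes plug in as
table keys.

## Scalarization

Per GA generation the incumbent's raw scores refresh the method-of-centers
state: normalization F_i = f_i/denom_i with denom_i = max(|f_prev,i|, 1e−8),
then α_i = 1.5·F_i. The absolute value in the denominator is a deliberate
deviation from the literal ratio f_i(Xᵏ)/f_i(Xᵏ⁻¹): raw docking scores
cross zero, and a signed denominator would silently flip the minimization
direction; the literal signed form is available via
`CentersState(signed_denominator=True)`. At k = 0 there is no previous
iterate and F ≡ 1, so the first bounds are α = (1.5, 1.5, 1.5).

The aggregate S(X, α) uses max-shifted log-sum-exp for both terms, exact to
ln(n)/ρ ≤ 1.1·10⁻⁵ at ρ = 10⁵, finite for |F| up to 10⁶ (a naive
implementation overflows at ρ·F ≈ 700). The second term evaluates to
λ·max_j g_j + O(ln q/ρ). One consequence worth stating plainly: for
in-bounds genomes this term is an *interior reward* of magnitude λ·(distance
to the nearest bound), and with λ = 100 it is large against the normalized
objective differences. Because angular variables have fixed range [−π, π]
while translation boxes are wider than π per side, the maximum residual is
always an angular one, so in practice the penalty disciplines the largest
Euler/torsion magnitude toward 0 and is neutral in translation. This is an
emergent property of the formula at its standard λ, retained as-is;
`AggregateConfig(lam=...)` exposes the factor.

Whether the bound update runs every generation or on a stride is
config-exposed (`update_stride`, default 1 — every generation).

## Genetic algorithm

Real-coded, multi-population. Operators (chosen as standard practice; the
method's testable contracts are the self-adaptive rate ranges, the
multi-population entropy narrowing, and convergence): binary tournament
selection; BLX-0.5 crossover applied to a pair with probability equal to
the parents' mean p_c gene; per-gene Gaussian mutation with σ = 10% of the
variable's current range, applied with the genome's own p_m; the p_c and
p_m genes cross and mutate alongside the design genes and are clamped to
[0.6, 1.0] and [0.0, 0.1]; one elite per population survives unchanged.
Fitness of the full new population is re-evaluated every generation, which
keeps per-generation objective updates (the centers refresh) coherent and
preserves elitist monotonicity for stationary objectives.

Entropy bookkeeping: each generation the population holding the global best
wins; H = −Σ p ln p over the win shares of the last `entropy_window` = 25
generations. A windowed tally, rather than a run-cumulative one, keeps H a
measure of current uncertainty — with cumulative counts an early lead
change *raises* the entropy for the rest of the run and the decline
property fails on its own benchmark. When H < 0.5·ln(n_populations), and at
most once per `narrow_stride` = 30 generations, the non-periodic bounds
shrink to 0.8× half-width centered on the incumbent, clipped to the
original box (so the incumbent is never excluded); angular variables keep
their full periodic range. The stride matters: shrinking every generation
collapses the box geometrically within ~30 generations and traps the search
(Rastrigin success drops measurably below stride ≈ 30).

Randomness: one master seed spawns independent per-population generators
(`SeedSequence.spawn`), so the population count never perturbs another
population's stream; identical seed and config give bitwise-identical
traces.

Defaults: 4 populations × 50 genomes, 300 generations, stall after 50
without 10⁻⁸ improvement. Docking runs in the tests and the acceptance
script use 250 generations with stall 100 — the toy systems have ≤ 6 search
dimensions and converge well within that budget.

## Synthetic systems — what they do and do not show

`make_harmonic_pocket` plants a rigid 4-heavy-atom star ligand (C center
with C, N, O arms of 4 Å) in an 11-atom cage. Each arm atom sits at the
center of a ring of three partners at exactly the pair's r_min — an evenly
spaced ring exerts zero net force on its central atom in every direction,
so the planted pose is near-stationary for both the Lennard-Jones and the
8-4 contact terms by construction (residual cross-pair drift ≲ 0.07 Å,
inside a 0.25 Å grid cell). The central atom gets a symmetric partner pair
along the free body diagonal, cancelling its otherwise unopposed attraction
to the rings; that pair is oppositely charged to the ligand core so the
Coulomb tail (∝1/r² under D = 4r) funnels the ligand toward the cage from
anywhere in the search box. The pair potential is built with Gaussian wells
(σ = 0.4 Å) at the planted pair distances plus a broad guiding basin. The
search box is centroid ± 5 Å — about three cage radii, and wider than π per
side so the box penalty stays translation-neutral. Build-time verification
runs a brute-force 11³-translation × 8³-rotation grid (0.25 Å / 30° steps)
and requires the planted pose to be the best grid cell *for each objective
separately*; a failed construction raises and is never emitted.

`make_conflict_system` separates the objectives: three tetrahedral cages
(4 atoms at 3.7 Å) sit at the vertices of a triangle (separation 7 Å),
each coupled to one objective through element-selective parameters — deep-ε
charged N for the force field, hydrophobic C for the empirical score, a
pair-potential well on element P for the knowledge-based score; the
empirical contact radii for N and P are set small so cages do not leak into
the wrong channel. The probe ligand is a single charged carbon. The
compromise pose is the centroid. Verification checks by translation grid
that each objective's minimum lies within 1 Å of its own site and that the
compromise pose's worst min–max-normalized score beats every site pose's.
The min–max normalization (0 = best, 1 = worst per objective across the
compared poses) is the scale-free way to ask "how unbalanced is this
pose?"; the per-iterate normalization of the optimizer itself is not
applicable across independent results.

What passing these tests shows: the full pipeline — parsing, kinematics,
three scorers, scalarization, optimizer — locates planted optima and
produces balanced compromises under controlled geometry. What it does not
show: chemical realism. The fixtures use pseudo-bond lengths, stylized
charges and hand-shaped potentials; no claim about accuracy on real
protein–ligand complexes follows from them.

One dynamical caveat the conflict tests exposed: because normalization is
relative to the incumbent, a pose that is relatively worse in *any one*
objective than the current incumbent scores worse under the max-like
aggregate — site poses and the balanced pose are each self-stable once
incumbent. The balanced outcome therefore depends on the middle region
being sampled while incumbents are still mediocre, which the fixture's box
(sites near the faces, compromise central) makes routine; the seeded
success-rate criterion (≥ 4/5) absorbs the residual hysteresis.

## Numerical choices and degenerate inputs

* Distances below 0.5 Å evaluate at 0.5 Å (f1, f3); the 8-4 term clamps the
  same way inside its fraction.
* Potential-table I/O uses `repr` floats: round-trips are bit-exact.
* Accuracy categories are left-closed ([0, 0.5), [0.5, 1.0), …, [3.0, ∞));
  a boundary RMSD belongs to the band above it.
* A ligand with a single atom (or no rotatable bonds) is legal everywhere:
  rotations act trivially, the torsion vector has length zero.
* An empty active site scores 0 in f1/f3 by the empty-sum convention but is
  rejected by the docking pipeline, which needs a box.
* Objectives returning non-finite values mark the genome +∞ (rejected);
  an all-infeasible population still evolves (selection is rank-based).
* `derive_pmf` with an empty bin writes the +3 kT ceiling, never ±∞; a zero
  or negative bulk density is an error.

## PMF recovery tolerance

The recovery check (10⁵ samples from a known U(r), Δr = 0.2 Å) compares the
derived table to U up to an additive constant on bins with ≥ 100 counts,
using the count-weighted RMS deviation with the count-weighted optimal
constant. RMS is the statistically meaningful reading of "recovers within
0.1 kT": a bin holding exactly 100 counts has sampling noise σ = kT/√100 =
0.1 kT by itself, so a max-deviation reading would fail occasionally by
pure Poisson noise at any sample size. Measured recovery is ≈ 0.02 kT RMS.

## Known limitations

* Rigid receptor; no ring conformer sampling or ligand strain energy.
* Hydrogen-bond term has no angular dependence; symmetry-equivalent atoms
  are not matched in RMSD (plain per-index RMSD, no re-superposition).
* The empirical and knowledge-based parameterizations are structural
  skeletons with pluggable tables, not reproductions of any published
  parameter set; virtual screening and affinity prediction are out of scope.
* Receptor partial charges cannot come from PDB input (the format has no
  charge column); they default to zero and must be set programmatically
  when electrostatics matter.
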