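"""Docking orchestration: multi-objective and single-objective modes.

``dock`` minimizes the aggregate S(X, alpha) of the three normalized scoring
functions under the method-of-centers bound schedule; ``dock_single`` runs
the same machinery on one raw scoring function for comparison.  Both report
the raw per-objective scores of the final pose.  Pose quality against a
reference is measured by plain heavy-atom RMSD in the shared receptor frame
(no re-superposition) and binned into the seven standard accuracy
categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ga, moo
from .conformation import Bounds, ConformationVector, apply_conformation, constraint_values
from .molecules import ActiveSite, Ligand, Receptor
from .scoring import (EmpiricalCoefficients, ForceFieldParams, PMFPotential, Site,
                      compute_empirical_terms, score_empirical, score_forcefield,
                      score_knowledge)

__all__ = ["DockingConfig", "DockingResult", "AccuracyCategory", "CATEGORIES",
           "dock", "dock_single", "rmsd", "classify_accuracy", "summarize",
           "Objectives"]


@dataclass
class AccuracyCategory:
    """One of the seven RMSD bands used to judge a docked pose."""

    label: str
    rmsd_range: tuple[float, float]


# left-closed intervals tiling [0, inf); a boundary value belongs upward
CATEGORIES: list[AccuracyCategory] = [
    AccuracyCategory("excellent", (0.0, 0.5)),
    AccuracyCategory("good_0.5_1.0", (0.5, 1.0)),
    AccuracyCategory("good_1.0_1.5", (1.0, 1.5)),
    AccuracyCategory("good_1.5_2.0", (1.5, 2.0)),
    AccuracyCategory("close", (2.0, 2.5)),
    AccuracyCategory("error", (2.5, 3.0)),
    AccuracyCategory("wrong", (3.0, float("inf"))),
]


@dataclass
class DockingConfig:
    """Everything a docking run needs besides the molecules themselves."""

    ff_params: ForceFieldParams = field(default_factory=ForceFieldParams)
    emp_params: ForceFieldParams | None = None   # contact radii for f2; defaults to ff_params
    emp_coeffs: EmpiricalCoefficients = field(default_factory=EmpiricalCoefficients)
    potential: PMFPotential | None = None
    aggregate: moo.AggregateConfig = field(default_factory=moo.AggregateConfig)
    r_weight: float = 1.5
    update_stride: int = 1          # generations between method-of-centers updates
    ga: ga.GAConfig = field(default_factory=ga.GAConfig)
    bounds_padding: float = 0.0     # extra A around the site box for translations


@dataclass
class DockingResult:
    best_pose: np.ndarray
    best_x: ConformationVector
    scores: np.ndarray              # raw (f1, f2, f3) of best_pose
    iterations: int                 # GA generations actually run
    n_evals: int                    # objective evaluations
    trace: list[dict]
    mode: str


class Objectives:
    """Raw (f1, f2, f3) evaluation for poses of one ligand in one site."""

    def __init__(self, ligand: Ligand, site: Site, config: DockingConfig):
        if len(site) == 0:
            raise ValueError("active site is empty")
        if config.potential is None:
            raise ValueError("a knowledge-based potential is required")
        self.ligand = ligand
        self.site = site
        self.config = config

    def raw(self, coords: np.ndarray) -> np.ndarray:
        """(3,) scores for one pose, or (P, 3) for a pose batch."""
        c = self.config
        f1 = score_forcefield(coords, self.ligand.atoms, self.site, c.ff_params)
        terms = compute_empirical_terms(coords, self.ligand.atoms, self.ligand,
                                        self.site, c.emp_params or c.ff_params)
        f2 = score_empirical(terms, c.emp_coeffs)
        f3 = score_knowledge(coords, self.ligand.atoms, self.site, c.potential)
        out = np.stack([np.atleast_1d(f1), np.atleast_1d(f2), np.atleast_1d(f3)],
                       axis=-1)
        return out if np.asarray(coords).ndim == 3 else out[0]

    def poses(self, X: np.ndarray, bounds: Bounds) -> np.ndarray:
        """(P, n_atoms, 3) coordinates from a (P, dim) design-vector batch."""
        return np.stack([apply_conformation(self.ligand,
                                            ConformationVector.from_array(row))
                         for row in X])


def _run(receptor_site: Site, ligand: Ligand, bounds: Bounds,
         config: DockingConfig, mode: str) -> DockingResult:
    obj = Objectives(ligand, receptor_site, config)
    n_tor = ligand.n_torsions
    state = {"centers": moo.CentersState(r_weight=config.r_weight),
             "initialized": False}

    single = mode.startswith("single-f")
    which = int(mode[-1]) - 1 if single else None

    def batch_objective(X: np.ndarray) -> np.ndarray:
        coords = obj.poses(X, bounds)
        f = obj.raw(coords)                      # (P, 3)
        if single:
            return f[:, which]
        cs = state["centers"]
        F = np.stack([moo.normalize_objectives(fi, cs) for fi in f])
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            g = constraint_values(ConformationVector.from_array(row), bounds)
            out[i] = moo.aggregate(F[i], cs.alpha, g, config.aggregate)
        return out

    def on_generation(ga_state: ga.GAState) -> None:
        if single:
            return
        if ga_state.generation % config.update_stride != 0:
            return
        best = ga_state.global_best
        coords = apply_conformation(ligand, ConformationVector.from_array(best.x))
        f_raw = obj.raw(coords)
        cs = state["centers"]
        if not state["initialized"]:
            # first update: seed the denominators from the initial best
            cs.f_prev = f_raw.copy()
            state["initialized"] = True
        F = moo.normalize_objectives(f_raw, cs)
        state["centers"] = moo.update_bounds(cs, F, f_raw=f_raw)

    best_x, best_fit, trace = ga.run(batch_objective, bounds, n_tor, config.ga,
                                     vectorized=True, on_generation=on_generation)
    xvec = ConformationVector.from_array(best_x)
    pose = apply_conformation(ligand, xvec)
    scores = obj.raw(pose)
    for t in trace[-1:]:
        t["final_scores"] = scores.tolist()
    return DockingResult(best_pose=pose, best_x=xvec, scores=scores,
                         iterations=len(trace),
                         n_evals=trace[-1]["n_evals"] if trace else 0,
                         trace=trace, mode=mode)


def _default_bounds(site: ActiveSite, padding: float = 0.0) -> Bounds:
    return Bounds(t_lo=site.box_lo - padding, t_hi=site.box_hi + padding)


def dock(receptor: Receptor, ligand: Ligand, active_site: ActiveSite,
         config: DockingConfig, bounds: Bounds | None = None) -> DockingResult:
    """Multi-objective docking: minimize the aggregate of all three scores.

    Each generation the incumbent's raw scores refresh the normalization
    denominators and the upper bounds alpha = r * F; the GA minimizes the
    smooth aggregate S.  The reported scores are raw re-evaluations of the
    returned pose, never the scalarized S.
    """
    site = Site.from_receptor(receptor, active_site)
    return _run(site, ligand,
                bounds or _default_bounds(active_site, config.bounds_padding),
                config, mode="multi")


def dock_single(receptor: Receptor, ligand: Ligand, active_site: ActiveSite,
                which: int, config: DockingConfig,
                bounds: Bounds | None = None) -> DockingResult:
    """Single-objective docking on f_which (1 = force-field, 2 = empirical,
    3 = knowledge-based), for comparison against the multi-objective mode."""
    if which not in (1, 2, 3):
        raise ValueError("which must be 1, 2 or 3")
    site = Site.from_receptor(receptor, active_site)
    return _run(site, ligand,
                bounds or _default_bounds(active_site, config.bounds_padding),
                config, mode=f"single-f{which}")


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Heavy-atom RMSD in A; same atom order, shared frame, no superposition."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def classify_accuracy(value: float) -> AccuracyCategory:
    """Map an RMSD to its accuracy band; boundary values belong upward."""
    if value < 0:
        raise ValueError("RMSD cannot be negative")
    for cat in CATEGORIES:
        lo, hi = cat.rmsd_range
        if lo <= value < hi:
            return cat
    return CATEGORIES[-1]


def summarize(results: list[tuple[str, float]]) -> dict:
    """Per-category fractions plus the mean RMSD over a result list."""
    if not results:
        raise ValueError("no results to summarize")
    counts = {cat.label: 0 for cat in CATEGORIES}
    values = []
    for _, r in results:
        counts[classify_accuracy(r).label] += 1
        values.append(r)
    n = len(results)
    return {"ratios": {k: v / n for k, v in counts.items()},
            "mean_rmsd": float(np.mean(values)),
            "n": n}
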