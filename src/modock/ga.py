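"""Entropy-adaptive multi-population real-coded genetic algorithm.

Several independent populations search the same design space.  The crossover
and mutation probabilities are not fixed constants but genes of each genome
(p_c in [0.6, 1.0], p_m in [0.0, 0.1]) that evolve alongside the design
variables.  Information entropy over which population currently holds the
global best measures how certain the search is about the optimum's location;
once the entropy falls below a threshold the translational search box is
shrunk around the incumbent, concentrating effort without ever losing it.

Concrete operators (binary tournament selection, BLX-0.5 crossover,
per-gene Gaussian mutation with sigma = 10% of the current variable range,
one-elite survival per population) are standard real-coded GA practice and
live behind this module's interface so they can be swapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conformation import Bounds

__all__ = ["Genome", "GAConfig", "GAState", "initialize", "evolve_generation",
           "population_entropy", "narrow_search_space", "run"]

PC_RANGE = (0.6, 1.0)
PM_RANGE = (0.0, 0.1)


@dataclass
class Genome:
    """One candidate: design vector, self-adaptive rates, and fitness."""

    x: np.ndarray
    pc: float
    pm: float
    fitness: float


@dataclass
class GAConfig:
    n_populations: int = 4
    pop_size: int = 50
    max_generations: int = 300
    entropy_threshold: float | None = None   # default 0.5 * ln(n_populations)
    shrink_factor: float = 0.8
    stall_generations: int = 50
    seed: int = 0
    narrow_stride: int = 30        # minimum generations between shrink events
    entropy_window: int = 25       # recent generations entering the win tally
    blx_alpha: float = 0.5
    mutation_sigma_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.n_populations < 1 or self.pop_size < 2:
            raise ValueError("need >= 1 population of >= 2 genomes")
        if not (0.0 < self.shrink_factor < 1.0):
            raise ValueError("shrink_factor must be in (0, 1)")
        if self.entropy_threshold is None:
            self.entropy_threshold = 0.5 * np.log(max(self.n_populations, 2))


@dataclass
class _Population:
    """Array-of-genomes storage: rows of x plus pc/pm/fitness columns."""

    x: np.ndarray      # (m, dim)
    pc: np.ndarray     # (m,)
    pm: np.ndarray     # (m,)
    fit: np.ndarray    # (m,)

    def best_index(self) -> int:
        return int(np.argmin(self.fit))

    def genome(self, i: int) -> Genome:
        return Genome(self.x[i].copy(), float(self.pc[i]), float(self.pm[i]),
                      float(self.fit[i]))


@dataclass
class GAState:
    populations: list[_Population]
    lo: np.ndarray
    hi: np.ndarray
    angular: np.ndarray            # bool mask: periodic variables, fixed range
    orig_lo: np.ndarray
    orig_hi: np.ndarray
    win_counts: np.ndarray         # tally over the recent window
    win_history: list[int] = field(default_factory=list)
    rngs: list[np.random.Generator] = field(default_factory=list)
    generation: int = 0
    entropy: float = 0.0
    last_narrow: int = 0
    n_evals: int = 0

    @property
    def best_per_pop(self) -> list[Genome]:
        return [p.genome(p.best_index()) for p in self.populations]

    @property
    def global_best(self) -> Genome:
        bests = self.best_per_pop
        return bests[int(np.argmin([b.fitness for b in bests]))]

    @property
    def current_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.lo.copy(), self.hi.copy()


def _resolve_bounds(bounds, n_torsions: int):
    """Accept a docking :class:`Bounds` or a generic (lo, hi[, angular]) tuple."""
    if isinstance(bounds, Bounds):
        lo, hi = bounds.lo_hi(n_torsions)
        angular = np.zeros(lo.size, dtype=bool)
        angular[3:] = True
        return lo, hi, angular
    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)
    angular = (np.asarray(bounds[2], dtype=bool) if len(bounds) > 2
               else np.zeros(lo.size, dtype=bool))
    return lo, hi, angular


def _make_objective(objective, vectorized: bool):
    if vectorized:
        return lambda X: np.asarray(objective(X), dtype=float)

    def batch(X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            v = objective(row)
            out[i] = v if np.isfinite(v) else np.inf
        return out
    return batch


def initialize(bounds, n_torsions: int, cfg: GAConfig,
               objective=None, vectorized: bool = False) -> GAState:
    """Seeded uniform initialization of all populations (fitness evaluated)."""
    lo, hi, angular = _resolve_bounds(bounds, n_torsions)
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_populations)
    rngs = [np.random.default_rng(s) for s in streams]
    fobj = _make_objective(objective, vectorized) if objective is not None else None
    pops: list[_Population] = []
    n_evals = 0
    for rng in rngs:
        x = rng.uniform(lo, hi, size=(cfg.pop_size, lo.size))
        pc = rng.uniform(*PC_RANGE, size=cfg.pop_size)
        pm = rng.uniform(*PM_RANGE, size=cfg.pop_size)
        fit = np.full(cfg.pop_size, np.inf)
        if fobj is not None:
            fit = np.where(np.isfinite(f := fobj(x)), f, np.inf)
            n_evals += cfg.pop_size
        pops.append(_Population(x, pc, pm, fit))
    state = GAState(populations=pops, lo=lo.copy(), hi=hi.copy(), angular=angular,
                    orig_lo=lo.copy(), orig_hi=hi.copy(),
                    win_counts=np.zeros(cfg.n_populations), rngs=rngs,
                    n_evals=n_evals)
    if fobj is not None:
        bests = [p.fit[p.best_index()] for p in pops]
        _record_win(state, int(np.argmin(bests)), cfg)
    return state


def _record_win(state: GAState, winner: int, cfg: GAConfig) -> None:
    """Tally which population holds the global best over a sliding window.

    A windowed tally (rather than a run-cumulative one) keeps the entropy a
    measure of *current* uncertainty: once one population consistently leads,
    the window concentrates and the entropy falls to zero, no matter how the
    early lead bounced between populations.
    """
    state.win_history.append(winner)
    recent = state.win_history[-max(cfg.entropy_window, 1):]
    state.win_counts = np.bincount(recent, minlength=cfg.n_populations).astype(float)
    state.entropy = population_entropy(state.win_counts)


def population_entropy(win_counts: np.ndarray) -> float:
    """Shannon entropy (nats) of the which-population-leads distribution."""
    c = np.asarray(win_counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("win counts must be nonnegative")
    total = c.sum()
    if total <= 0:
        raise ValueError("entropy undefined for all-zero win counts")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def _wrap_clip(x: np.ndarray, lo: np.ndarray, hi: np.ndarray,
               angular: np.ndarray) -> np.ndarray:
    """Periodic variables wrap into their range; box variables are clipped."""
    out = np.clip(x, lo, hi)
    if angular.any():
        span = hi[angular] - lo[angular]
        out[..., angular] = lo[angular] + np.mod(x[..., angular] - lo[angular], span)
    return out


def evolve_generation(state: GAState, objective, cfg: GAConfig,
                      vectorized: bool = False) -> GAState:
    """One generation over every population (state is updated in place).

    Selection is binary tournament; a pair is crossed (BLX-alpha on design
    genes and on the pc/pm genes themselves) with probability equal to the
    parents' mean pc gene; each gene then mutates with the genome's own pm
    probability, Gaussian with sigma = 10% of that variable's current range.
    The best genome of each population survives unchanged.  Fitness of the
    whole new population is (re)evaluated, so per-generation objective
    updates — the method-of-centers bound refresh — stay consistent.
    """
    fobj = _make_objective(objective, vectorized)
    lo, hi, angular = state.lo, state.hi, state.angular
    sigma = cfg.mutation_sigma_frac * (hi - lo)
    pc_lo, pc_hi = PC_RANGE
    pm_lo, pm_hi = PM_RANGE

    for pop, rng in zip(state.populations, state.rngs):
        m, dim = pop.x.shape
        elite = pop.best_index()
        new_x = [pop.x[elite].copy()]
        new_pc = [pop.pc[elite]]
        new_pm = [pop.pm[elite]]

        def tournament() -> int:
            i, j = rng.integers(0, m, size=2)
            return int(i if pop.fit[i] <= pop.fit[j] else j)

        while len(new_x) < m:
            p1, p2 = tournament(), tournament()
            g1 = np.concatenate([pop.x[p1], [pop.pc[p1], pop.pm[p1]]])
            g2 = np.concatenate([pop.x[p2], [pop.pc[p2], pop.pm[p2]]])
            if rng.random() < 0.5 * (pop.pc[p1] + pop.pc[p2]):
                gmin = np.minimum(g1, g2)
                gmax = np.maximum(g1, g2)
                d = gmax - gmin
                lo_c = gmin - cfg.blx_alpha * d
                hi_c = gmax + cfg.blx_alpha * d
                c1 = rng.uniform(lo_c, hi_c)
                c2 = rng.uniform(lo_c, hi_c)
            else:
                c1, c2 = g1.copy(), g2.copy()
            for child in (c1, c2):
                pm_gene = float(np.clip(child[dim + 1], pm_lo, pm_hi))
                mask = rng.random(dim + 2) < pm_gene
                noise = rng.normal(0.0, 1.0, dim + 2)
                child[:dim][mask[:dim]] += (sigma * noise[:dim])[mask[:dim]]
                if mask[dim]:
                    child[dim] += 0.1 * (pc_hi - pc_lo) * noise[dim]
                if mask[dim + 1]:
                    child[dim + 1] += 0.1 * (pm_hi - pm_lo) * noise[dim + 1]
                new_x.append(_wrap_clip(child[:dim], lo, hi, angular))
                new_pc.append(float(np.clip(child[dim], pc_lo, pc_hi)))
                new_pm.append(float(np.clip(child[dim + 1], pm_lo, pm_hi)))

        pop.x = np.array(new_x[:m])
        pop.pc = np.array(new_pc[:m])
        pop.pm = np.array(new_pm[:m])
        fit = fobj(pop.x)
        pop.fit = np.where(np.isfinite(fit), fit, np.inf)
        state.n_evals += m

    state.generation += 1
    bests = [p.fit[p.best_index()] for p in state.populations]
    _record_win(state, int(np.argmin(bests)), cfg)
    return state


def narrow_search_space(state: GAState, cfg: GAConfig) -> GAState:
    """Shrink the non-periodic search box around the incumbent when entropy is low.

    The new half-width is shrink_factor times the old, centered on the global
    best and clipped to the original box, so repeated shrinks can never
    exclude the incumbent.  Genomes left outside are wrapped back inside.
    Angular variables keep their full periodic range.
    """
    if state.entropy >= cfg.entropy_threshold:
        return state
    if state.generation - state.last_narrow < cfg.narrow_stride:
        return state
    center = state.global_best.x
    box = ~state.angular
    half = 0.5 * cfg.shrink_factor * (state.hi[box] - state.lo[box])
    new_lo = np.maximum(state.orig_lo[box], center[box] - half)
    new_hi = np.minimum(state.orig_hi[box], center[box] + half)
    ok = new_hi > new_lo
    state.lo[box] = np.where(ok, new_lo, state.lo[box])
    state.hi[box] = np.where(ok, new_hi, state.hi[box])
    for pop in state.populations:
        pop.x = _wrap_clip_box(pop.x, state.lo, state.hi, state.angular)
    state.last_narrow = state.generation
    return state


def _wrap_clip_box(x: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                   angular: np.ndarray) -> np.ndarray:
    span = hi - lo
    wrapped = lo + np.mod(x - lo, span)
    out = x.copy()
    outside = (x < lo) | (x > hi)
    out[outside] = wrapped[outside]
    return out


def run(objective, bounds, n_torsions: int, cfg: GAConfig,
        vectorized: bool = False, on_generation=None):
    """Full optimization loop.

    Returns ``(best_x, best_fitness, trace)`` where trace is one dict per
    generation: generation index, best fitness, entropy, current box volume
    and cumulative objective evaluations.  ``on_generation(state)`` runs
    after each generation and may mutate whatever the objective closes over
    (the docking pipeline refreshes the method-of-centers bounds there);
    fitness is re-evaluated every generation so such updates stay coherent.
    Identical seed and config give a bitwise-identical trace.
    """
    state = initialize(bounds, n_torsions, cfg, objective=objective,
                       vectorized=vectorized)
    trace: list[dict] = []
    best_ever = state.global_best
    stall = 0
    for _ in range(cfg.max_generations):
        evolve_generation(state, objective, cfg, vectorized=vectorized)
        if on_generation is not None:
            on_generation(state)
        gb = state.global_best
        if gb.fitness < best_ever.fitness - 1e-8:
            best_ever = gb
            stall = 0
        else:
            stall += 1
        narrow_search_space(state, cfg)
        box = ~state.angular
        vol = float(np.prod(state.hi[box] - state.lo[box])) if box.any() else 0.0
        trace.append({"generation": state.generation,
                      "best_fitness": float(gb.fitness),
                      "entropy": float(state.entropy),
                      "bounds_volume": vol,
                      "n_evals": int(state.n_evals)})
        if stall >= cfg.stall_generations:
            break
    final = min([best_ever, state.global_best], key=lambda g: g.fitness)
    return final.x, float(final.fitness), trace
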