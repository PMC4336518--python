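"""Method-of-centers bookkeeping and the log-sum-exp aggregate function.

The three raw scores are normalized against the previous iterate
(F_i = f_i(X^k) / f_i(X^{k-1})), each gets a shrinking upper bound
alpha_i = r * F_i with r = 1.5, and the bounded multi-objective problem is
collapsed into one smooth unconstrained objective

    S(X, alpha) = (1/rho) ln sum_i exp[rho (F_i - alpha_i)]
                + (lambda/rho) ln sum_j exp[rho g_j]

with rho = 1e5 and lambda = 100: a sharp, overflow-safe surrogate for
max_i(F_i - alpha_i) + lambda max_j g_j.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

__all__ = ["CentersState", "AggregateConfig", "normalize_objectives",
           "update_bounds", "aggregate"]

_EPS = 1e-8


@dataclass
class CentersState:
    """Per-iteration state of the method of centers.

    ``f_prev`` holds the previous iterate's raw scores (the normalization
    denominators), ``alpha`` the current upper bounds.  By default the
    denominator is |f_prev| floored at 1e-8: raw docking scores can be
    negative or cross zero, where the literal signed ratio would reverse the
    minimization direction; set ``signed_denominator`` for the literal form.
    """

    k: int = 0
    f_prev: np.ndarray = field(default_factory=lambda: np.ones(3))
    alpha: np.ndarray = field(default_factory=lambda: np.full(3, 1.5))
    r_weight: float = 1.5
    signed_denominator: bool = False

    def __post_init__(self) -> None:
        self.f_prev = np.asarray(self.f_prev, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)


def normalize_objectives(f_now: np.ndarray, state: CentersState) -> np.ndarray:
    """Normalized objectives F_i = f_i / denom_i.

    At k = 0 there is no previous iterate and F = (1, 1, 1) by convention,
    which makes the first bounds alpha = r * F "sufficiently large" relative
    to the normalized scale.
    """
    f_now = np.asarray(f_now, dtype=float)
    if state.k == 0:
        return np.ones_like(f_now)
    if state.signed_denominator:
        denom = np.where(np.abs(state.f_prev) < _EPS,
                         np.copysign(_EPS, state.f_prev + _EPS), state.f_prev)
    else:
        denom = np.maximum(np.abs(state.f_prev), _EPS)
    return f_now / denom


def update_bounds(state: CentersState, F_current: np.ndarray,
                  f_raw: np.ndarray | None = None) -> CentersState:
    """One method-of-centers step: alpha_i <- r * F_i(X^k), k <- k + 1.

    ``f_raw`` — the current iterate's raw scores — becomes the next
    iteration's normalization denominator; omit it to keep f_prev unchanged.
    """
    F_current = np.asarray(F_current, dtype=float)
    return replace(
        state,
        k=state.k + 1,
        alpha=state.r_weight * F_current,
        f_prev=np.asarray(f_raw, dtype=float) if f_raw is not None else state.f_prev,
    )


@dataclass
class AggregateConfig:
    """Sharpness rho and constraint penalty lambda of the aggregate function."""

    rho: float = 1e5
    lam: float = 100.0

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")


def aggregate(F: np.ndarray, alpha: np.ndarray, g: np.ndarray,
              cfg: AggregateConfig | None = None) -> float:
    """Smooth scalarization S(X, alpha); finite for all finite inputs.

    Both log-sum-exp terms are evaluated with the max-shift trick, so huge
    rho * value products (|F| up to 1e6 at rho = 1e5) cannot overflow.
    """
    cfg = cfg or AggregateConfig()
    F = np.asarray(F, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    g = np.atleast_1d(np.asarray(g, dtype=float))
    if g.size < 1:
        raise ValueError("at least one constraint residual is required")
    obj = logsumexp(cfg.rho * (F - alpha)) / cfg.rho
    pen = cfg.lam * logsumexp(cfg.rho * g) / cfg.rho
    return float(obj + pen)
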