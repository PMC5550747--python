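"""Per-founder fitness across patches and the optimal colonization rate.

A lineage's fitness over one patch cycle is the expected number of
next-patch founders per current founder — a reproductive number in the R0
sense.  Each planktonic cell founds a new patch with probability ``k_p``
and each biofilm cell with probability ``k_b``, giving

    W(c, r, t) = k_p e^{(r-c)t} + k_b [e^{(r-c)t} - 1] c/(r-c),

with the c = r limit W = k_p + k_b r t.  The optimal colonization rate c*
maximizes W over the strategy space [0, r]; depending on (r, t, k_p, k_b)
the optimum is pure plankton (c* = 0), pure biofilm (c* = r), or a mixed
investment — the three regimes of the allocation landscape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .within_patch import WithinPatchParams, _CR_GUARD

__all__ = [
    "TransmissionWeights",
    "FitnessPoint",
    "AllocationOptimum",
    "fitness_w",
    "per_founder_fitness",
    "fitness_gradient_zero_growth",
    "optimal_colonization",
    "classify_regime",
    "regime_boundaries",
    "landscape_grid",
]

Regime = Literal["pure_plankton", "mixed", "pure_biofilm"]

#: optimization results within this relative distance of a boundary of
#: [0, r] are classified as that boundary (float optimizers never return
#: exact endpoints)
_BOUNDARY_TOL = 1e-6


@dataclass(frozen=True)
class TransmissionWeights:
    """Per-cell transmission probabilities (reproductive values).

    ``k_p`` for planktonic cells and ``k_b`` for biofilm cells, both in
    [0, 1]; equivalently, the fractions of each compartment transmitted to
    found the next patch.
    """

    k_p: float
    k_b: float

    def __post_init__(self) -> None:
        for name in ("k_p", "k_b"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class FitnessPoint:
    """One point on the fitness landscape: colonization rate and W."""

    c: float
    W: float


@dataclass(frozen=True)
class AllocationOptimum:
    """Output of the colonization-rate optimizer.

    ``c_star`` in [0, r], its relative form ``c_star_rel`` = c*/r, the
    strategy regime, and the fitness value at the optimum.
    """

    c_star: float
    c_star_rel: float
    regime: Regime
    W_at_optimum: float


def fitness_w(c, r, t_end, k_p, k_b):
    """Vectorized per-founder fitness W(c, r, t); exact at c = r.

    Accepts scalars or broadcastable arrays. This is the workhorse used by
    the optimizer and the passaging simulation.
    """
    c = np.asarray(c, dtype=float)
    r = np.asarray(r, dtype=float)
    t_end = np.asarray(t_end, dtype=float)
    k_p = np.asarray(k_p, dtype=float)
    k_b = np.asarray(k_b, dtype=float)
    near = np.abs(r - c) < _CR_GUARD * np.maximum(r, 1.0)
    denom = np.where(near, 1.0, r - c)
    e = np.exp((r - c) * t_end)
    w = k_p * e + k_b * (e - 1.0) * c / denom
    w_limit = k_p + k_b * r * t_end
    out = np.where(near, w_limit, w)
    return float(out) if out.ndim == 0 else out


def per_founder_fitness(
    c: float, r: float, t_end: float, weights: TransmissionWeights
) -> FitnessPoint:
    """Per-founder fitness at one colonization rate.

    Consistent with the absolute fitness k_p P(t) + k_b B(t) divided by the
    inoculum P0 (W is per founding cell, hence independent of P0).
    """
    if c < 0 or r < 0 or t_end < 0:
        raise ValueError("c, r, t_end must be non-negative")
    return FitnessPoint(c=float(c), W=fitness_w(c, r, t_end, weights.k_p, weights.k_b))


def fitness_gradient_zero_growth(c: float, t_end: float, weights: TransmissionWeights) -> float:
    """dW/dc in the zero-growth limit r = 0:  t e^{-c t} (k_b - k_p).

    With no within-patch growth the allocation decision is a zero-sum game:
    the gradient has the sign of k_b - k_p everywhere, so the optimum is
    always a boundary (all-biofilm if k_b > k_p, all-plankton otherwise).
    """
    if c < 0 or t_end < 0:
        raise ValueError("c and t_end must be non-negative")
    return t_end * np.exp(-c * t_end) * (weights.k_b - weights.k_p)


def _argmax_w(r: float, t_end: float, k_p: float, k_b: float, n_grid: int = 1024) -> tuple[float, float]:
    """Grid pre-scan plus bounded refinement of W over [0, r].

    W(c) is observed unimodal on [0, r] in all probed regimes, but this is
    not proven; the dense pre-scan guards against a mistaken bracket.
    """
    grid = np.linspace(0.0, r, n_grid)
    vals = fitness_w(grid, r, t_end, k_p, k_b)
    i = int(np.argmax(vals))
    if i == 0 or i == n_grid - 1:
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, n_grid - 1)]
    else:
        lo, hi = grid[i - 1], grid[i + 1]
    res = minimize_scalar(
        lambda c: -fitness_w(c, r, t_end, k_p, k_b),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-13 * max(r, 1.0)},
    )
    c_ref = float(res.x)
    w_ref = fitness_w(c_ref, r, t_end, k_p, k_b)
    # endpoints are evaluated exactly (limit branch at c=r); keep whichever wins
    cands = [(w_ref, c_ref), (vals[0], 0.0), (vals[-1], r)]
    w_best, c_best = max(cands, key=lambda p: (p[0], p[1]))
    return c_best, float(w_best)


def optimal_colonization(r: float, t_end: float, weights: TransmissionWeights) -> AllocationOptimum:
    """Global maximum of W over the strategy space c in [0, r].

    Boundaries are included via their exact limits. Deterministic given the
    inputs.
    """
    if r <= 0 or t_end <= 0:
        raise ValueError("r and t_end must be positive")
    if weights.k_p == 0.0 and weights.k_b == 0.0:
        # degenerate flat-zero fitness: no transmission by either type;
        # conventionally no investment (c* = 0)
        return AllocationOptimum(c_star=0.0, c_star_rel=0.0, regime="pure_plankton", W_at_optimum=0.0)
    c_star, w_star = _argmax_w(r, t_end, weights.k_p, weights.k_b)
    rel = c_star / r
    if rel <= _BOUNDARY_TOL:
        regime: Regime = "pure_plankton"
        c_star, rel = 0.0, 0.0
        w_star = fitness_w(0.0, r, t_end, weights.k_p, weights.k_b)
    elif rel >= 1.0 - _BOUNDARY_TOL:
        regime = "pure_biofilm"
        c_star, rel = r, 1.0
        w_star = fitness_w(r, r, t_end, weights.k_p, weights.k_b)
    else:
        regime = "mixed"
    return AllocationOptimum(c_star=c_star, c_star_rel=rel, regime=regime, W_at_optimum=w_star)


def _dw_dc(c: float, r: float, t_end: float, k_p: float, k_b: float, h_rel: float = 1e-7) -> float:
    """One-sided-safe central difference of W in c (interior use only)."""
    h = h_rel * max(r, 1.0)
    lo, hi = max(c - h, 0.0), c + h
    return (fitness_w(hi, r, t_end, k_p, k_b) - fitness_w(lo, r, t_end, k_p, k_b)) / (hi - lo)


def classify_regime(r: float, t_end: float, weights: TransmissionWeights) -> Regime:
    """Label the allocation strategy favored at (r, t, k_p, k_b).

    Fast path: the signs of dW/dc at both boundaries decide the label when
    they are conclusive (down at 0 and up at r cannot both hold for a
    unimodal W; up at 0 and down at r implies an interior optimum). The
    interior optimizer is the fallback and the arbiter in ambiguous cases.
    """
    if r <= 0 or t_end <= 0:
        raise ValueError("r and t_end must be positive")
    k_p, k_b = weights.k_p, weights.k_b
    d0 = _dw_dc(1e-6 * r, r, t_end, k_p, k_b)
    dr = _dw_dc(r * (1 - 1e-6), r, t_end, k_p, k_b)
    if d0 < 0 and dr < 0:
        # decreasing at both boundaries: maximum at c = 0 (W unimodal)
        return "pure_plankton"
    if d0 > 0 and dr > 0:
        # increasing at both boundaries: maximum at c = r
        return "pure_biofilm"
    return optimal_colonization(r, t_end, weights).regime


def _bisect_boundary(
    kind: str, kp: float, r: float, t_end: float, lo: float, hi: float, tol: float
) -> float:
    """Bisect in k_b for the regime transition along one k_p column.

    kind='white': pure_plankton <-> (mixed or pure_biofilm), i.e. c* > 0.
    kind='black': (pure_plankton or mixed) <-> pure_biofilm, i.e. c* = r.
    Assumes the indicator is monotone in k_b (more biofilm value, more
    colonization), which holds throughout the probed parameter space.
    """

    def indicator(kb: float) -> bool:
        reg = classify_regime(r, t_end, TransmissionWeights(k_p=kp, k_b=kb))
        if kind == "white":
            return reg != "pure_plankton"
        return reg == "pure_biofilm"

    f_lo, f_hi = indicator(lo), indicator(hi)
    if f_lo == f_hi:
        return np.nan
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if indicator(mid) == f_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def regime_boundaries(
    r: float,
    t_end: float,
    k_grid: int = 101,
    tol: float = 1e-4,
):
    """Locate the two regime-transition curves in the (k_p, k_b) unit square.

    Returns a pandas DataFrame with columns ``k_p``, ``k_b_white``,
    ``k_b_black``: for each k_p on the grid, the k_b at which c* departs
    from 0 (white curve) and the k_b below which c* = r (black curve).
    Either entry is NaN where the transition does not occur inside [0, 1] —
    e.g. the black curve is absent at high growth rates, where even pure
    biofilm transmission favors a mixed strategy.
    """
    import pandas as pd

    if k_grid < 2:
        raise ValueError("k_grid must be >= 2")
    kps = np.linspace(0.0, 1.0, k_grid)
    white = np.full(k_grid, np.nan)
    black = np.full(k_grid, np.nan)
    for j, kp in enumerate(kps):
        white[j] = _bisect_boundary("white", kp, r, t_end, 0.0, 1.0, tol)
        black[j] = _bisect_boundary("black", kp, r, t_end, 0.0, 1.0, tol)
    return pd.DataFrame({"k_p": kps, "k_b_white": white, "k_b_black": black})


def landscape_grid(
    r_values: Sequence[float],
    t_values: Sequence[float],
    k_resolution: int = 101,
):
    """Dense c*/r surface over the (k_p, k_b) unit square, one panel per
    (r, t) combination.

    Returns a tidy pandas DataFrame with columns r, t, k_p, k_b,
    c_star_rel, regime — suitable for contour plotting. Deterministic.
    """
    import pandas as pd

    ks = np.linspace(0.0, 1.0, k_resolution)
    rows = []
    for r in r_values:
        for t in t_values:
            for kp in ks:
                for kb in ks:
                    opt = optimal_colonization(r, t, TransmissionWeights(k_p=kp, k_b=kb))
                    rows.append((r, t, kp, kb, opt.c_star_rel, opt.regime))
    return pd.DataFrame(rows, columns=["r", "t", "k_p", "k_b", "c_star_rel", "regime"])
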