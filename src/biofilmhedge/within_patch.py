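"""Within-patch dynamics of coupled biofilm and planktonic compartments.

A clonal lineage grows inside one ephemeral habitat patch for a duration
``t_end``.  Planktonic cells divide exponentially at rate ``r`` and join the
biofilm at the colonization rate ``c``; in the simplified model the biofilm
does not divide and does not disperse, giving

    dP/dt = (r - c) P,        dB/dt = c P,

with closed forms  P(t) = P0 e^{(r-c)t}  and  B(t) = c/(r-c) [P(t) - P0].
Both closed forms have removable singularities at c = r (static plankton,
linear biofilm accumulation) which are evaluated exactly by their limits.

The full model adds intrinsic biofilm growth G(B) (linear ``g`` or quadratic
``g sqrt(B)``, the surface-limited forms) and dispersal ``d`` back to the
plankton; it is integrated numerically.  Dispersed cells are returned to the
planktonic compartment (dP/dt gains ``+ d B``), an assumption documented in
the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "WithinPatchParams",
    "PatchState",
    "Trajectory",
    "planktonic_at",
    "biofilm_at",
    "solve_trajectory",
    "integrate_full_model",
    "biofilm_slope_limit",
    "total_size_derivative",
    "biofilm_maximizing_colonization",
]

GrowthForm = Literal["none", "linear", "quadratic"]

#: relative half-width of the guard band around c = r inside which the
#: closed forms are evaluated by their analytic limits
_CR_GUARD = 1e-12


@dataclass(frozen=True)
class WithinPatchParams:
    """Rates and initial conditions for one patch's growth episode.

    Parameters
    ----------
    r : float
        Planktonic exponential growth rate (per unit time, >= 0).
    c : float
        Colonization rate, plankton -> biofilm (per unit time, >= 0).
        ``c`` may exceed ``r``; the plankton then declines.
    t_end : float
        Growth duration of the patch (time units, >= 0).
    P0 : float
        Planktonic inoculum (cells, > 0).
    B0 : float
        Biofilm inoculum (cells, >= 0). Zero in the simplified model.
    d : float
        Dispersal rate, biofilm -> plankton (per unit time, >= 0).
        Zero in the simplified model.
    g : float
        Intrinsic biofilm growth coefficient. Cells/time for the linear
        form; cells^(1/2)/time for the quadratic form. Ignored when
        ``growth_form`` is ``"none"``.
    growth_form : {"none", "linear", "quadratic"}
        Functional form of intrinsic biofilm growth G(B): 0, g, or
        g*sqrt(B).
    """

    r: float
    c: float
    t_end: float
    P0: float
    B0: float = 0.0
    d: float = 0.0
    g: float = 0.0
    growth_form: GrowthForm = "none"

    def __post_init__(self) -> None:
        for name in ("r", "c", "t_end", "B0", "d", "g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.P0 <= 0:
            raise ValueError(f"P0 must be positive, got {self.P0}")
        if self.growth_form not in ("none", "linear", "quadratic"):
            raise ValueError(f"unknown growth_form {self.growth_form!r}")

    @property
    def is_simplified(self) -> bool:
        """True when the closed-form solution applies (no biofilm growth,
        no dispersal, empty initial biofilm)."""
        return self.growth_form == "none" and self.d == 0.0 and self.B0 == 0.0

    def _require_simplified(self) -> None:
        if not self.is_simplified:
            raise ValueError(
                "closed-form solution requires the simplified model "
                "(growth_form='none', d=0, B0=0); use integrate_full_model"
            )


class PatchState(NamedTuple):
    """Instantaneous state of one patch: time and the two compartments."""

    time: float
    P: float
    B: float


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered (P, B) states of one patch.

    ``times`` is strictly increasing; ``P`` and ``B`` are continuous cell
    counts aligned with it.
    """

    times: np.ndarray
    P: np.ndarray
    B: np.ndarray
    params: WithinPatchParams | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self):
        for t, p, b in zip(self.times, self.P, self.B):
            yield PatchState(float(t), float(p), float(b))

    def to_frame(self):
        """Return a pandas DataFrame with columns time, P, B."""
        import pandas as pd

        return pd.DataFrame({"time": self.times, "P": self.P, "B": self.B})


def _near_cr(r, c):
    return np.abs(r - c) < _CR_GUARD * np.maximum(r, 1.0)


def planktonic_at(params: WithinPatchParams, time) -> np.ndarray | float:
    """Planktonic cells P(t) = P0 e^{(r-c)t} in the simplified model.

    Exact at c = r (static plankton, returns P0). Accepts scalar or array
    ``time``; negative times are a domain error.
    """
    params._require_simplified()
    t = np.asarray(time, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = params.P0 * np.exp((params.r - params.c) * t)
    return out if out.ndim else float(out)


def biofilm_at(params: WithinPatchParams, time) -> np.ndarray | float:
    """Biofilm cells B(t) = c/(r-c) [P(t) - P0] in the simplified model.

    At c = r the removable singularity is evaluated by its limit
    B(t) = c P0 t (linear accumulation fed by a static plankton). The
    expression is valid, and non-negative, for c > r as well.
    """
    params._require_simplified()
    t = np.asarray(time, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    r, c, P0 = params.r, params.c, params.P0
    if _near_cr(r, c):
        out = c * P0 * t
    else:
        out = (c / (r - c)) * (P0 * np.exp((r - c) * t) - P0)
    return out if out.ndim else float(out)


def solve_trajectory(params: WithinPatchParams, times: Iterable[float]) -> Trajectory:
    """Evaluate the closed-form trajectory on a sorted, non-negative grid."""
    t = np.asarray(list(times) if not isinstance(times, np.ndarray) else times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    P = np.atleast_1d(planktonic_at(params, t))
    B = np.atleast_1d(biofilm_at(params, t))
    return Trajectory(times=t, P=P, B=B, params=params)


def integrate_full_model(
    params: WithinPatchParams,
    times: Iterable[float],
    rtol: float = 1e-8,
    atol: float = 1e-6,
) -> Trajectory:
    """Numerically integrate the full coupled model on a time grid.

        dP/dt = (r - c) P + d B
        dB/dt = G(B) + c P - d B,   G(B) = 0 | g | g sqrt(B)

    The quadratic form uses sqrt(max(B, 0)) so that G(0) = 0 and transient
    negative round-off cannot produce NaNs.  With ``growth_form='none'`` and
    ``d = 0`` the result agrees with the closed forms to integration
    tolerance.  P spans many orders of magnitude, hence a stiff-capable
    adaptive method (LSODA) at tight tolerances.
    """
    t = np.asarray(list(times) if not isinstance(times, np.ndarray) else times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    r, c, d, g = params.r, params.c, params.d, params.g
    form = params.growth_form

    def rhs(_t, y):
        P, B = y
        if form == "linear":
            G = g
        elif form == "quadratic":
            G = g * np.sqrt(max(B, 0.0))
        else:
            G = 0.0
        return ((r - c) * P + d * B, G + c * P - d * B)

    t0 = t[0] if t.size else 0.0
    y0 = (params.P0, params.B0)
    if t0 > 0:  # integrate up from the initial condition at time 0
        t_eval = np.concatenate([[0.0], t])
    else:
        t_eval = t
    sol = solve_ivp(
        rhs,
        (0.0, float(t_eval[-1]) if t_eval.size else 0.0),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message} (last t={sol.t[-1] if sol.t.size else None})")
    P, B = sol.y
    if t0 > 0:
        P, B = P[1:], B[1:]
    if np.any(P < -atol) or np.any(B < -atol):
        raise RuntimeError("integration produced negative cell counts beyond tolerance")
    return Trajectory(times=t, P=np.maximum(P, 0.0), B=np.maximum(B, 0.0), params=params)


def biofilm_slope_limit(P0: float, r: float, t_end: float) -> float:
    """Limiting slope of B with respect to c as c approaches r.

        lim_{c->r} dB/dc = -(1/2) P0 t (r t - 2)

    Negative iff r*t_end > 2 — the patch-quality threshold above which the
    biofilm count has an interior maximum at some c < r.
    """
    if P0 <= 0:
        raise ValueError("P0 must be positive")
    if t_end < 0 or r < 0:
        raise ValueError("r and t_end must be non-negative")
    return -0.5 * P0 * t_end * (r * t_end - 2.0)


#: below this value of |r-c|*t the closed-form derivative of P+B in c is
#: evaluated by its series expansion (catastrophic cancellation otherwise)
_SERIES_GUARD = 1e-4


def total_size_derivative(P0: float, r: float, c: float, t_end: float):
    """Derivative of total population size P(t)+B(t) with respect to c.

        d(P+B)/dc = -r P0 {1 + [(r-c)t - 1] e^{(r-c)t}} / (r-c)^2

    Equals 0 at t_end = 0 and is strictly negative for t_end > 0: any
    allocation toward the biofilm costs total population size.  Near c = r
    the expression is a 0/0 form and is evaluated by its series limit
    -r P0 [t^2/2 + (r-c) t^3/3].
    """
    if P0 <= 0:
        raise ValueError("P0 must be positive")
    if t_end < 0 or r < 0 or c < 0:
        raise ValueError("r, c, t_end must be non-negative")
    x = (r - c) * t_end
    if abs(x) < _SERIES_GUARD:
        return -r * P0 * (t_end**2 / 2.0 + (r - c) * t_end**3 / 3.0)
    return -r * P0 * (1.0 + (x - 1.0) * np.exp(x)) / (r - c) ** 2


def biofilm_maximizing_colonization(r: float, t_end: float, P0: float = 1.0) -> float:
    """Colonization rate in [0, r] that maximizes the biofilm count B(t_end).

    B is linear in P0, so the argmax is independent of the inoculum.  When
    r*t_end <= 2 the limiting slope at c = r is non-negative and the maximum
    sits on the boundary c = r; otherwise there is an interior optimum,
    located by a coarse grid scan followed by bounded scalar refinement.
    Ties within 1e-9 relative are resolved toward larger c.
    """
    from scipy.optimize import minimize_scalar

    if r <= 0 or t_end <= 0:
        raise ValueError("r and t_end must be positive")
    if r * t_end <= 2.0:
        return r

    def negB(c):
        p = WithinPatchParams(r=r, c=float(c), t_end=t_end, P0=P0)
        return -biofilm_at(p, t_end)

    grid = np.linspace(0.0, r, 512)
    vals = np.array([-negB(c) for c in grid])
    i = int(np.argmax(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(negB, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12 * max(r, 1.0)})
    c_star = float(res.x)
    # flat-tie resolution toward the boundary
    if -negB(r) >= -negB(c_star) * (1.0 - 1e-9):
        return r
    return c_star
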