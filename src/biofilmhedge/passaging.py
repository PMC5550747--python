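"""Serial-passaging simulation: growth/transmission cycles under
stochastic environments, and the bet-hedging summaries of lineage fitness.

A lineage starts as a planktonic inoculum with a fixed colonization rate c
and is passaged through a sequence of patches.  Each passage draws an
environment (r, t, k_p, k_b), grows the founders by the closed-form
within-patch model, and transmits k_p P(t) + k_b B(t) cells as the next
passage's (all-planktonic) founders.  The per-passage reproductive number
R0 is the ratio of founders in a passage to founders in the previous one;
because the within-patch model and the transmission step are linear in the
inoculum, R0 equals the per-founder fitness W(c, r, t) of the drawn
environment, independent of the founder count.

Bet hedging is read off three per-lineage summaries across passages: the
variance of R0 (risk), the arithmetic mean (short-term growth), and the
geometric mean (long-term growth, the quantity natural selection maximizes
in a fluctuating environment).  Response curves of each summary against
the colonization rate are characterized by linear-vs-quadratic ordinary
least squares, selected by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .environments import EnvironmentDistribution, EnvironmentDraw, draw_environments, make_treatment
from .fitness import fitness_w

__all__ = [
    "PassagingConfig",
    "PassageRecord",
    "LineageTrajectory",
    "ResponseCurveFit",
    "run_lineage",
    "run_experiment",
    "summarize_lineage",
    "fit_response_curves",
]

#: founder counts below this are treated as lineage extinction
_EXTINCTION_FLOOR = 1e-300

CMode = Literal["absolute", "relative"]


@dataclass(frozen=True)
class PassagingConfig:
    """Configuration of one passaging run.

    ``c`` is the lineage's fixed colonization rate.  With
    ``c_mode="absolute"`` (default) it is applied as-is every passage, and
    is naturally reported against the expected growth rate as c/mu_r.  With
    ``c_mode="relative"`` it is a fraction of each passage's drawn growth
    rate (c_abs = c * r_draw).
    """

    c: float
    treatment: EnvironmentDistribution
    n_passages: int = 10
    n_replicates: int = 100
    founders0: float = 5000.0
    c_mode: CMode = "absolute"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("c must be non-negative")
        if self.n_passages <= 0 or self.n_replicates <= 0:
            raise ValueError("passage and replicate counts must be positive")
        if self.founders0 <= 0:
            raise ValueError("founders0 must be positive")
        if self.c_mode not in ("absolute", "relative"):
            raise ValueError(f"unknown c_mode {self.c_mode!r}")


@dataclass(frozen=True)
class PassageRecord:
    """One growth/transmission cycle of one lineage."""

    index: int
    env: EnvironmentDraw
    founders_in: float
    P_end: float
    B_end: float
    transmitted: float
    R0: float


@dataclass(frozen=True)
class LineageTrajectory:
    """Ordered passage records of one lineage plus its R0 summaries."""

    records: tuple[PassageRecord, ...]
    var_R0: float = field(init=False)
    mean_R0: float = field(init=False)
    geomean_R0: float = field(init=False)

    def __post_init__(self) -> None:
        v, m, g = summarize_r0(self.r0_sequence)
        object.__setattr__(self, "var_R0", v)
        object.__setattr__(self, "mean_R0", m)
        object.__setattr__(self, "geomean_R0", g)

    @property
    def r0_sequence(self) -> np.ndarray:
        return np.array([rec.R0 for rec in self.records])

    def __len__(self) -> int:
        return len(self.records)


def summarize_r0(r0: np.ndarray) -> tuple[float, float, float]:
    """Sample variance (n-1), arithmetic mean, and geometric mean of an R0
    sequence.  The geometric mean is defined as 0 when any R0 is 0:
    extinction is absorbing, so a single zero annihilates long-term
    growth."""
    r0 = np.asarray(r0, dtype=float)
    if r0.size == 0:
        raise ValueError("empty R0 sequence")
    var = float(r0.var(ddof=1)) if r0.size > 1 else 0.0
    mean = float(r0.mean())
    if np.any(r0 <= 0.0):
        geo = 0.0
    else:
        geo = float(np.exp(np.mean(np.log(r0))))
    return var, mean, geo


def summarize_lineage(traj: LineageTrajectory) -> tuple[float, float, float]:
    """(var R0, mean R0, geometric mean R0) across a lineage's passages."""
    return summarize_r0(traj.r0_sequence)


def _passage_fitness(c: float, c_mode: CMode, env: dict) -> np.ndarray:
    """Per-founder fitness of every drawn environment at colonization c."""
    c_abs = c * env["r"] if c_mode == "relative" else c
    return fitness_w(c_abs, env["r"], env["t"], env["k_p"], env["k_b"])


def run_lineage(config: PassagingConfig, rng: np.random.Generator) -> LineageTrajectory:
    """Simulate one lineage through ``n_passages`` growth/transmission
    cycles, recording the full per-passage state.

    Founder counts are continuous (no demographic stochasticity) and are
    not reset between passages; a lineage whose founders underflow is
    marked extinct and records R0 = 0 for the remaining passages.
    """
    env = draw_environments(config.treatment, rng, size=config.n_passages)
    founders = config.founders0
    records: list[PassageRecord] = []
    for i in range(config.n_passages):
        e = EnvironmentDraw(
            r=float(env["r"][i]), t=float(env["t"][i]),
            k_p=float(env["k_p"][i]), k_b=float(env["k_b"][i]),
        )
        if founders <= _EXTINCTION_FLOOR:
            records.append(PassageRecord(index=i, env=e, founders_in=0.0,
                                         P_end=0.0, B_end=0.0, transmitted=0.0, R0=0.0))
            founders = 0.0
            continue
        c_abs = config.c * e.r if config.c_mode == "relative" else config.c
        x = (e.r - c_abs) * e.t
        P_end = founders * np.exp(x)
        if abs(e.r - c_abs) < 1e-12 * max(e.r, 1.0):
            B_end = c_abs * founders * e.t
        else:
            B_end = (c_abs / (e.r - c_abs)) * (P_end - founders)
        transmitted = e.k_p * P_end + e.k_b * B_end
        r0 = transmitted / founders
        records.append(PassageRecord(index=i, env=e, founders_in=founders,
                                     P_end=float(P_end), B_end=float(B_end),
                                     transmitted=float(transmitted), R0=float(r0)))
        founders = float(transmitted)
    return LineageTrajectory(records=tuple(records))


def run_experiment(
    c_values: Sequence[float],
    treatments: Sequence[str] = ("low", "mid", "high"),
    n_passages: int = 10,
    n_replicates: int = 100,
    founders0: float = 5000.0,
    c_mode: CMode = "absolute",
    convention: str = "cv",
    seed: int | None = None,
    mu_r: float = 0.06,
    mu_t: float = 40.0,
    mu_kp: float = 0.1,
    mu_kb: float = 0.6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run replicate lineages over a grid of colonization rates and
    variance treatments.

    Returns ``(lineages, summary)``:

    - ``lineages``: one row per (treatment, c, replicate) with the three
      per-lineage R0 summaries.
    - ``summary``: one row per (treatment, c, statistic) with the mean
      across replicates and a 95% normal-approximation confidence
      interval, plus ``c_rel`` = c / mu_r for plotting against the
      relative colonization axis.

    Per-passage R0 is independent of the founder count, so the summaries
    are fully determined by the environment draws and c. All randomness
    flows from ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for level in treatments:
        dist = make_treatment(level, convention=convention,
                              mu_r=mu_r, mu_t=mu_t, mu_kp=mu_kp, mu_kb=mu_kb)
        for c in c_values:
            # one vectorized draw block per (treatment, c): replicates x passages
            env = draw_environments(dist, rng, size=(n_replicates, n_passages))
            w = _passage_fitness(c, c_mode, env)
            # founder trajectories only matter for extinction flagging
            log_f = np.log(founders0) + np.cumsum(
                np.log(np.maximum(w, _EXTINCTION_FLOOR)), axis=1
            )
            extinct = np.any(log_f < np.log(1e-250), axis=1)
            r0 = np.array(w, copy=True)
            for rep in np.flatnonzero(extinct):
                dead = np.flatnonzero(log_f[rep] < np.log(1e-250))
                r0[rep, dead[0] + 1:] = 0.0
            for rep in range(n_replicates):
                v, m, g = summarize_r0(r0[rep])
                rows.append({"treatment": level, "c": c, "c_rel": c / mu_r,
                             "replicate": rep, "var_R0": v, "mean_R0": m,
                             "geomean_R0": g})
    lineages = pd.DataFrame(rows)
    stats = ["var_R0", "mean_R0", "geomean_R0"]
    agg = []
    for (level, c), grp in lineages.groupby(["treatment", "c"], sort=False):
        for stat in stats:
            x = grp[stat].to_numpy()
            m = x.mean()
            se = x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0
            agg.append({"treatment": level, "c": c, "c_rel": c / mu_r,
                        "statistic": stat, "mean": m,
                        "ci_lo": m - 1.96 * se, "ci_hi": m + 1.96 * se})
    return lineages, pd.DataFrame(agg)


@dataclass(frozen=True)
class ResponseCurveFit:
    """Linear-vs-quadratic characterization of a response curve.

    ``chosen`` is the model with the lower AIC; coefficients are in
    increasing polynomial order (intercept first). ``vertex`` is the
    stationary point of the quadratic (NaN for the linear model).
    """

    chosen: Literal["linear", "quadratic"]
    aic_linear: float
    aic_quadratic: float
    coef_linear: np.ndarray
    coef_quadratic: np.ndarray
    vertex: float

    @property
    def has_interior_maximum(self) -> bool:
        """True when the chosen model is a concave quadratic (a hump)."""
        return self.chosen == "quadratic" and self.coef_quadratic[2] < 0


def fit_response_curves(c_values: Sequence[float], y: Sequence[float]) -> ResponseCurveFit:
    """OLS fits of y ~ c and y ~ c + c^2, compared by AIC.

    Uses the full Gaussian log-likelihood AIC convention (statsmodels);
    both candidates share the additive constant, so the model choice is
    convention-invariant.
    """
    import statsmodels.api as sm

    c = np.asarray(c_values, dtype=float)
    y = np.asarray(y, dtype=float)
    if c.size < 4:
        raise ValueError("need at least 4 points to compare linear vs quadratic")
    if np.ptp(c) == 0:
        raise ValueError("degenerate design: all c values identical")
    X1 = sm.add_constant(c)
    X2 = sm.add_constant(np.column_stack([c, c**2]))
    fit1 = sm.OLS(y, X1).fit()
    fit2 = sm.OLS(y, X2).fit()
    b1 = np.asarray(fit1.params)
    b2 = np.asarray(fit2.params)
    vertex = -b2[1] / (2 * b2[2]) if b2[2] != 0 else np.nan
    chosen = "linear" if fit1.aic <= fit2.aic else "quadratic"
    return ResponseCurveFit(
        chosen=chosen,
        aic_linear=float(fit1.aic),
        aic_quadratic=float(fit2.aic),
        coef_linear=b1,
        coef_quadratic=b2,
        vertex=float(vertex),
    )
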