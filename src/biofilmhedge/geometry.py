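"""Frontier-limited lattice growth: how geometry caps biofilm expansion.

Planktonic populations grow exponentially; a biofilm does not, because
nutrient diffusion and steric packing restrict division to an active layer
at the exposed front.  This module abstracts that arrest to its geometric
core: cells live on a square/cubic lattice, and a cell may divide (into a
free von-Neumann neighbor) only if it lies within ``active_depth`` lattice
steps of the front.  There is no nutrient field and no mechanics — the
simulator exists to test the functional-form consequences of the rule:

- sparse cells with free space grow exponentially (doubling once per
  division time);
- after confluence the front advances at constant speed, so cumulative
  cell number follows a polynomial in time of order equal to the
  dimensionality of the growing body (linear for a front on a surface,
  quadratic for a 2D disk, cubic for a 3D ball);
- each time growth fills a finite dimension, the polynomial order drops by
  one, down to saturation in a fully bounded domain.

Divisions are synchronous epochs of length ``division_time``; within an
epoch, cells divide in randomized order and compete for free sites, which
breaks ties without biasing the front speed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import distance_transform_cdt
from scipy.stats import linregress

__all__ = [
    "GeometryConfig",
    "GrowthCurve",
    "OrderEstimate",
    "simulate_frontier_growth",
    "estimate_growth_order",
    "confluence_decay_check",
]


@dataclass(frozen=True)
class GeometryConfig:
    """Lattice, activity rule, and inoculum for one growth simulation.

    Parameters
    ----------
    dimensionality : {1, 2, 3}
        Spatial dimension of the biofilm body.
    geometry : {"radial", "substratum"}
        ``radial``: growth from seed cells at the domain center.
        ``substratum``: growth upward from a flat surface of dimension
        D-1 (the last axis is the growth normal; the surface sits at its
        lower wall).
    active_depth : int
        Depth of the dividing layer, in cell diameters from the exposed
        front (>= 1; the front itself is depth 1).
    domain_extent : tuple of (int | None)
        Finite bound per axis in cell diameters, or None for unbounded.
        Must have length ``dimensionality``.
    division_time : float
        Time units per division epoch for active cells.
    inoculum : int
        Number of seed cells. Radial seeds form a compact cluster at the
        center; substratum seeds are spread evenly along the surface.
    seed : int
        Seed for the site-choice randomness.
    """

    dimensionality: Literal[1, 2, 3]
    geometry: Literal["radial", "substratum"] = "radial"
    active_depth: int = 3
    domain_extent: tuple[int | None, ...] | None = None
    division_time: float = 1.0
    inoculum: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimensionality not in (1, 2, 3):
            raise ValueError("dimensionality must be 1, 2, or 3")
        if self.active_depth < 1:
            raise ValueError("active_depth must be >= 1")
        if self.division_time <= 0:
            raise ValueError("division_time must be positive")
        if self.inoculum < 1:
            raise ValueError("inoculum must be >= 1")
        ext = self.domain_extent
        if ext is None:
            ext = (None,) * self.dimensionality
        if len(ext) != self.dimensionality:
            raise ValueError("domain_extent length must equal dimensionality")
        if any(e is not None and e < 2 for e in ext):
            raise ValueError("finite extents must be >= 2 cell diameters")
        object.__setattr__(self, "domain_extent", tuple(ext))


@dataclass(frozen=True)
class GrowthCurve:
    """Cumulative cell counts N(t) and active-layer counts per epoch."""

    times: np.ndarray
    N: np.ndarray
    active: np.ndarray
    config: GeometryConfig
    filled: bool = False  #: True when the domain reached capacity

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.times, "N": self.N, "active": self.active})


@dataclass(frozen=True)
class OrderEstimate:
    """Least-squares polynomial order of N(t) on a log-log window."""

    order: float
    se: float
    converged: bool
    window: tuple[float, float]
    n_points: int


def _build_grid(config: GeometryConfig, n_epochs: int):
    """Allocate the occupancy and wall arrays with a one-cell border.

    Unbounded axes get enough room that the front cannot reach the border
    within ``n_epochs``; finite axes get walls (border cells that count as
    occupied for the depth rule but never divide or count toward N).
    """
    D = config.dimensionality
    margin = n_epochs + 2
    shape = []
    lo_wall = []
    for ax in range(D):
        ext = config.domain_extent[ax]
        growth_axis = config.geometry == "substratum" and ax == D - 1
        if ext is not None:
            shape.append(ext)
            lo_wall.append(True)
        elif growth_axis:
            shape.append(margin)
            lo_wall.append(True)  # the substratum surface is a wall
        elif config.geometry == "substratum":
            # lateral unbounded: room for sideways spread from the seeds
            shape.append(2 * margin + config.inoculum)
            lo_wall.append(False)
        else:
            shape.append(2 * margin + 1)
            lo_wall.append(False)
    full = tuple(s + 2 for s in shape)  # one-cell border all around
    occ = np.zeros(full, dtype=bool)
    wall = np.zeros(full, dtype=bool)
    for ax in range(D):
        ext = config.domain_extent[ax]
        growth_axis = config.geometry == "substratum" and ax == D - 1
        finite_lo = ext is not None or (growth_axis and lo_wall[ax])
        finite_hi = ext is not None
        sl_lo = [slice(None)] * D
        sl_hi = [slice(None)] * D
        sl_lo[ax] = 0
        sl_hi[ax] = full[ax] - 1
        if finite_lo or (growth_axis):
            wall[tuple(sl_lo)] = True
        if finite_hi:
            wall[tuple(sl_hi)] = True
    return occ, wall


def _seed_cells(config: GeometryConfig, occ: np.ndarray, rng: np.random.Generator) -> None:
    D = config.dimensionality
    shape = occ.shape
    if config.geometry == "radial":
        center = tuple(s // 2 for s in shape)
        # compact cluster: BFS fill of `inoculum` sites around the center
        frontier = [center]
        placed = 0
        seen = {center}
        while frontier and placed < config.inoculum:
            nxt = []
            for site in frontier:
                if placed >= config.inoculum:
                    break
                occ[site] = True
                placed += 1
                for ax in range(D):
                    for step in (-1, 1):
                        nb = list(site)
                        nb[ax] += step
                        nb = tuple(nb)
                        if nb not in seen:
                            seen.add(nb)
                            nxt.append(nb)
            frontier = nxt
    else:
        # seeds spread evenly along the surface (z = 1, just above the wall)
        lateral_shape = shape[:-1]
        n_sites = int(np.prod([s - 2 for s in lateral_shape])) if D > 1 else 1
        n = min(config.inoculum, max(n_sites, 1))
        if D == 1:
            occ[1] = True
            return
        lateral_sizes = [s - 2 for s in lateral_shape]
        flat = np.linspace(0, np.prod(lateral_sizes) - 1, n).round().astype(int)
        for f in np.unique(flat):
            idx = np.unravel_index(f, lateral_sizes)
            occ[tuple(i + 1 for i in idx) + (1,)] = True


_TAXICAB_NEIGHBORS = {
    1: [(-1,), (1,)],
    2: [(-1, 0), (1, 0), (0, -1), (0, 1)],
    3: [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)],
}


def simulate_frontier_growth(config: GeometryConfig, t_end: float) -> GrowthCurve:
    """Run the active-layer division process until ``t_end``.

    Returns the growth curve sampled at the end of each division epoch.
    If the domain fills completely the simulation stops early with the
    curve flagged ``filled``.
    """
    n_epochs = int(np.floor(t_end / config.division_time))
    if n_epochs < 1:
        raise ValueError("t_end must cover at least one division epoch")
    rng = np.random.default_rng(config.seed)
    occ, wall = _build_grid(config, n_epochs)
    _seed_cells(config, occ, rng)
    D = config.dimensionality
    offsets = _TAXICAB_NEIGHBORS[D]
    times, counts, actives = [], [], []
    filled = False
    for epoch in range(1, n_epochs + 1):
        # depth to the nearest exposed (empty, non-wall) site; wall cells
        # count as solid so the domain edge is never a "front"
        solid = occ | wall
        dist = distance_transform_cdt(solid, metric="taxicab")
        active_mask = occ & (dist <= config.active_depth)
        active_sites = np.argwhere(active_mask)
        if len(active_sites):
            order = rng.permutation(len(active_sites))
            free = ~solid
            for k in order:
                site = active_sites[k]
                choices = []
                for off in offsets:
                    nb = tuple(site + np.array(off))
                    if free[nb]:
                        choices.append(nb)
                if choices:
                    pick = choices[rng.integers(len(choices))] if len(choices) > 1 else choices[0]
                    occ[pick] = True
                    free[pick] = False
        times.append(epoch * config.division_time)
        counts.append(int(occ.sum()))
        actives.append(int(active_mask.sum()))
        interior = ~wall
        if not np.any(~occ & interior):
            filled = True
            break
    return GrowthCurve(
        times=np.array(times, dtype=float),
        N=np.array(counts, dtype=float),
        active=np.array(actives, dtype=float),
        config=config,
        filled=filled,
    )


def estimate_growth_order(
    curve: GrowthCurve | None,
    window: tuple[float, float],
    times: np.ndarray | None = None,
    N: np.ndarray | None = None,
    min_points: int = 10,
) -> OrderEstimate:
    """Polynomial order of N(t) on a window: OLS slope of log N vs log t.

    Also accepts raw ``times``/``N`` arrays in place of a curve (useful for
    synthetic checks). An exponential curve has no stable order; this is
    detected by comparing the slopes of the two half-windows — a drift
    upward beyond joint uncertainty flags ``converged=False``.
    """
    if curve is not None:
        times, N = curve.times, curve.N
    t = np.asarray(times, dtype=float)
    n = np.asarray(N, dtype=float)
    lo, hi = window
    mask = (t >= lo) & (t <= hi) & (n > 0) & (t > 0)
    if mask.sum() < min_points:
        raise ValueError(f"window contains {int(mask.sum())} usable samples; need >= {min_points}")
    lt, ln = np.log(t[mask]), np.log(n[mask])
    fit = linregress(lt, ln)
    half = lt < np.median(lt)
    converged = True
    if half.sum() >= 3 and (~half).sum() >= 3:
        f1 = linregress(lt[half], ln[half])
        f2 = linregress(lt[~half], ln[~half])
        se = float(np.hypot(f1.stderr or 0.0, f2.stderr or 0.0))
        if f2.slope - f1.slope > max(3 * se, 0.15 * abs(fit.slope)):
            converged = False
    return OrderEstimate(
        order=float(fit.slope),
        se=float(fit.stderr),
        converged=converged,
        window=(float(lo), float(hi)),
        n_points=int(mask.sum()),
    )


def confluence_decay_check(
    config: GeometryConfig,
    t_end: float,
    n_windows: int = 3,
    skip_fraction: float = 0.15,
) -> list[OrderEstimate]:
    """Order estimates over successive time windows of one simulation.

    The early transient (the exponential phase before the front forms) is
    skipped; the remaining span is split into ``n_windows`` equal log-time
    segments.  In a domain with finite axes the sequence of orders should
    be non-increasing (within uncertainty) as growth reaches confluence
    across each dimension.
    """
    if config.domain_extent is not None and all(e is None for e in config.domain_extent):
        if config.geometry == "radial":
            raise ValueError("confluence requires at least one finite axis")
    curve = simulate_frontier_growth(config, t_end)
    t = curve.times
    lo = t[0] + skip_fraction * (t[-1] - t[0])
    edges = np.exp(np.linspace(np.log(max(lo, t[0] + 1e-9)), np.log(t[-1]), n_windows + 1))
    out = []
    for a, b in zip(edges[:-1], edges[1:]):
        try:
            out.append(estimate_growth_order(curve, (a, b), min_points=5))
        except ValueError:
            continue
    return out
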