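"""Figure/table regeneration: drives the model modules with each figure's
reference parameterization and writes tidy CSVs (and optional plots).

Every output directory is self-describing: a ``run_metadata.json`` sidecar
records the normalized config, its hash, the seed, and the package
version, so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .config import config_hash, validate_config
from .environments import make_treatment
from .fitness import TransmissionWeights, landscape_grid, optimal_colonization, regime_boundaries
from .geometry import GeometryConfig, confluence_decay_check, simulate_frontier_growth
from .passaging import fit_response_curves, run_experiment
from .within_patch import (
    WithinPatchParams,
    biofilm_maximizing_colonization,
    integrate_full_model,
    solve_trajectory,
)

__all__ = ["FIGURE_IDS", "reproduce_figure", "write_metadata"]

log = logging.getLogger("biofilmhedge")

FIGURE_IDS = ("fig2", "fig3", "figS1", "figS2", "fig5", "fig1_analog")


def write_metadata(outdir: Path, config: dict[str, Any], seed: int) -> None:
    meta = {
        "config": config,
        "config_hash": config_hash(config),
        "seed": seed,
        "package": "biofilmhedge",
        "version": __version__,
    }
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2, default=str) + "\n")


def _csv(df: pd.DataFrame, path: Path) -> None:
    # pinned dialect: '.' decimal, UTF-8, header row, LF
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
    log.info("wrote=%s rows=%d", path, len(df))


def _fig2(outdir: Path, cfg: dict, plot: bool) -> None:
    r, P0, t_end = 0.08, 5e6, 40.0
    times = np.linspace(0.0, t_end, 201)
    rows = []
    for c_rel in np.linspace(0.1, 0.99, 12):
        traj = solve_trajectory(WithinPatchParams(r=r, c=c_rel * r, t_end=t_end, P0=P0), times)
        df = traj.to_frame()
        df.insert(0, "c_rel", c_rel)
        rows.append(df)
    _csv(pd.concat(rows, ignore_index=True), outdir / "fig2_AB_timeseries.csv")

    rows = []
    for r_i in np.linspace(0.02, 0.12, 6):
        for c_rel in np.linspace(0.01, 0.999, 200):
            p = WithinPatchParams(r=r_i, c=c_rel * r_i, t_end=t_end, P0=P0)
            traj = solve_trajectory(p, [t_end])
            rows.append((r_i, c_rel, traj.P[0], traj.B[0]))
    _csv(pd.DataFrame(rows, columns=["r", "c_rel", "P_end", "B_end"]),
         outdir / "fig2_CDE_endpoints.csv")

    rows = [(r_i, biofilm_maximizing_colonization(r_i, t_end) / r_i)
            for r_i in np.linspace(0.02, 0.12, 41)]
    df_f = pd.DataFrame(rows, columns=["r", "c_rel_max_biofilm"])
    _csv(df_f, outdir / "fig2_F_optimum.csv")
    if plot:
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        ax.plot(df_f["r"], df_f["c_rel_max_biofilm"])
        ax.set_xlabel("growth rate r")
        ax.set_ylabel("c/r maximizing biofilm")
        fig.savefig(outdir / "fig2_F_optimum.png", dpi=150)
        plt.close(fig)


def _fig3_like(outdir: Path, r_values, t_values, k_res: int, stem: str, plot: bool) -> None:
    grid = landscape_grid(r_values, t_values, k_res)
    for (r, t), panel in grid.groupby(["r", "t"]):
        name = f"{stem}_r{r:g}_t{t:g}"
        _csv(panel[["k_p", "k_b", "c_star_rel", "regime"]], outdir / f"{name}.csv")
        bounds = regime_boundaries(r, t, k_grid=min(k_res, 51))
        _csv(bounds, outdir / f"{name}_boundaries.csv")
        if plot:
            import matplotlib.pyplot as plt

            piv = panel.pivot_table(index="k_b", columns="k_p", values="c_star_rel")
            fig, ax = plt.subplots()
            m = ax.contourf(piv.columns, piv.index, piv.values, levels=21, cmap="viridis")
            fig.colorbar(m, ax=ax, label="c*/r")
            ax.plot(bounds["k_p"], bounds["k_b_white"], "w:", lw=2)
            ax.plot(bounds["k_p"], bounds["k_b_black"], "k:", lw=2)
            ax.set_xlabel("$k_p$")
            ax.set_ylabel("$k_b$")
            ax.set_title(f"r={r:g}, t={t:g}")
            fig.savefig(outdir / f"{name}.png", dpi=150)
            plt.close(fig)


def _figS1(outdir: Path, cfg: dict, plot: bool) -> None:
    t_end, P0 = 50.0, 5e6
    times = np.linspace(0.0, t_end, 101)
    rows = []
    for r in np.linspace(0.02, 0.12, 6):
        for c_rel in np.linspace(0.02, 0.98, 49):
            c = c_rel * r
            for form, g, d in (("none", 0.0, 0.0), ("linear", 40000.0, 0.01), ("quadratic", 1000.0, 0.01)):
                p = WithinPatchParams(r=r, c=c, t_end=t_end, P0=P0, d=d, g=g, growth_form=form)
                traj = integrate_full_model(p, times)
                rows.append((form, r, c_rel, traj.P[-1], traj.B[-1]))
    _csv(pd.DataFrame(rows, columns=["growth_form", "r", "c_rel", "P_end", "B_end"]),
         outdir / "figS1_models.csv")


def _fig5(outdir: Path, cfg: dict, seed: int, plot: bool) -> None:
    p = cfg["passaging"]
    env = cfg["environment"]
    lineages, summary = run_experiment(
        c_values=p["c_grid"],
        treatments=p["treatments"],
        n_passages=p["n_passages"],
        n_replicates=p["n_replicates"],
        founders0=p["founders0"],
        c_mode=p["c_mode"],
        convention=env["convention"],
        seed=seed,
        mu_r=env["mu_r"],
        mu_t=env["mu_t"],
        mu_kp=env["mu_kp"],
        mu_kb=env["mu_kb"],
    )
    _csv(lineages, outdir / "fig5_lineages.csv")
    _csv(summary, outdir / "fig5_summary.csv")
    fits = []
    for (level, stat), grp in summary.groupby(["treatment", "statistic"]):
        if len(grp) < 4:  # regression comparison needs a real grid
            continue
        y = np.log(np.maximum(grp["mean"].to_numpy(), 1e-300))
        fit = fit_response_curves(grp["c_rel"].to_numpy(), y)
        fits.append({"treatment": level, "statistic": stat, "chosen": fit.chosen,
                     "aic_linear": fit.aic_linear, "aic_quadratic": fit.aic_quadratic,
                     "vertex_c_rel": fit.vertex})
    if fits:
        _csv(pd.DataFrame(fits), outdir / "fig5_regressions.csv")
    if plot:
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
        for ax, stat, label in zip(axes, ["var_R0", "mean_R0", "geomean_R0"],
                                   ["variance in R0", "average R0", "geometric mean R0"]):
            for level, grp in summary[summary["statistic"] == stat].groupby("treatment"):
                ax.errorbar(grp["c_rel"], grp["mean"],
                            yerr=[grp["mean"] - grp["ci_lo"], grp["ci_hi"] - grp["mean"]],
                            label=level, fmt="o-", ms=3)
            ax.set_yscale("log")
            ax.set_xlabel("c / $\\mu_r$")
            ax.set_ylabel(label)
        axes[0].legend(title="variance")
        fig.tight_layout()
        fig.savefig(outdir / "fig5.png", dpi=150)
        plt.close(fig)


def _fig1_analog(outdir: Path, cfg: dict, seed: int, plot: bool) -> None:
    g = cfg["geometry"]
    config = GeometryConfig(
        dimensionality=g["dimensionality"],
        geometry=g["geometry"],
        active_depth=g["active_depth"],
        domain_extent=tuple(g["domain_extent"]) if g["domain_extent"] else None,
        division_time=g["division_time"],
        inoculum=g["inoculum"],
        seed=seed,
    )
    curve = simulate_frontier_growth(config, g["t_end"])
    _csv(curve.to_frame(), outdir / "fig1_analog_curve.csv")
    orders = confluence_decay_check(config, g["t_end"])
    _csv(pd.DataFrame([{"window_lo": o.window[0], "window_hi": o.window[1],
                        "order": o.order, "se": o.se, "converged": o.converged}
                       for o in orders]),
         outdir / "fig1_analog_orders.csv")
    if plot:
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        ax.loglog(curve.times, curve.N, "o-", ms=3)
        ax.set_xlabel("time")
        ax.set_ylabel("accumulated cells N(t)")
        fig.savefig(outdir / "fig1_analog.png", dpi=150)
        plt.close(fig)


def reproduce_figure(
    figure_id: str,
    config: dict[str, Any] | None = None,
    out: str | Path = "results",
    seed: int | None = None,
    plot: bool = False,
) -> Path:
    """Regenerate one figure's data (and optionally its plot).

    ``figure_id`` is one of FIGURE_IDS; unknown ids raise with the list of
    valid choices. Returns the output directory.
    """
    if figure_id not in FIGURE_IDS:
        raise ValueError(f"unknown figure id {figure_id!r}; valid ids: {', '.join(FIGURE_IDS)}")
    cfg = validate_config(config)  # idempotent on normalized configs
    if seed is None:
        seed = cfg["seed"]
    outdir = Path(out) / figure_id
    outdir.mkdir(parents=True, exist_ok=True)
    if figure_id == "fig2":
        _fig2(outdir, cfg, plot)
    elif figure_id == "fig3":
        _fig3_like(outdir, cfg["landscape"]["r_values"], [40.0],
                   cfg["landscape"]["k_resolution"], "fig3", plot)
    elif figure_id == "figS2":
        _fig3_like(outdir, [0.08], [10.0, 22.0, 34.0, 46.0, 58.0, 70.0],
                   cfg["landscape"]["k_resolution"], "figS2", plot)
    elif figure_id == "figS1":
        _figS1(outdir, cfg, plot)
    elif figure_id == "fig5":
        _fig5(outdir, cfg, seed, plot)
    else:
        _fig1_analog(outdir, cfg, seed, plot)
    write_metadata(outdir, cfg, seed)
    return outdir
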