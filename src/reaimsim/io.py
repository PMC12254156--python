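"""Writers for trajectories, sweep grids and heatmap figures.

All tabular output is CSV with frozen column names and deterministic row
order, so reruns with identical inputs are byte-identical.  Heatmaps are an
optional convenience output; a missing or broken rendering backend degrades
to a warning, never a failure.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .costs import CostLedger
from .model import Trajectory
from .scenarios import GridResult

__all__ = [
    "trajectory_to_frame",
    "write_trajectory_csv",
    "grid_to_frame",
    "write_grid_csv",
    "render_heatmaps",
]

log = logging.getLogger("reaimsim")

#: frozen trajectory CSV schema: one row per time point; flow and cost
#: columns on row i describe the step that *ended* at times[i] (zeros on the
#: initial row).
TRAJECTORY_COLUMNS = (
    "time_years",
    "unaware",
    "not_engaged",
    "not_initially_participating",
    "participating",
    "disengaged",
    "exposure",
    "initial_reach",
    "non_uptake",
    "delayed_reach",
    "disengagement",
    "reengagement",
    "initial_reach_cost",
    "delayed_reach_cost",
    "maintenance_cost",
    "reengagement_cost",
    "cumulative_cost",
)

GRID_COLUMNS = (
    "scenario",
    "p_initial_reach",
    "p_disengage",
    "participation",
    "cumulative_cost",
)


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    """Flatten a trajectory into a tidy DataFrame (see TRAJECTORY_COLUMNS)."""
    n_points = len(traj.states)
    stocks = np.array([s.as_tuple() for s in traj.states])
    flows = np.zeros((n_points, 6))
    incs = np.zeros((n_points, 4))
    for i, f in enumerate(traj.flows):
        flows[i + 1] = f.as_tuple()
    for i, c in enumerate(traj.cost_increments):
        incs[i + 1] = (
            c.initial_reach_cost,
            c.delayed_reach_cost,
            c.maintenance_cost,
            c.reengagement_cost,
        )
    cumulative = np.cumsum(incs.sum(axis=1))
    data = np.column_stack([traj.times, stocks, flows, incs, cumulative])
    return pd.DataFrame(data, columns=list(TRAJECTORY_COLUMNS))


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> Path:
    """Write one row per time point: time, stocks, flows, cost increments and
    the running cumulative total."""
    path = Path(path)
    trajectory_to_frame(traj).to_csv(path, index=False)
    return path


def grid_to_frame(grid: GridResult) -> pd.DataFrame:
    """Long-format sweep table, reach-major ascending row order."""
    n_r, n_d = grid.participation.shape
    reach = np.repeat(grid.reach_axis, n_d)
    dis = np.tile(grid.disengage_axis, n_r)
    return pd.DataFrame(
        {
            "scenario": grid.scenario.name,
            "p_initial_reach": reach,
            "p_disengage": dis,
            "participation": grid.participation.ravel(),
            "cumulative_cost": grid.cost.ravel(),
        }
    )


def write_grid_csv(grids: GridResult | Iterable[GridResult], path: str | Path) -> Path:
    """Write one or more sweep grids to a single long-format CSV."""
    if isinstance(grids, GridResult):
        grids = [grids]
    frame = pd.concat([grid_to_frame(g) for g in grids], ignore_index=True)
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def render_heatmaps(
    grids: Sequence[GridResult], path_prefix: str | Path
) -> list[Path]:
    """Render participation and cost heatmaps, one panel pair per scenario.

    Produces ``<prefix>participation.png`` and ``<prefix>cost.png``, each with
    one panel per scenario (side by side when several grids are supplied),
    reach on the x axis, disengagement on the y axis, and a colour scale
    shared across scenarios per outcome.  Returns the written paths; an empty
    input or an unavailable rendering backend logs a warning and returns an
    empty list.
    """
    grids = list(grids)
    if not grids:
        log.warning("render_heatmaps: no grids supplied, nothing to render")
        return []
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except Exception as exc:  # pragma: no cover - backend-dependent
        log.warning("render_heatmaps: rendering backend unavailable (%s); skipping", exc)
        return []

    prefix = str(path_prefix)
    written: list[Path] = []
    outcomes = (
        ("participation", lambda g: g.participation, "final participation proportion"),
        ("cost", lambda g: g.cost, "cumulative cost (cost units)"),
    )
    for name, extract, label in outcomes:
        values = [extract(g) for g in grids]
        vmin = min(v.min() for v in values)
        vmax = max(v.max() for v in values)
        fig, axes = plt.subplots(
            1, len(grids), figsize=(4 * len(grids), 3.6), squeeze=False
        )
        for ax, g, v in zip(axes[0], grids, values):
            mesh = ax.pcolormesh(
                g.reach_axis, g.disengage_axis, v.T, vmin=vmin, vmax=vmax,
                shading="nearest",
            )
            ax.set_xlabel("initial reach (annual proportion)")
            ax.set_ylabel("disengagement (annual proportion)")
            ax.set_title(g.scenario.name)
        fig.colorbar(mesh, ax=axes[0], label=label)
        out = Path(f"{prefix}{name}.png")
        fig.savefig(out, dpi=150)
        plt.close(fig)
        written.append(out)
        log.info("wrote %d %s panel(s) to %s", len(grids), name, out)
    return written
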