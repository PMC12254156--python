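"""Scenario presets, the reach × disengagement grid sweep, and surface metrics.

Four support-strategy scenarios are examined, distinguished by whether the
delayed-reach and re-engagement pathways are supported (annual proportion
0.94) or absent (0):

========================  ==============  ============
scenario                  delayed reach   re-engagement
========================  ==============  ============
no_support        (A/1)   0.00            0.00
enhanced_reach    (C/2)   0.94            0.00
reengagement_support (B/3) 0.00           0.94
both              (D/4)   0.94            0.94
========================  ==============  ============

For each scenario, initial reach and disengagement are swept over an
inclusive grid on [0, 1] and the model is run to the horizon at every grid
point, yielding a final-participation surface and a cumulative-cost surface.
The sweep is evaluated with a vectorised engine that integrates all grid
cells simultaneously; it applies exactly the same flow equations as
:func:`reaimsim.model.step`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .costs import CostParameters, cumulative_cost, unit_cost_increasing, unit_cost_retention
from .model import (
    Parameters,
    annual_to_step_fraction,
    make_default_parameters,
    participation_proportion,
    simulate,
)

__all__ = [
    "ScenarioSpec",
    "GridResult",
    "SCENARIO_NAMES",
    "scenario_presets",
    "run_scenario_point",
    "run_grid",
    "dominance_ratio",
    "high_participation_cells",
]

#: canonical scenario order (letters A, C, B, D == numbers 1, 2, 3, 4)
SCENARIO_NAMES = ("no_support", "enhanced_reach", "reengagement_support", "both")

_SUPPORT_LEVEL = 0.94


@dataclass(frozen=True)
class ScenarioSpec:
    """One support-strategy scenario: fixed delayed-reach and re-engagement
    annual proportions (initial reach and disengagement stay free)."""

    name: str
    p_delayed_reach: float
    p_reengage: float


def scenario_presets() -> dict[str, ScenarioSpec]:
    """The four canonical scenarios, keyed by name."""
    return {
        "no_support": ScenarioSpec("no_support", 0.0, 0.0),
        "enhanced_reach": ScenarioSpec("enhanced_reach", _SUPPORT_LEVEL, 0.0),
        "reengagement_support": ScenarioSpec(
            "reengagement_support", 0.0, _SUPPORT_LEVEL
        ),
        "both": ScenarioSpec("both", _SUPPORT_LEVEL, _SUPPORT_LEVEL),
    }


def run_scenario_point(
    scenario: ScenarioSpec,
    p_initial_reach: float,
    p_disengage: float,
    params: Parameters | None = None,
    costs: CostParameters | None = None,
) -> tuple[float, float]:
    """Simulate the full horizon at one (reach, disengagement) point.

    Returns ``(final participation proportion, cumulative total cost)``.
    """
    base = make_default_parameters() if params is None else params
    merged = base.replace(
        p_initial_reach=p_initial_reach,
        p_disengage=p_disengage,
        p_delayed_reach=scenario.p_delayed_reach,
        p_reengage=scenario.p_reengage,
    )
    traj = simulate(merged, costs=costs)
    return (
        participation_proportion(traj.final_state(), merged),
        cumulative_cost(traj).total,
    )


@dataclass(frozen=True)
class GridResult:
    """Participation and cumulative-cost surfaces for one scenario.

    ``participation[i, j]`` and ``cost[i, j]`` correspond to
    ``reach_axis[i]`` and ``disengage_axis[j]``; both axes ascend.
    """

    scenario: ScenarioSpec
    reach_axis: np.ndarray
    disengage_axis: np.ndarray
    participation: np.ndarray
    cost: np.ndarray

    def __post_init__(self) -> None:
        expected = (len(self.reach_axis), len(self.disengage_axis))
        if self.participation.shape != expected or self.cost.shape != expected:
            raise ValueError(
                f"matrix shape {self.participation.shape} does not match axes {expected}"
            )


def run_grid(
    scenario: ScenarioSpec,
    grid_resolution: int = 21,
    params: Parameters | None = None,
    costs: CostParameters | None = None,
) -> GridResult:
    """Sweep initial reach × disengagement over an inclusive grid on [0, 1].

    Every grid cell is a full-horizon simulation; the engine integrates all
    cells as numpy arrays in lock-step, which is exactly equivalent to calling
    :func:`run_scenario_point` cell by cell.  Deterministic: identical inputs
    produce a bit-identical :class:`GridResult`.
    """
    if grid_resolution < 2:
        raise ValueError(f"grid_resolution must be >= 2, got {grid_resolution}")
    p = make_default_parameters() if params is None else params
    c = CostParameters() if costs is None else costs

    reach_axis = np.linspace(0.0, 1.0, grid_resolution)
    dis_axis = np.linspace(0.0, 1.0, grid_resolution)
    # reach varies along rows (axis 0), disengagement along columns (axis 1)
    reach, dis = np.meshgrid(reach_axis, dis_axis, indexing="ij")

    n = p.steps_per_year
    dt = p.dt
    q_dis = 1.0 - (1.0 - dis) ** (1.0 / n)
    q_delayed = annual_to_step_fraction(scenario.p_delayed_reach, n)
    q_reengage = annual_to_step_fraction(scenario.p_reengage, n)

    # per-unit activity costs are constant over the run
    uc_initial = unit_cost_increasing(
        reach, c.initial_reach.base_cost, c.initial_reach.steepness
    )
    uc_delayed = unit_cost_increasing(
        scenario.p_delayed_reach, c.delayed_reach.base_cost, c.delayed_reach.steepness
    )
    uc_reengage = unit_cost_increasing(
        scenario.p_reengage, c.reengagement.base_cost, c.reengagement.steepness
    )
    uc_retain = unit_cost_retention(
        dis, c.maintenance.base_cost, c.maintenance.steepness
    )

    shape = reach.shape
    unaware = np.full(shape, p.total_population)
    nip = np.zeros(shape)  # not initially participating
    part = np.zeros(shape)
    diseng = np.zeros(shape)
    cost = np.zeros(shape)

    exposure_cap = p.exposure_rate * dt
    for _ in range(p.n_steps):
        exposure = np.minimum(exposure_cap, unaware)
        initial_reach_flow = reach * exposure  # not_engaged is a pure transit
        non_uptake = exposure - initial_reach_flow
        delayed_flow = q_delayed * nip
        diseng_flow = q_dis * part
        reengage_flow = q_reengage * diseng

        cost += (
            uc_initial * initial_reach_flow
            + uc_delayed * nip * dt
            + uc_reengage * diseng * dt
            + uc_retain * part * dt
        )

        unaware = unaware - exposure
        nip = nip - delayed_flow + non_uptake
        part = part + initial_reach_flow + delayed_flow + reengage_flow - diseng_flow
        diseng = diseng + diseng_flow - reengage_flow

    return GridResult(
        scenario=scenario,
        reach_axis=reach_axis,
        disengage_axis=dis_axis,
        participation=part / p.total_population,
        cost=cost,
    )


def dominance_ratio(grid: GridResult) -> float:
    """How strongly disengagement dominates reach in shaping participation.

    Ratio of the mean participation range across disengagement (at fixed
    reach) to the mean range across reach (at fixed disengagement).  Values
    above 1 mean varying disengagement moves the outcome more than varying
    reach does.  A constant surface returns 1 by convention (no dominance
    either way).

    Raises
    ------
    ValueError
        If either axis has fewer than 2 points.
    """
    if len(grid.reach_axis) < 2 or len(grid.disengage_axis) < 2:
        raise ValueError("dominance_ratio needs at least 2 points on each axis")
    across_disengagement = float(np.mean(np.ptp(grid.participation, axis=1)))
    across_reach = float(np.mean(np.ptp(grid.participation, axis=0)))
    if across_disengagement == 0.0 and across_reach == 0.0:
        return 1.0
    if across_reach == 0.0:
        return float("inf")
    return across_disengagement / across_reach


def high_participation_cells(grid: GridResult, threshold: float) -> int:
    """Number of grid cells whose final participation is >= ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    return int(np.count_nonzero(grid.participation >= threshold))
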