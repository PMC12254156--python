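"""Per-person activity-cost curves and cumulative implementation cost.

Each support strategy (initial reach, delayed reach, retention/maintenance,
re-engagement) carries a hypothetical per-person activity cost that grows with
the ambition of the organisational target.  Reaching a target fraction
``θ`` of a cohort follows a normalised exponential curve

    c(θ) = c0 · (e^{kθ} − 1) / (e^k − 1),

which is 0 at θ = 0, c0 at θ = 1, and strictly increasing and convex in
between: the marginal person is ever harder (costlier) to reach.  Retention
support mirrors this as a negative exponential in the disengagement target —
driving disengagement towards zero requires the most intensive (and most
expensive) support, while tolerating full disengagement costs nothing.

Costs accrue along a simulated trajectory: per person crossing the
initial-reach flow, and per person-year of support applied to the
not-initially-participating pool (delayed reach), the disengaged pool
(re-engagement) and the participating pool (retention).  Increments are
aggregated into a cumulative implementation cost; no discounting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import FlowRecord, Parameters, StockState, Trajectory

__all__ = [
    "ActivityCost",
    "CostParameters",
    "CostLedger",
    "unit_cost_increasing",
    "unit_cost_retention",
    "accrue_step_cost",
    "cumulative_cost",
]


@dataclass(frozen=True)
class ActivityCost:
    """One activity's cost curve: base cost c0 (per person, or per
    person-year for stock-based activities) and curve steepness k > 0."""

    base_cost: float = 1.0
    steepness: float = 3.0

    def __post_init__(self) -> None:
        if self.base_cost < 0:
            raise ValueError(f"base_cost must be >= 0, got {self.base_cost}")
        if not self.steepness > 0:
            raise ValueError(f"steepness must be > 0, got {self.steepness}")


@dataclass(frozen=True)
class CostParameters:
    """Cost curves for the four support activities."""

    initial_reach: ActivityCost = field(default_factory=ActivityCost)
    delayed_reach: ActivityCost = field(default_factory=ActivityCost)
    maintenance: ActivityCost = field(default_factory=ActivityCost)
    reengagement: ActivityCost = field(default_factory=ActivityCost)


def unit_cost_increasing(target, base_cost: float = 1.0, steepness: float = 3.0):
    """Per-person cost of pursuing an organisational target fraction.

    ``base_cost · (e^(k·target) − 1) / (e^k − 1)``: 0 at target 0, ``base_cost``
    at target 1, strictly increasing and convex on (0, 1).  Accepts scalars or
    numpy arrays.
    """
    t = np.asarray(target, dtype=float)
    if np.any(t < 0.0) or np.any(t > 1.0):
        raise ValueError(f"target must lie in [0, 1], got {target}")
    out = base_cost * np.expm1(steepness * t) / np.expm1(steepness)
    return float(out) if np.isscalar(target) else out


def unit_cost_retention(p_disengage, base_cost: float = 1.0, steepness: float = 3.0):
    """Per participant-year cost of retention support at a disengagement target.

    The mirror image of :func:`unit_cost_increasing`: lower disengagement
    requires more intensive support, so the cost is ``base_cost`` when the
    target disengagement is 0 and falls to 0 when disengagement is 1 (no
    retention effort at all).
    """
    p = np.asarray(p_disengage, dtype=float)
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError(f"p_disengage must lie in [0, 1], got {p_disengage}")
    return unit_cost_increasing(1.0 - p, base_cost, steepness)


@dataclass(frozen=True)
class CostLedger:
    """Cost broken down by activity (one step's increment, or a cumulative
    total); ``total`` is always the sum of the four components."""

    initial_reach_cost: float = 0.0
    delayed_reach_cost: float = 0.0
    maintenance_cost: float = 0.0
    reengagement_cost: float = 0.0

    _FIELDS = (
        "initial_reach_cost",
        "delayed_reach_cost",
        "maintenance_cost",
        "reengagement_cost",
    )

    @property
    def total(self) -> float:
        return (
            self.initial_reach_cost
            + self.delayed_reach_cost
            + self.maintenance_cost
            + self.reengagement_cost
        )

    def __add__(self, other: "CostLedger") -> "CostLedger":
        return CostLedger(
            self.initial_reach_cost + other.initial_reach_cost,
            self.delayed_reach_cost + other.delayed_reach_cost,
            self.maintenance_cost + other.maintenance_cost,
            self.reengagement_cost + other.reengagement_cost,
        )


def accrue_step_cost(
    state: StockState,
    flows: FlowRecord,
    params: Parameters,
    costs: CostParameters,
    dt: float,
) -> CostLedger:
    """Cost increment for one step, given the step-start state and its flows.

    Accrual bases:

    - initial reach: event-based, per person crossing the initial-reach flow;
    - delayed reach: per person-year of support applied to the
      not-initially-participating pool;
    - re-engagement: per person-year of support applied to the disengaged pool;
    - retention (maintenance): per participant-year of retention support.

    Stock-based components use the step-start stock values, matching the
    step-start flow evaluation of the integrator.
    """
    c = costs
    return CostLedger(
        initial_reach_cost=unit_cost_increasing(
            params.p_initial_reach, c.initial_reach.base_cost, c.initial_reach.steepness
        )
        * flows.initial_reach,
        delayed_reach_cost=unit_cost_increasing(
            params.p_delayed_reach, c.delayed_reach.base_cost, c.delayed_reach.steepness
        )
        * state.not_initially_participating
        * dt,
        reengagement_cost=unit_cost_increasing(
            params.p_reengage, c.reengagement.base_cost, c.reengagement.steepness
        )
        * state.disengaged
        * dt,
        maintenance_cost=unit_cost_retention(
            params.p_disengage, c.maintenance.base_cost, c.maintenance.steepness
        )
        * state.participating
        * dt,
    )


def cumulative_cost(trajectory: Trajectory) -> CostLedger:
    """Component-wise sum of all step increments of a trajectory."""
    total = CostLedger()
    for inc in trajectory.cost_increments:
        total = total + inc
    return total
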