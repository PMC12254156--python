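"""Five-stock engagement pathway: deterministic fixed-step integration.

The model tracks a closed population moving through five engagement states of a
public health program::

    unaware --exposure--> not_engaged --initial reach--> participating
                               |                          ^   |
                          non-uptake              delayed |   | disengagement
                               v                    reach |   v
                    not_initially_participating ----------+  disengaged
                               participating <----re-engagement----+

Stocks hold head-counts; flows move persons between stocks once per update
step (``dt = 1/steps_per_year`` years).  The four proportion parameters are
*annual effective fractions*: the share of a stock that transitions over one
whole year regardless of the sub-annual step size.  Integration is an explicit
fixed-step difference-equation scheme and the whole model is deterministic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids a module cycle
    from .costs import CostLedger, CostParameters

__all__ = [
    "Parameters",
    "StockState",
    "FlowRecord",
    "Trajectory",
    "make_default_parameters",
    "annual_to_step_fraction",
    "initial_state",
    "step",
    "simulate",
    "participation_proportion",
]

#: absolute head-count tolerance used by stock invariant checks
_ATOL = 1e-9

_PROPORTION_FIELDS = ("p_initial_reach", "p_disengage", "p_delayed_reach", "p_reengage")


@dataclass(frozen=True)
class Parameters:
    """Global model constants and the four annual flow proportions.

    Parameters
    ----------
    total_population:
        Closed population size N (persons).  Default 5000.
    exposure_rate:
        Constant awareness-raising flow E (persons/year).  Default 150.
    p_initial_reach:
        Annual effective fraction of newly exposed persons who immediately
        participate.
    p_disengage:
        Annual effective fraction of participants who disengage.
    p_delayed_reach:
        Annual effective fraction of initially non-participating persons who
        join later through the supported delayed-reach pathway.
    p_reengage:
        Annual effective fraction of disengaged persons who resume
        participation through the supported re-engagement pathway.
    steps_per_year:
        Number of equation updates per simulated year.  Default 12.
    horizon_years:
        Simulated horizon T in years.  Default 50.
    """

    total_population: float = 5000.0
    exposure_rate: float = 150.0
    p_initial_reach: float = 0.0
    p_disengage: float = 0.0
    p_delayed_reach: float = 0.0
    p_reengage: float = 0.0
    steps_per_year: int = 12
    horizon_years: float = 50.0

    def __post_init__(self) -> None:
        if not self.total_population > 0:
            raise ValueError(
                f"total_population must be > 0, got {self.total_population}"
            )
        if self.exposure_rate < 0:
            raise ValueError(f"exposure_rate must be >= 0, got {self.exposure_rate}")
        for name in _PROPORTION_FIELDS:
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if not (isinstance(self.steps_per_year, (int, np.integer)) and self.steps_per_year >= 1):
            raise ValueError(
                f"steps_per_year must be an integer >= 1, got {self.steps_per_year}"
            )
        if not self.horizon_years > 0:
            raise ValueError(f"horizon_years must be > 0, got {self.horizon_years}")

    @property
    def dt(self) -> float:
        """Step length in years."""
        return 1.0 / self.steps_per_year

    @property
    def n_steps(self) -> int:
        """Total number of update steps over the horizon."""
        return int(round(self.horizon_years * self.steps_per_year))

    def replace(self, **changes) -> "Parameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)


def make_default_parameters() -> Parameters:
    """Default configuration: N=5000, E=150/yr, 12 steps/yr, 50-year horizon,
    all four proportions 0."""
    return Parameters()


def annual_to_step_fraction(p: float, steps_per_year: int) -> float:
    """Convert an annual effective fraction to the equivalent per-step fraction.

    Returns ``q`` such that applying ``q`` for ``steps_per_year`` consecutive
    steps depletes the same share of a stock as ``p`` does over one year:
    ``1 - (1 - q)**steps_per_year == p``.  In particular ``p = 0.94`` with
    monthly steps gives ``q ≈ 0.2090``, so an isolated cohort loses exactly
    94% per model year (not the ~92% that naive division by 12 would give).

    Raises
    ------
    ValueError
        If ``p`` is outside [0, 1] or ``steps_per_year < 1``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"annual fraction must lie in [0, 1], got {p}")
    if steps_per_year < 1:
        raise ValueError(f"steps_per_year must be >= 1, got {steps_per_year}")
    return 1.0 - (1.0 - p) ** (1.0 / steps_per_year)


@dataclass(frozen=True)
class StockState:
    """Head-counts in the five engagement compartments at one instant."""

    unaware: float = 0.0
    not_engaged: float = 0.0
    not_initially_participating: float = 0.0
    participating: float = 0.0
    disengaged: float = 0.0

    _FIELDS = (
        "unaware",
        "not_engaged",
        "not_initially_participating",
        "participating",
        "disengaged",
    )

    def total(self) -> float:
        """Sum of all five stocks."""
        return (
            self.unaware
            + self.not_engaged
            + self.not_initially_participating
            + self.participating
            + self.disengaged
        )

    def validate(self, total_population: float | None = None) -> None:
        """Check non-negativity and, optionally, conservation of persons.

        Raises
        ------
        ValueError
            If any stock is below ``-1e-9`` or, when ``total_population`` is
            given, the stock sum deviates from it by more than a relative
            tolerance of 1e-9.
        """
        for name in self._FIELDS:
            if getattr(self, name) < -_ATOL:
                raise ValueError(f"stock {name} is negative: {getattr(self, name)}")
        if total_population is not None:
            if abs(self.total() - total_population) > _ATOL * total_population:
                raise ValueError(
                    f"stocks sum to {self.total()}, expected {total_population}"
                )

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (
            self.unaware,
            self.not_engaged,
            self.not_initially_participating,
            self.participating,
            self.disengaged,
        )


def initial_state(params: Parameters) -> StockState:
    """Pre-rollout state: the whole population unaware of the program."""
    return StockState(unaware=params.total_population)


@dataclass(frozen=True)
class FlowRecord:
    """Persons moved along each of the six flows during one step."""

    exposure: float = 0.0
    initial_reach: float = 0.0
    non_uptake: float = 0.0
    delayed_reach: float = 0.0
    disengagement: float = 0.0
    reengagement: float = 0.0

    _FIELDS = (
        "exposure",
        "initial_reach",
        "non_uptake",
        "delayed_reach",
        "disengagement",
        "reengagement",
    )

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in self._FIELDS)


def step(state: StockState, params: Parameters) -> tuple[StockState, FlowRecord]:
    """Advance the model one update step of length ``1/steps_per_year`` years.

    Within-step semantics (chosen so that conservation holds exactly and the
    result is order-independent):

    1. ``exposure = min(E·dt, unaware)`` moves unaware → not_engaged; exposure
       halts once the unaware stock is exhausted.
    2. The not_engaged stock is a one-step transit: everything present after
       the exposure inflow is split by the *annual* initial-reach proportion —
       a fraction ``p_initial_reach`` participates immediately, the remainder
       moves to not_initially_participating.
    3. Delayed reach, disengagement and re-engagement are rate-driven outflows
       evaluated on their source stocks *at step start* (they do not see
       same-step inflows), using per-step fractions obtained with
       :func:`annual_to_step_fraction`.

    Returns the new state and the per-step :class:`FlowRecord`.
    """
    state.validate()

    n = params.steps_per_year
    dt = params.dt

    exposure = min(params.exposure_rate * dt, max(state.unaware, 0.0))
    in_transit = state.not_engaged + exposure
    initial_reach = params.p_initial_reach * in_transit
    non_uptake = in_transit - initial_reach

    delayed_reach = (
        annual_to_step_fraction(params.p_delayed_reach, n)
        * state.not_initially_participating
    )
    disengagement = annual_to_step_fraction(params.p_disengage, n) * state.participating
    reengagement = annual_to_step_fraction(params.p_reengage, n) * state.disengaged

    new_state = StockState(
        unaware=state.unaware - exposure,
        not_engaged=0.0,
        not_initially_participating=state.not_initially_participating
        - delayed_reach
        + non_uptake,
        participating=state.participating
        + initial_reach
        + delayed_reach
        + reengagement
        - disengagement,
        disengaged=state.disengaged + disengagement - reengagement,
    )
    flows = FlowRecord(
        exposure=exposure,
        initial_reach=initial_reach,
        non_uptake=non_uptake,
        delayed_reach=delayed_reach,
        disengagement=disengagement,
        reengagement=reengagement,
    )
    return new_state, flows


@dataclass
class Trajectory:
    """Full record of one simulation run.

    ``states`` has one entry per time point (``n_steps + 1``); ``flows`` and
    ``cost_increments`` have one entry per step.
    """

    times: np.ndarray
    states: list[StockState]
    flows: list[FlowRecord]
    cost_increments: list["CostLedger"]
    params: Parameters
    costs: "CostParameters | None" = None

    def participation(self) -> np.ndarray:
        """Participation proportion at every recorded time point."""
        return np.array(
            [s.participating / self.params.total_population for s in self.states]
        )

    def final_state(self) -> StockState:
        return self.states[-1]


def simulate(
    params: Parameters,
    costs: "CostParameters | None" = None,
    start: StockState | None = None,
) -> Trajectory:
    """Run the model over the full horizon from the default initial state.

    Applies :func:`step` for ``horizon_years × steps_per_year`` steps starting
    from everyone unaware (or from ``start`` if given), recording every state,
    flow record and — when ``costs`` is supplied (default cost parameters are
    used when it is ``None``) — per-step cost increments.
    """
    from .costs import CostParameters, accrue_step_cost

    if costs is None:
        costs = CostParameters()
    state = initial_state(params) if start is None else start
    state.validate()

    n_steps = params.n_steps
    times = np.arange(n_steps + 1) * params.dt
    states = [state]
    flows: list[FlowRecord] = []
    increments: list = []
    for _ in range(n_steps):
        new_state, flow = step(state, params)
        increments.append(accrue_step_cost(state, flow, params, costs, params.dt))
        states.append(new_state)
        flows.append(flow)
        state = new_state
    return Trajectory(
        times=times,
        states=states,
        flows=flows,
        cost_increments=increments,
        params=params,
        costs=costs,
    )


def participation_proportion(state: StockState, params: Parameters) -> float:
    """Reach outcome: participating persons divided by the total population."""
    return state.participating / params.total_population
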