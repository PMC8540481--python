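"""Time-pressure scheduling of in-capillary serial dilutions.

Each calibration level is constituted in its collection vial from two
hydrodynamic transfers: working standard (WS) and diluent (DBGE).  Because
delivered volume is proportional to the pressure·time product (laminar
flow), holding

    t_WS * p_WS + t_DBGE * p_DBGE = budget  (constant across levels)

keeps the total collected volume identical for every level, and the target
concentration fixes how the budget splits between the two transfers:

    product_WS = budget * c_target / c_stock
    product_DBGE = budget - product_WS

The scheduler realises each ideal product as an instrument-executable
(time, pressure) pair subject to the pressure range, the pressure and time
quantisation, and a maximum transfer time:

1. at the default transfer time, if the implied pressure is in range, round
   it to the pressure quantum (half away from zero) — this may introduce a
   small, reported dilution error;
2. if the implied pressure is too high, lengthen the transfer: take the
   smallest on-grid time above the default for which the pressure is within
   range *and* lands exactly on the pressure grid (product preserved);
3. if the implied pressure is too low, pin the pressure at the minimum and
   shorten the time, snapped to the time grid.

The schedule records the achieved concentration recomputed from the
realised products, so any quantisation error is explicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .physics import psi_to_kpa

__all__ = [
    "TransferStep",
    "InstrumentConstraints",
    "DilutionSchedule",
    "SchedulingInfeasibleError",
    "reference_budget",
    "plan_level",
    "plan_series",
]

_GRID_RTOL = 1e-9


class SchedulingInfeasibleError(ValueError):
    """No instrument-executable (time, pressure) pair realises a transfer."""


@dataclass(frozen=True)
class TransferStep:
    """One hydrodynamic transfer: which solution, for how long, at what pressure."""

    solution: str  # "WS" or "DBGE"
    duration_min: float
    pressure_psi: float

    def __post_init__(self) -> None:
        if self.solution not in ("WS", "DBGE"):
            raise ValueError(f"unknown solution label {self.solution!r}")
        if self.duration_min <= 0:
            raise ValueError("transfer duration must be positive")
        if self.pressure_psi <= 0:
            raise ValueError("transfer pressure must be positive")

    @property
    def product(self) -> float:
        """Pressure·time product in psi·min — proportional to delivered volume."""
        return self.duration_min * self.pressure_psi

    @property
    def pressure_kpa(self) -> float:
        return psi_to_kpa(self.pressure_psi)


@dataclass(frozen=True)
class InstrumentConstraints:
    """Executable envelope of the instrument's pressure system.

    Pressures in psi, times in minutes.  ``p_quantum`` / ``t_quantum`` are
    the setting resolutions; ``t_default`` is the preferred transfer time
    (the shortest that gives repeatable delivery) and ``t_max`` the longest
    acceptable one.
    """

    p_min: float
    p_max: float
    p_quantum: float
    t_default: float = 10.0
    t_max: float = 15.0
    t_quantum: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.p_min <= self.p_max:
            raise ValueError("need 0 < p_min <= p_max")
        if self.p_quantum <= 0 or self.t_quantum <= 0:
            raise ValueError("quanta must be positive")
        if not 0 < self.t_default <= self.t_max:
            raise ValueError("need 0 < t_default <= t_max")


@dataclass(frozen=True)
class DilutionSchedule:
    """Executable recipe for one calibration level.

    ``ws_step``/``dbge_step`` are ``None`` for the pass-through (undiluted
    working standard) level.  ``achieved_concentration`` is recomputed from
    the realised pressure·time products, so it may deviate from the target
    when quantisation forced rounding; the deviation is reported as
    ``relative_dilution_error``.
    """

    target_concentration: float
    ws_step: TransferStep | None
    dbge_step: TransferStep | None
    budget: float
    achieved_concentration: float
    relative_dilution_error: float

    @property
    def undiluted(self) -> bool:
        return self.ws_step is None and self.dbge_step is None

    @property
    def ws_product(self) -> float:
        return 0.0 if self.ws_step is None else self.ws_step.product

    @property
    def dbge_product(self) -> float:
        return 0.0 if self.dbge_step is None else self.dbge_step.product

    @property
    def total_product(self) -> float:
        return self.ws_product + self.dbge_product


def reference_budget(t_ref: float, p_ref: float) -> float:
    """Pressure·time budget (psi·min) defined by the 2-fold-dilution reference.

    The mid-range level is an equal-parts mix: both transfers run for
    ``t_ref`` at ``p_ref``, so the constant total products sum is
    ``2 * t_ref * p_ref``.
    """
    if t_ref <= 0 or p_ref <= 0:
        raise ValueError("reference time and pressure must be positive")
    return 2.0 * t_ref * p_ref


def _round_to_quantum(x: float, q: float) -> float:
    """Round to the nearest multiple of ``q``, half away from zero."""
    n = math.floor(abs(x) / q + 0.5 + _GRID_RTOL)
    return math.copysign(n * q, x)


def _on_grid(x: float, q: float) -> bool:
    n = x / q
    return abs(n - round(n)) <= _GRID_RTOL * max(1.0, abs(n))


def _time_grid(c: InstrumentConstraints) -> Iterable[float]:
    """On-grid times strictly above the default, up to ``t_max``, ascending."""
    k = 1
    while True:
        t = c.t_default + k * c.t_quantum
        if t > c.t_max + _GRID_RTOL:
            return
        yield t
        k += 1


def _resolve_product(
    product: float, constraints: InstrumentConstraints, solution: str
) -> TransferStep:
    """Realise an ideal pressure·time product as an executable step."""
    c = constraints
    p0 = product / c.t_default

    if c.p_min - _GRID_RTOL <= p0 <= c.p_max + _GRID_RTOL:
        # Rule 1: keep the default time, quantise the pressure.
        p = min(max(_round_to_quantum(p0, c.p_quantum), c.p_min), c.p_max)
        return TransferStep(solution, c.t_default, p)

    if p0 > c.p_max:
        # Rule 2: smallest on-grid time whose exact pressure is executable.
        for t in _time_grid(c):
            p = product / t
            if p <= c.p_max + _GRID_RTOL and p >= c.p_min - _GRID_RTOL and _on_grid(p, c.p_quantum):
                p = _round_to_quantum(p, c.p_quantum)  # clean float representation
                return TransferStep(solution, t, p)
        raise SchedulingInfeasibleError(
            f"{solution} product {product:g} psi·min has no executable "
            f"(t <= {c.t_max:g} min, p <= {c.p_max:g} psi) realisation"
        )

    # Rule 3: pressure pinned at the minimum, time snapped to the grid.
    t = _round_to_quantum(product / c.p_min, c.t_quantum)
    if t <= 0:
        t = c.t_quantum
    if t > c.t_max + _GRID_RTOL:
        raise SchedulingInfeasibleError(
            f"{solution} product {product:g} psi·min needs t = {t:g} min at "
            f"p_min = {c.p_min:g} psi, above t_max = {c.t_max:g} min"
        )
    return TransferStep(solution, t, c.p_min)


def plan_level(
    c_target: float,
    c_stock: float,
    budget: float,
    constraints: InstrumentConstraints,
) -> DilutionSchedule:
    """Schedule the WS and DBGE transfers for one calibration level.

    Raises :class:`SchedulingInfeasibleError` if either transfer cannot be
    realised within the constraints, and ``ValueError`` for a target above
    the stock concentration.  A target equal to the stock yields the
    pass-through (no-transfer) level.
    """
    if c_stock <= 0:
        raise ValueError("stock concentration must be positive")
    if not 0 < c_target <= c_stock:
        raise ValueError(
            f"target {c_target:g} µg/mL must be in (0, stock = {c_stock:g}]"
        )
    if budget <= 0:
        raise ValueError("budget must be positive")

    if math.isclose(c_target, c_stock, rel_tol=1e-12):
        return DilutionSchedule(
            target_concentration=c_target,
            ws_step=None,
            dbge_step=None,
            budget=budget,
            achieved_concentration=c_stock,
            relative_dilution_error=0.0,
        )

    ideal_ws = budget * c_target / c_stock
    ideal_dbge = budget - ideal_ws
    ws = _resolve_product(ideal_ws, constraints, "WS")
    dbge = _resolve_product(ideal_dbge, constraints, "DBGE")

    achieved = c_stock * ws.product / (ws.product + dbge.product)
    return DilutionSchedule(
        target_concentration=c_target,
        ws_step=ws,
        dbge_step=dbge,
        budget=budget,
        achieved_concentration=achieved,
        relative_dilution_error=(achieved - c_target) / c_target,
    )


def plan_series(
    targets: Sequence[float],
    c_stock: float,
    budget: float,
    constraints: InstrumentConstraints,
) -> list[DilutionSchedule]:
    """Schedule a whole calibration series, one level per target."""
    if len(targets) == 0:
        raise ValueError("target list must be non-empty")
    schedules = []
    for i, c_target in enumerate(targets):
        try:
            schedules.append(plan_level(c_target, c_stock, budget, constraints))
        except (SchedulingInfeasibleError, ValueError) as exc:
            raise type(exc)(f"level {i} ({c_target:g} µg/mL): {exc}") from exc
    return schedules
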