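"""Expansion of dilution schedules into a full timed instrument sequence.

A preparation run is more than the transfers themselves: the capillary is
rinsed and dried before each solution phase, filled with the solution to be
dispensed, its tip cleaned between vials, and each constituted vial is
finally mixed by air bubbling.  This module emits the ordered event list
for a whole run in either flow direction, and accounts for total duration
and per-liquid reagent consumption.

Modes differ only in which sample tray holds the source vials:

* reverse (``R``) — sources in the outlet tray, collection vials in the
  inlet tray; the run proceeds unattended into separation.
* forward (``F``) — the opposite arrangement.

The event multiset, and hence the total duration, is identical in the two
modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .physics import CapillaryGeometry, Fluid, volume_from_product
from .scheduler import DilutionSchedule

__all__ = [
    "SequenceEvent",
    "RinseProtocol",
    "MethodSequence",
    "build_sequence",
    "reagent_budget",
    "vial_volumes",
]

EVENT_KINDS = ("rinse", "fill", "transfer", "tip_clean", "mix", "separate")


@dataclass(frozen=True)
class SequenceEvent:
    """One timed instrument action."""

    kind: str
    liquid: str
    duration_min: float
    pressure_psi: float = 0.0
    source_tray: str = ""
    dest_tray: str = ""
    vial: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.duration_min < 0:
            raise ValueError("event duration must be non-negative")


@dataclass(frozen=True)
class RinseProtocol:
    """Capillary conditioning around the two transfer phases.

    Durations in minutes; rinses run at ``rinse_pressure_psi``.  The tip
    clean (immersion of the capillary tip in water between vials) has no
    intrinsic duration on the instrument and defaults to 0 min.
    """

    rinse_pressure_psi: float = 20.0
    initial: tuple[tuple[str, float], ...] = (
        ("water", 1.5),
        ("methanol", 1.0),
        ("air", 1.5),
    )
    ws_fill_min: float = 2.0
    intermediate: tuple[tuple[str, float], ...] = (("water", 3.0),)
    dbge_fill_min: float = 2.0
    final: tuple[tuple[str, float], ...] = (
        ("water", 1.5),
        ("methanol", 1.5),
        ("air", 1.5),
    )
    tip_clean_min: float = 0.0
    mix_min: float = 1.0
    mix_pressure_psi: float = 30.0

    @classmethod
    def none(cls) -> "RinseProtocol":
        """Bare-bones protocol: transfers and the final mix only."""
        return cls(
            initial=(), ws_fill_min=0.0, intermediate=(), dbge_fill_min=0.0,
            final=(), tip_clean_min=0.0,
        )


@dataclass(frozen=True)
class MethodSequence:
    """Ordered event list for one preparation run."""

    mode: str
    events: tuple[SequenceEvent, ...]

    @property
    def total_duration_min(self) -> float:
        """Preparation time: all events except separation annotations."""
        return sum(e.duration_min for e in self.events if e.kind != "separate")


def _trays(mode: str) -> tuple[str, str]:
    if mode == "R":
        return "outlet", "inlet"
    if mode == "F":
        return "inlet", "outlet"
    raise ValueError(f"mode must be 'R' or 'F', got {mode!r}")


def build_sequence(
    schedules: Sequence[DilutionSchedule],
    mode: str = "R",
    protocol: RinseProtocol | None = None,
    vial_capacity_ul: float | None = None,
    geometry: CapillaryGeometry | None = None,
    fluid: Fluid | None = None,
) -> MethodSequence:
    """Expand schedules into the timed event sequence for one run.

    Event order: initial rinse/dry and WS fill; WS transfer to every vial
    (tip clean before each); water rinse and DBGE fill; DBGE transfer to
    every vial; final rinse/dry; per-vial air-bubbling mix.  Pass-through
    (undiluted) levels receive no transfers or mix.

    If ``vial_capacity_ul`` is given together with geometry and fluid, a
    warning is issued for any vial whose collected volume would exceed it.
    """
    if not schedules:
        raise ValueError("schedule list must be non-empty")
    src, dst = _trays(mode)
    proto = protocol or RinseProtocol()
    p_rinse = proto.rinse_pressure_psi
    events: list[SequenceEvent] = []

    def rinse_block(block: Iterable[tuple[str, float]]) -> None:
        for liquid, minutes in block:
            if minutes > 0:
                events.append(SequenceEvent("rinse", liquid, minutes, p_rinse))

    def fill(liquid: str, minutes: float) -> None:
        if minutes > 0:
            events.append(
                SequenceEvent("fill", liquid, minutes, p_rinse, source_tray=src)
            )

    def transfers(which: str) -> None:
        for i, sched in enumerate(schedules):
            step = sched.ws_step if which == "WS" else sched.dbge_step
            if step is None:
                continue
            if proto.tip_clean_min >= 0:
                events.append(
                    SequenceEvent("tip_clean", "water", proto.tip_clean_min)
                )
            events.append(
                SequenceEvent(
                    "transfer", which, step.duration_min, step.pressure_psi,
                    source_tray=src, dest_tray=dst, vial=f"vial-{i + 1}",
                )
            )

    rinse_block(proto.initial)
    fill("WS", proto.ws_fill_min)
    transfers("WS")
    rinse_block(proto.intermediate)
    fill("DBGE", proto.dbge_fill_min)
    transfers("DBGE")
    rinse_block(proto.final)
    for i, sched in enumerate(schedules):
        if sched.undiluted:
            continue
        events.append(
            SequenceEvent(
                "mix", "air", proto.mix_min, proto.mix_pressure_psi,
                dest_tray=dst, vial=f"vial-{i + 1}",
            )
        )

    seq = MethodSequence(mode=mode, events=tuple(events))

    if vial_capacity_ul is not None and geometry is not None and fluid is not None:
        for vial, vol in vial_volumes(seq, geometry, fluid).items():
            if vol > vial_capacity_ul:
                warnings.warn(
                    f"{vial} collects {vol:.1f} µL, above the configured "
                    f"capacity of {vial_capacity_ul:g} µL",
                    stacklevel=2,
                )
    return seq


def reagent_budget(
    seq: MethodSequence,
    geometry: CapillaryGeometry,
    fluid: Fluid,
    kinds: tuple[str, ...] = ("rinse", "fill", "transfer"),
    loaded_ul: "dict[str, float] | None" = None,
) -> dict[str, float]:
    """Dispensed volume (µL) per liquid over the pressurised events.

    Air (drying and mixing) is excluded — it is not a consumed reagent.
    ``kinds`` restricts which event kinds count (e.g. ``("transfer",)`` for
    the volume that actually reaches the collection vials).  If
    ``loaded_ul`` maps liquids to their loaded source volumes, a warning is
    issued where consumption exceeds the load.
    """
    budget: dict[str, float] = {}
    for e in seq.events:
        if e.kind not in kinds or e.liquid == "air":
            continue
        if e.pressure_psi <= 0 or e.duration_min <= 0:
            continue
        vol = volume_from_product(e.pressure_psi * e.duration_min, geometry, fluid)
        budget[e.liquid] = budget.get(e.liquid, 0.0) + vol
    if loaded_ul:
        for liquid, used in budget.items():
            loaded = loaded_ul.get(liquid)
            if loaded is not None and used > loaded:
                warnings.warn(
                    f"{liquid}: dispensing {used:.1f} µL exceeds the "
                    f"{loaded:g} µL loaded",
                    stacklevel=2,
                )
    return budget


def vial_volumes(
    seq: MethodSequence, geometry: CapillaryGeometry, fluid: Fluid
) -> dict[str, float]:
    """Collected volume (µL) per destination vial, from transfer events only."""
    out: dict[str, float] = {}
    for e in seq.events:
        if e.kind != "transfer" or not e.vial:
            continue
        vol = volume_from_product(e.pressure_psi * e.duration_min, geometry, fluid)
        out[e.vial] = out.get(e.vial, 0.0) + vol
    return out
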