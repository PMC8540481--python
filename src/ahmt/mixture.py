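"""Composition of constituted calibration solutions.

A calibration vial receives volumes of the working standard (analytes plus
internal standard) and of the diluent (internal standard only); the
resulting concentrations are volume-weighted averages.  Because both source
solutions carry the internal standard at the same level, the mixed solution
inherits it unchanged — the property that makes internal-standard
calibration work regardless of the dilution factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .physics import CapillaryGeometry, Fluid, delivered_volume
from .scheduler import DilutionSchedule

__all__ = ["Solution", "MixedVial", "mix", "schedule_to_composition"]


@dataclass(frozen=True)
class Solution:
    """A liquid with per-species concentrations (µg/mL).

    ``internal_standard`` names the species used as the internal standard,
    if any; species absent from ``concentrations`` are at zero.
    """

    name: str
    concentrations: Mapping[str, float]
    internal_standard: str | None = None

    def __post_init__(self) -> None:
        for species, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {species!r}")
        if (
            self.internal_standard is not None
            and self.internal_standard not in self.concentrations
        ):
            raise ValueError(
                f"internal standard {self.internal_standard!r} not among species"
            )

    def concentration(self, species: str) -> float:
        return float(self.concentrations.get(species, 0.0))

    @property
    def is_concentration(self) -> float:
        """Concentration of the internal standard (0 if none declared)."""
        if self.internal_standard is None:
            return 0.0
        return self.concentration(self.internal_standard)


@dataclass(frozen=True)
class MixedVial:
    """A vial holding given volumes (µL) of given solutions."""

    components: Sequence[tuple[Solution, float]]

    @property
    def total_volume(self) -> float:
        return sum(v for _, v in self.components)

    @property
    def solution(self) -> Solution:
        return mix(self.components)


def mix(components: Sequence[tuple[Solution, float]], name: str = "mix") -> Solution:
    """Volume-weighted (mass-conserving) mixture of solutions.

    ``components`` are (solution, volume µL) pairs; at least one volume must
    be positive.  The internal-standard label is propagated when the
    components agree on it.
    """
    if not components:
        raise ValueError("cannot mix zero components")
    for _, v in components:
        if v < 0:
            raise ValueError("component volumes must be non-negative")
    total = sum(v for _, v in components)
    if total <= 0:
        raise ValueError("all component volumes are zero")

    species: set[str] = set()
    for sol, _ in components:
        species.update(sol.concentrations)
    out = {
        s: sum(sol.concentration(s) * v for sol, v in components) / total
        for s in sorted(species)
    }
    is_labels = {sol.internal_standard for sol, _ in components} - {None}
    is_label = is_labels.pop() if len(is_labels) == 1 else None
    return Solution(name, out, internal_standard=is_label)


def schedule_to_composition(
    schedule: DilutionSchedule,
    geometry: CapillaryGeometry,
    fluid: Fluid,
    ws: Solution,
    dbge: Solution,
) -> Solution:
    """Composition of the vial constituted by one dilution schedule.

    Volumes come from the laminar-flow model, but the resulting
    concentrations depend only on the ratio of the two pressure·time
    products — geometry and viscosity cancel (both transfers share them).
    The pass-through schedule returns the working standard unchanged.
    """
    if schedule.undiluted:
        return ws
    name = f"cal-{schedule.target_concentration:g}"
    v_ws = delivered_volume(schedule.ws_step, geometry, fluid)
    v_dbge = delivered_volume(schedule.dbge_step, geometry, fluid)
    return mix([(ws, v_ws), (dbge, v_dbge)], name=name)
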