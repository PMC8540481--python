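"""Pressure-driven laminar flow through a fused-silica capillary.

The pressure system of a capillary-electrophoresis instrument can double as
a dispensing pump: a constant pressure applied across the capillary drives a
laminar flow, so every (pressure, time) pair corresponds to a delivered
volume via the Hagen-Poiseuille law

    Q = dP * pi * r**4 / (8 * eta * L)

where ``r`` is the inner radius, ``L`` the total capillary length and
``eta`` the dynamic viscosity of the pumped liquid.  All internal arithmetic
is SI; the public surface speaks the instrument's units — psi, minutes and
microlitres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "KPA_PER_PSI",
    "PA_PER_PSI",
    "Pressure",
    "CapillaryGeometry",
    "Fluid",
    "psi_to_kpa",
    "kpa_to_psi",
    "poiseuille_flow",
    "delivered_volume",
    "volume_from_product",
]

#: Exact conversion factor between pounds per square inch and kilopascal.
KPA_PER_PSI = 6.894757
PA_PER_PSI = KPA_PER_PSI * 1e3

M3_PER_S_TO_UL_PER_MIN = 1e9 * 60.0


def psi_to_kpa(p_psi: float) -> float:
    """Convert a pressure from psi to kPa (1 psi = 6.894757 kPa)."""
    if not math.isfinite(p_psi):
        raise ValueError(f"pressure must be finite, got {p_psi!r}")
    return p_psi * KPA_PER_PSI


def kpa_to_psi(p_kpa: float) -> float:
    """Convert a pressure from kPa to psi (inverse of :func:`psi_to_kpa`)."""
    if not math.isfinite(p_kpa):
        raise ValueError(f"pressure must be finite, got {p_kpa!r}")
    return p_kpa / KPA_PER_PSI


@dataclass(frozen=True)
class Pressure:
    """A pressure, stored canonically in psi (the instrument's unit)."""

    psi: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.psi):
            raise ValueError(f"pressure must be finite, got {self.psi!r}")

    @property
    def kpa(self) -> float:
        return psi_to_kpa(self.psi)

    @property
    def pa(self) -> float:
        return self.psi * PA_PER_PSI

    @classmethod
    def from_kpa(cls, p_kpa: float) -> "Pressure":
        return cls(kpa_to_psi(p_kpa))


@dataclass(frozen=True)
class CapillaryGeometry:
    """Dimensions of the separation capillary.

    Dispensing flow is governed by the *total* length; the effective
    (inlet-to-detector) length is carried only as detection metadata.
    Lengths in metres.
    """

    total_length: float
    effective_length: float
    inner_diameter: float

    def __post_init__(self) -> None:
        if self.inner_diameter <= 0:
            raise ValueError("inner_diameter must be positive")
        if not 0 < self.effective_length < self.total_length:
            raise ValueError(
                "effective_length must satisfy 0 < effective < total "
                f"(got {self.effective_length} vs {self.total_length})"
            )

    @property
    def inner_radius(self) -> float:
        return self.inner_diameter / 2.0

    @classmethod
    def from_cm_um(
        cls, total_length_cm: float, effective_length_cm: float, id_um: float
    ) -> "CapillaryGeometry":
        """Build from the units instrument software uses (cm and µm)."""
        return cls(total_length_cm / 100.0, effective_length_cm / 100.0, id_um / 1e6)


@dataclass(frozen=True)
class Fluid:
    """A Newtonian liquid characterised by its dynamic viscosity in Pa·s."""

    viscosity: float
    name: str = "water"

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")

    @classmethod
    def from_mpas(cls, viscosity_mpas: float, name: str = "water") -> "Fluid":
        return cls(viscosity_mpas * 1e-3, name)


def _as_pressure(dp: "Pressure | float") -> Pressure:
    return dp if isinstance(dp, Pressure) else Pressure(float(dp))


def poiseuille_flow(
    geometry: CapillaryGeometry, fluid: Fluid, dp: "Pressure | float"
) -> float:
    """Volumetric flow rate (m³/s) through the capillary at pressure ``dp``.

    ``dp`` is a :class:`Pressure` or a plain number in psi.  The flow is
    strictly linear in the applied pressure and in the inverse viscosity.
    """
    dp = _as_pressure(dp)
    if dp.psi <= 0:
        raise ValueError("transfer pressure must be positive")
    r = geometry.inner_radius
    return dp.pa * math.pi * r**4 / (8.0 * fluid.viscosity * geometry.total_length)


def delivered_volume(step, geometry: CapillaryGeometry, fluid: Fluid) -> float:
    """Volume (µL) delivered by one timed transfer.

    ``step`` is anything exposing ``pressure_psi`` and ``duration_min``
    (e.g. a scheduler ``TransferStep``).  The result depends on pressure and
    time only through their product.
    """
    if step.duration_min <= 0:
        raise ValueError("transfer duration must be positive")
    q = poiseuille_flow(geometry, fluid, step.pressure_psi)
    return q * M3_PER_S_TO_UL_PER_MIN * step.duration_min


def volume_from_product(
    product_psi_min: float, geometry: CapillaryGeometry, fluid: Fluid
) -> float:
    """Volume (µL) corresponding to a pressure·time product (psi·min).

    Convenience for budget accounting: because flow is linear in pressure,
    the delivered volume of any transfer is proportional to its
    pressure·time product.
    """
    if product_psi_min < 0:
        raise ValueError("pressure-time product must be non-negative")
    if product_psi_min == 0:
        return 0.0
    q = poiseuille_flow(geometry, fluid, 1.0)
    return q * M3_PER_S_TO_UL_PER_MIN * product_psi_min
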