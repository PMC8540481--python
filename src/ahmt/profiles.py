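"""Reference instrument profiles and method defaults.

Constants of the validated reference method on a PA800 Plus-class CE
system: a 30.5 cm (20.5 cm to detector) × 50 µm i.d. bare fused-silica
capillary, aqueous solutions at ambient tray temperature, a 100 µg/mL
working standard of procaine/prilocaine/bupivacaine with procaine as the
internal standard at 100 µg/mL in both source solutions, and the two vial
formats:

* PCR vials — transfers between 2.5 and 30 psi in 0.5 psi steps; the
  2-fold reference level runs 10 min at 20 psi per solution (budget
  400 psi·min, ≈ 93 µL per vial).
* nanoVials — transfers from 0.5 psi in 0.1 psi steps, up to the 3.8 psi
  maximum the method uses; reference 10 min at 2 psi per solution (budget
  40 psi·min, ≈ 9 µL per vial).
"""

from __future__ import annotations

from .mixture import Solution
from .physics import CapillaryGeometry, Fluid
from .scheduler import InstrumentConstraints, reference_budget
from .simulate import AnalyteModel, NoiseModel

__all__ = [
    "REFERENCE_GEOMETRY",
    "WATER",
    "PCR_CONSTRAINTS",
    "NANOVIAL_CONSTRAINTS",
    "PCR_BUDGET",
    "NANOVIAL_BUDGET",
    "PCR_VIAL_CAPACITY_UL",
    "NANOVIAL_CAPACITY_UL",
    "CALIBRATION_TARGETS",
    "STOCK_CONCENTRATION",
    "IS_LABEL",
    "working_solution",
    "diluent",
    "DEFAULT_ANALYTES",
    "DEFAULT_NOISE",
    "constraints_for_vial",
    "budget_for_vial",
]

#: 30.5 cm total / 20.5 cm effective length, 50 µm inner diameter.
REFERENCE_GEOMETRY = CapillaryGeometry.from_cm_um(30.5, 20.5, 50.0)

#: Water at ~25 °C (ambient sample tray); viscosity 0.89 mPa·s.
WATER = Fluid.from_mpas(0.89, "water")

PCR_CONSTRAINTS = InstrumentConstraints(
    p_min=2.5, p_max=30.0, p_quantum=0.5, t_default=10.0, t_max=15.0, t_quantum=1.0
)
#: nanoVial p_max is the maximum the method uses, not an instrument limit.
NANOVIAL_CONSTRAINTS = InstrumentConstraints(
    p_min=0.5, p_max=3.8, p_quantum=0.1, t_default=10.0, t_max=15.0, t_quantum=1.0
)

PCR_BUDGET = reference_budget(10.0, 20.0)  # 400 psi·min
NANOVIAL_BUDGET = reference_budget(10.0, 2.0)  # 40 psi·min

PCR_VIAL_CAPACITY_UL = 200.0
NANOVIAL_CAPACITY_UL = 50.0

#: Diluted calibration levels (µg/mL); the undiluted 100 µg/mL working
#: standard is additionally used as the top calibrator.
CALIBRATION_TARGETS = (6.25, 12.5, 25.0, 37.5, 50.0, 75.0)
STOCK_CONCENTRATION = 100.0
IS_LABEL = "procaine"


def working_solution(stock: float = STOCK_CONCENTRATION) -> Solution:
    """Working standard: both analytes and the IS at the stock level."""
    return Solution(
        "WS",
        {"prilocaine": stock, "bupivacaine": stock, IS_LABEL: stock},
        internal_standard=IS_LABEL,
    )


def diluent(is_concentration: float = STOCK_CONCENTRATION) -> Solution:
    """Diluted background electrolyte spiked with the IS only."""
    return Solution("DBGE", {IS_LABEL: is_concentration}, internal_standard=IS_LABEL)


#: Synthetic-detector fixture: migration times and response factors chosen
#: to give baseline-resolved peaks of realistic magnitude on a short
#: capillary.  They are properties of the generator, not of any instrument.
DEFAULT_ANALYTES = (
    AnalyteModel(IS_LABEL, migration_time_min=1.6, response_factor=1.0e-4),
    AnalyteModel("prilocaine", migration_time_min=2.1, response_factor=2.3e-4),
    AnalyteModel("bupivacaine", migration_time_min=2.6, response_factor=1.2e-4),
)

#: 2% area CV (below the method's <3% repeatability requirement), 1%
#: shared migration drift, 0.5 mAU baseline noise.
DEFAULT_NOISE = NoiseModel(area_cv=0.02, migration_drift_cv=0.01, baseline_sd=5e-4)


def constraints_for_vial(vial: str) -> InstrumentConstraints:
    try:
        return {"pcr": PCR_CONSTRAINTS, "nano": NANOVIAL_CONSTRAINTS}[vial]
    except KeyError:
        raise ValueError(f"unknown vial type {vial!r} (expected 'pcr' or 'nano')")


def budget_for_vial(vial: str) -> float:
    try:
        return {"pcr": PCR_BUDGET, "nano": NANOVIAL_BUDGET}[vial]
    except KeyError:
        raise ValueError(f"unknown vial type {vial!r} (expected 'pcr' or 'nano')")
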