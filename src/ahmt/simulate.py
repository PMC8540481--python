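"""Synthetic electropherograms with known ground truth.

The detector trace of a CE run is emulated as a sum of Gaussian peaks on a
noisy baseline.  Peak *area* is modelled as

    area = response_factor * concentration * migration_time

— proportional to residence time in the detector window, which is exactly
why time-corrected peak areas (area / migration time) are used downstream:
the correction removes the velocity dependence.  Runs share a single
migration-drift factor across all peaks (the whole separation speeds up or
slows down together), so the analyte/IS TCPA ratio cancels the drift.

Nothing here reproduces real separation physics (electroosmotic flow,
electromigration dispersion, stacking); the generator exists to give the
calibration statistics inputs with exactly known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .mixture import Solution

__all__ = [
    "AnalyteModel",
    "NoiseModel",
    "Electropherogram",
    "simulate_run",
    "simulate_series",
]


@dataclass(frozen=True)
class AnalyteModel:
    """Detector response model for one species.

    ``response_factor`` is in AU·mL/µg: true peak area (AU·min) equals
    response_factor × concentration (µg/mL) × migration time (min).
    """

    name: str
    migration_time_min: float
    response_factor: float
    peak_width_sigma_min: float = 0.02

    def __post_init__(self) -> None:
        if self.migration_time_min <= 0:
            raise ValueError("migration time must be positive")
        if self.response_factor <= 0:
            raise ValueError("response factor must be positive")
        if self.peak_width_sigma_min <= 0:
            raise ValueError("peak width must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic imperfections of a run.

    * ``area_cv`` — multiplicative (log-normal, mean-1) noise on each peak
      area; independent between peaks and runs.
    * ``migration_drift_cv`` — relative scatter of a per-run velocity factor
      shared by all peaks of the run.
    * ``baseline_sd`` — additive white detector noise (AU).
    """

    area_cv: float = 0.02
    migration_drift_cv: float = 0.01
    baseline_sd: float = 5e-4
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.area_cv, self.migration_drift_cv, self.baseline_sd) < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class Electropherogram:
    """A uniformly sampled detector trace with its generating metadata."""

    time_min: np.ndarray
    absorbance: np.ndarray
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.time_min, "absorbance_au": self.absorbance})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, metadata: dict | None = None) -> "Electropherogram":
        df = pd.read_csv(path)
        return cls(
            df["time_min"].to_numpy(), df["absorbance_au"].to_numpy(),
            metadata or {},
        )


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative mean-1 log-normal noise with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size) if size else 1.0
    s = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * s**2, s, size=size))


def simulate_run(
    composition: Solution,
    analytes: Sequence[AnalyteModel],
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
    sampling_hz: float = 10.0,
    duration_min: float | None = None,
) -> Electropherogram:
    """Generate one detector trace for a solution of known composition.

    The per-run drift factor scales every migration time; true areas use
    the *drifted* migration time, so area/time ratios stay drift-free.
    Metadata records the drift, per-analyte true areas and drifted
    migration times — the generator's ground-truth manifest.
    """
    if not analytes:
        raise ValueError("analyte list must be non-empty")
    rng = rng if rng is not None else np.random.default_rng(noise.seed)

    drift = rng.normal(0.0, noise.migration_drift_cv) if noise.migration_drift_cv else 0.0
    velocity_factor = 1.0 + drift

    if duration_min is None:
        duration_min = 1.3 * max(a.migration_time_min for a in analytes)
    n = int(round(duration_min * 60.0 * sampling_hz)) + 1
    t = np.linspace(0.0, duration_min, n)

    trace = np.zeros(n)
    true_areas: dict[str, float] = {}
    centers: dict[str, float] = {}
    for a in analytes:
        conc = composition.concentration(a.name)
        center = a.migration_time_min * velocity_factor
        area = a.response_factor * conc * center * _lognormal_factor(rng, noise.area_cv)
        true_areas[a.name] = float(area)
        centers[a.name] = float(center)
        if area > 0:
            sig = a.peak_width_sigma_min
            trace += area / (sig * np.sqrt(2.0 * np.pi)) * np.exp(
                -0.5 * ((t - center) / sig) ** 2
            )
    if noise.baseline_sd > 0:
        trace += rng.normal(0.0, noise.baseline_sd, size=n)

    return Electropherogram(
        t,
        trace,
        metadata={
            "concentrations": dict(composition.concentrations),
            "internal_standard": composition.internal_standard,
            "drift": float(drift),
            "true_areas": true_areas,
            "migration_times": centers,
        },
    )


def simulate_series(
    compositions: Sequence[Solution],
    analytes: Sequence[AnalyteModel],
    noise: NoiseModel,
    replicates: int = 3,
    seed: int | None = None,
    sampling_hz: float = 10.0,
) -> list[Electropherogram]:
    """Replicate runs for every calibration level, seed-reproducible.

    Returns ``len(compositions) * replicates`` traces in level-major order;
    each trace's metadata carries its level index and replicate number.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed if seed is not None else noise.seed)
    traces = []
    for level, comp in enumerate(compositions):
        for rep in range(replicates):
            run = simulate_run(comp, analytes, noise, rng=rng, sampling_hz=sampling_hz)
            run.metadata.update(level=level, replicate=rep)
            traces.append(run)
    return traces
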