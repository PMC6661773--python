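"""Synthetic data generation for the whole pipeline.

The original study's raw data (chromatograms, run tables, subject plasma
concentrations) are not deposited anywhere, so every downstream stage is
exercised against simulated inputs with known ground truth:

* subject concentration-time profiles from a one-compartment oral
  absorption model (first-order absorption and elimination, optional lag),
* calibration/QC run tables whose analyte/IS response ratios sit on a known
  straight line perturbed by a proportional + additive Gaussian error model
  and per-plasma-lot factors,
* MRM chromatograms built as Gaussian peaks on a flat baseline with white
  noise, on a 0-5 min axis at a 0.6 s sampling interval.

Presets named ``MET_LIKE`` and ``CFZ_LIKE`` place the noise-free kinetics
in the neighbourhood of the published single-dose study (850 mg metformin
/ 50 mg canagliflozin); they are simulator presets, not claims about the
original volunteers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chromatography import (
    RUN_TIME_MIN,
    Chromatogram,
    MRMTransition,
)
from .nca import PKProfile

__all__ = [
    "PKModelParams",
    "AssayErrorModel",
    "SamplingSchedule",
    "RunDesign",
    "simulate_profile",
    "simulate_run",
    "simulate_chromatogram",
    "simulate_qc_battery",
    "MET_LIKE",
    "CFZ_LIKE",
    "MET_ERROR",
    "CFZ_ERROR",
    "STUDY_SCHEDULE",
    "CHROMATOGRAM_POINTS",
]

#: 0.6 s sampling interval -> 501 samples across the 5 min run
CHROMATOGRAM_POINTS = 501


@dataclass(frozen=True)
class PKModelParams:
    """One-compartment oral absorption model parameters.

    Concentration for t > tlag:

        C(t) = F * D * ka / (V_F * (ka - ke))
               * (exp(-ke (t - tlag)) - exp(-ka (t - tlag)))

    with dose ``D`` in ng, apparent volume ``V_F`` (= V/F) in mL, so C is
    in ng/mL.  ``ka`` must differ from ``ke`` (the closed form above is
    degenerate at ka == ke).
    """

    dose: float  # ng
    volume_over_f: float  # mL (apparent volume of distribution, V/F)
    ka: float  # 1/h
    ke: float  # 1/h
    bioavailability: float = 1.0
    tlag: float = 0.0  # h

    def __post_init__(self) -> None:
        if self.dose <= 0 or self.volume_over_f <= 0:
            raise ValueError("dose and volume_over_f must be positive")
        if self.ka <= 0 or self.ke <= 0:
            raise ValueError("ka and ke must be positive")
        if self.ka == self.ke:
            raise ValueError("ka == ke makes the closed form degenerate")
        if not (0 <= self.bioavailability <= 1):
            raise ValueError("bioavailability must lie in [0, 1]")
        if self.tlag < 0:
            raise ValueError("tlag must be non-negative")

    def concentration(self, times) -> np.ndarray:
        """Noise-free concentration (ng/mL) at the given times (h)."""
        t = np.asarray(times, dtype=float)
        shifted = t - self.tlag
        pref = (self.bioavailability * self.dose * self.ka
                / (self.volume_over_f * (self.ka - self.ke)))
        c = pref * (np.exp(-self.ke * shifted) - np.exp(-self.ka * shifted))
        return np.where(shifted > 0, c, 0.0)

    @property
    def tmax(self) -> float:
        """Analytic time of maximum concentration."""
        return self.tlag + math.log(self.ka / self.ke) / (self.ka - self.ke)

    @property
    def auc_inf(self) -> float:
        """Analytic AUC0-inf = F*D / (V_F * ke), in ng*h/mL."""
        return self.bioavailability * self.dose / (self.volume_over_f * self.ke)


@dataclass(frozen=True)
class AssayErrorModel:
    """Measurement error: c -> c*(1 + N(0, cv)) + N(0, additive_sd), >= 0.

    ``lloq`` marks the assay's lower limit of quantification; generated
    values below it are flagged BLQ but retained, so downstream BLQ
    policies stay testable.
    """

    proportional_cv: float = 0.05
    additive_sd: float = 0.0  # ng/mL
    lloq: float = 1.0  # ng/mL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.proportional_cv < 0 or self.additive_sd < 0:
            raise ValueError("error magnitudes must be non-negative")
        if self.lloq <= 0:
            raise ValueError("lloq must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def perturb(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        noisy = v * (1.0 + rng.normal(0.0, self.proportional_cv, v.shape))
        if self.additive_sd > 0:
            noisy = noisy + rng.normal(0.0, self.additive_sd, v.shape)
        elif self.proportional_cv == 0:
            noisy = v.copy()
        return np.maximum(noisy, 0.0)


@dataclass(frozen=True)
class SamplingSchedule:
    """Blood sampling times in hours, strictly increasing from zero."""

    times: tuple[float, ...]

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.times)
        object.__setattr__(self, "times", t)
        if len(t) == 0:
            raise ValueError("schedule must be non-empty")
        if t[0] < 0 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("times must be non-negative and strictly increasing")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)


#: the published single-dose sampling schedule (hours)
STUDY_SCHEDULE = SamplingSchedule(
    (0, 0.5, 1, 1.5, 2, 3, 4, 6, 7, 8, 10, 12, 16, 24, 48, 72)
)

# Presets: kinetics in the neighbourhood of the published study means
# (MET t1/2 6.03 h, tmax ~3.5 h, AUC0-inf ~12576 ng*h/mL after 850 mg;
#  CFZ t1/2 8.19 h, tmax ~4 h, AUC0-inf ~3963 ng*h/mL after 50 mg).
MET_LIKE = PKModelParams(dose=850e6, volume_over_f=5.88e5,
                         ka=0.57, ke=math.log(2) / 6.03)
CFZ_LIKE = PKModelParams(dose=50e6, volume_over_f=1.49e5,
                         ka=0.55, ke=math.log(2) / 8.19)
MET_ERROR = AssayErrorModel(proportional_cv=0.05, additive_sd=0.0, lloq=50.0)
CFZ_ERROR = AssayErrorModel(proportional_cv=0.05, additive_sd=0.0, lloq=10.0)


def simulate_profile(
    params: PKModelParams,
    schedule: SamplingSchedule,
    error: AssayErrorModel,
    subject_id: str = "S1",
    analyte: str = "MET",
    rng: np.random.Generator | None = None,
) -> PKProfile:
    """Sample one subject's profile at the schedule and apply assay error.

    With ``rng`` omitted a generator is seeded from ``error.seed``, so
    identical inputs reproduce bit-identical profiles.
    """
    if rng is None:
        rng = error.rng()
    t = schedule.as_array()
    clean = params.concentration(t)
    measured = error.perturb(clean, rng)
    return PKProfile(
        subject_id=subject_id,
        analyte=analyte,
        times=t,
        concentrations=measured,
        blq=measured < error.lloq,
    )


@dataclass(frozen=True)
class RunDesign:
    """Design of one analytical run: which levels, how many replicates.

    ``levels`` maps analyte -> nominal concentrations (ng/mL).  The true
    response-ratio line ``true_slope * X + true_intercept`` may be given per
    analyte (mapping) or shared (scalar).  ``lot_effects`` multiplies the
    true ratio per plasma lot; replicates cycle through the lots.
    """

    levels: Mapping[str, Sequence[float]]
    replicates: int = 1
    true_slope: Mapping[str, float] | float = 1.0
    true_intercept: Mapping[str, float] | float = 0.0
    lot_effects: Mapping[str, float] = field(default_factory=lambda: {"lot1": 1.0})
    role: str = "standard"
    is_area: float = 5.0e4  # counts, nominal internal-standard response

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for analyte, concs in self.levels.items():
            if any(c <= 0 for c in concs):
                raise ValueError(f"non-positive nominal level for {analyte}")
        if not self.lot_effects:
            raise ValueError("at least one plasma lot required")

    def line(self, analyte: str) -> tuple[float, float]:
        slope = (self.true_slope[analyte]
                 if isinstance(self.true_slope, Mapping) else self.true_slope)
        intercept = (self.true_intercept[analyte]
                     if isinstance(self.true_intercept, Mapping)
                     else self.true_intercept)
        return float(slope), float(intercept)


def simulate_run(
    design: RunDesign,
    error: AssayErrorModel,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate peak-area measurements for a calibration/QC run.

    Returns the run-data table with columns ``sample_id, analyte, role,
    nominal_ng_ml, analyte_area, is_area, lot``.  The response ratio at
    nominal X is ``slope*X + intercept`` times the lot factor, perturbed by
    the error model (additive noise acts on the concentration scale and is
    mapped through the slope); the IS area is held at its nominal value so
    the ratio carries all the noise.
    """
    if rng is None:
        rng = error.rng()
    lots = list(design.lot_effects)
    rows = []
    counter = 0
    for analyte in design.levels:
        slope, intercept = design.line(analyte)
        for nominal in design.levels[analyte]:
            for rep in range(design.replicates):
                lot = lots[counter % len(lots)]
                ratio = (slope * nominal + intercept) * design.lot_effects[lot]
                noisy = ratio * (1.0 + rng.normal(0.0, error.proportional_cv))
                if error.additive_sd > 0:
                    noisy += rng.normal(0.0, error.additive_sd * abs(slope))
                counter += 1
                rows.append(
                    {
                        "sample_id": f"{analyte}_{design.role}_{nominal:g}_{rep + 1}",
                        "analyte": analyte,
                        "role": design.role,
                        "nominal_ng_ml": float(nominal),
                        "analyte_area": noisy * design.is_area,
                        "is_area": design.is_area,
                        "lot": lot,
                    }
                )
    return pd.DataFrame(rows)


def simulate_chromatogram(
    transitions: Sequence[MRMTransition],
    concentrations: Mapping[str, float],
    noise_sd: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    response_factor: float | Mapping[str, float] = 1.0,
    peak_sigma_min: float = 0.05,
    baseline: float = 0.0,
    n_points: int = CHROMATOGRAM_POINTS,
) -> list[Chromatogram]:
    """Gaussian peaks on a flat baseline plus white noise, one per transition.

    The peak for each transition is centred at its retention time with
    amplitude ``response_factor * concentration`` (counts); the time axis
    spans the full 5 min run.
    """
    for analyte, conc in concentrations.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {analyte}")
    if rng is None:
        rng = np.random.default_rng(seed)
    t = np.linspace(0.0, RUN_TIME_MIN, n_points)
    out = []
    for tr in transitions:
        conc = float(concentrations.get(tr.analyte, 0.0))
        rf = (response_factor[tr.analyte]
              if isinstance(response_factor, Mapping) else response_factor)
        amplitude = rf * conc
        y = baseline + amplitude * np.exp(
            -0.5 * ((t - tr.retention_time) / peak_sigma_min) ** 2
        )
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, t.shape)
        out.append(Chromatogram(transition=tr, times=t, intensities=y))
    return out


def simulate_qc_battery(
    levels: Mapping[str, float],
    replicates: int = 6,
    days: int = 3,
    bias: float = 0.0,
    error: AssayErrorModel | None = None,
    analyte: str = "MET",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Back-calculated QC concentrations for an accuracy/precision battery.

    ``levels`` maps QC-level name (LLOQ/LQC/MQC/HQC) to its nominal
    concentration; each level gets ``replicates`` measurements on each of
    ``days`` days.  ``bias`` is a relative systematic error (+0.05 = +5%).
    Columns: ``analyte, level, nominal_ng_ml, day, conc_found_ng_ml, blq``.
    """
    if error is None:
        error = AssayErrorModel()
    if rng is None:
        rng = error.rng()
    rows = []
    for level, nominal in levels.items():
        if nominal <= 0:
            raise ValueError(f"non-positive nominal for level {level}")
        for day in range(1, days + 1):
            truth = np.full(replicates, nominal * (1.0 + bias))
            found = error.perturb(truth, rng)
            for val in found:
                rows.append(
                    {
                        "analyte": analyte,
                        "level": level,
                        "nominal_ng_ml": float(nominal),
                        "day": day,
                        "conc_found_ng_ml": float(val),
                        "blq": int(val < error.lloq),
                    }
                )
    return pd.DataFrame(rows)
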