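"""Bioanalytical method-validation statistics.

The FDA-style validation battery for a plasma LC-MS/MS assay: intra- and
inter-day accuracy and precision at four QC levels, extraction recovery,
matrix effect across plasma lots, dilution integrity, a five-condition
stability battery, and blank-plasma selectivity.  Every statistic reduces
to two quantities —

* accuracy% = 100 * mean found / nominal,
* RSD%      = 100 * sample SD (n-1) / mean,

judged against the +/-15% acceptance band (+/-20% at the LLOQ).
Percentages are reported rounded half-away-from-zero to two decimals,
matching the usual validation-table formatting; pass ``ndigits=None``
for full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AcceptanceRules",
    "QCLevel",
    "QCBatteryResult",
    "StabilityResult",
    "round_half_away",
    "accuracy_percent",
    "rsd_percent",
    "qc_battery",
    "recovery_percent",
    "mean_recovery",
    "matrix_factor",
    "dilution_integrity",
    "stability_battery",
    "selectivity_check",
    "MET_QC_LEVELS",
    "CFZ_QC_LEVELS",
    "STABILITY_CONDITIONS",
]

#: the five stability experiments performed in a standard validation
STABILITY_CONDITIONS = (
    "short_term",
    "freeze_thaw",
    "long_term",
    "processed",
    "dry_extract",
)

#: QC level presets (ng/mL) for the two analytes of the assay
MET_QC_LEVELS = {"LLOQ": 50.0, "LQC": 150.0, "MQC": 1000.0, "HQC": 4000.0}
CFZ_QC_LEVELS = {"LLOQ": 10.0, "LQC": 30.0, "MQC": 200.0, "HQC": 800.0}


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (1.005 -> 1.01, -1.005 -> -1.01)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _maybe_round(x: float, ndigits: int | None) -> float:
    return x if ndigits is None else round_half_away(x, ndigits)


@dataclass(frozen=True)
class AcceptanceRules:
    """Acceptance bands, percent half-widths; LLOQ gets the relaxed band."""

    acc_limit: float = 15.0
    rsd_limit: float = 15.0
    lloq_acc_limit: float = 20.0
    lloq_rsd_limit: float = 20.0
    lloq_level: str = "LLOQ"

    def limits_for(self, level: str) -> tuple[float, float]:
        if level == self.lloq_level:
            return self.lloq_acc_limit, self.lloq_rsd_limit
        return self.acc_limit, self.rsd_limit

    def passes(self, level: str, accuracy_pct: float, rsd_pct: float) -> bool:
        acc_lim, rsd_lim = self.limits_for(level)
        return abs(accuracy_pct - 100.0) <= acc_lim and rsd_pct <= rsd_lim


@dataclass(frozen=True)
class QCLevel:
    name: str  # LLOQ | LQC | MQC | HQC
    nominal: float  # ng/mL
    analyte: str = ""

    def __post_init__(self) -> None:
        if self.nominal <= 0:
            raise ValueError("nominal must be positive")


@dataclass(frozen=True)
class QCBatteryResult:
    level: QCLevel
    n: int
    mean_found: float
    accuracy_pct: float
    rsd_pct: float
    passed: bool
    scope: str = "intra_day"  # intra_day | inter_day


@dataclass(frozen=True)
class StabilityResult:
    condition: str
    level: QCLevel
    n: int
    mean_found: float
    accuracy_pct: float
    rsd_pct: float
    passed: bool
    vs_fresh_pct: float | None = None


def accuracy_percent(
    mean_found: float, nominal: float, ndigits: int | None = 2
) -> float:
    """100 * mean found / nominal."""
    if nominal <= 0:
        raise ValueError("nominal must be positive")
    return _maybe_round(100.0 * mean_found / nominal, ndigits)


def rsd_percent(values: Sequence[float], ndigits: int | None = 2) -> float:
    """Relative standard deviation: 100 * sample SD (n-1) / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("RSD needs at least two values")
    mean = float(np.mean(v))
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return _maybe_round(100.0 * float(np.std(v, ddof=1)) / mean, ndigits)


def qc_battery(
    measurements: pd.DataFrame,
    rules: AcceptanceRules | None = None,
    levels: Mapping[str, float] | None = None,
    analyte: str = "",
    intra_day: int | None = None,
) -> tuple[list[QCBatteryResult], list[QCBatteryResult], list[str]]:
    """Intra-day and inter-day accuracy/precision at each QC level.

    ``measurements`` uses the battery schema (``level, nominal_ng_ml, day,
    conc_found_ng_ml``).  Intra-day statistics use one day's replicates
    (``intra_day``, default the earliest day); inter-day statistics pool
    every day's replicates (n = replicates x days).  Returns
    ``(intra_results, inter_results, notes)`` where ``notes`` lists levels
    requested via ``levels`` but absent from the data (reported, not fatal).
    """
    rules = rules or AcceptanceRules()
    notes: list[str] = []
    if levels:
        for name in levels:
            if name not in set(measurements["level"]):
                notes.append(f"level {name} missing from measurements")
    intra: list[QCBatteryResult] = []
    inter: list[QCBatteryResult] = []
    for level_name, grp in measurements.groupby("level", sort=False):
        nominal = float(grp["nominal_ng_ml"].iloc[0])
        qc = QCLevel(str(level_name), nominal, analyte)
        day0 = intra_day if intra_day is not None else int(grp["day"].min())
        for scope, sub in (("intra_day", grp[grp["day"] == day0]), ("inter_day", grp)):
            vals = sub["conc_found_ng_ml"].to_numpy(dtype=float)
            if vals.size < 2:
                notes.append(f"{scope} at {level_name}: fewer than two replicates")
                continue
            mean_found = float(np.mean(vals))
            acc = accuracy_percent(mean_found, nominal)
            rsd = rsd_percent(vals)
            res = QCBatteryResult(
                level=qc,
                n=vals.size,
                mean_found=mean_found,
                accuracy_pct=acc,
                rsd_pct=rsd,
                passed=rules.passes(qc.name, acc, rsd),
                scope=scope,
            )
            (intra if scope == "intra_day" else inter).append(res)
    return intra, inter, notes


def recovery_percent(
    extracted_areas: Sequence[float],
    post_extraction_areas: Sequence[float],
    ndigits: int | None = 2,
) -> tuple[float, float]:
    """Extraction recovery at one level: (recovery%, RSD%).

    Recovery compares analyte spiked *before* the full extraction against
    analyte spiked into already-extracted (post-extraction) matrix:
    100 * mean(extracted) / mean(post-extraction).  The RSD is that of the
    per-replicate extracted responses.
    """
    ext = np.asarray(extracted_areas, dtype=float)
    post = np.asarray(post_extraction_areas, dtype=float)
    if ext.size == 0 or post.size == 0:
        raise ValueError("both area lists must be non-empty")
    post_mean = float(np.mean(post))
    if post_mean == 0:
        raise ValueError("zero post-extraction mean response")
    rec = 100.0 * float(np.mean(ext)) / post_mean
    rsd = rsd_percent(ext, ndigits=None) if ext.size > 1 else 0.0
    return _maybe_round(rec, ndigits), _maybe_round(rsd, ndigits)


def mean_recovery(per_level_recoveries: Sequence[float],
                  ndigits: int | None = 2) -> float:
    """Across-level mean of per-level recovery percentages."""
    v = np.asarray(per_level_recoveries, dtype=float)
    if v.size == 0:
        raise ValueError("no recoveries given")
    return _maybe_round(float(np.mean(v)), ndigits)


@dataclass(frozen=True)
class MatrixEffectResult:
    mf_per_lot: dict[str, float]
    rsd_pct: float
    passed: bool


def matrix_factor(
    post_extraction_spiked_areas: Mapping[str, float],
    neat_solution_area: float,
    rsd_limit: float = 15.0,
) -> MatrixEffectResult:
    """Matrix factor per plasma lot and the across-lot RSD.

    MF(lot) = area in post-extraction-spiked matrix / area in neat
    solution; ionisation suppression gives MF < 1, enhancement > 1.  The
    assay passes when the across-lot RSD of the MFs is <= 15%.
    """
    if len(post_extraction_spiked_areas) < 2:
        raise ValueError("matrix effect needs at least two plasma lots")
    if neat_solution_area == 0:
        raise ValueError("zero neat-solution response")
    mfs = {
        lot: float(area) / float(neat_solution_area)
        for lot, area in post_extraction_spiked_areas.items()
    }
    rsd = rsd_percent(list(mfs.values()))
    return MatrixEffectResult(mf_per_lot=mfs, rsd_pct=rsd, passed=rsd <= rsd_limit)


@dataclass(frozen=True)
class DilutionResult:
    dilution_factor: int
    mean_reported: float  # ng/mL, after multiplying by the dilution factor
    accuracy_pct: float
    rsd_pct: float
    passed: bool


def dilution_integrity(
    measured_conc: Sequence[float] | float,
    dilution_factor: int,
    nominal_undiluted: float,
    limit_pct: float = 15.0,
) -> DilutionResult:
    """Accuracy of an above-range sample after dilution with blank matrix.

    Each measured (diluted) concentration is multiplied back by the
    dilution factor and compared with the undiluted nominal; pass requires
    accuracy within +/-15% and RSD <= 15%.
    """
    if dilution_factor < 2:
        raise ValueError("dilution factor must be >= 2")
    if nominal_undiluted <= 0:
        raise ValueError("nominal must be positive")
    measured = np.atleast_1d(np.asarray(measured_conc, dtype=float))
    reported = measured * dilution_factor
    mean_rep = float(np.mean(reported))
    acc = accuracy_percent(mean_rep, nominal_undiluted)
    rsd = rsd_percent(reported) if reported.size > 1 else 0.0
    return DilutionResult(
        dilution_factor=dilution_factor,
        mean_reported=mean_rep,
        accuracy_pct=acc,
        rsd_pct=rsd,
        passed=abs(acc - 100.0) <= limit_pct and rsd <= limit_pct,
    )


def stability_battery(
    measurements: pd.DataFrame,
    fresh_reference: Mapping[str, float] | None = None,
    rules: AcceptanceRules | None = None,
    analyte: str = "",
) -> list[StabilityResult]:
    """Stability statistics per (condition, level).

    ``measurements`` columns: ``condition, level, nominal_ng_ml,
    conc_found_ng_ml``.  The primary metric is accuracy against nominal (as
    validation tables report it); when ``fresh_reference`` maps level ->
    freshly-prepared mean, the stressed/fresh ratio is also reported.
    Stability levels (LQC/HQC) all use the +/-15% band.
    """
    rules = rules or AcceptanceRules()
    known = set(STABILITY_CONDITIONS)
    results: list[StabilityResult] = []
    for (condition, level_name), grp in measurements.groupby(
        ["condition", "level"], sort=False
    ):
        if condition not in known:
            raise ValueError(f"unknown stability condition {condition!r}")
        nominal = float(grp["nominal_ng_ml"].iloc[0])
        vals = grp["conc_found_ng_ml"].to_numpy(dtype=float)
        if vals.size < 2:
            raise ValueError(
                f"stability {condition}/{level_name}: need >= 2 replicates"
            )
        mean_found = float(np.mean(vals))
        acc = accuracy_percent(mean_found, nominal)
        rsd = rsd_percent(vals)
        vs_fresh = None
        if fresh_reference and level_name in fresh_reference:
            vs_fresh = round_half_away(
                100.0 * mean_found / float(fresh_reference[level_name])
            )
        results.append(
            StabilityResult(
                condition=str(condition),
                level=QCLevel(str(level_name), nominal, analyte),
                n=vals.size,
                mean_found=mean_found,
                accuracy_pct=acc,
                rsd_pct=rsd,
                passed=rules.passes(str(level_name), acc, rsd),
                vs_fresh_pct=vs_fresh,
            )
        )
    return results


@dataclass(frozen=True)
class SelectivityResult:
    interference_pct: dict[str, float]  # per lot
    passed: bool
    threshold_pct: float


def selectivity_check(
    blank_areas: Mapping[str, float],
    lloq_areas: Sequence[float],
    is_internal_standard: bool = False,
) -> SelectivityResult:
    """Blank-plasma interference at the analyte's retention window.

    interference% = 100 * blank response / mean LLOQ response, per plasma
    lot.  Thresholds follow the usual regulatory convention: <= 20% of the
    LLOQ response for analytes, <= 5% for internal standards.
    """
    lloq = np.asarray(lloq_areas, dtype=float)
    if lloq.size == 0 or float(np.mean(lloq)) <= 0:
        raise ValueError("LLOQ responses must be positive")
    if not blank_areas:
        raise ValueError("at least one blank lot required")
    mean_lloq = float(np.mean(lloq))
    threshold = 5.0 if is_internal_standard else 20.0
    interference = {
        lot: round_half_away(100.0 * float(area) / mean_lloq)
        for lot, area in blank_areas.items()
    }
    passed = all(v <= threshold for v in interference.values())
    return SelectivityResult(
        interference_pct=interference, passed=passed, threshold_pct=threshold
    )
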