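"""Calibration-curve fitting and back-calculation.

Quantitation rests on a straight line relating the analyte/IS peak-area
ratio Y to the nominal concentration X (ng/mL): Y = slope*X + intercept.
Blanks and zero samples are excluded from the regression; the fit may be
unweighted or weighted 1/x or 1/x^2 (common bioanalytical practice when
the range spans two orders of magnitude).  Back-calculation inverts the
line, X = (Y - intercept)/slope, and each standard's back-calculated
accuracy is judged against +/-15% of nominal (+/-20% at the LLOQ).

The module follows the Model/Results convention:

>>> res = CalibrationModel(standards, weighting="none").fit()
>>> res.curve.slope, res.curve.r
>>> res.back_calculate(0.0712).conc
>>> res.assess().curve_passed
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CalibrationStandard",
    "CalibrationCurve",
    "CalibrationModel",
    "CalibrationResults",
    "BackCalcResult",
    "CurveAssessment",
    "fit_calibration",
    "back_calculate",
    "assess_curve",
    "standards_from_run",
]

Weighting = Literal["none", "1/x", "1/x2"]

#: back-calculated accuracy acceptance half-widths (percent of nominal)
ACC_LIMIT_PCT = 15.0
ACC_LIMIT_LLOQ_PCT = 20.0
#: minimum fraction of standards that must pass for the curve to pass
CURVE_PASS_FRACTION = 0.75


@dataclass(frozen=True)
class CalibrationStandard:
    """One calibration sample: a spiked standard, a blank, or a zero."""

    nominal: float | None  # ng/mL; None for blanks/zeros
    response_ratio: float  # analyte area / IS area
    role: str = "standard"  # standard | blank | zero

    def __post_init__(self) -> None:
        if self.role == "standard":
            if self.nominal is None or self.nominal <= 0:
                raise ValueError("standards need a positive nominal concentration")
        elif self.role not in ("blank", "zero"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted response-ratio line with its validated range."""

    analyte: str
    slope: float  # ratio per (ng/mL)
    intercept: float  # ratio
    r: float  # (weighted) Pearson correlation
    weighting: Weighting
    range_low: float  # ng/mL
    range_high: float  # ng/mL

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("slope must be non-zero")
        if not self.range_low < self.range_high:
            raise ValueError("range_low must be below range_high")
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError("correlation outside [-1, 1]")

    def predict(self, nominal) -> np.ndarray:
        return self.slope * np.asarray(nominal, dtype=float) + self.intercept


@dataclass(frozen=True)
class BackCalcResult:
    conc: float  # ng/mL
    in_range: bool
    blq: bool  # negative back-calculated value


@dataclass(frozen=True)
class CurveAssessment:
    """Per-standard accuracy table and the overall curve decision."""

    table: pd.DataFrame  # nominal, back_calc, accuracy_pct, limit_pct, passed
    curve_passed: bool
    fraction_passed: float


def _weights(x: np.ndarray, weighting: Weighting) -> np.ndarray:
    if weighting == "none":
        return np.ones_like(x)
    if weighting == "1/x":
        return 1.0 / x
    if weighting == "1/x2":
        return 1.0 / x**2
    raise ValueError(f"unknown weighting {weighting!r}")


def _weighted_pearson(x, y, w) -> float:
    xm = np.average(x, weights=w)
    ym = np.average(y, weights=w)
    cov = np.sum(w * (x - xm) * (y - ym))
    vx = np.sum(w * (x - xm) ** 2)
    vy = np.sum(w * (y - ym) ** 2)
    if vx == 0 or vy == 0:
        raise ValueError("degenerate data: zero variance")
    return float(cov / np.sqrt(vx * vy))


class CalibrationModel:
    """Weighted least-squares model of response ratio on nominal concentration.

    Blank and zero samples in ``standards`` are carried along (they verify
    absence of interference) but never enter the regression.
    """

    def __init__(
        self,
        standards: Sequence[CalibrationStandard],
        weighting: Weighting = "none",
        analyte: str = "",
    ) -> None:
        self.standards = list(standards)
        self.weighting = weighting
        self.analyte = analyte
        usable = [s for s in self.standards if s.role == "standard"]
        if len(usable) < 2:
            raise ValueError("need at least two usable standards")
        x = np.array([s.nominal for s in usable], dtype=float)
        if np.unique(x).size < 2:
            raise ValueError("all nominal levels identical; cannot fit a line")
        self._x = x
        self._y = np.array([s.response_ratio for s in usable], dtype=float)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        analyte: str | None = None,
        weighting: Weighting = "none",
    ) -> "CalibrationModel":
        """Build from a run-data table (``analyte_area``/``is_area`` columns)."""
        standards = standards_from_run(df, analyte=analyte)
        return cls(standards, weighting=weighting, analyte=analyte or "")

    def fit(self) -> "CalibrationResults":
        w = _weights(self._x, self.weighting)
        design = sm.add_constant(self._x)
        wls = sm.WLS(self._y, design, weights=w).fit()
        intercept, slope = wls.params
        r = _weighted_pearson(self._x, self._y, w)
        curve = CalibrationCurve(
            analyte=self.analyte,
            slope=float(slope),
            intercept=float(intercept),
            r=r,
            weighting=self.weighting,
            range_low=float(self._x.min()),
            range_high=float(self._x.max()),
        )
        return CalibrationResults(model=self, curve=curve, wls_results=wls)


class CalibrationResults:
    """Fitted curve plus back-calculation and acceptance assessment."""

    def __init__(self, model: CalibrationModel, curve: CalibrationCurve,
                 wls_results=None) -> None:
        self.model = model
        self.curve = curve
        self.wls_results = wls_results

    def back_calculate(self, ratio: float) -> BackCalcResult:
        return back_calculate(self.curve, ratio)

    def assess(self, standards: Sequence[CalibrationStandard] | None = None
               ) -> CurveAssessment:
        return assess_curve(self.curve, standards or self.model.standards)

    def summary(self) -> str:
        c = self.curve
        lines = [
            f"Calibration: {c.analyte or '(unnamed analyte)'}",
            f"  Y = {c.slope:.6g}·X {'+' if c.intercept >= 0 else '−'} "
            f"{abs(c.intercept):.6g}   (weighting: {c.weighting})",
            f"  r = {c.r:.4f}   range {c.range_low:g}–{c.range_high:g} ng/mL",
        ]
        assessment = self.assess()
        lines.append(
            f"  standards passing: {assessment.fraction_passed * 100:.0f}%"
            f"  -> curve {'ACCEPTED' if assessment.curve_passed else 'REJECTED'}"
        )
        return "\n".join(lines)

    def to_report(self) -> dict:
        c = self.curve
        a = self.assess()
        return {
            "analyte": c.analyte,
            "slope": c.slope,
            "intercept": c.intercept,
            "r": c.r,
            "weighting": c.weighting,
            "range_ng_ml": [c.range_low, c.range_high],
            "curve_passed": bool(a.curve_passed),
            "standards": a.table.to_dict(orient="records"),
        }


def fit_calibration(
    standards: Sequence[CalibrationStandard],
    weighting: Weighting = "none",
    analyte: str = "",
) -> CalibrationCurve:
    """Functional wrapper over :class:`CalibrationModel`."""
    return CalibrationModel(standards, weighting=weighting, analyte=analyte).fit().curve


def back_calculate(curve: CalibrationCurve, ratio: float) -> BackCalcResult:
    """Invert the line: X = (ratio - intercept)/slope, with range/BLQ flags."""
    conc = (ratio - curve.intercept) / curve.slope
    return BackCalcResult(
        conc=float(conc),
        in_range=bool(curve.range_low <= conc <= curve.range_high),
        blq=bool(conc < 0),
    )


def assess_curve(
    curve: CalibrationCurve,
    standards: Sequence[CalibrationStandard],
    acc_limit: float = ACC_LIMIT_PCT,
    lloq_acc_limit: float = ACC_LIMIT_LLOQ_PCT,
) -> CurveAssessment:
    """Back-calculated accuracy of every non-zero standard, with pass flags.

    Per-standard rule (bounds inclusive): |accuracy - 100| <= 15, relaxed to
    <= 20 at the lowest (LLOQ) level.  The curve passes when at least 75% of
    standards pass and the LLOQ-level and highest-level standards all pass.
    """
    usable = [s for s in standards if s.role == "standard"]
    if not usable:
        raise ValueError("no standards to assess")
    nominals = np.array([s.nominal for s in usable], dtype=float)
    lloq_level = nominals.min()
    top_level = nominals.max()
    rows = []
    for s in usable:
        bc = back_calculate(curve, s.response_ratio)
        accuracy = 100.0 * bc.conc / s.nominal
        limit = lloq_acc_limit if s.nominal == lloq_level else acc_limit
        rows.append(
            {
                "nominal_ng_ml": s.nominal,
                "back_calc_ng_ml": bc.conc,
                "accuracy_pct": accuracy,
                "limit_pct": limit,
                "passed": bool(abs(accuracy - 100.0) <= limit),
            }
        )
    table = pd.DataFrame(rows)
    frac = float(table["passed"].mean())
    lloq_ok = bool(table.loc[table["nominal_ng_ml"] == lloq_level, "passed"].all())
    top_ok = bool(table.loc[table["nominal_ng_ml"] == top_level, "passed"].all())
    passed = frac >= CURVE_PASS_FRACTION and lloq_ok and top_ok
    return CurveAssessment(table=table, curve_passed=passed, fraction_passed=frac)


def standards_from_run(
    df: pd.DataFrame, analyte: str | None = None
) -> list[CalibrationStandard]:
    """Extract calibration standards from a run-data table.

    Expects the run-data schema (``analyte, role, nominal_ng_ml,
    analyte_area, is_area``); rows with role blank/zero are kept as such,
    rows with role ``standard`` become fit points.
    """
    if analyte is not None:
        df = df[df["analyte"] == analyte]
    out = []
    for _, row in df.iterrows():
        role = str(row["role"])
        if role not in ("standard", "blank", "zero"):
            continue
        is_area = float(row["is_area"])
        # a true blank carries no internal standard; its ratio is moot
        ratio = float(row["analyte_area"]) / is_area if is_area else 0.0
        nominal = float(row["nominal_ng_ml"]) if role == "standard" else None
        out.append(CalibrationStandard(nominal=nominal, response_ratio=ratio,
                                       role=role))
    return out
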