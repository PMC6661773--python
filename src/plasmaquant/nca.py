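"""Non-compartmental pharmacokinetic analysis (NCA).

Model-free estimation of the standard single-dose parameters from a
concentration-time profile: observed Cmax and tmax, AUC by trapezoid
(linear, or linear-up/log-down which is exact on mono-exponential decay),
the terminal elimination rate constant lambda_z (= Kel) from a log-linear
fit over an automatically selected terminal subset, t1/2 = ln2/lambda_z,
and AUC extrapolated to infinity via Clast/lambda_z.

The entry point follows the Model/Results convention: build an :class:`NCA`
from a :class:`PKProfile` (or a tidy DataFrame), call :meth:`NCA.fit`, and
read estimates off the returned :class:`NCAResult`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PKProfile",
    "NCA",
    "NCAResult",
    "cmax_tmax",
    "auc_trapezoid",
    "fit_lambda_z",
    "extrapolate",
    "summarize_cohort",
]

AUCMethod = Literal["linear", "linear_up_log_down"]

#: above this percent of AUC0-inf coming from the extrapolated tail, warn
EXTRAPOLATION_WARN_PCT = 20.0


@dataclass(frozen=True)
class PKProfile:
    """Concentration-time data for one subject and analyte.

    ``blq`` flags observations below the lower limit of quantification;
    flagged values are retained so that the handling policy (zero the
    leading ones, drop embedded and trailing ones) is applied explicitly
    at analysis time rather than silently at data entry.
    """

    subject_id: str
    analyte: str
    times: np.ndarray  # hours
    concentrations: np.ndarray  # ng/mL
    blq: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        b = (np.zeros(t.size, dtype=bool) if self.blq is None
             else np.asarray(self.blq, dtype=bool))
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "blq", b)
        if not (t.shape == c.shape == b.shape) or t.ndim != 1:
            raise ValueError("times, concentrations and blq must be equal-length 1-D")
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "analyte": self.analyte,
                "time_h": self.times,
                "conc_ng_ml": self.concentrations,
                "blq": self.blq.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PKProfile":
        if df["subject_id"].nunique() != 1 or df["analyte"].nunique() != 1:
            raise ValueError("frame must hold exactly one subject/analyte profile")
        df = df.sort_values("time_h")
        return cls(
            subject_id=str(df["subject_id"].iloc[0]),
            analyte=str(df["analyte"].iloc[0]),
            times=df["time_h"].to_numpy(),
            concentrations=df["conc_ng_ml"].to_numpy(),
            blq=df.get("blq", pd.Series(0, index=df.index)).to_numpy().astype(bool),
        )


def _apply_blq_policy(profile: PKProfile) -> tuple[np.ndarray, np.ndarray]:
    """Return usable (times, concentrations).

    Leading BLQ observations (before the first measurable point) are set to
    zero and kept; embedded and trailing BLQ observations are dropped.
    """
    t, c, b = profile.times, profile.concentrations, profile.blq
    measurable = np.nonzero(~b)[0]
    if measurable.size == 0:
        return np.empty(0), np.empty(0)
    first = measurable[0]
    keep = ~b
    keep[:first] = True  # leading BLQ retained as zeros
    c = c.copy()
    c[:first] = 0.0
    return t[keep], c[keep]


def cmax_tmax(profile: PKProfile) -> tuple[float, float]:
    """Observed maximum concentration and its time; ties go to the earliest."""
    mask = ~profile.blq
    if not mask.any():
        raise ValueError("all observations are BLQ; Cmax is undefined")
    c = profile.concentrations[mask]
    t = profile.times[mask]
    i = int(np.argmax(c))  # argmax returns the first maximum -> earliest time
    return float(c[i]), float(t[i])


def _segment_auc(t1, t2, c1, c2, method: AUCMethod) -> float:
    dt = t2 - t1
    if method == "linear_up_log_down" and c1 > c2 > 0:
        return (c1 - c2) * dt / math.log(c1 / c2)
    return 0.5 * (c1 + c2) * dt


def auc_trapezoid(
    profile: PKProfile,
    method: AUCMethod = "linear_up_log_down",
    t_end: float | None = None,
) -> float:
    """AUC from time zero to ``t_end`` (default: last usable time).

    Linear trapezoids throughout, except that with ``linear_up_log_down``
    strictly decreasing positive segments use the logarithmic trapezoid
    (C1-C2)*dt/ln(C1/C2), the exact integral of an exponential through the
    two points.  ``t_end`` may fall between samples; the closing partial
    segment is interpolated consistently with its rule.
    """
    t, c = _apply_blq_policy(profile)
    if t.size < 2:
        raise ValueError("need at least two usable points for AUC")
    if t_end is None:
        t_end = float(t[-1])
    if t_end > t[-1] + 1e-12:
        raise ValueError("t_end beyond the last usable observation")
    total = 0.0
    for i in range(t.size - 1):
        t1, t2, c1, c2 = t[i], t[i + 1], c[i], c[i + 1]
        if t2 <= t_end:
            total += _segment_auc(t1, t2, c1, c2, method)
        else:
            if t_end > t1:
                # interpolate the concentration at t_end within this segment
                if method == "linear_up_log_down" and c1 > c2 > 0:
                    lam = math.log(c1 / c2) / (t2 - t1)
                    c_end = c1 * math.exp(-lam * (t_end - t1))
                else:
                    c_end = c1 + (c2 - c1) * (t_end - t1) / (t2 - t1)
                total += _segment_auc(t1, t_end, c1, c_end, method)
            break
    return total


def _adjusted_r2(r2: float, n: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def fit_lambda_z(
    profile: PKProfile,
    selection: Literal["auto"] | Sequence[int] = "auto",
    min_points: int = 3,
) -> tuple[float, int, float]:
    """Terminal elimination rate constant from a log-linear fit.

    Candidate points are the strictly-positive, non-BLQ observations
    strictly after tmax.  In ``auto`` mode every terminal subset (last 3,
    last 4, ..., all candidates) is fitted by least squares of ln C on t and
    the subset with the highest adjusted R-squared wins; ties favour more
    points.  Returns ``(lambda_z, n_points, r2_adj)``.

    An explicit ``selection`` gives indices into the profile's time axis.
    """
    _, tmax = cmax_tmax(profile)
    if selection == "auto":
        mask = (~profile.blq) & (profile.times > tmax) & (profile.concentrations > 0)
        t_all = profile.times[mask]
        c_all = profile.concentrations[mask]
        if t_all.size < min_points:
            raise ValueError("fewer than %d usable terminal points" % min_points)
        best: tuple[float, int, float] | None = None
        for k in range(min_points, t_all.size + 1):
            t_k, c_k = t_all[-k:], c_all[-k:]
            fit = stats.linregress(t_k, np.log(c_k))
            adj = _adjusted_r2(fit.rvalue**2, k)
            # >= with a tie tolerance: later (larger) subsets win exact ties
            if best is None or adj >= best[2] - 1e-12:
                best = (-fit.slope, k, adj)
        slope_neg, n_pts, adj = best
    else:
        idx = np.asarray(selection, dtype=int)
        if idx.size < min_points:
            raise ValueError("explicit selection needs >= %d points" % min_points)
        t_k = profile.times[idx]
        c_k = profile.concentrations[idx]
        if np.any(c_k <= 0):
            raise ValueError("selected points must have positive concentrations")
        fit = stats.linregress(t_k, np.log(c_k))
        n_pts = idx.size
        adj = _adjusted_r2(fit.rvalue**2, n_pts)
        slope_neg = -fit.slope
    if slope_neg <= 0:
        raise ValueError("terminal slope is non-negative; lambda_z not estimable")
    return float(slope_neg), int(n_pts), float(adj)


def extrapolate(auc_last: float, c_last: float, lambda_z: float) -> tuple[float, float]:
    """AUC0-inf = AUC0-t + Clast/lambda_z and the extrapolated percentage."""
    if lambda_z <= 0:
        raise ValueError("lambda_z must be positive")
    if c_last < 0:
        raise ValueError("c_last must be non-negative")
    auc_inf = auc_last + c_last / lambda_z
    pct = 0.0 if auc_inf == 0 else 100.0 * (auc_inf - auc_last) / auc_inf
    return float(auc_inf), float(pct)


@dataclass(frozen=True)
class NCAResult:
    """Estimates from :meth:`NCA.fit` for one subject and analyte."""

    subject_id: str
    analyte: str
    cmax: float
    tmax: float
    auc_last: float
    auc_inf: float
    lambda_z: float
    t_half: float
    pct_extrapolated: float
    n_lambda_points: int
    lambda_r2_adj: float
    method: str
    extrapolation_warning: bool

    @property
    def kel(self) -> float:
        """Elimination rate constant; synonymous with lambda_z here."""
        return self.lambda_z

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "analyte": self.analyte,
            "cmax_ng_ml": self.cmax,
            "tmax_h": self.tmax,
            "auc_last_ng_h_ml": self.auc_last,
            "auc_inf_ng_h_ml": self.auc_inf,
            "lambda_z_per_h": self.lambda_z,
            "kel_per_h": self.kel,
            "t_half_h": self.t_half,
            "pct_extrapolated": self.pct_extrapolated,
            "n_lambda_points": self.n_lambda_points,
            "lambda_r2_adj": self.lambda_r2_adj,
        }

    def summary(self) -> str:
        lines = [
            f"NCA results: {self.analyte}, subject {self.subject_id}",
            f"  Cmax      {self.cmax:12.2f} ng/mL",
            f"  tmax      {self.tmax:12.2f} h",
            f"  AUC0-t    {self.auc_last:12.2f} ng*h/mL  ({self.method})",
            f"  AUC0-inf  {self.auc_inf:12.2f} ng*h/mL  "
            f"({self.pct_extrapolated:.2f}% extrapolated"
            + (", WARNING > 20%" if self.extrapolation_warning else "")
            + ")",
            f"  lambda_z  {self.lambda_z:12.4f} 1/h  "
            f"({self.n_lambda_points} points, adj R2 {self.lambda_r2_adj:.4f})",
            f"  t1/2      {self.t_half:12.2f} h",
        ]
        return "\n".join(lines)


class NCA:
    """Non-compartmental analysis of one concentration-time profile.

    Parameters
    ----------
    profile : PKProfile
        Subject profile; BLQ flags are honoured (leading -> 0, embedded and
        trailing -> excluded).
    method : {"linear_up_log_down", "linear"}
        Trapezoid rule for AUC.
    lambda_selection : "auto" or sequence of int
        Terminal-subset choice for the lambda_z regression.
    """

    def __init__(
        self,
        profile: PKProfile,
        method: AUCMethod = "linear_up_log_down",
        lambda_selection: Literal["auto"] | Sequence[int] = "auto",
    ) -> None:
        self.profile = profile
        self.method = method
        self.lambda_selection = lambda_selection

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "NCA":
        return cls(PKProfile.from_frame(df), **kwargs)

    def fit(self) -> NCAResult:
        prof = self.profile
        cmax, tmax = cmax_tmax(prof)
        auc_last = auc_trapezoid(prof, method=self.method)
        lam, n_pts, adj = fit_lambda_z(prof, selection=self.lambda_selection)
        t_usable, c_usable = _apply_blq_policy(prof)
        c_last = float(c_usable[-1])
        auc_inf, pct = extrapolate(auc_last, c_last, lam)
        return NCAResult(
            subject_id=prof.subject_id,
            analyte=prof.analyte,
            cmax=cmax,
            tmax=tmax,
            auc_last=auc_last,
            auc_inf=auc_inf,
            lambda_z=lam,
            t_half=math.log(2) / lam,
            pct_extrapolated=pct,
            n_lambda_points=n_pts,
            lambda_r2_adj=adj,
            method=self.method,
            extrapolation_warning=pct > EXTRAPOLATION_WARN_PCT,
        )


_SUMMARY_PARAMS = [
    ("tmax_h", "tmax (h)"),
    ("cmax_ng_ml", "Cmax (ng/mL)"),
    ("auc_last_ng_h_ml", "AUC0-t (ng h/mL)"),
    ("auc_inf_ng_h_ml", "AUC0-inf (ng h/mL)"),
    ("t_half_h", "t1/2 (h)"),
    ("kel_per_h", "Kel (1/h)"),
]


def summarize_cohort(results: Iterable[NCAResult]) -> pd.DataFrame:
    """Mean +/- sample SD of each PK parameter, per analyte.

    SDs use the n-1 denominator; a single-subject cohort reports SD 0.0.
    Returns a tidy frame with a pre-formatted ``mean_sd`` column laid out
    like a conventional PK summary table.
    """
    rows = [r.to_dict() for r in results]
    if not rows:
        raise ValueError("no NCA results to summarize")
    df = pd.DataFrame(rows)
    out = []
    for analyte, grp in df.groupby("analyte", sort=False):
        for col, label in _SUMMARY_PARAMS:
            vals = grp[col].to_numpy(dtype=float)
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            out.append(
                {
                    "analyte": analyte,
                    "parameter": label,
                    "n": vals.size,
                    "mean": mean,
                    "sd": sd,
                    "mean_sd": f"{mean:.2f} ± {sd:.2f}",
                }
            )
    return pd.DataFrame(out)
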