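"""MRM chromatogram handling: peak detection, integration and signal-to-noise.

A targeted LC-MS/MS acquisition monitors one precursor/product ion pair
(Q1 -> Q3) per compound and records an intensity trace against retention
time.  Quantitation downstream works on the integrated peak *area* of the
analyte relative to its co-eluting internal standard, so the only jobs of
this module are (1) locating the apex of the expected peak inside a
retention-time window, (2) integrating the baseline-subtracted trace
between the flanking peak bounds, and (3) estimating signal-to-noise,
which anchors the lower limit of quantification (LLOQ, S/N >= 10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MRMTransition",
    "Chromatogram",
    "PeakResult",
    "SNRResult",
    "find_peak",
    "integrate_peak",
    "estimate_snr",
    "read_chromatograms_csv",
    "write_chromatograms_csv",
    "MET_TRANSITION",
    "PPL_TRANSITION",
    "CFZ_TRANSITION",
    "TDF_TRANSITION",
]

#: total LC run time in minutes; retention times must fall inside (0, RUN_TIME_MIN]
RUN_TIME_MIN = 5.0

#: default fraction of apex height below which a local minimum ends the peak
BOUND_FRACTION = 0.05

#: default S/N threshold supporting an LLOQ claim
LLOQ_SNR = 10.0


@dataclass(frozen=True)
class MRMTransition:
    """One monitored Q1 -> Q3 ion pair.

    The source voltages (declustering potential ``dp``, entrance potential
    ``ep``, collision energy ``ce``, cell exit potential ``cep``) are carried
    as acquisition metadata only; nothing downstream computes on them.
    """

    analyte: str
    q1_mz: float
    q3_mz: float
    retention_time: float  # minutes
    is_internal_standard: bool = False
    paired_is: str | None = None
    dp: float | None = None
    ep: float | None = None
    ce: float | None = None
    cep: float | None = None

    def __post_init__(self) -> None:
        if not (self.q1_mz > self.q3_mz > 0):
            raise ValueError(
                f"require q1_mz > q3_mz > 0, got {self.q1_mz} -> {self.q3_mz}"
            )
        if not (0 < self.retention_time <= RUN_TIME_MIN):
            raise ValueError(
                f"retention time {self.retention_time} min outside (0, {RUN_TIME_MIN}]"
            )


# Acquisition parameters of the published assay.  Metformin (MET) is paired
# with propranolol (PPL) and canagliflozin (CFZ) with tadalafil (TDF).
MET_TRANSITION = MRMTransition("MET", 130.2, 60.1, 0.9, paired_is="PPL",
                               dp=26, ep=10, ce=19, cep=12)
PPL_TRANSITION = MRMTransition("PPL", 260.2, 183.0, 1.1, is_internal_standard=True,
                               dp=120, ep=10, ce=28, cep=12)
CFZ_TRANSITION = MRMTransition("CFZ", 462.3, 191.0, 4.5, paired_is="TDF",
                               dp=61, ep=10, ce=15, cep=18)
TDF_TRANSITION = MRMTransition("TDF", 390.2, 268.2, 3.0, is_internal_standard=True,
                               dp=73, ep=10, ce=50, cep=17.4)


@dataclass(frozen=True)
class Chromatogram:
    """Intensity trace of a single MRM transition."""

    transition: MRMTransition
    times: np.ndarray  # minutes, strictly increasing
    intensities: np.ndarray  # counts

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intensities = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intensities)
        if times.ndim != 1 or times.shape != intensities.shape:
            raise ValueError("times and intensities must be 1-D and equal length")
        if times.size < 2:
            raise ValueError("a chromatogram needs at least two points")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def sampling_interval(self) -> float:
        return float(np.median(np.diff(self.times)))


@dataclass(frozen=True)
class PeakResult:
    """Located and integrated peak for one transition."""

    apex_time: float  # minutes
    area: float  # count*min, baseline-subtracted
    height: float  # counts above local baseline
    found: bool
    bounds: tuple[float, float]  # integration bounds, minutes
    snr: float = math.nan

    def with_snr(self, snr: float) -> "PeakResult":
        return replace(self, snr=snr)


@dataclass(frozen=True)
class SNRResult:
    snr: float
    lloq_supported: bool
    zero_noise_warning: bool = False


def _window_slice(chrom: Chromatogram, lo: float, hi: float) -> slice:
    i0, i1 = np.searchsorted(chrom.times, [lo, hi], side="left")
    i1 = int(np.searchsorted(chrom.times, hi, side="right"))
    return slice(int(i0), i1)


def find_peak(
    chrom: Chromatogram,
    expected_rt: float | None = None,
    window: float = 0.2,
    baseline_threshold: float = 0.0,
    bound_fraction: float = BOUND_FRACTION,
) -> PeakResult:
    """Locate the apex near ``expected_rt`` and delimit the peak.

    The apex is the maximum intensity within ``expected_rt +/- window``.
    Peak bounds extend outward from the apex to the nearest flanking local
    minima whose intensity has dropped below ``bound_fraction`` of the apex
    (or to the trace edge).  A peak is "found" only when the apex exceeds
    ``baseline_threshold``; a flat blank trace yields ``found=False``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if expected_rt is None:
        expected_rt = chrom.transition.retention_time
    lo, hi = expected_rt - window, expected_rt + window
    if hi < chrom.times[0] or lo > chrom.times[-1]:
        raise ValueError("retention-time window lies outside the time axis")
    sl = _window_slice(chrom, lo, hi)
    if sl.stop - sl.start == 0:
        raise ValueError("retention-time window contains no samples")

    y = chrom.intensities
    apex = sl.start + int(np.argmax(y[sl]))
    apex_height_raw = float(y[apex])
    cut = bound_fraction * apex_height_raw

    left = apex
    while left > 0:
        if y[left] <= cut and y[left - 1] >= y[left]:
            break
        left -= 1
    right = apex
    n = y.size - 1
    while right < n:
        if y[right] <= cut and y[right + 1] >= y[right]:
            break
        right += 1

    bounds = (float(chrom.times[left]), float(chrom.times[right]))
    # height above the local linear baseline at the apex
    b0, b1 = y[left], y[right]
    t0, t1 = chrom.times[left], chrom.times[right]
    if t1 > t0:
        base_at_apex = b0 + (b1 - b0) * (chrom.times[apex] - t0) / (t1 - t0)
    else:
        base_at_apex = b0
    height = max(0.0, apex_height_raw - float(base_at_apex))
    found = apex_height_raw > baseline_threshold
    area = max(0.0, integrate_peak(chrom, bounds)) if found else 0.0
    return PeakResult(
        apex_time=float(chrom.times[apex]),
        area=area,
        height=height if found else 0.0,
        found=found,
        bounds=bounds,
    )


def integrate_peak(
    chrom: Chromatogram,
    bounds: tuple[float, float],
    subtract_baseline: bool = True,
) -> float:
    """Trapezoidal area between ``bounds`` (minutes).

    With ``subtract_baseline`` the linear segment joining the intensities at
    the two bound endpoints is removed first, which makes the area invariant
    to any constant offset of the trace.
    """
    t_lo, t_hi = bounds
    if t_hi < t_lo:
        raise ValueError("inverted integration bounds")
    if t_lo < chrom.times[0] - 1e-12 or t_hi > chrom.times[-1] + 1e-12:
        raise ValueError("integration bounds outside the time axis")
    sl = _window_slice(chrom, t_lo, t_hi)
    t = chrom.times[sl]
    y = chrom.intensities[sl].astype(float)
    if t.size < 2:
        return 0.0
    if subtract_baseline:
        base = np.interp(t, [t[0], t[-1]], [y[0], y[-1]])
        y = y - base
    return float(np.trapezoid(y, t))


def estimate_snr(
    chrom: Chromatogram,
    peak: PeakResult,
    noise_region: tuple[float, float] = (0.0, 0.4),
    lloq_snr: float = LLOQ_SNR,
) -> SNRResult:
    """Peak height over the standard deviation of a peak-free region.

    ``noise_region`` must not overlap the peak bounds.  A zero-variance
    region (an idealised noiseless trace) reports infinite S/N with a
    warning flag instead of failing.
    """
    n_lo, n_hi = noise_region
    if n_hi <= n_lo:
        raise ValueError("empty noise region")
    if peak.found and not (n_hi <= peak.bounds[0] or n_lo >= peak.bounds[1]):
        raise ValueError("noise region overlaps the peak bounds")
    sl = _window_slice(chrom, n_lo, n_hi)
    region = chrom.intensities[sl]
    if region.size < 2:
        raise ValueError("noise region contains fewer than two samples")
    sd = float(np.std(region, ddof=1))
    if sd == 0.0:
        snr = math.inf if peak.height > 0 else 0.0
        return SNRResult(snr=snr, lloq_supported=snr >= lloq_snr,
                         zero_noise_warning=True)
    snr = peak.height / sd
    return SNRResult(snr=snr, lloq_supported=snr >= lloq_snr)


# ---------------------------------------------------------------------------
# plain-text IO; vendor raw files and mzML are out of scope for this package

def write_chromatograms_csv(path, chromatograms: Sequence[Chromatogram]) -> None:
    """Write traces as long-format CSV: ``transition_id,time_min,intensity``."""
    frames = [
        pd.DataFrame(
            {
                "transition_id": c.transition.analyte,
                "time_min": c.times,
                "intensity": c.intensities,
            }
        )
        for c in chromatograms
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_chromatograms_csv(
    path, transitions: Mapping[str, MRMTransition]
) -> dict[str, Chromatogram]:
    """Read the long-format CSV written by :func:`write_chromatograms_csv`.

    ``transitions`` supplies the acquisition metadata for each
    ``transition_id`` since the CSV stores only the trace itself.
    """
    df = pd.read_csv(path)
    out: dict[str, Chromatogram] = {}
    for tid, grp in df.groupby("transition_id", sort=False):
        if tid not in transitions:
            raise KeyError(f"no MRMTransition supplied for {tid!r}")
        out[str(tid)] = Chromatogram(
            transition=transitions[tid],
            times=grp["time_min"].to_numpy(),
            intensities=grp["intensity"].to_numpy(),
        )
    return out
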