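"""High-throughput plate-reader well-scan analysis.

A well-scan export carries per-point fluorescence intensities for the
scaffold (green), live (blue) and dead (red) channels.  The analysis path
is: gate scan points on scaffold overlap (green strictly above 2000 a.u.
by convention), form the raw dead/live intensity ratio per point, apply
the voxel-to-pixel correction

    corrected = pi * (3 * raw / (4 * pi))**(2/3),

which maps a volume-proportional ratio onto the corresponding
great-circle-area scale (the plate reader integrates over a volume while
the dose-response is referenced to a cross-section), fit a Gaussian to the
per-dose histogram of corrected ratios, and assemble the per-dose means
into a dose-response table for Hill fitting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .dose_response import HillFit, fit_hill

DEFAULT_GREEN_GATE = 2000.0

_WELLSCAN_COLUMNS = ["well", "dose_uM", "point", "fi_green", "fi_blue", "fi_red"]


@dataclass(frozen=True)
class DoseSummary:
    """Gaussian summary of corrected dead/live ratios at one dose."""

    dose: float
    mean: float
    sd: float
    n: int
    fit_flag: str = ""   # "", "moment_fallback" or "degenerate"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def read_wellscan(path) -> pd.DataFrame:
    """Read a well-scan CSV (columns well, dose_uM, point, fi_green, fi_blue, fi_red)."""
    df = pd.read_csv(path)
    missing = [c for c in _WELLSCAN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"well-scan CSV missing columns {missing}")
    return df


def gate_by_scaffold(scan: pd.DataFrame, green_threshold: float = DEFAULT_GREEN_GATE) -> pd.DataFrame:
    """Retain scan points overlapping the scaffold: FI_green strictly above gate."""
    if scan.empty:
        raise ValueError("scan is empty")
    kept = scan[scan["fi_green"] > green_threshold].copy()
    if kept.empty:
        warnings.warn("all scan points gated out by the scaffold gate", stacklevel=2)
    return kept


def voxel_to_pixel_correct(raw_ratio):
    """Voxel(volume)-to-pixel(area) correction of a dead/live intensity ratio.

    ``corrected = pi * (3*raw/(4*pi))**(2/3)``; maps a sphere-volume scale
    onto its great-circle-area scale, so ``4*pi/3 -> pi`` and ``0 -> 0``.
    Monotone increasing and concave on raw > 0.
    """
    raw = np.asarray(raw_ratio, dtype=float)
    if np.any(raw < 0):
        raise ValueError("raw ratio must be non-negative")
    out = math.pi * (3.0 * raw / (4.0 * math.pi)) ** (2.0 / 3.0)
    return out if out.ndim else float(out)


def pixel_to_voxel_ratio(corrected):
    """Inverse of :func:`voxel_to_pixel_correct`: area scale back to volume scale."""
    corr = np.asarray(corrected, dtype=float)
    if np.any(corr < 0):
        raise ValueError("corrected ratio must be non-negative")
    out = (4.0 * math.pi / 3.0) * (corr / math.pi) ** 1.5
    return out if out.ndim else float(out)


def fit_gaussian(values, min_bins: int = 10) -> tuple[float, float, float, str]:
    """Least-squares Gaussian fit to the binned frequency histogram.

    Bins follow the Freedman-Diaconis rule with at least ``min_bins`` bins.
    Falls back to sample moments (flag ``"moment_fallback"``) when the fit
    does not converge or explains less than 90 % of the histogram variance;
    identical values short-circuit to a degenerate summary.

    Returns ``(mean, sd, amplitude, flag)``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(x) == 0:
        return float(x[0]), 0.0, float(x.size), "degenerate"

    iqr = np.subtract(*np.percentile(x, [75, 25]))
    width = 2.0 * iqr / x.size ** (1.0 / 3.0)
    # cap at 4*sqrt(n) bins so a collapsed IQR cannot explode the histogram
    n_cap = max(min_bins, int(4 * math.sqrt(x.size)))
    n_bins = int(np.clip(math.ceil(np.ptp(x) / width) if width > 0 else min_bins,
                         min_bins, n_cap))
    counts, edges = np.histogram(x, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(t, amp, mu, sd):
        return amp * np.exp(-0.5 * ((t - mu) / sd) ** 2)

    p0 = [counts.max(), float(x.mean()), float(x.std(ddof=1))]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(gauss, centers, counts, p0=p0, maxfev=10000)
        amp, mu, sd = float(popt[0]), float(popt[1]), abs(float(popt[2]))
        resid = counts - gauss(centers, *popt)
        sst = float(((counts - counts.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 0.0
        if r2 < 0.9:
            return float(x.mean()), float(x.std(ddof=1)), float(counts.max()), "moment_fallback"
        return mu, sd, amp, ""
    except (RuntimeError, ValueError):
        return float(x.mean()), float(x.std(ddof=1)), float(counts.max()), "moment_fallback"


def build_dose_response(
    scan: pd.DataFrame,
    green_threshold: float = DEFAULT_GREEN_GATE,
) -> list[DoseSummary]:
    """Per-dose Gaussian summaries of corrected dead/live ratios.

    Gate on scaffold overlap, form corrected FI_red/FI_blue per retained
    point, Gaussian-fit the per-dose histogram, and return summaries
    ordered by dose.  Doses with no retained points are dropped with a
    warning.
    """
    doses = np.unique(scan["dose_uM"].to_numpy(float))
    if doses.size < 2:
        raise ValueError("need >= 2 distinct doses")
    summaries = []
    for dose in np.sort(doses):
        sub = scan[scan["dose_uM"] == dose]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kept = sub[sub["fi_green"] > green_threshold]
        if kept.empty:
            warnings.warn(f"dose {dose:g} uM: all points gated out; dropped", stacklevel=2)
            continue
        blue = kept["fi_blue"].to_numpy(float)
        red = kept["fi_red"].to_numpy(float)
        raw = red / np.clip(blue, 1e-9, None)
        corrected = voxel_to_pixel_correct(raw)
        if corrected.size >= 3:
            mean, sd, _amp, flag = fit_gaussian(corrected)
        else:
            mean, sd, flag = float(corrected.mean()), float(corrected.std(ddof=0)), "moment_fallback"
        summaries.append(DoseSummary(dose=float(dose), mean=mean, sd=sd,
                                     n=int(corrected.size), fit_flag=flag))
    return summaries


def summaries_to_viability(summaries: list[DoseSummary]) -> pd.DataFrame:
    """Map per-dose corrected-ratio means to a viability-like response.

    The corrected means are taken back to the raw volumetric dead/live
    ratio ``rho`` through the inverse correction, and viability is
    ``1 / (1 + rho)`` (live fraction of a dead+live mixture).  Columns:
    dose_uM, response, weight_sd.
    """
    rows = []
    for s in summaries:
        rho = pixel_to_voxel_ratio(max(s.mean, 0.0))
        rows.append({"dose_uM": s.dose, "response": 1.0 / (1.0 + rho), "weight_sd": s.sd})
    return pd.DataFrame(rows)


def ht_hill_fit(scan: pd.DataFrame, green_threshold: float = DEFAULT_GREEN_GATE) -> HillFit:
    """Full HT path: gate -> correct -> Gaussian -> normalise -> Hill fit.

    The viability-like response is fitted in 2-parameter mode with
    ``top, bottom = (1, 0)`` after normalisation to the zero-dose response.
    """
    summaries = build_dose_response(scan, green_threshold)
    table = summaries_to_viability(summaries)
    resp = table["response"].to_numpy(float)
    resp = resp / resp[0]   # normalise to the lowest (zero) dose
    return fit_hill(
        table["dose_uM"].to_numpy(float), resp, fix_top_bottom=(1.0, 0.0)
    )
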