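"""Hill dose-response fitting and group-separation statistics.

The drug response of a spheroid population is modelled by the Hill
(four-parameter logistic) equation

    response(d) = bottom + (top - bottom) / (1 + (d / IC50)**n)

with ``IC50`` the half-maximal dose, ``n`` the Hill coefficient
(cooperativity), and ``top``/``bottom`` the asymptotic responses at zero
and saturating dose.  Response here is a viability-like quantity that
*decreases* with dose.  Dose 0 is handled by the power form directly
(``response(0) = top`` exactly), so no log-dose transform is needed.

Group separation between dose levels is quantified by the ROC AUC in its
rank (Mann-Whitney) formulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import mannwhitneyu


class FitFailure(RuntimeError):
    """No Hill fit converged from any start."""


@dataclass(frozen=True)
class HillParams:
    """Hill-equation parameters: IC50 in uM, n dimensionless, top > bottom."""

    ic50: float
    n: float
    top: float = 1.0
    bottom: float = 0.0

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")
        if self.n <= 0:
            raise ValueError("Hill coefficient n must be positive")
        if not self.top > self.bottom:
            raise ValueError("top must exceed bottom")


@dataclass(frozen=True)
class HillFit:
    """Result of a Hill fit: parameters, goodness of fit and diagnostics."""

    params: HillParams
    r_squared: float
    stderr: dict
    n_obs: int
    extrapolated: bool = False   # IC50 outside the fitted dose range
    degenerate: bool = False     # flat response, top ~ bottom


def hill_response(dose, p: HillParams):
    """Evaluate the Hill curve at ``dose`` (scalar or array, uM, >= 0)."""
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, (dose / p.ic50) ** p.n, 0.0)
    out = p.bottom + (p.top - p.bottom) / (1.0 + ratio)
    return out if out.ndim else float(out)


def _hill4(d, ic50, n, top, bottom):
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(d > 0, (np.asarray(d) / ic50) ** n, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


def fit_hill(
    doses,
    responses,
    weights=None,
    fix_top_bottom: tuple[float, float] | None = None,
) -> HillFit:
    """Nonlinear least-squares Hill fit.

    Fits ``(ic50, n, top, bottom)`` with bounds ``ic50 > 0``, ``n > 0``;
    multi-starts over a geometric grid of IC50 seeds spanning the positive
    dose range and ``n in {0.5, 1, 2, 4}``, keeping the lowest residual.
    ``fix_top_bottom=(top, bottom)`` switches to the 2-parameter mode used
    after normalisation to the zero-dose response.

    ``weights`` are per-observation standard deviations (as in
    ``curve_fit(sigma=...)``).
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if d.shape != y.shape or d.ndim != 1:
        raise ValueError("doses and responses must be 1-D and equal length")
    distinct = np.unique(d)
    if distinct.size < 4:
        raise ValueError("need >= 4 distinct doses")
    if np.ptp(y) == 0:
        return HillFit(
            params=HillParams(ic50=float(np.median(d[d > 0])), n=1.0,
                              top=float(y[0]) + 1e-12, bottom=float(y[0])),
            r_squared=0.0, stderr={}, n_obs=d.size, degenerate=True,
        )

    pos = d[d > 0]
    ic50_seeds = np.geomspace(pos.min() / 3.0, pos.max() * 3.0, 7)
    n_seeds = (0.5, 1.0, 2.0, 4.0)
    span = float(np.ptp(y))
    sigma = np.asarray(weights, float) if weights is not None else None

    two_param = fix_top_bottom is not None
    if two_param:
        top0, bot0 = fix_top_bottom

        def model(dd, ic50, n):
            return _hill4(dd, ic50, n, top0, bot0)

        bounds = ([1e-12, 1e-3], [np.inf, 50.0])
    else:
        model = _hill4
        lo_y, hi_y = y.min() - span, y.max() + span
        bounds = ([1e-12, 1e-3, lo_y, lo_y], [np.inf, 50.0, hi_y, hi_y])

    best = None
    for ic0 in ic50_seeds:
        for n0 in n_seeds:
            p0 = [ic0, n0] if two_param else [ic0, n0, y.max(), y.min()]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, pcov = curve_fit(
                        model, d, y, p0=p0, sigma=sigma, bounds=bounds,
                        maxfev=20000,
                    )
            except (RuntimeError, ValueError):
                continue
            resid = y - model(d, *popt)
            ssr = float(resid @ resid)
            if best is None or ssr < best[0]:
                best = (ssr, popt, pcov)
    if best is None:
        raise FitFailure("no Hill fit converged from any start")

    ssr, popt, pcov = best
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(len(popt), np.nan)
    if two_param:
        params = HillParams(ic50=float(popt[0]), n=float(popt[1]),
                            top=float(fix_top_bottom[0]), bottom=float(fix_top_bottom[1]))
        stderr = {"ic50": float(perr[0]), "n": float(perr[1])}
    else:
        top, bottom = float(popt[2]), float(popt[3])
        if top < bottom:  # reparameterise so top > bottom (n flips sign role)
            top, bottom = bottom, top
        if top <= bottom:
            top = bottom + 1e-12
        params = HillParams(ic50=float(popt[0]), n=float(popt[1]), top=top, bottom=bottom)
        stderr = dict(zip(("ic50", "n", "top", "bottom"), map(float, perr)))
    extrapolated = not (pos.min() <= params.ic50 <= pos.max())
    degenerate = abs(params.top - params.bottom) < 1e-6 * max(1.0, span)
    return HillFit(params=params, r_squared=float(r2), stderr=stderr,
                   n_obs=int(d.size), extrapolated=extrapolated, degenerate=degenerate)


def fit_viability_profile(doses, viabilities, robust: bool = True) -> HillFit:
    """Hill fit to per-spheroid viabilities, aggregated per dose first.

    Viability lives on [0, 1], so additive measurement noise is censored at
    the ends of the scale; the per-dose *median* is unaffected by one-sided
    censoring (as long as less than half the mass clips) where the mean is
    biased inward.  ``robust=True`` therefore fits the Hill curve to
    per-dose medians; ``robust=False`` uses means.
    """
    d = np.asarray(doses, dtype=float)
    v = np.asarray(viabilities, dtype=float)
    if d.shape != v.shape:
        raise ValueError("doses and viabilities must be equal length")
    levels = np.unique(d)
    agg = np.array([
        (np.median if robust else np.mean)(v[d == lev]) for lev in levels
    ])
    return fit_hill(levels, agg)


def roc_auc(group_low, group_high) -> float:
    """ROC AUC separating two viability groups (rank / Mann-Whitney form).

    Probability that a value from ``group_high`` exceeds one from
    ``group_low``, ties counted half.
    """
    lo = np.asarray(group_low, dtype=float)
    hi = np.asarray(group_high, dtype=float)
    if lo.size == 0 or hi.size == 0:
        raise ValueError("both groups must be nonempty")
    u = mannwhitneyu(hi, lo, alternative="two-sided").statistic
    return float(u) / (lo.size * hi.size)
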