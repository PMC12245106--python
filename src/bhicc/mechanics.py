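"""Elastic microgel contact mechanics.

Alginate microgels settling into a hexagonal-close-packed template deform
at their contacts under the balance of gravity, buoyancy and elastic
restoring stress.  The equilibrium centre-to-centre distance ``Di`` between
neighbouring microgels of diameter ``R`` satisfies a quartic in ``Di/2``

    x**4 - a*x**3 - 3*a**2*x**2 + 5*a**3*x - 2*a**4*(1 - lam) = 0,

with ``a = R/2`` and ``lam`` a dimensionless load built from the loading
group ``rho_w * Calg * g / Ec``.  At ``lam = 0`` the quartic factors as
``(x - a)**3 * (x + 2*a)`` so tangent rigid spheres (``Di = R``) are
recovered exactly; for small loads the physical root detaches from the
triple root as ``Di/R ~ 1 - (2*lam/3)**(1/3)``.

The flattened contact disc has diameter

    Rcap = 2*sqrt((R/2)**2 - (Di/2)**2),

which after templating becomes the interconnecting channel diameter of the
inverted-colloidal-crystal framework.

Unit conventions: lengths in micrometres, moduli in kPa at the user surface
(Pa internally for the loading group), stresses in kPa, strains fractional.

.. note::
   The printed loading group ``rho_w*Calg*g/Ec`` carries units of 1/m in SI;
   this module evaluates it with SI base values inserted literally and treats
   the resulting number as the dimensionless load.  ``solve_contact_distance``
   also accepts ``lam`` directly so callers can apply their own
   nondimensionalisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq


class ModelDomainError(ValueError):
    """Raised when parameters leave the regime where the contact model holds."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StressStrainCurve:
    """Uniaxial compressive stress-strain record.

    Parameters
    ----------
    strain : array-like
        Fractional compressive strain, non-negative and strictly ascending.
    stress : array-like
        Compressive stress in kPa, same length as ``strain``.
    """

    strain: np.ndarray
    stress: np.ndarray

    def __post_init__(self) -> None:
        strain = np.asarray(self.strain, dtype=float)
        stress = np.asarray(self.stress, dtype=float)
        object.__setattr__(self, "strain", strain)
        object.__setattr__(self, "stress", stress)
        if strain.ndim != 1 or stress.shape != strain.shape:
            raise ValueError("strain and stress must be 1-D and equal length")
        if strain.size < 2:
            raise ValueError("need at least 2 samples")
        if not np.all(np.diff(strain) > 0):
            raise ValueError("strain must be strictly ascending")
        if not (np.all(np.isfinite(stress)) and np.all(np.isfinite(strain))):
            raise ValueError("stress and strain must be finite")
        if np.any(strain < 0):
            raise ValueError("strain must be non-negative")

    def __len__(self) -> int:
        return int(self.strain.size)


@dataclass(frozen=True)
class MicrogelBatch:
    """One electrosprayed alginate microgel batch.

    ``calg`` is the alginate mass-per-volume fraction (0.030 for a
    3.0 % w/v solution), ``ec`` the compressive modulus in Pa, and
    ``radius_mean``/``radius_sd`` the microgel *diameter* statistics in um
    (field name kept for symmetry with the R symbol of the model).
    """

    calg: float
    ec: float
    radius_mean: float
    radius_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.calg <= 0.1:
            raise ValueError("calg must lie in (0, 0.1]")
        if self.ec <= 0:
            raise ValueError("ec must be positive")
        if self.radius_mean <= 0:
            raise ValueError("radius_mean must be positive")


@dataclass(frozen=True)
class PhysicalConstants:
    rho_w: float = 1000.0   # water density, kg m^-3
    g: float = 9.81         # gravitational acceleration, m s^-2

    def __post_init__(self) -> None:
        if self.rho_w <= 0 or self.g <= 0:
            raise ValueError("constants must be positive")


@dataclass(frozen=True)
class ContactSolution:
    """Equilibrium contact geometry for one microgel pair."""

    di: float           # centre-to-centre distance, um
    di_over_r: float
    rcap: float         # contact-disc (channel) diameter, um
    lam: float
    variant: str = "eq3"

    def __post_init__(self) -> None:
        if not 0 < self.di_over_r <= 1 + 1e-12:
            raise ValueError("Di must lie in (0, R]")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def estimate_compressive_modulus(curve: StressStrainCurve, n_points: int = 11) -> float:
    """Small-strain compressive modulus Ec in kPa.

    Ordinary least-squares line (with intercept) through the first
    ``n_points`` samples of the stress-strain curve; the slope is returned.
    With fewer than ``n_points`` samples all available points are used and a
    warning is emitted.
    """
    if len(curve) < 2:
        raise ValueError("need at least 2 samples to fit a slope")
    if len(curve) < n_points:
        warnings.warn(
            f"curve has {len(curve)} < {n_points} samples; using all of them",
            stacklevel=2,
        )
        n_points = len(curve)
    eps = curve.strain[:n_points]
    sig = curve.stress[:n_points]
    slope, _intercept = np.polyfit(eps, sig, 1)
    return float(slope)


def dimensionless_load(
    batch: MicrogelBatch,
    constants: PhysicalConstants = PhysicalConstants(),
    variant: str = "eq3",
) -> float:
    """Dimensionless load ``lam`` of the force-balance quartic.

    ``variant='eq2'`` evaluates ``2*rho_w*calg*g / ec`` and
    ``variant='eq3'`` evaluates ``rho_w*calg*g / (3*ec)``, with SI base
    values inserted literally (see module note on units).
    """
    group = constants.rho_w * batch.calg * constants.g / batch.ec
    if variant == "eq2":
        return 2.0 * group
    if variant == "eq3":
        return group / 3.0
    raise ValueError(f"unknown variant {variant!r}; expected 'eq2' or 'eq3'")


def _quartic(x: np.ndarray, a: float, lam: float) -> np.ndarray:
    return x**4 - a * x**3 - 3 * a**2 * x**2 + 5 * a**3 * x - 2 * a**4 * (1 - lam)


def solve_contact_distance(r: float, lam: float, variant: str = "eq3") -> ContactSolution:
    """Solve the contact quartic for the centre-to-centre distance ``Di``.

    The physical root is the largest real root of the quartic in ``(0, a]``
    (``a = R/2``), located by bracketed bisection; it perturbs off the
    triple root at ``a`` as ``Di/R ~ 1 - (2*lam/3)**(1/3)``.
    """
    if r <= 0:
        raise ValueError("microgel diameter r must be positive")
    if lam < 0:
        raise ValueError("lam must be non-negative")
    a = r / 2.0
    if lam == 0.0:
        return ContactSolution(di=r, di_over_r=1.0, rcap=0.0, lam=0.0, variant=variant)
    # bracket below the perturbed root; widen geometrically if needed
    lo = a * (1.0 - 2.0 * (2.0 * lam) ** (1.0 / 3.0))
    hi = a
    while lo > 0 and _quartic(lo, a, lam) * _quartic(hi, a, lam) > 0:
        lo = lo - (hi - lo)
    if lo <= 0 and _quartic(1e-12 * a, a, lam) * _quartic(hi, a, lam) > 0:
        raise ModelDomainError(
            f"no real root in (0, R/2] for lam={lam:g}; load outside model domain"
        )
    lo = max(lo, 1e-12 * a)
    x = brentq(_quartic, lo, hi, args=(a, lam), xtol=1e-14 * a)
    if abs(_quartic(x, a, lam)) > 1e-10 * a**4:
        raise ModelDomainError("root residual exceeds tolerance")
    di = 2.0 * x
    return ContactSolution(
        di=di, di_over_r=di / r, rcap=cap_diameter(r, di), lam=lam, variant=variant
    )


def cap_diameter(r: float, di: float) -> float:
    """Contact-disc (channel) diameter ``Rcap = 2*sqrt((R/2)^2 - (Di/2)^2)``."""
    if di < 0 or r <= 0:
        raise ValueError("require r > 0 and di >= 0")
    if di > r * (1 + 1e-12):
        raise ValueError("di cannot exceed r for spheres in contact")
    di = min(di, r)
    return float(np.sqrt(r * r - di * di))


def predict_channel_diameter(
    batch: MicrogelBatch,
    constants: PhysicalConstants = PhysicalConstants(),
    variant: str = "eq3",
) -> ContactSolution:
    """Full chain: loading group -> quartic root -> cap diameter."""
    lam = dimensionless_load(batch, constants, variant)
    return solve_contact_distance(batch.radius_mean, lam, variant)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_stress_strain(path) -> StressStrainCurve:
    """Read a two-column CSV (``strain``, ``stress_kpa``; header required)."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "strain" not in cols or "stress_kpa" not in cols:
        raise ValueError(
            f"expected columns 'strain' and 'stress_kpa', found {list(df.columns)}"
        )
    return StressStrainCurve(
        strain=df[cols["strain"]].to_numpy(float),
        stress=df[cols["stress_kpa"]].to_numpy(float),
    )
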