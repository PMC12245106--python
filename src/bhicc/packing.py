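"""Hexagonal lattice packing geometry of the void array.

A circular dish (or well-plate punch) is filled with equal spherical voids
templated by close-packed microgels.  Within one layer the void centres sit
on a triangular (hexagonal) lattice; successive layers alternate between
the A and B registrations of hexagonal close packing, with layer spacing
``pitch*sqrt(2/3)``.  This module counts how many voids fit entirely inside
the dish — the throughput capacity of the framework — and reports the ideal
HCP packing fraction ``pi/(3*sqrt(2)) ~ 0.74`` and void number density
``sqrt(2)/d**3``.

Counts are exact enumerations, not area estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

HCP_PACKING_FRACTION = math.pi / (3.0 * math.sqrt(2.0))

#: in-plane offset of a B layer relative to an A layer, in pitch units
_B_OFFSET = (0.5, 0.5 / math.sqrt(3.0))


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of the void lattice inside a circular container.

    All lengths in micrometres.  ``pitch`` defaults to the void diameter
    (tangent voids); ``layer_spacing`` defaults to the HCP value
    ``pitch*sqrt(2/3)``.  ``registration`` is either ``"centered"`` (one
    void centred at the container centre, rows along x — deterministic) or
    ``"best-of-translations"`` (maximise the count over a small grid of
    lattice offsets).
    """

    void_diameter: float
    container_diameter: float
    layers: int = 1
    pitch: float | None = None
    layer_spacing: float | None = None
    registration: str = "centered"

    def __post_init__(self) -> None:
        if self.void_diameter <= 0 or self.container_diameter <= 0:
            raise ValueError("diameters must be positive")
        if self.layers < 1:
            raise ValueError("layers must be >= 1")
        if self.pitch is None:
            object.__setattr__(self, "pitch", float(self.void_diameter))
        if self.layer_spacing is None:
            object.__setattr__(self, "layer_spacing", self.pitch * math.sqrt(2.0 / 3.0))
        if self.pitch <= 0 or self.layer_spacing <= 0:
            raise ValueError("pitch and layer_spacing must be positive")
        if self.registration not in ("centered", "best-of-translations"):
            raise ValueError(f"unknown registration {self.registration!r}")


def _lattice_points(pitch: float, r_max: float, offset: tuple[float, float] = (0.0, 0.0)):
    """(x, y) triangular-lattice points with |p| <= r_max.

    ``offset`` is in pitch units, applied to every point.
    """
    row_h = pitch * math.sqrt(3.0) / 2.0
    ox, oy = offset[0] * pitch, offset[1] * pitch
    j_max = int(math.ceil((r_max + abs(oy)) / row_h)) + 1
    pts = []
    for j in range(-j_max, j_max + 1):
        y = j * row_h + oy
        if abs(y) > r_max:
            continue
        x_shift = (j % 2) * pitch / 2.0 + ox
        half_w = math.sqrt(max(r_max * r_max - y * y, 0.0))
        i_lo = int(math.ceil((-half_w - x_shift) / pitch))
        i_hi = int(math.floor((half_w - x_shift) / pitch))
        for i in range(i_lo, i_hi + 1):
            pts.append((i * pitch + x_shift, y))
    return pts


def count_circles_in_circle(spec: LatticeSpec, offset: tuple[float, float] = (0.0, 0.0)) -> int:
    """Number of lattice voids lying entirely inside the container, one layer.

    A void of diameter ``d`` lies entirely inside a container of diameter
    ``D`` iff its centre is within radius ``(D - d)/2`` of the centre.
    """
    if spec.void_diameter > spec.container_diameter:
        warnings.warn("void larger than container; count is 0", stacklevel=2)
        return 0
    r_max = (spec.container_diameter - spec.void_diameter) / 2.0
    if spec.registration == "centered":
        return len(_lattice_points(spec.pitch, r_max, offset))
    # best-of-translations: scan lattice offsets over one unit cell
    best = 0
    for fx in np.linspace(0.0, 0.5, 6):
        for fy in np.linspace(0.0, math.sqrt(3.0) / 4.0, 6):
            n = len(_lattice_points(spec.pitch, r_max, (offset[0] + fx, offset[1] + fy)))
            best = max(best, n)
    return best


def hcp_capacity(spec: LatticeSpec) -> dict:
    """Void capacity of the multi-layer HCP lattice.

    Returns per-layer counts (A/B registrations alternate), the total over
    ``spec.layers`` layers, the ideal HCP packing fraction, and the void
    number density in voids per microlitre.
    """
    per_layer = []
    for k in range(spec.layers):
        off = (0.0, 0.0) if k % 2 == 0 else _B_OFFSET
        per_layer.append(count_circles_in_circle(spec, offset=off))
    d = spec.void_diameter
    number_density_um3 = math.sqrt(2.0) / d**3   # ideal HCP, voids per um^3
    return {
        "per_layer": per_layer,
        "total": int(sum(per_layer)),
        "packing_fraction": HCP_PACKING_FRACTION,
        "number_density_per_uL": number_density_um3 * 1e9,
    }
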