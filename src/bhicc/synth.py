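"""Synthetic data generators with full ground truth.

Every analysis in this package is validated by generator/analyzer closure:
inputs are simulated with known ground truth and the pipeline must recover
it.  Three kinds of input are emulated:

* **Two-photon-like 3-channel volumes** of an HCP spheroid array: the
  scaffold channel (green) is bright hydrogel with dark spherical voids and
  dark cylindrical interconnecting channels; each occupied void holds a
  spheroid whose voxels emit blue (live) or red (dead), the dead fraction
  set by a Hill dose-response.  Gaussian read noise and Poisson shot noise
  are added; intensities are 12-bit-like (0-4095 scale).
* **Plate-reader well scans**: a 6x6 grid of scan points per well, each
  point reporting green/blue/red intensities whose red/blue ratio encodes
  the local dead/live volume ratio.
* **Histology channel pairs**: bivariate pixel intensities with a
  prescribed Pearson correlation, emulating trichrome red/blue channels.

All generators are deterministic given (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import HillParams, hill_response
from .packing import LatticeSpec, _B_OFFSET, _lattice_points

# 12-bit-like intensity scale; defaults chosen so the conventional
# ">2000 a.u." scaffold gate separates framework from background cleanly
INTENSITY_SCALE = 4095.0
GREEN_PLATEAU = 3000.0
GREEN_VOID = 200.0
CELL_INTENSITY = 3000.0
BACKGROUND = 100.0
DEFAULT_NOISE = {"gauss_sd": 50.0, "poisson_gain": 1.0}
DEFAULT_VOXEL_SIZE = (5.0, 5.0, 5.0)


@dataclass(frozen=True)
class VoidLattice:
    """Jittered HCP void-centre lattice.

    ``centers`` is (N, 3) in um, columns (x, y, z); ``layer_index`` gives
    the layer of each centre (0 = bottom).
    """

    centers: np.ndarray
    layer_index: np.ndarray
    spec: LatticeSpec
    jitter_sd: float
    seed: int

    def __len__(self) -> int:
        return int(self.centers.shape[0])


@dataclass(frozen=True)
class VolumeImage:
    """3-channel 3D fluorescence volume.

    Channel arrays are (z, y, x); ``voxel_size`` is (dx, dy, dz) in um.
    green = scaffold, blue = live, red = dead.
    """

    green: np.ndarray
    blue: np.ndarray
    red: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not (self.green.shape == self.blue.shape == self.red.shape):
            raise ValueError("all channels must share one shape")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self):
        return self.green.shape


@dataclass(frozen=True)
class GroundTruth:
    """Per-spheroid truth record for one simulated volume.

    ``spheroids`` columns: void_x_um, void_y_um, void_z_um, diameter_um,
    viability, dead_fraction_drawn.
    """

    spheroids: pd.DataFrame
    dose: float
    hill: HillParams
    noise: dict
    seed: int


# ---------------------------------------------------------------------------
# Lattice
# ---------------------------------------------------------------------------

def build_void_lattice(spec: LatticeSpec, jitter_sd: float = 0.0, seed: int = 0) -> VoidLattice:
    """Void centres of an HCP lattice inside the container.

    Layer ``k`` sits at ``z = k * layer_spacing``; odd layers take the B
    registration.  Isotropic Gaussian jitter of ``jitter_sd`` um is added
    to each centre.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    r_max = (spec.container_diameter - spec.void_diameter) / 2.0
    pts, layers = [], []
    if r_max < 0:
        import warnings

        warnings.warn("container too small for a single void; empty lattice", stacklevel=2)
    else:
        for k in range(spec.layers):
            off = (0.0, 0.0) if k % 2 == 0 else _B_OFFSET
            layer_pts = _lattice_points(spec.pitch, r_max, off)
            z = k * spec.layer_spacing
            pts.extend((x, y, z) for x, y in layer_pts)
            layers.extend([k] * len(layer_pts))
    centers = np.asarray(pts, dtype=float).reshape(-1, 3)
    if jitter_sd > 0 and len(centers):
        centers = centers + rng.normal(0.0, jitter_sd, size=centers.shape)
    return VoidLattice(
        centers=centers,
        layer_index=np.asarray(layers, dtype=int),
        spec=spec,
        jitter_sd=float(jitter_sd),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Volume rasterisation
# ---------------------------------------------------------------------------

def _local_box(shape, center_vox, radius_vox):
    """Clipped (z, y, x) slice tuple around a centre."""
    lo = [max(int(math.floor(c - r - 1)), 0) for c, r in zip(center_vox, radius_vox)]
    hi = [min(int(math.ceil(c + r + 2)), s) for c, r, s in zip(center_vox, radius_vox, shape)]
    return tuple(slice(a, b) for a, b in zip(lo, hi))


def _sphere_mask(shape, box, center_vox, radius_um, voxel_size_zyx):
    zz, yy, xx = np.ogrid[box[0], box[1], box[2]]
    dz = (zz - center_vox[0]) * voxel_size_zyx[0]
    dy = (yy - center_vox[1]) * voxel_size_zyx[1]
    dx = (xx - center_vox[2]) * voxel_size_zyx[2]
    return dz * dz + dy * dy + dx * dx <= radius_um * radius_um


def _carve_cylinder(green, p0, p1, radius_um, voxel_size_zyx, value):
    """Set voxels within ``radius_um`` of segment p0-p1 (um, zyx) to value."""
    vs = np.asarray(voxel_size_zyx, float)
    lo_um = np.minimum(p0, p1) - radius_um
    hi_um = np.maximum(p0, p1) + radius_um
    lo = np.maximum((lo_um / vs).astype(int) - 1, 0)
    hi = np.minimum(np.ceil(hi_um / vs).astype(int) + 2, green.shape).astype(int)
    if np.any(lo >= hi):
        return
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    zz, yy, xx = np.meshgrid(
        (np.arange(lo[0], hi[0]) + 0.0) * vs[0],
        (np.arange(lo[1], hi[1]) + 0.0) * vs[1],
        (np.arange(lo[2], hi[2]) + 0.0) * vs[2],
        indexing="ij",
    )
    pts = np.stack([zz, yy, xx], axis=-1)
    seg = p1 - p0
    seg_len2 = float(seg @ seg)
    if seg_len2 == 0:
        return
    t = np.clip(((pts - p0) @ seg) / seg_len2, 0.0, 1.0)
    closest = p0 + t[..., None] * seg
    d2 = ((pts - closest) ** 2).sum(axis=-1)
    sub = green[box]
    sub[d2 <= radius_um * radius_um] = value
    green[box] = sub


def simulate_volume(
    lattice: VoidLattice,
    diam_mean: float,
    diam_sd: float,
    dose: float,
    hill: HillParams,
    cap_diameter: float = 45.0,
    noise: dict | None = None,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    seed: int = 0,
    occupancy: float = 1.0,
    rim_death: bool = False,
) -> tuple[VolumeImage, GroundTruth]:
    """Rasterise a 3-channel volume of spheroids in the void lattice.

    The green channel is a bright plateau with dark spherical voids and
    dark cylinders (diameter ``cap_diameter``) joining neighbouring voids.
    Each occupied void holds a centred spheroid of diameter drawn from
    ``N(diam_mean, diam_sd)``; each spheroid voxel is dead with probability
    ``1 - hill_response(dose)/top`` (independently, unless ``rim_death``
    places dead voxels outermost-first), emitting red; live voxels emit
    blue.  Gaussian read noise and Poisson shot noise are then applied to
    every channel.

    Returns the volume and a per-spheroid :class:`GroundTruth`.
    """
    if diam_mean > lattice.spec.void_diameter:
        raise ValueError("mean spheroid diameter exceeds void diameter")
    noise = dict(DEFAULT_NOISE if noise is None else noise)
    rng = np.random.default_rng(seed)
    dx, dy, dz = voxel_size
    vs_zyx = (dz, dy, dx)
    void_r = lattice.spec.void_diameter / 2.0
    margin = void_r + 3 * max(voxel_size)

    if len(lattice) == 0:
        raise ValueError("empty lattice")
    c = lattice.centers
    origin = c.min(axis=0) - margin            # (x, y, z) um of voxel (0,0,0)
    extent = c.max(axis=0) - c.min(axis=0) + 2 * margin
    shape = (
        int(math.ceil(extent[2] / dz)),
        int(math.ceil(extent[1] / dy)),
        int(math.ceil(extent[0] / dx)),
    )

    green = np.full(shape, GREEN_PLATEAU, dtype=np.float32)
    blue = np.full(shape, BACKGROUND, dtype=np.float32)
    red = np.full(shape, BACKGROUND, dtype=np.float32)

    centers_zyx = np.stack(
        [(c[:, 2] - origin[2]) / dz, (c[:, 1] - origin[1]) / dy, (c[:, 0] - origin[0]) / dx],
        axis=1,
    )
    # carve voids
    for cz in centers_zyx:
        rad_vox = (void_r / dz, void_r / dy, void_r / dx)
        box = _local_box(shape, cz, rad_vox)
        mask = _sphere_mask(shape, box, cz, void_r, vs_zyx)
        sub = green[box]
        sub[mask] = GREEN_VOID
        green[box] = sub
    # carve interconnecting channels between neighbouring voids
    chan_r = cap_diameter / 2.0
    if chan_r > 0 and len(lattice) > 1:
        cutoff = 1.3 * lattice.spec.pitch
        c_um_zyx = np.stack([c[:, 2] - origin[2], c[:, 1] - origin[1], c[:, 0] - origin[0]], axis=1)
        for i in range(len(lattice)):
            d = np.linalg.norm(c_um_zyx[i + 1:] - c_um_zyx[i], axis=1)
            for j in np.nonzero(d <= cutoff)[0] + i + 1:
                _carve_cylinder(green, c_um_zyx[i], c_um_zyx[j], chan_r, vs_zyx, GREEN_VOID)

    # spheroids
    viability = float(hill_response(dose, hill)) / hill.top
    occupied = rng.random(len(lattice)) < occupancy
    records = []
    for idx in np.nonzero(occupied)[0]:
        diam = rng.normal(diam_mean, diam_sd)
        diam = float(np.clip(diam, 4 * max(voxel_size), lattice.spec.void_diameter))
        cz = centers_zyx[idx]
        rad = diam / 2.0
        rad_vox = (rad / dz, rad / dy, rad / dx)
        box = _local_box(shape, cz, rad_vox)
        mask = _sphere_mask(shape, box, cz, rad, vs_zyx)
        n_vox = int(mask.sum())
        if n_vox == 0:
            continue
        if rim_death:
            zz, yy, xx = np.ogrid[box[0], box[1], box[2]]
            r2 = (
                ((zz - cz[0]) * dz) ** 2
                + ((yy - cz[1]) * dy) ** 2
                + ((xx - cz[2]) * dx) ** 2
            )
            order = np.argsort(-np.broadcast_to(r2, mask.shape)[mask])
            n_dead = int(round((1.0 - viability) * n_vox))
            dead_flat = np.zeros(n_vox, dtype=bool)
            dead_flat[order[:n_dead]] = True
        else:
            dead_flat = rng.random(n_vox) < (1.0 - viability)
        dead_mask = np.zeros_like(mask)
        dead_mask[mask] = dead_flat
        live_mask = mask & ~dead_mask
        sub_b, sub_r = blue[box], red[box]
        sub_b[live_mask] = CELL_INTENSITY
        sub_r[dead_mask] = CELL_INTENSITY
        blue[box], red[box] = sub_b, sub_r
        records.append(
            {
                "void_x_um": c[idx, 0] - origin[0],
                "void_y_um": c[idx, 1] - origin[1],
                "void_z_um": c[idx, 2] - origin[2],
                "diameter_um": diam,
                "viability": viability,
                "dead_fraction_drawn": float(dead_flat.mean()),
            }
        )

    for arr in (green, blue, red):
        gain = noise.get("poisson_gain", 0.0)
        if gain and gain > 0:
            arr[:] = rng.poisson(np.clip(arr, 0, None) * gain).astype(np.float32) / gain
        sd = noise.get("gauss_sd", 0.0)
        if sd and sd > 0:
            arr += rng.normal(0.0, sd, size=arr.shape).astype(np.float32)
        np.clip(arr, 0.0, INTENSITY_SCALE, out=arr)

    volume = VolumeImage(green=green, blue=blue, red=red, voxel_size=(dx, dy, dz))
    truth = GroundTruth(
        spheroids=pd.DataFrame.from_records(records),
        dose=float(dose),
        hill=hill,
        noise=noise,
        seed=int(seed),
    )
    return volume, truth


# ---------------------------------------------------------------------------
# Well scans
# ---------------------------------------------------------------------------

def simulate_wellscan(
    doses,
    hill: HillParams,
    points_per_well: int = 36,
    wells_per_dose: int = 4,
    noise: dict | None = None,
    seed: int = 0,
    mask_radius_frac: float | None = None,
) -> pd.DataFrame:
    """Plate-reader well-scan table (6x6 grid per well).

    For each dose and well, ``points_per_well`` scan points report
    (FI_green, FI_blue, FI_red).  In-framework points carry green above the
    scaffold gate and a red/blue ratio equal to the local dead/live volume
    ratio ``(1 - v)/v`` with ``v = hill_response(dose)/top``, perturbed by
    per-point fill variation (``frac_sd``) and additive Gaussian read noise
    (``gauss_sd``).  ``mask_radius_frac`` optionally marks grid points
    outside that fraction of the well radius as off-framework (green below
    gate), emulating circular-well clipping of the square grid.

    Columns: well, dose_uM, point, fi_green, fi_blue, fi_red.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise ValueError("doses must be nonempty")
    noise = {"gauss_sd": 30.0, "frac_sd": 0.02, **(noise or {})}
    rng = np.random.default_rng(seed)
    side = int(round(math.sqrt(points_per_well)))
    grid = np.arange(points_per_well)
    gx = (grid % side + 0.5) / side - 0.5
    gy = (grid // side + 0.5) / side - 0.5
    in_framework = np.ones(points_per_well, dtype=bool)
    if mask_radius_frac is not None:
        in_framework = np.hypot(gx, gy) <= mask_radius_frac / 2.0

    rows = []
    for dose in doses:
        v = float(hill_response(dose, hill)) / hill.top
        for w in range(wells_per_dose):
            well_id = f"d{dose:g}_w{w}"
            live = np.clip(v + rng.normal(0.0, noise["frac_sd"], points_per_well), 1e-3, 1.0)
            dead = np.clip(1.0 - live, 0.0, 1.0)
            fi_green = np.where(in_framework, GREEN_PLATEAU, 500.0)
            fi_blue = CELL_INTENSITY * live
            fi_red = CELL_INTENSITY * dead
            g_sd = noise["gauss_sd"]
            if g_sd > 0:
                fi_green = fi_green + rng.normal(0, g_sd, points_per_well)
                fi_blue = fi_blue + rng.normal(0, g_sd, points_per_well)
                fi_red = fi_red + rng.normal(0, g_sd, points_per_well)
            for p in range(points_per_well):
                rows.append(
                    {
                        "well": well_id,
                        "dose_uM": float(dose),
                        "point": p + 1,
                        "fi_green": max(float(fi_green[p]), 0.0),
                        "fi_blue": max(float(fi_blue[p]), 0.0),
                        "fi_red": max(float(fi_red[p]), 0.0),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Histology pixels and per-spheroid viabilities
# ---------------------------------------------------------------------------

def simulate_histology(rho: float, n_pixels: int, seed: int = 0) -> pd.DataFrame:
    """Two-channel pixel table with target Pearson correlation ``rho``.

    Pixels are drawn from a bivariate normal with correlation ``rho`` and
    affinely mapped to 8-bit-like intensity scales (Pearson's R is
    affine-invariant, so the target carries through exactly).
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n_pixels)
    z2 = rho * z1 + math.sqrt(max(1.0 - rho * rho, 0.0)) * rng.standard_normal(n_pixels)
    # intensities are left unclipped: Pearson's R is exactly affine-invariant
    # only on the unbounded scale, and read noise can dip below zero anyway
    blue = 120.0 + 40.0 * z1
    red = 110.0 + 35.0 * z2
    return pd.DataFrame({"blue": blue, "red": red})


def simulate_spheroid_viabilities(
    doses,
    hill: HillParams,
    n_per_dose: int = 300,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-spheroid viability table straight from the Hill truth.

    A light-weight stand-in for full volume simulation: for each dose,
    ``n_per_dose`` spheroid viabilities ``hill_response(dose)/top + noise``
    clipped to [0, 1].  Columns: dose_uM, viability.
    """
    doses = np.asarray(doses, dtype=float)
    rng = np.random.default_rng(seed)
    frames = []
    for dose in doses:
        v = float(hill_response(dose, hill)) / hill.top
        vals = np.clip(v + rng.normal(0.0, noise_sd, n_per_dose), 0.0, 1.0)
        frames.append(pd.DataFrame({"dose_uM": dose, "viability": vals}))
    return pd.concat(frames, ignore_index=True)
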