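"""Automated high-content image processing of spheroid-array volumes.

The pipeline mirrors how a screening microscopist would read these
volumes: void spaces are located from the scaffold (green) channel, where
they appear as dark quasi-periodic spheres of known diameter; within each
void the spheroid contour is delineated by thresholding the OR-merge of
the live (blue) and dead (red) channels — deliberately independent of
viability — and per-voxel viability is then the complement of the dead
fraction inside the contour.  Spheroid size is the maximum over z of the
per-slice equivalent-circle diameter.

Results are emitted as per-spheroid records and as a "circle map": a 2D
summary placing each spheroid at its (x, y) location with its diameter and
a viability colour.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label

from . import mechanics
from .synth import VolumeImage, _local_box


@dataclass(frozen=True)
class RegionOfInterest:
    """A void space: candidate spheroid site."""

    id: int
    center: tuple[float, float, float]   # (x, y, z) um
    radius: float                        # um
    center_vox: tuple[int, int, int]     # (z, y, x) voxel indices


@dataclass(frozen=True)
class SpheroidRecord:
    """Per-spheroid readout: location, size, viability."""

    roi_id: int
    center: tuple[float, float, float]   # (x, y, z) um
    diameter: float                      # um, nan if empty
    contour_voxels: int
    dead_voxels: int
    viability: float                     # nan if empty
    flags: str = ""

    def __post_init__(self) -> None:
        if self.contour_voxels > 0:
            if self.dead_voxels > self.contour_voxels:
                raise ValueError("dead voxels cannot exceed contour voxels")
            if not 0.0 <= self.viability <= 1.0:
                raise ValueError("viability must lie in [0, 1]")


@dataclass(frozen=True)
class CircleMap:
    """Circle-map summary: one (x, y, diameter, viability, color) per spheroid."""

    entries: pd.DataFrame
    colormap: str = "RdYlBu"

    def __post_init__(self) -> None:
        required = {"x_um", "y_um", "diameter_um", "viability", "color"}
        if not required.issubset(self.entries.columns):
            raise ValueError(f"circle map requires columns {sorted(required)}")


def _threshold(values: np.ndarray, method) -> float:
    """Resolve a threshold spec: 'otsu' or ('fixed', value) / 'fixed:<v>'."""
    if isinstance(method, str) and method.startswith("fixed:"):
        return float(method.split(":", 1)[1])
    if isinstance(method, tuple) and method[0] == "fixed":
        return float(method[1])
    if method == "otsu":
        if np.ptp(values) == 0:
            return float(values.flat[0]) + 1.0   # nothing exceeds it
        return float(threshold_otsu(values))
    raise ValueError(f"unknown threshold method {method!r}")


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------

def detect_voids(
    green: np.ndarray,
    expected_diameter: float,
    voxel_size: tuple[float, float, float],
) -> list[RegionOfInterest]:
    """Locate void spaces as local minima of the smoothed scaffold channel.

    The green channel is Gaussian-smoothed at about a quarter of the void
    diameter, inverted, and candidate centres are intensity peaks at least
    ``expected_diameter / 2`` apart whose smoothed intensity is darker than
    the midpoint of the smoothed dynamic range.
    """
    dx, dy, dz = voxel_size
    if expected_diameter < 4 * min(voxel_size):
        raise ValueError("expected_diameter must span at least 4 voxels")
    sigma_um = expected_diameter / 4.0
    sigma = (sigma_um / dz, sigma_um / dy, sigma_um / dx)
    smooth = ndimage.gaussian_filter(np.asarray(green, dtype=np.float32), sigma)
    if np.ptp(smooth) < 1e-6:
        warnings.warn("uniform scaffold channel; no voids detected", stacklevel=2)
        return []
    inverted = smooth.max() - smooth
    min_dist_vox = max(int(expected_diameter / 2.0 / max(voxel_size)), 1)
    cutoff = smooth.min() + 0.5 * np.ptp(smooth)   # centres must be dark
    peaks = peak_local_max(
        inverted,
        min_distance=min_dist_vox,
        threshold_abs=float(smooth.max() - cutoff),
        exclude_border=False,
    )
    # refine each peak to the maximum of the euclidean distance transform
    # of the dark phase inside its neighbourhood: the void centre is the
    # centre of the inscribed dark sphere, which channels and boundary
    # neighbours cannot displace the way they displace the smoothed minimum
    lightly = ndimage.gaussian_filter(np.asarray(green, dtype=np.float32), 1.0)
    dark = lightly < cutoff
    edt = ndimage.distance_transform_edt(dark, sampling=(dz, dy, dx))
    r_ref = 0.6 * expected_diameter / 2.0
    rois = []
    for i, (pz, py, px) in enumerate(peaks):
        box = _local_box(green.shape, (pz, py, px), (r_ref / dz, r_ref / dy, r_ref / dx))
        zz, yy, xx = np.ogrid[box[0], box[1], box[2]]
        ball = (
            ((zz - pz) * dz) ** 2 + ((yy - py) * dy) ** 2 + ((xx - px) * dx) ** 2
        ) <= r_ref**2
        local = np.where(ball, edt[box], -1.0)
        if local.max() > 0:
            # average over the argmax plateau to kill voxel-grid bias
            plateau = np.argwhere(local >= local.max() - max(dx, dy, dz) / 2)
            cz, cy, cx = plateau.mean(axis=0) + [box[0].start, box[1].start, box[2].start]
        else:
            cz, cy, cx = float(pz), float(py), float(px)
        rois.append(
            RegionOfInterest(
                id=i,
                center=(cx * dx, cy * dy, cz * dz),
                radius=expected_diameter / 2.0,
                center_vox=(int(round(cz)), int(round(cy)), int(round(cx))),
            )
        )
    return rois


def _roi_box(shape, roi: RegionOfInterest, voxel_size):
    dx, dy, dz = voxel_size
    rad_vox = (roi.radius / dz, roi.radius / dy, roi.radius / dx)
    lo = [max(int(np.floor(c - r)), 0) for c, r in zip(roi.center_vox, rad_vox)]
    hi = [
        min(int(np.ceil(c + r)) + 1, s)
        for c, r, s in zip(roi.center_vox, rad_vox, shape)
    ]
    return tuple(slice(a, b) for a, b in zip(lo, hi))


def segment_spheroid(
    red: np.ndarray,
    blue: np.ndarray,
    roi: RegionOfInterest,
    voxel_size: tuple[float, float, float],
    threshold_method="otsu",
) -> tuple[np.ndarray, tuple]:
    """Spheroid contour inside one ROI from the OR-merged red/blue channels.

    The merge is the voxelwise maximum of red and blue, so the contour is
    independent of the live/dead split.  Voxels inside the ROI sphere whose
    merged intensity exceeds the threshold form the candidate mask; the
    largest connected component is kept.  Returns ``(mask, box)`` where
    ``box`` is the (z, y, x) slice tuple the mask lives in; the mask is
    empty when no spheroid is present (flagged downstream, not raised).
    """
    dx, dy, dz = voxel_size
    box = _roi_box(red.shape, roi, voxel_size)
    merged = np.maximum(red[box], blue[box]).astype(np.float32)
    zz, yy, xx = np.ogrid[box[0], box[1], box[2]]
    inside = (
        ((zz - roi.center_vox[0]) * dz) ** 2
        + ((yy - roi.center_vox[1]) * dy) ** 2
        + ((xx - roi.center_vox[2]) * dx) ** 2
    ) <= roi.radius**2
    thr = _threshold(merged[inside], threshold_method)
    mask = inside & (merged > thr)
    if not mask.any():
        return mask, box
    lab, n = label(mask, return_num=True, connectivity=1)
    if n > 1:
        counts = np.bincount(lab.ravel())[1:]
        mask = lab == (int(np.argmax(counts)) + 1)
    return mask, box


def score_viability(
    red: np.ndarray,
    blue: np.ndarray,
    mask: np.ndarray,
    box: tuple,
    threshold_method="otsu",
) -> tuple[float, int]:
    """Viability = 1 - dead-voxel fraction of the contour.

    The red channel is thresholded within the contour and compared to the
    red-blue merge: a dead voxel is one whose red intensity exceeds the
    threshold.  Otsu on a unimodal red distribution (all-live or all-dead
    spheroid) would split pure noise, so when the two implied classes are
    not separated the contour is scored all-dead or all-live by whether
    red carries the bulk of the merged signal.  Returns
    ``(viability, dead_voxels)``; viability is nan for an empty mask.
    """
    if not mask.any():
        return float("nan"), 0
    red_in = np.asarray(red[box], dtype=np.float32)[mask]
    merged_in = np.maximum(red_in, np.asarray(blue[box], dtype=np.float32)[mask])
    all_dead = red_in.mean() > 0.5 * merged_in.mean()
    if np.ptp(red_in) == 0:
        dead = int(red_in.size) if all_dead else 0
        return 1.0 - dead / mask.sum(), dead
    thr = _threshold(red_in, threshold_method)
    dead = int((red_in > thr).sum())
    lo, hi = red_in[red_in <= thr], red_in[red_in > thr]
    if threshold_method == "otsu" and lo.size and hi.size:
        if (hi.mean() - lo.mean()) < 4 * max(lo.std(), hi.std(), 1e-6):
            dead = int(red_in.size) if all_dead else 0
    return 1.0 - dead / mask.sum(), dead


def measure_spheroid_diameter(mask: np.ndarray, voxel_size) -> float:
    """Maximum over z of the per-slice equivalent-circle diameter, in um.

    Each z slice contributes ``2*sqrt(area/pi)`` from its in-plane voxel
    area; the largest such diameter is the spheroid diameter.
    """
    if not mask.any():
        raise ValueError("empty mask has no diameter")
    dx, dy, _ = voxel_size
    areas = mask.sum(axis=(1, 2)).astype(float) * dx * dy
    return float(2.0 * np.sqrt(areas.max() / np.pi))


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def process_volume(
    volume: VolumeImage,
    expected_diameter: float = 250.0,
    threshold_method="otsu",
    viability_colormap: str = "RdYlBu",
    log=None,
) -> tuple[list[SpheroidRecord], CircleMap]:
    """Full high-content pipeline: detect -> segment -> score -> measure.

    Failures at a single ROI are recorded as flags on that record, never
    raised.  Returns the spheroid records and the circle map.
    """
    dxyz = volume.voxel_size
    rois = detect_voids(volume.green, expected_diameter, dxyz)
    records = []
    for roi in rois:
        t0 = time.perf_counter()
        mask, box = segment_spheroid(volume.red, volume.blue, roi, dxyz, threshold_method)
        if not mask.any():
            records.append(
                SpheroidRecord(
                    roi_id=roi.id, center=roi.center, diameter=float("nan"),
                    contour_voxels=0, dead_voxels=0, viability=float("nan"),
                    flags="no_spheroid",
                )
            )
            continue
        viability, dead = score_viability(volume.red, volume.blue, mask, box, threshold_method)
        diameter = measure_spheroid_diameter(mask, dxyz)
        records.append(
            SpheroidRecord(
                roi_id=roi.id, center=roi.center, diameter=diameter,
                contour_voxels=int(mask.sum()), dead_voxels=dead,
                viability=viability,
            )
        )
        if log is not None:
            log.debug(
                "roi %d: %d voxels, viability %.3f, %.3f s",
                roi.id, int(mask.sum()), viability, time.perf_counter() - t0,
            )
    cmap = build_circle_map(records, colormap=viability_colormap)
    return records, cmap


def build_circle_map(records: list[SpheroidRecord], colormap: str = "RdYlBu") -> CircleMap:
    """Circle-map table from spheroid records (one entry per record)."""
    from matplotlib import cm, colors as mcolors

    mappable = cm.ScalarMappable(norm=mcolors.Normalize(0, 1), cmap=colormap)
    rows = []
    for r in records:
        v = r.viability
        color = mcolors.to_hex(mappable.to_rgba(v)) if np.isfinite(v) else "#808080"
        rows.append(
            {
                "roi_id": r.roi_id,
                "x_um": r.center[0],
                "y_um": r.center[1],
                "diameter_um": r.diameter,
                "viability": v,
                "color": color,
            }
        )
    df = pd.DataFrame(
        rows, columns=["roi_id", "x_um", "y_um", "diameter_um", "viability", "color"]
    )
    return CircleMap(entries=df, colormap=colormap)


def records_to_frame(records: list[SpheroidRecord]) -> pd.DataFrame:
    """Tabular form of spheroid records (stable CSV schema)."""
    return pd.DataFrame(
        [
            {
                "roi_id": r.roi_id,
                "x_um": r.center[0],
                "y_um": r.center[1],
                "z_um": r.center[2],
                "diameter_um": r.diameter,
                "contour_voxels": r.contour_voxels,
                "dead_voxels": r.dead_voxels,
                "viability": r.viability,
                "flags": r.flags,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# 2D lattice metrics (microgel assembly images)
# ---------------------------------------------------------------------------

def hcp_lattice_metrics(centers: np.ndarray, r: float, pitch: float | None = None) -> dict:
    """Centre-to-centre distance and cap-diameter statistics of a 2D lattice.

    For each point, in-plane neighbours within ``1.3 * pitch`` (up to the 6
    hexagonal contacts) define the pair set; mutual pairs are deduplicated.
    Each pair distance ``Di`` yields a cap diameter through the contact
    relation ``Rcap = sqrt(R^2 - Di^2)`` (pairs with ``Di > R`` contribute
    no cap).  ``pitch`` defaults to ``r``.
    """
    pts = np.asarray(centers, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 points")
    pitch = r if pitch is None else pitch
    cutoff = 1.3 * pitch
    di = []
    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    pairs = tree.query_pairs(cutoff)
    for i, j in sorted(pairs):
        di.append(float(np.linalg.norm(pts[i] - pts[j])))
    if not di:
        raise ValueError("no neighbour pairs within cutoff")
    di = np.asarray(di)
    rcaps = np.array([mechanics.cap_diameter(r, d) for d in di[di <= r]])
    return {
        "di_mean": float(di.mean()),
        "di_sd": float(di.std(ddof=1)) if di.size > 1 else 0.0,
        "di_over_r_mean": float((di / r).mean()),
        "di_over_r_sd": float((di / r).std(ddof=1)) if di.size > 1 else 0.0,
        "rcap_per_pair": rcaps,
        "rcap_mean": float(rcaps.mean()) if rcaps.size else float("nan"),
        "rcap_sd": float(rcaps.std(ddof=1)) if rcaps.size > 1 else 0.0,
        "n_pairs": int(di.size),
    }
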