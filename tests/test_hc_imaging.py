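"""High-content imaging pipeline: closure against generator ground truth."""

import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

from bhicc.dose_response import HillParams
from bhicc.hc_imaging import (
    RegionOfInterest,
    build_circle_map,
    detect_voids,
    hcp_lattice_metrics,
    measure_spheroid_diameter,
    process_volume,
    records_to_frame,
    score_viability,
    segment_spheroid,
)
from bhicc.mechanics import cap_diameter
from bhicc.packing import LatticeSpec
from bhicc.synth import build_void_lattice, simulate_volume

NOISELESS = {"gauss_sd": 0.0, "poisson_gain": 0.0}
VOX = (5.0, 5.0, 5.0)


def _match(detected, truth_xyz, tol):
    """greedy matching of detected centres to truth within tol; returns recall, precision."""
    if len(detected) == 0:
        return 0.0, 0.0
    tree = cKDTree(truth_xyz)
    d, idx = tree.query(detected)
    hit = d <= tol
    recall = len(set(idx[hit])) / len(truth_xyz)
    precision = hit.sum() / len(detected)
    return recall, precision


def _synthetic_ball(radius_um, vox=VOX, pad=3, intensity=3000.0):
    """Digital sphere in a padded box: (red, blue, roi)."""
    dx, dy, dz = vox
    n = int(2 * radius_um / dx) + 2 * pad + 1
    c = n // 2
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
    r2 = ((zz - c) * dz) ** 2 + ((yy - c) * dy) ** 2 + ((xx - c) * dx) ** 2
    ball = r2 <= radius_um**2
    blue = np.where(ball, intensity, 100.0)
    red = np.full_like(blue, 100.0)
    roi = RegionOfInterest(
        id=0, center=(c * dx, c * dy, c * dz), radius=radius_um + 2 * dx,
        center_vox=(c, c, c),
    )
    return red, blue, roi


class TestDetectVoids:
    def test_noiseless_centers_within_one_voxel(self, small_lattice, noiseless_volume):
        vol, truth = noiseless_volume
        rois = detect_voids(vol.green, 250.0, vol.voxel_size)
        assert len(rois) == len(truth.spheroids)
        detected = np.array([r.center for r in rois])
        truth_xyz = truth.spheroids[["void_x_um", "void_y_um", "void_z_um"]].to_numpy()
        recall, precision = _match(detected, truth_xyz, tol=math.sqrt(3) * 5.0)
        assert recall == 1.0 and precision == 1.0

    def test_uniform_image_empty(self):
        with pytest.warns(UserWarning):
            rois = detect_voids(np.full((20, 40, 40), 3000.0), 50.0, VOX)
        assert rois == []

    def test_noisy_recall_precision(self, noisy_volume):
        vol, truth = noisy_volume
        rois = detect_voids(vol.green, 250.0, vol.voxel_size)
        detected = np.array([r.center for r in rois])
        truth_xyz = truth.spheroids[["void_x_um", "void_y_um", "void_z_um"]].to_numpy()
        recall, precision = _match(detected, truth_xyz, tol=125.0)
        assert recall >= 0.95
        assert precision >= 0.95


class TestSegmentSpheroid:
    def test_volume_matches_sphere(self):
        red, blue, roi = _synthetic_ball(90.0)
        mask, _ = segment_spheroid(red, blue, roi, VOX)
        expected = 4 / 3 * math.pi * 90.0**3 / (5.0**3)
        assert mask.sum() == pytest.approx(expected, rel=0.05)

    def test_empty_void_flagged_not_raised(self):
        red = np.full((30, 30, 30), 100.0)
        blue = np.full((30, 30, 30), 100.0)
        roi = RegionOfInterest(id=0, center=(75, 75, 75), radius=60.0, center_vox=(15, 15, 15))
        mask, _ = segment_spheroid(red, blue, roi, VOX)
        assert not mask.any()

    def test_or_gate_contour_invariance(self, rng):
        # moving voxels from blue to red must not change the contour
        red, blue, roi = _synthetic_ball(80.0)
        mask_live, _ = segment_spheroid(red, blue, roi, VOX)
        inside = blue > 1000
        flip = rng.random(inside.sum()) < 0.5
        red2, blue2 = red.copy(), blue.copy()
        vals = blue2[inside]
        red2[inside] = np.where(flip, vals, red2[inside])
        blue2[inside] = np.where(flip, 100.0, vals)
        mask_half, _ = segment_spheroid(red2, blue2, roi, VOX)
        assert np.array_equal(mask_live, mask_half)


class TestScoreViability:
    def test_extremes(self, rng):
        red, blue, roi = _synthetic_ball(60.0)
        mask, box = segment_spheroid(red, blue, roi, VOX)
        v, dead = score_viability(red, blue, mask, box)
        assert v == 1.0 and dead == 0
        # all dead: red carries the whole signal
        v, dead = score_viability(blue, red, mask, box)
        assert v == 0.0 and dead == mask.sum()

    def test_known_dead_fraction(self, rng):
        red, blue, roi = _synthetic_ball(80.0)
        inside = blue > 1000
        kill = rng.random(inside.sum()) < 0.30
        vals = blue[inside]
        red[inside] = np.where(kill, vals, 100.0)
        blue[inside] = np.where(kill, 100.0, vals)
        mask, box = segment_spheroid(red, blue, roi, VOX)
        v, _ = score_viability(red, blue, mask, box)
        assert v == pytest.approx(0.70, abs=0.02)

    def test_empty_mask_undefined(self):
        red = np.zeros((5, 5, 5))
        v, dead = score_viability(red, red, np.zeros((5, 5, 5), bool), (slice(None),) * 3)
        assert math.isnan(v) and dead == 0


class TestMeasureDiameter:
    def test_digital_sphere(self):
        red, blue, roi = _synthetic_ball(90.0)
        mask, _ = segment_spheroid(red, blue, roi, VOX)
        assert measure_spheroid_diameter(mask, VOX) == pytest.approx(180.0, abs=5.0)

    def test_oblate_ellipsoid_reports_equator(self):
        zz, yy, xx = np.mgrid[0:50, 0:60, 0:60]
        mask = (
            ((zz - 25) * 5.0 / 50.0) ** 2
            + ((yy - 30) * 5.0 / 100.0) ** 2
            + ((xx - 30) * 5.0 / 100.0) ** 2
        ) <= 1.0
        assert measure_spheroid_diameter(mask, VOX) == pytest.approx(200.0, abs=5.0)

    def test_single_voxel(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        expected = 2 * math.sqrt(25.0 / math.pi)
        assert measure_spheroid_diameter(mask, VOX) == pytest.approx(expected)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            measure_spheroid_diameter(np.zeros((3, 3, 3), bool), VOX)


class TestProcessVolume:
    def test_closure_viability_and_diameter(self, noisy_volume):
        vol, truth = noisy_volume
        records, cmap = process_volume(vol, expected_diameter=250.0)
        frame = records_to_frame(records)
        scored = frame.dropna(subset=["viability"])
        assert len(scored) == len(truth.spheroids)
        # match by position to compare per-spheroid values
        tree = cKDTree(truth.spheroids[["void_x_um", "void_y_um", "void_z_um"]].to_numpy())
        _, idx = tree.query(scored[["x_um", "y_um", "z_um"]].to_numpy())
        truth_v = truth.spheroids["viability"].to_numpy()[idx]
        mae = np.abs(scored["viability"].to_numpy() - truth_v).mean()
        assert mae <= 0.05
        truth_d = truth.spheroids["diameter_um"].to_numpy()[idx]
        assert np.abs(scored["diameter_um"].to_numpy() - truth_d).mean() <= 5.0

    def test_circle_map_one_entry_per_record(self, noisy_volume):
        vol, _ = noisy_volume
        records, cmap = process_volume(vol, expected_diameter=250.0)
        assert len(cmap.entries) == len(records)
        assert cmap.entries["viability"].dropna().between(0, 1).all()

    def test_circle_map_roundtrip(self, tmp_path, noisy_volume):
        import pandas as pd

        vol, _ = noisy_volume
        _, cmap = process_volume(vol, expected_diameter=250.0)
        p = tmp_path / "cmap.csv"
        cmap.entries.to_csv(p, index=False)
        back = pd.read_csv(p)
        pd.testing.assert_frame_equal(back, cmap.entries, check_exact=False, rtol=1e-12)

    def test_dose_series_monotone(self, small_lattice):
        hill = HillParams(ic50=20.0, n=2.0)
        means = []
        for i, dose in enumerate([0.0, 20.0, 200.0]):
            vol, _ = simulate_volume(
                small_lattice, 179.2, 9.76, dose, hill, seed=21 + i
            )
            records, _ = process_volume(vol, expected_diameter=250.0)
            frame = records_to_frame(records)
            means.append(frame["viability"].mean())
        assert means[0] > means[1] > means[2]


class TestLatticeMetrics:
    @staticmethod
    def _hex_points(pitch, n=5):
        pts = []
        for j in range(-n, n + 1):
            for i in range(-n, n + 1):
                pts.append((i * pitch + (j % 2) * pitch / 2, j * pitch * math.sqrt(3) / 2))
        return np.asarray(pts)

    def test_perfect_lattice(self):
        pts = self._hex_points(100.0)
        m = hcp_lattice_metrics(pts, r=100.0)
        assert m["di_over_r_mean"] == pytest.approx(1.0)
        assert m["di_over_r_sd"] == pytest.approx(0.0, abs=1e-12)
        assert m["rcap_mean"] == pytest.approx(0.0, abs=1e-6)

    def test_compressed_lattice_recovers_generator_ratio(self):
        rng = np.random.default_rng(8)
        r = 250.0
        pts = self._hex_points(0.932 * r, n=6)
        pts = pts + rng.normal(0, 0.5, pts.shape)
        m = hcp_lattice_metrics(pts, r=r, pitch=0.932 * r)
        assert m["di_over_r_mean"] == pytest.approx(0.932, abs=0.005)

    def test_jensen_gap_on_jittered_lattice(self):
        # Rcap is concave in Di near contact, so mean per-pair Rcap differs
        # from Rcap at the mean Di; brute-force both sides
        rng = np.random.default_rng(9)
        r = 250.0
        pts = self._hex_points(0.95 * r, n=6) + rng.normal(0, 2.0, (169, 2))
        m = hcp_lattice_metrics(pts, r=r, pitch=0.95 * r)
        di_mean = m["di_over_r_mean"] * r
        assert m["rcap_mean"] != pytest.approx(cap_diameter(r, di_mean), abs=1e-3)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            hcp_lattice_metrics(np.array([[0.0, 0.0]]), r=1.0)
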