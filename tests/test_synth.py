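"""Generators: lattice, volumes, well scans, histology pixels."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare, pearsonr

from bhicc.dose_response import HillParams
from bhicc.packing import LatticeSpec, count_circles_in_circle
from bhicc.synth import (
    build_void_lattice,
    simulate_histology,
    simulate_spheroid_viabilities,
    simulate_volume,
    simulate_wellscan,
)

NOISELESS = {"gauss_sd": 0.0, "poisson_gain": 0.0}


class TestVoidLattice:
    def test_counts_match_packing_enumeration(self):
        spec = LatticeSpec(void_diameter=1.0, container_diameter=3.0)
        lat = build_void_lattice(spec, jitter_sd=0.0, seed=0)
        assert len(lat) == 7 == count_circles_in_circle(spec)

    def test_layer_spacing_default(self):
        spec = LatticeSpec(void_diameter=100.0, container_diameter=400.0, layers=3)
        lat = build_void_lattice(spec, seed=0)
        z = np.unique(lat.centers[:, 2])
        assert np.allclose(np.diff(z), 100.0 * math.sqrt(2.0 / 3.0))
        assert spec.layer_spacing == pytest.approx(0.8165 * spec.pitch, rel=1e-4)

    def test_deterministic_given_seed(self):
        spec = LatticeSpec(void_diameter=100.0, container_diameter=600.0)
        a = build_void_lattice(spec, jitter_sd=3.0, seed=5)
        b = build_void_lattice(spec, jitter_sd=3.0, seed=5)
        assert np.array_equal(a.centers, b.centers)

    def test_nearest_neighbour_distance_with_jitter(self):
        from scipy.spatial import cKDTree

        spec = LatticeSpec(void_diameter=100.0, container_diameter=1200.0)
        lat = build_void_lattice(spec, jitter_sd=2.0, seed=3)
        d, _ = cKDTree(lat.centers).query(lat.centers, k=2)
        nn = d[:, 1]
        assert np.all(np.abs(nn - spec.pitch) < 3 * 2.0 * 2)  # pairs add 2 jitters

    def test_too_small_container_warns_empty(self):
        with pytest.warns(UserWarning):
            lat = build_void_lattice(
                LatticeSpec(void_diameter=10.0, container_diameter=9.0), seed=0
            )
        assert len(lat) == 0


class TestSimulateVolume:
    def test_zero_dose_all_live(self, small_lattice):
        hill = HillParams(ic50=20.0, n=1.0)
        vol, truth = simulate_volume(
            small_lattice, 179.2, 9.76, dose=0.0, hill=hill, noise=NOISELESS, seed=1
        )
        assert float(vol.red.max()) <= 200.0  # background only, no dead voxels
        assert np.all(truth.spheroids["viability"] == 1.0)
        assert np.all(truth.spheroids["dead_fraction_drawn"] == 0.0)

    def test_midpoint_dose_half_dead(self, small_lattice):
        hill = HillParams(ic50=20.0, n=3.0)
        vol, truth = simulate_volume(
            small_lattice, 179.2, 9.76, dose=20.0, hill=hill, noise=NOISELESS, seed=2
        )
        fractions = truth.spheroids["dead_fraction_drawn"].to_numpy()
        # binomial error per spheroid at ~20k voxels is ~0.004; allow 5 sd
        assert np.all(np.abs(fractions - 0.5) < 0.02)

    def test_dead_counts_binomial(self, small_lattice):
        # chi-square of per-spheroid dead counts against Binomial(n_i, 0.3)
        hill = HillParams(ic50=30.0, n=1.0)
        dose = 30.0 * 3.0 / 7.0  # viability 0.7
        _, truth = simulate_volume(
            small_lattice, 179.2, 9.76, dose=dose, hill=hill, noise=NOISELESS, seed=3
        )
        f = truth.spheroids["dead_fraction_drawn"].to_numpy()
        # normalised deviates should be standard normal; chi-square on their
        # squares with dof = n spheroids
        r_vox = (truth.spheroids["diameter_um"] / 2 / 5.0) ** 3 * 4 / 3 * math.pi
        z = (f - 0.3) / np.sqrt(0.3 * 0.7 / r_vox)
        stat = float((z**2).sum())
        from scipy.stats import chi2

        assert chi2.sf(stat, df=z.size) > 1e-4

    def test_green_periodic_along_z(self):
        spec = LatticeSpec(void_diameter=80.0, container_diameter=300.0, layers=4)
        lat = build_void_lattice(spec, seed=1)
        hill = HillParams(ic50=20.0, n=1.0)
        vol, _ = simulate_volume(
            lat, 50.0, 2.0, dose=0.0, hill=hill, cap_diameter=20.0,
            noise=NOISELESS, voxel_size=(4.0, 4.0, 4.0), seed=4,
        )
        profile = vol.green.mean(axis=(1, 2))
        profile = profile - profile.mean()
        ac = np.correlate(profile, profile, mode="full")[profile.size - 1:]
        # first non-trivial autocorrelation peak at the layer spacing
        expected_lag = spec.layer_spacing / 4.0
        lo = int(expected_lag * 0.6)
        peak = lo + int(np.argmax(ac[lo: int(expected_lag * 1.5)]))
        assert abs(peak - expected_lag) <= 2

    def test_deterministic(self, small_lattice):
        hill = HillParams(ic50=20.0, n=1.0)
        v1, t1 = simulate_volume(small_lattice, 179.2, 9.76, 10.0, hill, seed=9)
        v2, t2 = simulate_volume(small_lattice, 179.2, 9.76, 10.0, hill, seed=9)
        assert np.array_equal(v1.green, v2.green)
        assert np.array_equal(v1.red, v2.red)
        assert t1.spheroids.equals(t2.spheroids)

    def test_oversized_spheroid_rejected(self, small_lattice):
        with pytest.raises(ValueError):
            simulate_volume(small_lattice, 300.0, 1.0, 0.0, HillParams(ic50=1.0, n=1.0))


class TestWellScan:
    def test_row_count(self):
        scan = simulate_wellscan([0, 10, 20], HillParams(ic50=20.0, n=1.0), seed=0)
        assert len(scan) == 3 * 4 * 36
        assert set(scan.columns) == {"well", "dose_uM", "point", "fi_green", "fi_blue", "fi_red"}
        per_dose = scan.groupby("dose_uM").size()
        assert (per_dose == 144).all()

    def test_noiseless_points_identical(self):
        scan = simulate_wellscan(
            [50.0], HillParams(ic50=20.0, n=1.0),
            noise={"gauss_sd": 0.0, "frac_sd": 0.0}, seed=0,
        )
        assert scan["fi_red"].nunique() == 1
        assert scan["fi_blue"].nunique() == 1

    def test_ratio_monotone_in_dose(self):
        scan = simulate_wellscan(
            [0, 10, 20, 50, 100, 200], HillParams(ic50=25.0, n=1.3), seed=1
        )
        ratio = (scan["fi_red"] / scan["fi_blue"].clip(lower=1e-9)).groupby(scan["dose_uM"]).mean()
        assert ratio.is_monotonic_increasing

    def test_mask_pushes_corner_points_below_gate(self):
        scan = simulate_wellscan(
            [0.0], HillParams(ic50=20.0, n=1.0), seed=2, mask_radius_frac=1.0
        )
        out = scan[scan["fi_green"] < 2000]
        assert 0 < len(out) < len(scan)


class TestHistology:
    def test_rho_one_is_affine(self):
        df = simulate_histology(1.0, 1000, seed=0)
        r = pearsonr(df["blue"], df["red"]).statistic
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_rho_zero_uncorrelated(self):
        df = simulate_histology(0.0, 100_000, seed=1)
        assert abs(pearsonr(df["blue"], df["red"]).statistic) < 0.01

    @pytest.mark.parametrize("rho", [0.649, 0.856, 0.933])
    def test_target_correlations_recovered(self, rho):
        df = simulate_histology(rho, 100_000, seed=2)
        assert pearsonr(df["blue"], df["red"]).statistic == pytest.approx(rho, abs=0.005)

    def test_invalid_rho(self):
        with pytest.raises(ValueError):
            simulate_histology(1.5, 100)


def test_viability_table_structure():
    hill = HillParams(ic50=20.0, n=2.0)
    df = simulate_spheroid_viabilities([0, 10, 20, 50], hill, n_per_dose=50, seed=0)
    assert len(df) == 200
    assert df["viability"].between(0, 1).all()
    med = df.groupby("dose_uM")["viability"].median()
    assert med.is_monotonic_decreasing
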