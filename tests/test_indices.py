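"""Vegetation-index registry and spectral operators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import gaussian_filter1d
from scipy.stats import spearmanr

from hyperspad.errors import HyperspadError, UndefinedResultError
from hyperspad.indices import (
    GROUPS,
    SpectrumContext,
    compute_all,
    compute_index,
    continuum_removal,
    default_registry,
    derivative_spectrum,
    red_edge_position,
    registry_wavelengths,
    sample_band,
    vi_cube,
)
from hyperspad.preprocess import FWHM_TO_SIGMA, gaussian_resample
from hyperspad.spectral_io import ReflectanceCube
from hyperspad.synth_field import (
    WAVELENGTHS_1NM,
    simulate_leaf_spectrum,
)


def by_name(registry):
    return {d.name: d for d in registry}


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------

class TestRegistryStructure:
    def test_sixty_indices_nine_groups(self, registry):
        assert len(registry) == 60
        present = {d.group for d in registry}
        assert present == set(GROUPS)

    def test_unique_band_union_is_145(self, registry, sensor):
        assert registry_wavelengths(registry, sensor).size == 145

    def test_set_semantics_of_wavelength_union(self, registry, sensor):
        ndvi = by_name(registry)["NDVI"]
        sri = by_name(registry)["SRI"]
        assert registry_wavelengths([ndvi], sensor).size == 2
        # NDVI and SRI share both bands: union still counts each once
        assert registry_wavelengths([ndvi, sri], sensor).size == 2


# ---------------------------------------------------------------------------
# Operators
# ---------------------------------------------------------------------------

class TestSampleBand:
    def test_snaps_to_nearest_center(self, sensor, rng):
        spec = rng.random(272)
        v = sample_band(spec, sensor.band_centers, 550.9)
        assert v == spec[sensor.nearest_band(550.9)]

    def test_exact_center(self, sensor, rng):
        spec = rng.random(272)
        c = sensor.band_centers[100]
        assert sample_band(spec, sensor.band_centers, c) == spec[100]

    def test_outside_span_rejected(self, sensor, rng):
        with pytest.raises(HyperspadError):
            sample_band(rng.random(272), sensor.band_centers, 399.0)


class TestDerivative:
    def test_linear_ramp_slope(self):
        w = WAVELENGTHS_1NM
        d = derivative_spectrum(0.001 * w, w)
        assert np.allclose(d[30:-30], 0.001, atol=1e-10)

    def test_constant_zero(self):
        w = WAVELENGTHS_1NM
        assert np.allclose(derivative_spectrum(np.full(w.size, 0.4), w), 0,
                           atol=1e-12)

    def test_sine_matches_analytic_cosine(self):
        """SG derivative of a slow sine tracks the analytic cosine (the
        25-point quadratic window attenuates the amplitude by ~1.5%)."""
        w = WAVELENGTHS_1NM
        period = 200.0
        amp = 2 * np.pi / period
        y = np.sin(2 * np.pi * w / period)
        d = derivative_spectrum(y, w)
        expected = amp * np.cos(2 * np.pi * w / period)
        assert np.allclose(d[40:-40], expected[40:-40], atol=0.02 * amp)

    def test_too_short_rejected(self):
        with pytest.raises(HyperspadError):
            derivative_spectrum(np.ones(5), np.arange(5.0))


class TestContinuumRemoval:
    def test_linear_spectrum_is_its_own_hull(self):
        w = np.arange(600.0, 701.0)
        spec = 0.2 + 0.001 * (w - 600.0)
        _, cr, depth = continuum_removal(spec, w, (600, 700))
        assert np.allclose(cr, 1.0, atol=1e-12)
        assert np.allclose(depth, 0.0, atol=1e-12)

    def test_v_absorption_hand_geometry(self):
        """V-shaped dip of depth d on a linear continuum: maximum band
        depth equals d / hull(vertex), computed by hand."""
        w = np.arange(600.0, 701.0)
        cont = 0.3 + 0.001 * (w - 600.0)
        spec = cont.copy()
        vertex = 50                          # 650 nm
        dip = 0.1
        tri = dip * np.maximum(0.0, 1.0 - np.abs(w - 650.0) / 20.0)
        spec -= tri
        _, cr, depth = continuum_removal(spec, w, (600, 700))
        hull_at_vertex = cont[vertex]        # hull = the linear continuum
        assert abs(depth[vertex] - dip / hull_at_vertex) < 1e-12
        assert abs(depth.max() - dip / hull_at_vertex) < 1e-12

    def test_nonpositive_reflectance_rejected(self):
        w = np.arange(600.0, 701.0)
        spec = np.full(w.size, 0.2)
        spec[10] = 0.0
        with pytest.raises(HyperspadError):
            continuum_removal(spec, w, (600, 700))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 999))
    def test_cr_always_in_unit_interval(self, seed):
        r = np.random.default_rng(seed)
        w = np.arange(600.0, 701.0)
        spec = 0.05 + r.random(w.size)
        _, cr, depth = continuum_removal(spec, w, (600, 700))
        assert np.all((cr > 0) & (cr <= 1.0))
        assert np.all((depth >= 0) & (depth < 1.0))


class TestRedEdgePosition:
    def test_logistic_edge_max_derivative(self):
        w = WAVELENGTHS_1NM
        spec = 0.05 + 0.45 / (1 + np.exp(-(w - 715.0) / 10.0))
        rep = red_edge_position(spec, w, method="max_derivative")
        assert abs(rep - 715.0) <= 1.0

    def test_four_point_hand_formula(self, sensor):
        spec = np.zeros(272)
        vals = {670: 0.05, 700: 0.10, 740: 0.40, 780: 0.50}
        for nm, v in vals.items():
            spec[sensor.nearest_band(nm)] = v
        rep = red_edge_position(spec, sensor.band_centers,
                                method="four_point")
        hand = 700 + 40 * ((0.05 + 0.50) / 2 - 0.10) / (0.40 - 0.10)
        assert abs(rep - hand) < 1e-12

    def test_rep_monotone_in_simulator_spad(self, campaigns, leaf_model):
        reps = [red_edge_position(
            simulate_leaf_spectrum(s, leaf_model, campaigns[0], seed=0,
                                   noise=False), WAVELENGTHS_1NM)
            for s in range(15, 61, 5)]
        assert np.all(np.diff(reps) >= 0)

    def test_flat_spectrum_undefined(self):
        with pytest.raises(UndefinedResultError):
            red_edge_position(np.full(601, 0.3), WAVELENGTHS_1NM)


# ---------------------------------------------------------------------------
# Index evaluation
# ---------------------------------------------------------------------------

class TestFlatSpectrumIdentities:
    def test_nd_sr_and_ari_identities(self, registry, sensor):
        flat = np.full(272, 0.4)
        vals = dict(zip((d.name for d in registry),
                        compute_all(registry, flat, sensor.band_centers)))
        for nd in ("NDVI", "NDVI705", "PRI", "NPQI", "GNDVI", "NDCI1",
                   "NDCI2", "NDWI970", "PSRI"):
            assert vals[nd] == pytest.approx(0.0, abs=1e-12), nd
        for sr in ("SRI", "VREI1", "GM1", "RGRI", "WBI", "SR705"):
            assert vals[sr] == pytest.approx(1.0, abs=1e-12), sr
        assert vals["ARI1"] == pytest.approx(0.0, abs=1e-12)


# hand-coded closed-form evaluations for the dual-implementation oracle;
# r(nm) samples the fixture spectrum at the nearest band center
HAND_FORMULAS = {
    "NDVI": lambda r: (r(800) - r(670)) / (r(800) + r(670)),
    "SRI": lambda r: r(800) / r(670),
    "EVI": lambda r: 2.5 * (r(800) - r(670))
    / (r(800) + 6 * r(670) - 7.5 * r(480) + 1),
    "RDVI": lambda r: (r(800) - r(670)) / np.sqrt(r(800) + r(670)),
    "LAI": lambda r: 3.618 * (2.5 * (r(800) - r(670))
                              / (r(800) + 6 * r(670) - 7.5 * r(480) + 1)
                              ) - 0.118,
    "NDVI705": lambda r: (r(750) - r(705)) / (r(750) + r(705)),
    "mSR705": lambda r: (r(750) - r(445)) / (r(705) - r(445)),
    "mNDVI705": lambda r: (r(750) - r(705)) / (r(750) + r(705) - 2 * r(445)),
    "VREI1": lambda r: r(740) / r(720),
    "VREI2": lambda r: (r(734) - r(747)) / (r(715) + r(726)),
    "REPI4": lambda r: 700 + 40 * ((r(670) + r(780)) / 2 - r(700))
    / (r(740) - r(700)),
    "GM1": lambda r: r(750) / r(550),
    "PRI": lambda r: (r(531) - r(570)) / (r(531) + r(570)),
    "SIPI": lambda r: (r(800) - r(445)) / (r(800) - r(680)),
    "RGRI": lambda r: r(690) / r(550),
    "PSRI": lambda r: (r(680) - r(500)) / r(750),
    "NPQI": lambda r: (r(415) - r(435)) / (r(415) + r(435)),
    "CRI1": lambda r: 1 / r(510) - 1 / r(550),
    "CRI2": lambda r: 1 / r(510) - 1 / r(700),
    "ARI1": lambda r: 1 / r(550) - 1 / r(700),
    "ARI2": lambda r: r(800) * (1 / r(550) - 1 / r(700)),
    "WBI": lambda r: r(900) / r(970),
    "NDWI970": lambda r: (r(880) - r(970)) / (r(880) + r(970)),
    "MCARI": lambda r: ((r(700) - r(670)) - 0.2 * (r(700) - r(550)))
    * (r(700) / r(670)),
    "TCARI": lambda r: 3 * ((r(700) - r(670)) - 0.2 * (r(700) - r(550))
                            * (r(700) / r(670))),
    "SAVI": lambda r: 1.5 * (r(800) - r(670)) / (r(800) + r(670) + 0.5),
    "GNDVI": lambda r: (r(800) - r(550)) / (r(800) + r(550)),
    "MTVI2": lambda r: 1.5 * (1.2 * (r(800) - r(550))
                              - 2.5 * (r(670) - r(550)))
    / np.sqrt((2 * r(800) + 1) ** 2
              - (6 * r(800) - 5 * np.sqrt(r(670))) - 0.5),
    "NDCI1": lambda r: (r(708) - r(665)) / (r(708) + r(665)),
    "NDCI2": lambda r: (r(762) - r(527)) / (r(762) + r(527)),
    "Datt": lambda r: (r(850) - r(710)) / (r(850) - r(680)),
    "CIrededge": lambda r: r(750) / r(710) - 1,
    "CIgreen": lambda r: r(800) / r(550) - 1,
    "MTCI": lambda r: (r(754) - r(709)) / (r(709) - r(681)),
    "Carter": lambda r: r(695) / r(420),
    "SR705": lambda r: r(750) / r(705),
    "MCARI/OSAVI": lambda r: (((r(700) - r(670))
                               - 0.2 * (r(700) - r(550)))
                              * (r(700) / r(670)))
    / (1.16 * (r(800) - r(670)) / (r(800) + r(670) + 0.16)),
    "TCARI/OSAVI": lambda r: (3 * ((r(700) - r(670))
                                   - 0.2 * (r(700) - r(550))
                                   * (r(700) / r(670))))
    / (1.16 * (r(800) - r(670)) / (r(800) + r(670) + 0.16)),
}


@pytest.fixture(scope="module")
def fixture_spectrum(sensor=None):
    """Piecewise-linear leaf-like spectrum on the 272-band grid."""
    from hyperspad.spectral_io import SensorModel

    s = SensorModel()
    knots_nm = [400, 450, 550, 620, 680, 710, 760, 900, 1000]
    knots_r = [0.06, 0.05, 0.16, 0.10, 0.05, 0.20, 0.48, 0.50, 0.44]
    return s, np.interp(s.band_centers, knots_nm, knots_r)


class TestDualImplementationOracle:
    def test_closed_form_indices_match_hand_coded(self, registry,
                                                  fixture_spectrum):
        sensor, spec = fixture_spectrum

        def r(nm):
            return float(spec[int(np.argmin(np.abs(sensor.band_centers
                                                   - nm)))])

        defs = by_name(registry)
        for name, hand in HAND_FORMULAS.items():
            got = compute_index(defs[name], spec, sensor.band_centers)
            assert got == pytest.approx(hand(r), rel=1e-12), name


class TestInvarianceClasses:
    def test_declared_scale_invariance(self, registry, fixture_spectrum):
        """Pure ratio/ND indices are invariant to R -> 2R; indices with
        additive constants (SAVI, EVI, ...) must not be."""
        sensor, spec = fixture_spectrum
        base = compute_all(registry, spec, sensor.band_centers)
        scaled = compute_all(registry, 2.0 * spec, sensor.band_centers)
        for d, a, b in zip(registry, base, scaled):
            if d.scale_invariant:
                assert b == pytest.approx(a, rel=1e-9, abs=1e-9), d.name
            else:
                assert abs(a - b) > 1e-6 * max(1.0, abs(a)), d.name


class TestResamplingRobustness:
    def test_value_stability_and_rank_stability(self, registry, sensor,
                                                campaigns, leaf_model):
        """Indices declared resample-robust agree within 2% between the
        (SRF-matched) 1-nm and 272-band evaluations of the same leaf;
        snapping-sensitive indices preserve the SPAD ranking."""
        spads = np.arange(15, 61, 5)
        v1, v2 = [], []
        for s in spads:
            sp = simulate_leaf_spectrum(s, leaf_model, campaigns[0],
                                        seed=0, noise=False)
            smooth = gaussian_filter1d(sp, 6.0 / FWHM_TO_SIGMA,
                                       mode="nearest")
            v1.append(compute_all(registry, smooth, WAVELENGTHS_1NM))
            v2.append(compute_all(registry,
                                  gaussian_resample(sp, WAVELENGTHS_1NM,
                                                    sensor),
                                  sensor.band_centers))
        v1, v2 = np.array(v1), np.array(v2)
        for j, d in enumerate(registry):
            if d.resample_robust:
                scale = max(v1[:, j].max() - v1[:, j].min(),
                            np.abs(v1[:, j]).max(), 1e-6)
                tol = np.maximum(0.02 * scale,
                                 np.maximum(0.02 * np.abs(v1[:, j]), 1e-4))
                assert np.all(np.abs(v1[:, j] - v2[:, j]) <= tol), d.name
            else:
                rho = spearmanr(v1[:, j], v2[:, j]).statistic
                assert rho >= 0.85, d.name


class TestViCube:
    def make_cube(self, sensor, spec, shape=(2, 3)):
        data = np.broadcast_to(spec.astype(np.float32),
                               shape + (272,)).copy()
        return ReflectanceCube(data=data, sensor=sensor)

    def test_uniform_cube_constant_maps(self, registry, fixture_spectrum):
        sensor, spec = fixture_spectrum
        cube = self.make_cube(sensor, spec)
        out = vi_cube(cube, registry)
        assert out.shape == (2, 3, 60)
        for j in range(60):
            band = out[:, :, j]
            assert np.all(band == band[0, 0]) or np.all(np.isnan(band))

    def test_single_pixel_equals_compute_all(self, registry,
                                             fixture_spectrum):
        sensor, spec = fixture_spectrum
        cube = self.make_cube(sensor, spec, shape=(1, 1))
        out = vi_cube(cube, registry)[0, 0]
        # compare against the spectrum as stored (float32) in the cube
        direct = compute_all(registry, cube.data[0, 0].astype(float),
                             sensor.band_centers)
        np.testing.assert_allclose(out, direct, rtol=1e-6, equal_nan=True)

    def test_mask_propagates_nan(self, registry, fixture_spectrum):
        sensor, spec = fixture_spectrum
        cube = self.make_cube(sensor, spec)
        mask = np.zeros((2, 3), dtype=bool)
        mask[0, 0] = True
        out = vi_cube(cube, registry, mask=mask)
        assert np.all(np.isnan(out[1, 2]))
        assert np.isfinite(out[0, 0]).sum() > 0

    def test_datt_map_monotone_along_spad_gradient(self, registry, sensor,
                                                   campaigns, leaf_model):
        """A cube whose rows step up in SPAD yields a Datt index map
        monotone along the gradient (generator ground truth)."""
        spads = [20, 30, 40, 50]
        rows = [gaussian_resample(
            simulate_leaf_spectrum(s, leaf_model, campaigns[0], seed=0,
                                   noise=False), WAVELENGTHS_1NM, sensor)
            for s in spads]
        data = np.stack(rows)[:, None, :].astype(np.float32)
        cube = ReflectanceCube(data=data, sensor=sensor)
        j = [d.name for d in registry].index("Datt")
        datt = vi_cube(cube, registry)[:, 0, j]
        assert np.all(np.diff(datt) > 0)
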