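"""Sensitive-volume convolution: footprints, signals, kvol/kpos, variance."""

import numpy as np
import pytest
from scipy.integrate import dblquad

from conftest import ALL_GEOMETRIES, brute_signal, brute_window_average, random_concave_model
from smallfield.errors import UnsupportedGeometryError
from smallfield.geometry import DoseProfileModel
from smallfield.response import (
    DETECTOR_PRESETS,
    PositionWindow,
    SensitiveVolume,
    expected_signal,
    footprint_height,
    kpos,
    kvol,
    measured_signal,
    signal_variance,
)

MODEL = DoseProfileModel(1, 0, -0.01, 1, 0, -0.01, valid_halfwidth=10)
UNIFORM = DoseProfileModel(0.7, 0, 0, 1, 0, 0, valid_halfwidth=50)


class TestFootprintHeight:
    def test_parallel_cylinder_is_uniform_disk(self):
        g = SensitiveVolume("cylinder", 0.5, 1.0, "parallel")
        assert footprint_height(g, 0.1, 0.2) == pytest.approx(1 / (np.pi * 0.25))
        assert footprint_height(g, 0.6, 0.0) == 0.0

    def test_sphere_height_and_normalization(self):
        g = SensitiveVolume("sphere", 1.0)
        expected = 2 * np.sqrt(1 - 0.25) / (4 / 3 * np.pi)
        assert footprint_height(g, 0.5, 0.0) == pytest.approx(expected, rel=1e-12)
        integral, _ = dblquad(lambda y, x: float(footprint_height(g, x, y)),
                              -1, 1, -1, 1, epsabs=1e-10)
        assert integral == pytest.approx(1.0, abs=1e-8)

    def test_perpendicular_cylinder_normalization(self):
        g = SensitiveVolume("cylinder", 1.0, 2.6, "perpendicular")
        assert footprint_height(g, 0.0, 0.0) == pytest.approx(
            2.0 / (np.pi * 2.6), rel=1e-12)
        integral, _ = dblquad(lambda y, x: float(footprint_height(g, x, y)),
                              -1, 1, -1.3, 1.3, epsabs=1e-10)
        assert integral == pytest.approx(1.0, abs=1e-8)

    def test_unknown_shape_rejected(self):
        with pytest.raises(UnsupportedGeometryError):
            SensitiveVolume("cube", 1.0)

    @pytest.mark.parametrize("geom", ALL_GEOMETRIES, ids=lambda g: f"{g.shape}-{g.orientation}")
    def test_uniform_dose_gives_uniform_signal(self, geom):
        assert measured_signal(UNIFORM, geom) == pytest.approx(0.7, rel=1e-12)
        w = PositionWindow(0.3, 0.2)
        assert expected_signal(UNIFORM, geom, w) == pytest.approx(0.7, rel=1e-12)
        assert signal_variance(UNIFORM, geom, w) == pytest.approx(0.0, abs=1e-14)


class TestMeasuredSignal:
    """Hand-derived footprint moments as closed-form oracles."""

    def test_parallel_cylinder_disk_moments(self):
        g = SensitiveVolume("cylinder", 0.5, 1.0, "parallel")
        r = 0.5
        exact = 1 - 2 * 0.01 * r**2 / 4 + 1e-4 * r**4 / 24
        assert measured_signal(MODEL, g) == pytest.approx(exact, abs=1e-13)
        assert exact == pytest.approx(0.99875, abs=3e-7)

    def test_sphere_ball_moments(self):
        g = SensitiveVolume("sphere", 1.0)
        exact = 1 - 2 * 0.01 / 5 + 1e-4 / 35
        assert measured_signal(MODEL, g) == pytest.approx(exact, abs=1e-13)

    def test_perpendicular_cylinder_moments(self):
        g = SensitiveVolume("cylinder", 1.0, 2.6, "perpendicular")
        exact = (1 - 0.01 / 4) * (1 - 0.01 * 2.6**2 / 12) \
            + 1e-4 * (2.6**2 / 48 - (1 / 4) * (2.6**2 / 12))
        assert measured_signal(MODEL, g) == pytest.approx(exact, abs=1e-13)

    @pytest.mark.parametrize("geom", ALL_GEOMETRIES, ids=lambda g: f"{g.shape}-{g.orientation}")
    def test_matches_brute_force_grid(self, geom):
        rng = np.random.default_rng(7)
        for _ in range(3):
            m = random_concave_model(rng)
            ref = brute_signal(m, geom, 0.3, -0.2)
            assert measured_signal(m, geom, 0.3, -0.2) == pytest.approx(ref, rel=1e-5)

    def test_extrapolation_warning(self):
        tight = DoseProfileModel(1, 0, -0.01, 1, 0, -0.01, valid_halfwidth=0.4)
        with pytest.warns(RuntimeWarning, match="valid region"):
            measured_signal(tight, SensitiveVolume("sphere", 1.0))


class TestExpectedSignalAndKpos:
    def test_zero_window_reduces_to_signal(self):
        g = SensitiveVolume("sphere", 1.0)
        w0 = PositionWindow(0.0, 0.0)
        assert expected_signal(MODEL, g, w0) == measured_signal(MODEL, g)
        assert kpos(MODEL, g, w0).value == pytest.approx(1.0, abs=1e-14)

    def test_point_detector_window_moments(self):
        w = PositionWindow(0.5, 0.8)
        exact = (1 - 0.01 * 0.5**2 / 3) * (1 - 0.01 * 0.8**2 / 3)
        assert expected_signal(MODEL, None, w) == pytest.approx(exact, abs=1e-14)
        assert kpos(MODEL, None, w).value == pytest.approx(1 / exact, abs=1e-13)

    def test_window_average_matches_brute_force(self):
        g = SensitiveVolume("cylinder_hemisphere_tip", 1.0, 2.6, "perpendicular")
        w = PositionWindow(0.4, 0.3)
        ref = brute_window_average(MODEL, g, w, n=161)
        assert expected_signal(MODEL, g, w) == pytest.approx(ref, rel=1e-7)

    def test_kpos_nondecreasing_in_window(self):
        g = SensitiveVolume("cylinder", 0.5, 1.0, "parallel")
        vals = [kpos(MODEL, g, PositionWindow(w, w)).value for w in (0.0, 0.1, 0.3, 0.6)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert all(v >= 1.0 for v in vals)

    def test_kpos_unity_for_studied_detectors(self):
        # realistic small-field curvature, 0.1 mm positioning half-widths
        w = PositionWindow(0.1, 0.1)
        steep = DoseProfileModel(1, 0, -0.055, 1, 0, -0.055, valid_halfwidth=3)
        for geom in DETECTOR_PRESETS.values():
            assert round(kpos(steep, geom, w).value, 3) == 1.000


class TestKvol:
    def test_point_detector_is_one(self):
        assert kvol(MODEL, None) == 1.0

    def test_disk_example(self):
        g = SensitiveVolume("cylinder", 0.5, 1.0, "parallel")
        assert kvol(MODEL, g) == pytest.approx(1 / 0.9987502604166667, rel=1e-12)

    def test_nondecreasing_in_radius(self):
        vals = [kvol(MODEL, SensitiveVolume("sphere", r)) for r in (0.2, 0.5, 1.0, 1.65)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_flat_msr_field_ratio_is_clin_kvol(self):
        flat = DoseProfileModel(1, 0, -1e-7, 1, 0, -1e-7, valid_halfwidth=40)
        g = DETECTOR_PRESETS["PRB-0002"]
        kv_msr = kvol(flat, g)
        assert abs(kv_msr - 1) < 1e-4
        kv_clin = kvol(MODEL, g)
        assert kv_clin / kv_msr == pytest.approx(kv_clin, abs=1e-4)


class TestSignalVariance:
    def test_zero_for_uniform_or_zero_window(self):
        g = SensitiveVolume("sphere", 1.0)
        assert signal_variance(UNIFORM, g, PositionWindow(0.5, 0.5)) == 0.0
        assert signal_variance(MODEL, g, PositionWindow(0.0, 0.0)) == 0.0

    def test_linear_model_closed_form(self):
        lin = DoseProfileModel(1, 0.05, 0, 1, 0, 0, valid_halfwidth=30)
        var = signal_variance(lin, None, PositionWindow(0.3, 0.0))
        assert var == pytest.approx(0.05**2 * 0.3**2 / 3, rel=1e-10)

    @pytest.mark.parametrize("geom", ALL_GEOMETRIES, ids=lambda g: f"{g.shape}-{g.orientation}")
    def test_nonnegative(self, geom):
        rng = np.random.default_rng(11)
        for _ in range(3):
            m = random_concave_model(rng)
            assert signal_variance(m, geom, PositionWindow(0.2, 0.2)) >= 0.0
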