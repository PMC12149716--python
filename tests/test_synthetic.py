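"""Synthetic-data generator: profiles, sessions, spectra, round trips."""

import numpy as np
import pytest

from smallfield import synthetic
from smallfield.errors import InvalidSpecError
from smallfield.quenching import BirksParameters, kioq_ratio, synthetic_polystyrene_table


class TestProfiles:
    def test_symmetric_profile_peaks_at_one_on_axis(self):
        spec = synthetic.SyntheticFieldSpec(10.0, 2.0)
        df = synthetic.make_profile(spec, "cross-line")
        i0 = np.argmin(np.abs(df["position_mm"].to_numpy()))
        assert df["value"].iloc[i0] == pytest.approx(df["value"].max(), rel=1e-12)
        assert df["value"].max() == pytest.approx(1.0, rel=1e-12)
        v = df["value"].to_numpy()
        assert np.allclose(v, v[::-1], rtol=1e-12)

    def test_fwhm_against_dense_grid_oracle(self):
        spec = synthetic.SyntheticFieldSpec(0.6, 2.0)
        x = np.linspace(0, 12, 4_000_001)
        v = synthetic.axis_profile(x, 0.6, 2.0)
        fwhm_grid = 2 * np.interp(-0.5, -v, x)
        assert abs(synthetic.analytic_fwhm(spec) - fwhm_grid) < 1e-5
        # small fields broaden: FWHM exceeds the nominal side
        assert synthetic.analytic_fwhm(spec) > 6.0

    def test_zero_noise_deterministic_across_seeds(self):
        spec = synthetic.SyntheticFieldSpec(1.0, 2.0)
        a = synthetic.make_profile(spec, "cross-line", rng_seed=1, noise_rel=0.0)
        b = synthetic.make_profile(spec, "cross-line", rng_seed=2, noise_rel=0.0)
        assert a.equals(b)

    def test_invalid_specs_rejected(self):
        with pytest.raises(InvalidSpecError):
            synthetic.SyntheticFieldSpec(0.0, 2.0)
        with pytest.raises(InvalidSpecError):
            synthetic.SyntheticFieldSpec(1.0, -1.0)
        with pytest.raises(InvalidSpecError):
            synthetic.make_profile(synthetic.SyntheticFieldSpec(1.0), n_points=5)


class TestSessions:
    def test_clean_session_reproduces_generating_ratios(self):
        spec = synthetic.SyntheticSessionSpec(reading_noise_rel=0.0, n_repeats=1)
        fields = [synthetic.SyntheticFieldSpec(s) for s in (0.6, 1.0, 10.0)]
        data = synthetic.make_session(fields, spec)
        plus = data.readings[data.readings.polarity == "+"].set_index("field_side_cm")
        ratio = plus.loc[0.6, "reading"] / plus.loc[10.0, "reading"]
        truth = data.truth.set_index("field_side_cm")
        expected = truth.loc[0.6, "of_true"] / truth.loc[10.0, "of_true"]
        assert ratio == pytest.approx(expected, rel=1e-12)

    def test_injected_recombination_is_self_consistent(self):
        spec = synthetic.SyntheticSessionSpec(true_B=0.0035, reading_noise_rel=0.0,
                                              n_repeats=1)
        data = synthetic.make_session([synthetic.SyntheticFieldSpec(0.6)], spec)
        t = data.truth.iloc[0]
        r = t["raw_kpol_ratio_true"]
        assert t["kion_ratio_true"] == pytest.approx(1 / (1 + 0.0035 * (1 - r)), rel=1e-12)
        # applying the correction recovers the generating corrected ratio
        assert r * t["kion_ratio_true"] == pytest.approx(t["of_true"], rel=1e-12)

    def test_standard_error_of_mean_ratio(self):
        # seven detectors x two measurements at 0.1% reading noise: the SEM of
        # the mean clin/msr ratio lands near 0.1% * sqrt(2) / sqrt(14)
        rng = np.random.default_rng(8)
        ratios = []
        for _ in range(400):
            clin = 1.0 + 0.001 * rng.standard_normal(14)
            msr = 1.0 + 0.001 * rng.standard_normal(14)
            ratios.append(np.mean(clin / msr))
        se = np.std(ratios, ddof=1)
        assert 0.0002 < se < 0.00055  # ~0.03%

    def test_b_out_of_range_rejected(self):
        with pytest.raises(InvalidSpecError):
            synthetic.SyntheticSessionSpec(true_B=0.05)


class TestMsrPrimeRecovery:
    def test_b_and_kpol_recovered_over_many_seeds(self):
        from smallfield.workflow import _fit_B_from_msr_prime

        B_true = 0.0035
        fits = []
        for seed in range(100):
            spec = synthetic.SyntheticSessionSpec(
                true_B=B_true, reading_noise_rel=0.001, n_repeats=2, rng_seed=seed)
            fits.append(_fit_B_from_msr_prime(synthetic.make_msr_prime_session(spec)).B)
        fits = np.asarray(fits)
        se = fits.std(ddof=1) / np.sqrt(fits.size)
        assert abs(fits.mean() - B_true) < 3 * se


class TestSpectra:
    def test_constant_soft_fraction_identical_spectra(self):
        spectra = synthetic.make_spectra([0.6, 2.0, 10.0], soft_fraction_curve=lambda s: 0.05)
        table = synthetic_polystyrene_table()
        for s in (0.6, 2.0):
            assert spectra[s].particles == spectra[10.0].particles
            assert spectra[s].weights == spectra[10.0].weights
            assert kioq_ratio(spectra[s], spectra[10.0], table,
                              BirksParameters(kB=0.019)) == pytest.approx(1.0, abs=1e-12)

    def test_default_spectra_quenching_scale(self):
        # field-size dependence lands in the few-tenths-of-a-percent range
        spectra = synthetic.make_spectra([0.6, 10.0, 30.0])
        table = synthetic_polystyrene_table()
        params = BirksParameters(kB=0.019)
        k_small = kioq_ratio(spectra[0.6], spectra[10.0], table, params)
        k_large = kioq_ratio(spectra[30.0], spectra[10.0], table, params)
        assert 0.001 <= abs(k_small - 1) <= 0.005
        assert k_small < 1 < k_large  # quenching grows with field size

    def test_decreasing_soft_fraction_rejected(self):
        with pytest.raises(InvalidSpecError):
            synthetic.make_spectra([0.6, 10.0], soft_fraction_curve=lambda s: -s)


class TestYamlRoundtrip:
    def test_field_specs_roundtrip(self):
        specs = [synthetic.SyntheticFieldSpec(0.6, 2.0, (0.5, -0.3)),
                 synthetic.SyntheticFieldSpec(10.0)]
        text = synthetic.field_spec_to_yaml(specs)
        back = synthetic.field_spec_from_yaml(text)
        assert back == specs
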