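"""Diffusivity-spectrum construction and the Lm_D length-scale mapping."""
import math

import numpy as np
import pytest
from scipy.special import gamma as gamma_fn
from scipy.stats import levy_stable

from xedwi import (FitOptions, ParameterError, ParameterMap, calibrate_zone_truth,
                   compute_lmd_map, diffusivity_spectrum, lmd_from_spectrum,
                   lmd_value, spectrum_from_curve_nnls)
from xedwi.spectrum import DiffusivitySpectrum
from xedwi.stable import stable_pdf, stable_pdf_series

DELTA_MS = 8.5

#: grid wide enough that the renormalisation correction is < 1e-3 even for
#: the heavy alpha = 0.5 tail (used for the mathematical self-consistency
#: checks; map computation uses the narrower default grid)
WIDE_OPTS = FitOptions(d_min=1e-7, d_max=1e5, n_points=1500)


class TestStableDensity:
    def test_levy_closed_form(self):
        """alpha = 1/2 is the Levy distribution: f(x) = x^-1.5 e^(-1/4x)/(2 sqrt(pi))."""
        x = np.geomspace(0.05, 50, 30)
        want = x ** -1.5 * np.exp(-1.0 / (4 * x)) / (2 * np.sqrt(np.pi))
        assert np.allclose(stable_pdf(x, 0.5), want, rtol=1e-9)

    @pytest.mark.parametrize("alpha", [0.6, 0.75, 0.85, 0.95])
    def test_against_scipy_levy_stable(self, alpha):
        """Independent oracle: scipy's stable pdf in the S1 parameterisation."""
        x = np.geomspace(0.2, 50, 25)
        scale = np.cos(np.pi * alpha / 2) ** (1 / alpha)
        ref = levy_stable.pdf(x, alpha, 1, loc=0, scale=scale)
        ok = ref > 1e-10
        assert np.allclose(stable_pdf(x[ok], alpha), ref[ok], rtol=2e-5)

    def test_series_error_monitor_flags_bulk_at_high_alpha(self):
        """The series' own error bound exposes where float64 cancellation kills it."""
        vals, err = stable_pdf_series(np.array([0.3]), 0.9)
        assert err[0] > 1.0  # hopeless — and reported as such
        vals, err = stable_pdf_series(np.array([5.0]), 0.9)
        assert err[0] < 1e-15  # right tail converges cleanly

    def test_alpha_bounds(self):
        with pytest.raises(ParameterError):
            stable_pdf(np.array([1.0]), 1.5)
        with pytest.raises(ParameterError):
            stable_pdf(np.array([-1.0]), 0.8)


class TestDiffusivitySpectrum:
    def test_delta_at_alpha_one(self):
        spec = diffusivity_spectrum(0.04, 1.0)
        assert spec.d.size == 1 and spec.d[0] == 0.04
        assert spec.integral() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.5, 0.6, 0.7, 0.8, 0.9, 0.95])
    def test_normalisation(self, alpha):
        spec = diffusivity_spectrum(0.045, alpha, WIDE_OPTS)
        assert spec.integral() == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("alpha", [0.5, 0.7, 0.85, 0.95])
    def test_forward_transform_self_consistency(self, alpha):
        """Sum p_i e^(-b D_i) dD_i reproduces exp(-(b DDC)^alpha) within 1e-3."""
        ddc = 0.045
        spec = diffusivity_spectrum(ddc, alpha, WIDE_OPTS)
        b = np.linspace(0.0, 30.0, 61)
        assert np.max(np.abs(spec.forward(b) - np.exp(-(b * ddc) ** alpha))) < 1e-3

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            diffusivity_spectrum(0.04, 1.2)
        with pytest.raises(ParameterError):
            diffusivity_spectrum(-0.01, 0.8)
        with pytest.raises(ParameterError):
            diffusivity_spectrum(0.04, 0.0)


class TestLmD:
    def test_closed_form_delta(self):
        """Delta spectrum at D = 0.04, delta = 8.5 ms: sqrt(2 D delta) = 260.8 um."""
        want = math.sqrt(2 * 0.04 * 8.5e-3) * 1e4
        assert lmd_value(0.04, 1.0, DELTA_MS) == pytest.approx(want, rel=1e-12)
        assert lmd_value(0.04, 1.0, DELTA_MS) == pytest.approx(260.8, abs=0.05)

    def test_near_mono_series_path_matches_closed_form(self):
        """alpha just below the delta cutoff agrees with sqrt(2 D delta) within 1%."""
        want = math.sqrt(2 * 0.04 * 8.5e-3) * 1e4
        got = lmd_value(0.04, 0.9985, DELTA_MS)
        assert got == pytest.approx(want, rel=0.01)

    def test_scale_invariance_of_normalisation(self):
        spec = diffusivity_spectrum(0.045, 0.85)
        doubled = DiffusivitySpectrum(d=spec.d, p=2 * spec.p, dweights=spec.dweights)
        renorm = DiffusivitySpectrum(d=spec.d, p=doubled.p / doubled.integral(),
                                     dweights=spec.dweights)
        assert lmd_from_spectrum(renorm, DELTA_MS) == pytest.approx(
            lmd_from_spectrum(spec, DELTA_MS), rel=1e-12)

    def test_unnormalised_spectrum_rejected(self):
        spec = diffusivity_spectrum(0.045, 0.85)
        bad = DiffusivitySpectrum(d=spec.d, p=2 * spec.p, dweights=spec.dweights)
        with pytest.raises(ParameterError):
            lmd_from_spectrum(bad, DELTA_MS)

    def test_sqrt_scaling_in_ddc(self):
        """Doubling DDC at fixed alpha scales Lm_D by sqrt(2) within 1%."""
        ratio = lmd_value(0.06, 0.85, DELTA_MS) / lmd_value(0.03, 0.85, DELTA_MS)
        assert ratio == pytest.approx(math.sqrt(2), rel=0.01)

    def test_monotone_in_ddc(self):
        vals = [lmd_value(d, 0.8, DELTA_MS) for d in (0.02, 0.03, 0.05, 0.08)]
        assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize("alpha,rtol", [(0.75, 0.04), (0.8, 0.02), (0.85, 0.02),
                                            (0.9, 0.02), (0.97, 0.01)])
    def test_closed_form_moment_oracle(self, alpha, rtol):
        """E[sqrt(D)] = sqrt(DDC) Gamma(1 - 1/(2a))/Gamma(1/2) for the full
        spectrum; the extended default grid reproduces it up to the residual
        tail truncation (larger for heavier tails, hence the looser band at
        alpha = 0.75)."""
        want = math.sqrt(2 * 0.045 * 8.5e-3) * 1e4 \
            * gamma_fn(1 - 0.5 / alpha) / gamma_fn(0.5)
        assert lmd_value(0.045, alpha, DELTA_MS) == pytest.approx(want, rel=rtol)

    @pytest.mark.parametrize("alpha", [0.75, 0.85, 0.95])
    def test_nnls_oracle_agreement(self, alpha):
        """Analytic spectrum vs independent NNLS inversion: Lm_D within 2%."""
        series = lmd_value(0.045, alpha, DELTA_MS)
        nnls = lmd_from_spectrum(spectrum_from_curve_nnls(0.045, alpha), DELTA_MS)
        assert nnls == pytest.approx(series, rel=0.02)


class TestLmdMap:
    def make_maps(self, ddc_val=0.045, alpha_val=1.0, shape=(4, 3, 2)):
        affine = np.eye(4)
        ddc = np.full(shape, ddc_val)
        alpha = np.full(shape, alpha_val)
        ddc[0, 0, 0] = np.nan
        alpha[0, 0, 0] = np.nan
        return (ParameterMap(name="DDC", data=ddc, affine=affine),
                ParameterMap(name="alpha", data=alpha, affine=affine))

    def test_alpha_one_uniform_closed_form(self):
        ddc, alpha = self.make_maps(0.045, 1.0)
        lmd = compute_lmd_map(ddc, alpha)
        want = math.sqrt(2 * 0.045 * 8.5e-3) * 1e4
        assert np.allclose(lmd.data[lmd.valid], want, rtol=1e-6)
        assert np.isnan(lmd.data[0, 0, 0])

    def test_memoisation_transparency(self):
        rng = np.random.default_rng(2)
        shape = (5, 4, 3)
        affine = np.eye(4)
        ddc = ParameterMap(name="DDC", data=rng.uniform(0.02, 0.08, shape), affine=affine)
        alpha = ParameterMap(name="alpha", data=rng.uniform(0.6, 1.0, shape), affine=affine)
        a = compute_lmd_map(ddc, alpha, memoize=True)
        b = compute_lmd_map(ddc, alpha, memoize=False)
        assert np.array_equal(a.data, b.data, equal_nan=True)

    def test_map_path_matches_direct_spectrum_path(self):
        """The factored per-alpha lookup agrees with the full spectrum build."""
        opts = FitOptions()
        for ddc_v, alpha_v in [(0.03, 0.8), (0.05, 0.7), (0.07, 0.9)]:
            dq = round(ddc_v / opts.quant_ddc) * opts.quant_ddc
            aq = round(alpha_v / opts.quant_alpha) * opts.quant_alpha
            ddc, alpha = self.make_maps(dq, aq, shape=(2, 1, 1))
            got = compute_lmd_map(ddc, alpha, opts).data[1, 0, 0]
            assert got == pytest.approx(lmd_value(dq, aq, opts.delta_ms, opts), rel=5e-3)

    def test_mismatched_masks_rejected(self):
        ddc, alpha = self.make_maps()
        alpha.data[1, 1, 1] = np.nan
        with pytest.raises(ParameterError):
            compute_lmd_map(ddc, alpha)

    def test_invalid_voxels_propagate(self):
        ddc, alpha = self.make_maps()
        lmd = compute_lmd_map(ddc, alpha)
        assert np.array_equal(lmd.valid, ddc.valid)


class TestCalibration:
    @pytest.mark.parametrize("adc_t,lmd_t", [(0.042, 313.0), (0.044, 326.0), (0.039, 302.0)])
    def test_targets_reproduced(self, adc_t, lmd_t):
        ddc, alpha = calibrate_zone_truth(adc_t, lmd_t, b1=12.0, delta_ms=DELTA_MS)
        assert (12.0 * ddc) ** alpha / 12.0 == pytest.approx(adc_t, rel=1e-5)
        assert lmd_value(ddc, alpha, DELTA_MS) == pytest.approx(lmd_t, rel=1e-3)

    def test_default_phantom_truths_are_calibrated(self):
        """The frozen default zone truths match the published-median targets."""
        from xedwi.phantom import (TABLE_ZONE_ADC_BASELINE, TABLE_ZONE_LMD_BASELINE,
                                   _DEFAULT_ZONE_ALPHA, _DEFAULT_ZONE_DDC)

        for d, a, adc_t, lmd_t in zip(_DEFAULT_ZONE_DDC, _DEFAULT_ZONE_ALPHA,
                                      TABLE_ZONE_ADC_BASELINE, TABLE_ZONE_LMD_BASELINE):
            assert (12.0 * d) ** a / 12.0 == pytest.approx(adc_t, rel=1e-3)
            assert lmd_value(d, a, DELTA_MS) == pytest.approx(lmd_t, rel=2e-3)

    def test_unreachable_target_raises(self):
        with pytest.raises(ParameterError):
            calibrate_zone_truth(0.042, 150.0, b1=12.0, delta_ms=DELTA_MS)
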