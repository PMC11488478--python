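"""Lorentzian models, resolution convolution, fitting, width analysis."""

import numpy as np
import pytest

from qenspol.qens_models import (
    ModelSpec,
    QFitResult,
    analyze_widths,
    convolve_resolution,
    eval_elastic_lorentzian,
    eval_two_lorentzian,
    fit_q_slice,
    lorentzian,
    select_model,
)
from qenspol.spectra_core import SqwMap
from qenspol.synthetic_data import default_omega_grid, gamma_global


class TestLorentzian:
    def test_peak_value_closed_form(self):
        assert lorentzian(np.array([0.0]), 0.1)[0] == pytest.approx(
            1.0 / (0.1 * np.pi), rel=1e-12
        )

    def test_unit_area(self):
        gamma = 0.07
        om = np.linspace(-100 * gamma, 100 * gamma, 20001)
        assert np.trapezoid(lorentzian(om, gamma), om) == pytest.approx(1.0, abs=1e-2)

    def test_symmetry_and_positivity(self):
        om = np.linspace(-1, 1, 101)
        y = lorentzian(om, 0.2)
        assert np.allclose(y, y[::-1])
        assert np.all(y > 0)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            lorentzian(np.array([0.0]), 0.0)


class TestConvolution:
    def test_delta_maps_to_kernel(self, omega, resolution):
        k = resolution.kernel(omega)
        j0 = int(np.argmin(np.abs(omega)))
        d = omega[1] - omega[0]
        delta = np.zeros_like(omega)
        delta[j0] = 1.0 / d
        assert np.allclose(convolve_resolution(delta, omega, k), k, rtol=1e-12)

    def test_lorentzian_widths_add(self):
        g1, g2 = 0.05, 0.05
        om = np.arange(-40 * (g1 + g2), 40 * (g1 + g2) + 1e-12, 0.002)
        out = convolve_resolution(lorentzian(om, g1), om, lorentzian(om, g2))
        assert np.max(np.abs(out - lorentzian(om, g1 + g2))) < 1e-3

    def test_area_preserved(self, omega, resolution):
        k = resolution.kernel(omega)
        y = 0.6 * np.exp(-0.5 * (omega / 0.1) ** 2) / (0.1 * np.sqrt(2 * np.pi))
        out = convolve_resolution(y, omega, k)
        assert np.trapezoid(out, omega) == pytest.approx(
            np.trapezoid(y, omega), abs=1e-6
        )

    def test_non_uniform_grid_rejected(self):
        om = np.array([-0.2, -0.1, 0.05, 0.2])
        with pytest.raises(ValueError, match="uniform"):
            convolve_resolution(np.ones(4), om, np.ones(4))


def _direct_sum_eval(omega, kernel, slice_pre, bkg0, bkg1):
    """Independent direct-sum convolution for cross-checking the evaluators."""
    d = omega[1] - omega[0]
    j0 = int(np.argmin(np.abs(omega)))
    n = omega.size
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            kk = i - j + j0
            if 0 <= kk < n:
                acc += slice_pre[j] * kernel[kk]
        out[i] = acc * d + bkg0 + bkg1 * omega[i]
    return out


class TestEvaluators:
    def test_fully_elastic_is_scaled_kernel(self, omega, resolution):
        k = resolution.kernel(omega)
        y = eval_elastic_lorentzian(omega, k, a0=1.0, amp=2.0, gamma=0.1,
                                    bkg_intercept=0.3)
        assert np.allclose(y, 2.0 * k + 0.3, rtol=1e-12)

    def test_no_elastic_area_equals_amplitude(self, omega, resolution):
        k = resolution.kernel(omega)
        y = eval_elastic_lorentzian(omega, k, a0=0.0, amp=0.8, gamma=0.05)
        assert np.trapezoid(y, omega) == pytest.approx(0.8, rel=0.05)

    def test_matches_independent_direct_sum(self, resolution):
        om = default_omega_grid(omega_max=0.4, domega=0.01)
        k = resolution.kernel(om)
        rng = np.random.default_rng(5)
        a0, amp, gamma, b0, b1 = 0.37, 1.8, 0.09, 0.02, -0.01
        d = om[1] - om[0]
        j0 = int(np.argmin(np.abs(om)))
        slice_pre = amp * (1 - a0) * lorentzian(om, gamma)
        slice_pre[j0] += amp * a0 / d
        expected = _direct_sum_eval(om, k, slice_pre, b0, b1)
        got = eval_elastic_lorentzian(om, k, a0, amp, gamma, b0, b1)
        assert np.allclose(got, expected, rtol=1e-10, atol=1e-12)

    def test_two_lorentzian_degenerates_to_one(self, omega, resolution):
        k = resolution.kernel(omega)
        one = eval_two_lorentzian(omega, k, amp1=1.2, gamma1=0.08, amp2=0.0,
                                  gamma2=0.5)
        direct = convolve_resolution(1.2 * lorentzian(omega, 0.08), omega, k)
        assert np.allclose(one, direct, rtol=1e-12)

    def test_zero_internal_width_collapses_amplitudes(self, omega, resolution):
        k = resolution.kernel(omega)
        collapsed = eval_two_lorentzian(omega, k, amp1=0.7, gamma1=0.08,
                                        amp2=0.5, gamma2=1e-12)
        single = convolve_resolution(1.2 * lorentzian(omega, 0.08), omega, k)
        assert np.allclose(collapsed, single, rtol=1e-6)

    def test_second_component_is_convolution_of_dynamics(self, resolution):
        # amp2·L(γ1+γ2) must equal the numeric convolution L(γ1)⊗L(γ2)
        g1, g2 = 0.06, 0.1
        om = default_omega_grid(omega_max=40 * (g1 + g2), domega=0.002)
        k = resolution.kernel(om)
        route_a = eval_two_lorentzian(om, k, amp1=0.0, gamma1=g1, amp2=1.0,
                                      gamma2=g2)
        inner = convolve_resolution(lorentzian(om, g1), om, lorentzian(om, g2))
        route_b = convolve_resolution(inner, om, k)
        assert np.max(np.abs(route_a - route_b)) < 1e-3


class TestFitQSlice:
    def _noiseless_map(self, omega, resolution, a0=0.4, gamma=0.064,
                       amp=1.0, bkg=(1e-3, 2e-4)):
        k = resolution.kernel(omega)
        y = eval_elastic_lorentzian(omega, k, a0, amp, gamma, *bkg)
        scale = 1e4 / y.max()
        sig = np.sqrt(np.clip(y * scale, 1, None)) / scale
        return SqwMap([0.8], omega, y[None, :], sig[None, :])

    def test_noiseless_recovery(self, omega, resolution):
        m = self._noiseless_map(omega, resolution)
        r = fit_q_slice(m, 0, ModelSpec(kind="elastic_lorentzian"), resolution)
        assert r.red_chi2 < 1e-10
        assert r.params["a0"] == pytest.approx(0.4, rel=1e-4)
        assert r.params["gamma1"] == pytest.approx(0.064, rel=1e-4)
        assert r.params["amp"] == pytest.approx(1.0, rel=1e-4)

    def test_rescaling_leaves_chi2_and_widths(self, omega, resolution):
        m = self._noiseless_map(omega, resolution)
        m10 = m.copy(intensity=10 * m.intensity, sigma=10 * m.sigma)
        r1 = fit_q_slice(m, 0, ModelSpec(kind="elastic_lorentzian"), resolution)
        r2 = fit_q_slice(m10, 0, ModelSpec(kind="elastic_lorentzian"), resolution)
        assert r2.params["gamma1"] == pytest.approx(r1.params["gamma1"], rel=1e-6)
        assert r2.params["amp"] == pytest.approx(10 * r1.params["amp"], rel=1e-6)

    def test_two_lorentzian_noiseless_recovery(self, omega, resolution):
        k = resolution.kernel(omega)
        y = eval_two_lorentzian(omega, k, amp1=0.6, gamma1=0.02, amp2=0.4,
                                gamma2=0.12, bkg_intercept=5e-4)
        sig = np.full_like(y, 1e-4)
        m = SqwMap([1.0], omega, y[None, :], sig[None, :])
        spec = ModelSpec(kind="two_lorentzian", n_components=2,
                         delta_included=False)
        r = fit_q_slice(m, 0, spec, resolution)
        assert r.red_chi2 < 1e-6
        assert r.params["gamma1"] == pytest.approx(0.02, rel=1e-3)
        assert r.params["gamma2"] == pytest.approx(0.12, rel=1e-3)


def _mock_results(q, gammas, errs):
    return [
        QFitResult(q=float(qq), model=ModelSpec(), params={"gamma1": float(g)},
                   ci={"gamma1": float(e)}, red_chi2=1.0, n_points=100, n_free=5)
        for qq, g, e in zip(q, gammas, errs)
    ]


class TestAnalyzeWidths:
    def test_exact_linear_q2_recovers_d(self):
        q = np.linspace(0.45, 1.95, 16)
        d_true = 5.5  # Å²/ns
        gam = gamma_global(q, d_true, 0.0)
        w = analyze_widths(_mock_results(q, gam, np.full(q.size, 1e-5)),
                           "linear_q2")
        assert w.d_eff == pytest.approx(d_true, rel=1e-6)
        assert abs(w.intercept) < 1e-9

    def test_constant_mode(self):
        q = np.linspace(0.45, 1.95, 16)
        w = analyze_widths(
            _mock_results(q, np.full(q.size, 0.064), np.full(q.size, 1e-3)),
            "constant",
        )
        assert w.gamma_bar == pytest.approx(0.064, rel=1e-9)
        assert abs(w.slope) <= 2 * w.slope_err

    def test_jump_diffusion_recovery(self):
        q = np.linspace(0.4, 1.8, 8)
        gam = gamma_global(q, 6.0, 10.0)
        w = analyze_widths(_mock_results(q, gam, np.full(q.size, 1e-6)),
                           "jump_diffusion")
        assert w.d_eff == pytest.approx(6.0, rel=0.01)
        assert w.tau == pytest.approx(10.0, rel=0.01)

    def test_negative_slope_reported_as_zero(self):
        q = np.linspace(0.45, 1.95, 8)
        gam = 0.08 - 0.01 * q**2
        w = analyze_widths(_mock_results(q, gam, np.full(q.size, 1e-4)),
                           "linear_q2")
        assert w.d_eff == 0.0
        assert w.d_eff_raw < 0
        assert w.d_eff_err > 0

    def test_insufficient_points_rejected(self):
        q = np.array([0.5, 0.7, 0.9])
        with pytest.raises(ValueError, match="≥ 4"):
            analyze_widths(_mock_results(q, q, q), "jump_diffusion")


class TestSelectModel:
    def _with_chi2(self, results, chi2):
        for r in results:
            r.red_chi2 = chi2
        return results

    def test_flat_widths_good_chi2_selects_elastic(self):
        q = np.linspace(0.45, 1.95, 16)
        rng = np.random.default_rng(0)
        gam = 0.064 + rng.normal(0, 1e-3, q.size)
        res8 = self._with_chi2(_mock_results(q, gam, np.full(q.size, 1.5e-3)), 1.0)
        res10 = self._with_chi2(_mock_results(q, gam, np.full(q.size, 1e-3)), 1.0)
        rep = select_model(res8, res10)
        assert rep.chosen == "elastic_lorentzian"
        assert not rep.ambiguous

    def test_rising_widths_escalate(self):
        q = np.linspace(0.45, 1.95, 16)
        gam = 0.05 + 0.03 * q**2
        res8 = self._with_chi2(_mock_results(q, gam, np.full(q.size, 1e-3)), 1.0)
        res10 = self._with_chi2(_mock_results(q, gam, np.full(q.size, 1e-3)), 1.0)
        rep = select_model(res8, res10)
        assert rep.chosen == "two_lorentzian"
        assert rep.ambiguous  # χ² fine but slope rising

    def test_bad_chi2_with_flat_widths_escalates(self):
        q = np.linspace(0.45, 1.95, 16)
        rng = np.random.default_rng(1)
        gam = 0.064 + rng.normal(0, 1e-3, q.size)
        res8 = self._with_chi2(_mock_results(q, gam, np.full(q.size, 1.5e-3)), 5.0)
        res10 = self._with_chi2(_mock_results(q, gam, np.full(q.size, 1e-3)), 1.0)
        rep = select_model(res8, res10)
        assert rep.chosen == "two_lorentzian"
        assert not rep.chi2_ok
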