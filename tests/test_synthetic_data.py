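"""Generator tests: width law, spectral normalization, channel assembly."""

import math

import numpy as np
import pytest

from qenspol.polarization import correct_flipping_ratio, separate
from qenspol.qens_models import HBAR_MEV_PS
from qenspol.synthetic_data import (
    BufferTruth,
    CoherentTruth,
    InstrumentTruth,
    ProteinTruth,
    assemble_channels,
    coherent_amplitude_for_ratio_crossing,
    default_omega_grid,
    eisf_sphere,
    gamma_global,
    make_buffer_truth,
    make_coherent_truth,
    make_incoherent_truth,
)


class TestGammaGlobal:
    def test_simple_diffusion_value(self):
        # D = 6.03 Å²/ns at q = 1 Å⁻¹, simple diffusion
        assert gamma_global(1.0, 6.03, 0.0) == pytest.approx(3.969017757e-3, rel=1e-9)

    def test_zero_q_gives_zero(self):
        assert gamma_global(0.0, 123.0, 5.0) == 0.0

    def test_jump_plateau_at_high_q(self):
        # Γ → ħ/τ for large q
        tau = 10.0
        assert gamma_global(100.0, 6.0, tau) == pytest.approx(
            HBAR_MEV_PS / tau, rel=0.01
        )

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            gamma_global(-1.0, 6.0, 0.0)


class TestIncoherentTruth:
    def test_fully_elastic_limit(self, q_grid, omega):
        truth = ProteinTruth(eisf_per_q=np.ones(q_grid.size), d_global=0.0,
                             amplitude=2.0)
        m = make_incoherent_truth(truth, q_grid, omega)
        j0 = int(np.argmin(np.abs(omega)))
        d = omega[1] - omega[0]
        # all weight in the ω=0 bin, total spectral weight = amplitude
        assert np.allclose(m.intensity[:, j0] * d, 2.0, rtol=1e-12)
        off = np.delete(m.intensity, j0, axis=1)
        assert np.all(off == 0)

    def test_elastic_plus_lorentzian_structure(self, q_grid, omega):
        truth = ProteinTruth(eisf_per_q=np.full(q_grid.size, 0.4),
                             gamma_internal=0.064, d_global=0.0)
        m = make_incoherent_truth(truth, q_grid, omega)
        j0 = int(np.argmin(np.abs(omega)))
        d = omega[1] - omega[0]
        lor_peak = 0.6 * 0.064 / np.pi / 0.064**2
        assert m.intensity[0, j0] == pytest.approx(0.4 / d + lor_peak, rel=1e-12)
        # off-peak bins are pure Lorentzian
        assert m.intensity[0, j0 + 10] == pytest.approx(
            0.6 * (0.064 / np.pi) / (0.064**2 + omega[j0 + 10] ** 2), rel=1e-12
        )

    def test_spectral_weight_matches_closed_form(self, q_grid, omega):
        # delta weight + truncated-Lorentzian arctan mass
        truth = ProteinTruth(eisf_per_q=np.full(q_grid.size, 0.4),
                             gamma_internal=0.064, d_global=0.0, amplitude=1.7)
        m = make_incoherent_truth(truth, q_grid, omega)
        d = omega[1] - omega[0]
        measured = m.intensity.sum(axis=1) * d
        expected = 1.7 * (0.4 + 0.6 * (2 / np.pi) * np.arctan(omega[-1] / 0.064))
        assert np.allclose(measured, expected, rtol=1e-3)


class TestCoherentTruth:
    def test_zero_amplitude_gives_zero_map(self, q_grid, omega):
        m = make_coherent_truth(CoherentTruth(sq_amplitude=0.0), q_grid, omega)
        assert np.all(m.intensity == 0)

    def test_peaks_toward_center(self, q_grid, omega):
        m = make_coherent_truth(
            CoherentTruth(sq_peak_center=1.95, sq_peak_width=0.4), q_grid, omega
        )
        i_peak = int(np.argmin(np.abs(q_grid - 1.95)))
        i_low = int(np.argmin(np.abs(q_grid - 0.45)))
        assert np.all(m.intensity[i_peak] >= m.intensity[i_low])

    def test_unit_area_on_wide_grid(self):
        # ω grid wide enough that the Lorentzian tail mass is < 1e-4
        truth = CoherentTruth(sq_amplitude=0.8, gamma_coh=0.1)
        om = np.arange(-650.0, 650.0 + 1e-9, 0.02)
        m = make_coherent_truth(truth, np.array([1.95]), om)
        area = np.trapezoid(m.intensity[0], om)
        assert area == pytest.approx(0.8, rel=1e-4)


class TestAssembleChannels:
    def test_pure_incoherent_gives_one_to_two_ratio(self, q_grid, omega, resolution):
        inc = make_incoherent_truth(
            ProteinTruth(eisf_per_q=np.full(q_grid.size, 0.5)), q_grid, omega
        )
        coh = make_coherent_truth(CoherentTruth(sq_amplitude=0.0), q_grid, omega)
        instrument = InstrumentTruth(resolution=resolution,
                                     flipping_ratio=math.inf)
        pair, _ = assemble_channels(inc, coh, instrument, noise=False)
        nz = pair.sf.intensity > 1e-12
        assert np.allclose(
            pair.nsf.intensity[nz] / pair.sf.intensity[nz], 0.5, rtol=1e-10
        )

    def test_pure_coherent_is_non_spin_flip(self, q_grid, omega, resolution):
        inc = make_incoherent_truth(
            ProteinTruth(eisf_per_q=np.zeros(q_grid.size), amplitude=0.0),
            q_grid, omega,
        )
        coh = make_coherent_truth(CoherentTruth(), q_grid, omega)
        instrument = InstrumentTruth(resolution=resolution, flipping_ratio=math.inf)
        pair, truth = assemble_channels(inc, coh, instrument, noise=False)
        assert np.allclose(pair.sf.intensity, 0.0, atol=1e-14)
        assert np.allclose(pair.nsf.intensity, truth.coh.intensity, rtol=1e-12)

    def test_noiseless_roundtrip_through_separation(self, q_grid, omega, resolution):
        inc = make_incoherent_truth(
            ProteinTruth(eisf_per_q=np.full(q_grid.size, 0.4)), q_grid, omega
        )
        coh = make_coherent_truth(CoherentTruth(), q_grid, omega)
        instrument = InstrumentTruth(resolution=resolution, flipping_ratio=20.0)
        pair, truth = assemble_channels(inc, coh, instrument, noise=False)
        sep = separate(correct_flipping_ratio(pair))
        scale = np.max(np.abs(truth.inc.intensity))
        assert np.allclose(sep.inc.intensity, truth.inc.intensity,
                           rtol=1e-10, atol=1e-10 * scale)
        assert np.allclose(sep.coh.intensity, truth.coh.intensity,
                           rtol=1e-10, atol=1e-10 * scale)

    def test_seeded_generation_reproducible(self, q_grid, omega, resolution):
        inc = make_incoherent_truth(
            ProteinTruth(eisf_per_q=np.full(q_grid.size, 0.4)), q_grid, omega
        )
        coh = make_coherent_truth(CoherentTruth(), q_grid, omega)
        instrument = InstrumentTruth(resolution=resolution, seed=42)
        p1, _ = assemble_channels(inc, coh, instrument)
        p2, _ = assemble_channels(inc, coh, instrument)
        assert np.array_equal(p1.nsf.intensity, p2.nsf.intensity)
        assert np.array_equal(p1.sf.intensity, p2.sf.intensity)

    def test_poisson_sigma_matches_expected_counts(self, resolution):
        # E[σ²·scale²] = expected counts, checked over 200 replicates
        q = np.array([0.6, 1.2])
        om = default_omega_grid(omega_max=0.25, domega=0.01)
        inc = make_incoherent_truth(
            ProteinTruth(eisf_per_q=np.full(2, 0.4)), q, om
        )
        coh = make_coherent_truth(CoherentTruth(sq_amplitude=0.0), q, om)
        instrument = InstrumentTruth(resolution=resolution, counts_scale=500.0)
        _, truth = assemble_channels(inc, coh, instrument, noise=False)
        lam = (truth.coh.intensity + truth.inc.intensity / 3.0) * 500.0
        # mixing with R=20 barely changes nsf; use the nsf channel
        r = instrument.flipping_ratio
        lam = (r * lam + (2 / 3) * truth.inc.intensity * 500.0) / (r + 1)
        rng = np.random.default_rng(3)
        acc = np.zeros_like(lam)
        n = 200
        for _ in range(n):
            pair, _ = assemble_channels(inc, coh, instrument, rng=rng)
            acc += (pair.nsf.sigma * 500.0) ** 2
        mean_var = acc / n
        big = lam > 50
        assert np.allclose(mean_var[big], lam[big], rtol=0.05)


class TestBuffer:
    def test_default_coherent_dominates_at_peak(self, q_grid, omega):
        inc, coh = make_buffer_truth(q_grid, omega)
        d = omega[1] - omega[0]
        i_peak = int(np.argmin(np.abs(q_grid - 1.95)))
        assert coh.intensity[i_peak].sum() * d > inc.intensity[i_peak].sum() * d

    def test_zero_amplitudes_give_zero_maps(self, q_grid, omega):
        params = BufferTruth(inc_amplitude=0.0,
                             coherent=CoherentTruth(sq_amplitude=0.0))
        inc, coh = make_buffer_truth(q_grid, omega, params)
        assert np.all(inc.intensity == 0) and np.all(coh.intensity == 0)

    def test_amplitude_solver_places_crossing(self, resolution):
        # the analytic construction pins the coh/inc ratio at the target q
        params = BufferTruth()
        amp = coherent_amplitude_for_ratio_crossing(
            1.15, params, resolution, window=0.25
        )
        assert amp > 0
        shape = np.exp(-((1.15 - params.coherent.sq_peak_center) ** 2)
                       / (2 * params.coherent.sq_peak_width**2))
        # at the peak the ratio exceeds the threshold by 1/shape
        assert amp * shape < amp


def test_eisf_sphere_limits():
    q = np.linspace(0.0, 2.0, 21)
    a0 = eisf_sphere(q, radius=2.3)
    assert a0[0] == pytest.approx(1.0)
    assert np.all(np.diff(a0[:10]) < 0)
    assert np.all((a0 >= 0) & (a0 <= 1))
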