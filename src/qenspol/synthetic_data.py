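"""Synthetic polarized-QENS spectra with known ground truth.

The generator emulates the statistical structure of a polarized
quasi-elastic neutron scattering measurement of a globular protein in a
deuterated buffer:

* an **incoherent protein signal** built from an EISF A₀(q), a global
  diffusion width Γ_glob(q) = ħDq²/(1 + Dq²τ) and a q-independent
  internal width Γ_int;
* a **coherent contribution** whose S(q) is a Gaussian bump peaking at
  high q (the D₂O-like structure-factor maximum near 2 Å⁻¹) with a
  quasi-elastic Lorentzian lineshape;
* a **buffer** consisting of a broad residual-¹H incoherent Lorentzian
  plus a dominant coherent component of the same bump shape;
* instrument effects: resolution convolution (Gaussian kernels with FWHM
  defaults of 30.8 and 65.77 μeV), finite flipping-ratio channel mixing,
  and Poisson counting noise on the non-spin-flip / spin-flip channels.

Ideal channel fractions follow the nuclear-spin-incoherent algebra:
nsf = coh + (1/3)·inc, sf = (2/3)·inc.  Everything is seeded and
bitwise reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.special import voigt_profile

from .polarization import PolarizedPair, SeparatedSet, SeparationCoefficients
from .qens_models import HBAR_MEV_PS, convolve_resolution, lorentzian
from .spectra_core import ResolutionModel, SqwMap

__all__ = [
    "ProteinTruth",
    "CoherentTruth",
    "BufferTruth",
    "InstrumentTruth",
    "gamma_global",
    "eisf_sphere",
    "make_incoherent_truth",
    "make_coherent_truth",
    "make_buffer_truth",
    "assemble_channels",
    "coherent_amplitude_for_ratio_crossing",
    "default_q_grid",
    "default_omega_grid",
]

#: default instrument conditions: FWHM in meV of the two resolution settings
RESOLUTION_FWHM_MEV = (0.0308, 0.06577)


def default_q_grid(q_min: float = 0.45, q_max: float = 1.95, dq: float = 0.1) -> np.ndarray:
    """Momentum-transfer bin centers (Å⁻¹); defaults cover 0.45–1.95, Δq = 0.1."""
    n = int(round((q_max - q_min) / dq)) + 1
    return q_min + dq * np.arange(n)


def default_omega_grid(omega_max: float = 1.5, domega: float = 0.005) -> np.ndarray:
    """Symmetric uniform energy grid (meV) containing ω = 0 exactly."""
    n = int(round(omega_max / domega))
    return domega * np.arange(-n, n + 1)


@dataclass
class ProteinTruth:
    """Ground truth for the incoherent protein signal.

    ``eisf_per_q`` is A₀(q) ∈ [0, 1]; ``gamma_internal`` the q-independent
    internal HWHM in meV; ``d_global`` the global diffusion coefficient in
    Å²/ns with ``tau_jump`` the jump residence time in ps (0 = simple
    diffusion); ``amplitude`` the total incoherent spectral weight per q.
    """

    eisf_per_q: np.ndarray
    gamma_internal: float = 0.064
    d_global: float = 0.0
    tau_jump: float = 0.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        self.eisf_per_q = np.asarray(self.eisf_per_q, dtype=float)
        if np.any((self.eisf_per_q < 0) | (self.eisf_per_q > 1)):
            raise ValueError("EISF values must lie in [0, 1]")
        for name in ("gamma_internal", "d_global", "tau_jump"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")


@dataclass
class CoherentTruth:
    """Coherent contribution: Gaussian S(q) bump × quasi-elastic Lorentzian."""

    sq_peak_center: float = 1.95   # Å⁻¹, D₂O-like structure-factor maximum
    sq_peak_width: float = 0.25    # Å⁻¹ Gaussian width (bump localized at high q)
    sq_amplitude: float = 1.5      # peak coherent weight relative to incoherent
    gamma_coh: float = 0.10        # meV, faster than the internal dynamics

    def __post_init__(self) -> None:
        for name in ("sq_peak_center", "sq_peak_width", "sq_amplitude", "gamma_coh"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")


@dataclass
class BufferTruth:
    """Buffer: broad residual incoherent line + dominant coherent bump."""

    inc_amplitude: float = 0.25
    gamma_inc: float = 0.3         # meV, broad residual ¹H incoherence
    coherent: CoherentTruth = field(
        default_factory=lambda: CoherentTruth(sq_amplitude=0.6, gamma_coh=0.15)
    )


@dataclass
class InstrumentTruth:
    """Instrument effects applied when assembling observed channels."""

    resolution: ResolutionModel = field(
        default_factory=lambda: ResolutionModel(kind="gaussian", fwhm=RESOLUTION_FWHM_MEV[1])
    )
    flipping_ratio: float = 20.0   # realistic supermirror + flipper
    counts_scale: float = 1e4      # mean counts at the elastic peak
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.flipping_ratio > 1:
            raise ValueError("flipping_ratio must be > 1")
        if self.counts_scale <= 0:
            raise ValueError("counts_scale must be > 0")


def gamma_global(q, d: float, tau: float = 0.0) -> np.ndarray | float:
    """Jump-diffusion HWHM Γ(q) = ħ·D·q²/(1 + D·q²·τ) in meV.

    ``q`` in Å⁻¹, ``d`` in Å²/ns, ``tau`` in ps.  τ = 0 reduces to simple
    diffusion Γ = ħDq²; for large q the width saturates at ħ/τ.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0) or d < 0 or tau < 0:
        raise ValueError("q, d and tau must be ≥ 0")
    d_ps = d / 1000.0  # Å²/ns → Å²/ps
    out = HBAR_MEV_PS * d_ps * q**2 / (1.0 + d_ps * q**2 * tau)
    return float(out) if out.ndim == 0 else out


def eisf_sphere(q, radius: float) -> np.ndarray:
    """EISF of diffusion inside a sphere, A₀(q) = [3 j₁(qR)/(qR)]²."""
    q = np.asarray(q, dtype=float)
    x = q * radius
    with np.errstate(invalid="ignore", divide="ignore"):
        j1_over = (np.sin(x) - x * np.cos(x)) / x**3
        a0 = (3.0 * j1_over) ** 2
    return np.where(x == 0, 1.0, a0)


def _delta_bin(omega: np.ndarray) -> tuple[int, float]:
    j = int(np.argmin(np.abs(omega)))
    d = float(omega[1] - omega[0])
    return j, d


def make_incoherent_truth(
    truth: ProteinTruth, q_grid: np.ndarray, omega_grid: np.ndarray
) -> SqwMap:
    """Noiseless pre-convolution incoherent map.

    Per q: ``amplitude·[A₀(q)·L(Γ_glob(q)) + (1−A₀(q))·L(Γ_glob(q)+Γ_int)]``.
    When the global width vanishes the first term is an elastic line,
    represented as its full weight placed in the ω = 0 bin (divided by the
    bin width), which becomes the resolution lineshape after convolution.
    """
    q_grid = np.asarray(q_grid, dtype=float)
    omega_grid = np.asarray(omega_grid, dtype=float)
    if truth.eisf_per_q.size == 1:
        a0 = np.full(q_grid.size, float(truth.eisf_per_q))
    else:
        if truth.eisf_per_q.size != q_grid.size:
            raise ValueError("eisf_per_q length must match the q grid")
        a0 = truth.eisf_per_q
    j0, d = _delta_bin(omega_grid)
    intensity = np.zeros((q_grid.size, omega_grid.size))
    for i, q in enumerate(q_grid):
        gg = float(gamma_global(q, truth.d_global, truth.tau_jump))
        if gg > 0:
            first = lorentzian(omega_grid, gg)
        else:
            first = np.zeros_like(omega_grid)
            first[j0] = 1.0 / d
        g2 = gg + truth.gamma_internal
        if g2 > 0:
            second = lorentzian(omega_grid, g2)
        else:
            second = np.zeros_like(omega_grid)
            second[j0] = 1.0 / d
        intensity[i] = truth.amplitude * (a0[i] * first + (1.0 - a0[i]) * second)
    sigma = np.full_like(intensity, 1e-12 * max(intensity.max(), 1.0))
    return SqwMap(q_grid, omega_grid, intensity, sigma, label="inc truth")


def make_coherent_truth(
    truth: CoherentTruth, q_grid: np.ndarray, omega_grid: np.ndarray
) -> SqwMap:
    """Noiseless pre-convolution coherent map: Gaussian-in-q × Lorentzian-in-ω."""
    q_grid = np.asarray(q_grid, dtype=float)
    omega_grid = np.asarray(omega_grid, dtype=float)
    sq = truth.sq_amplitude * np.exp(
        -((q_grid - truth.sq_peak_center) ** 2) / (2.0 * truth.sq_peak_width**2)
    ) if truth.sq_amplitude > 0 else np.zeros(q_grid.size)
    if truth.gamma_coh > 0:
        line = lorentzian(omega_grid, truth.gamma_coh)
    else:
        j0, d = _delta_bin(omega_grid)
        line = np.zeros_like(omega_grid)
        line[j0] = 1.0 / d
    intensity = sq[:, None] * line[None, :]
    sigma = np.full_like(intensity, 1e-12 * max(intensity.max(), 1.0))
    return SqwMap(q_grid, omega_grid, intensity, sigma, label="coh truth")


def make_buffer_truth(
    q_grid: np.ndarray, omega_grid: np.ndarray, params: BufferTruth | None = None
) -> tuple[SqwMap, SqwMap]:
    """Noiseless pre-convolution (incoherent, coherent) buffer maps."""
    p = params or BufferTruth()
    q_grid = np.asarray(q_grid, dtype=float)
    omega_grid = np.asarray(omega_grid, dtype=float)
    if p.inc_amplitude > 0 and p.gamma_inc > 0:
        line = lorentzian(omega_grid, p.gamma_inc)
        inc_i = p.inc_amplitude * np.tile(line, (q_grid.size, 1))
    else:
        inc_i = np.zeros((q_grid.size, omega_grid.size))
    sigma = np.full_like(inc_i, 1e-12 * max(inc_i.max(), 1.0))
    inc = SqwMap(q_grid, omega_grid, inc_i, sigma, label="buffer inc truth")
    coh = make_coherent_truth(p.coherent, q_grid, omega_grid)
    coh.label = "buffer coh truth"
    return inc, coh


def _convolve_map(m: SqwMap, res: ResolutionModel) -> SqwMap:
    out = np.empty_like(m.intensity)
    for i in range(m.q_centers.size):
        out[i] = convolve_resolution(m.intensity[i], m.omega, res.kernel(m.omega, i))
    return m.copy(intensity=out, label=m.label + " ⊗ res")


def assemble_channels(
    inc: SqwMap,
    coh: SqwMap,
    instrument: InstrumentTruth,
    noise: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[PolarizedPair, SeparatedSet]:
    """Forward model: truth maps → observed polarized channels.

    Convolves both components with the resolution, forms ideal channels
    (nsf = coh + inc/3, sf = 2·inc/3), mixes them with the finite
    flipping ratio, and applies Poisson noise with expected counts
    ``counts_scale · intensity`` (σ = √counts, in intensity units).  Also
    returns the noiseless resolution-convolved separated truth.
    """
    c = SeparationCoefficients()
    inc_c = _convolve_map(inc, instrument.resolution)
    coh_c = _convolve_map(coh, instrument.resolution)
    nsf_i = coh_c.intensity + c.inc_in_nsf * inc_c.intensity
    sf_i = c.inc_in_sf * inc_c.intensity
    r = instrument.flipping_ratio
    if math.isinf(r):
        obs_nsf, obs_sf = nsf_i, sf_i
    else:
        obs_nsf = (r * nsf_i + sf_i) / (r + 1.0)
        obs_sf = (nsf_i + r * sf_i) / (r + 1.0)

    scale = instrument.counts_scale
    if noise:
        rng = rng or np.random.default_rng(instrument.seed)
        def poissonize(lam):
            counts = rng.poisson(np.clip(lam * scale, 0.0, None))
            return counts / scale, np.sqrt(np.maximum(counts, 1.0)) / scale
        nsf_obs, nsf_sig = poissonize(obs_nsf)
        sf_obs, sf_sig = poissonize(obs_sf)
    else:
        # noiseless: keep the would-be counting error as the uncertainty
        nsf_obs, nsf_sig = obs_nsf, np.sqrt(np.clip(obs_nsf * scale, 1.0, None)) / scale
        sf_obs, sf_sig = obs_sf, np.sqrt(np.clip(obs_sf * scale, 1.0, None)) / scale

    nsf = inc.copy(intensity=nsf_obs, sigma=nsf_sig, label="nsf")
    sf = inc.copy(intensity=sf_obs, sigma=sf_sig, label="sf")
    pair = PolarizedPair(nsf=nsf, sf=sf, flipping_ratio=r, kikf_applied=True)

    tot_truth = inc_c.copy(intensity=inc_c.intensity + coh_c.intensity, label="tot truth ⊗ res")
    truth = SeparatedSet(inc=inc_c, coh=coh_c, tot=tot_truth)
    return pair, truth


def coherent_amplitude_for_ratio_crossing(
    q_star: float,
    buffer_params: BufferTruth,
    resolution: ResolutionModel,
    window: float,
    threshold: float = 0.5,
) -> float:
    """Coherent S(q) amplitude placing the coh/inc ratio crossing at q*.

    Uses the analytic Voigt profile (Lorentzian ⊗ Gaussian resolution) and
    adaptive quadrature for the window integrals — an independent route
    from the discrete pipeline — and solves
    ``A·exp(−(q*−c)²/2w²)·F(γ_coh) = threshold·B·F(γ_inc)``
    for A, where F(γ) is the windowed Voigt area.
    """
    if resolution.kind != "gaussian":
        raise ValueError("analytic construction requires a gaussian resolution")
    s = resolution.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    def windowed_voigt(gamma):
        val, _ = quad(lambda w: voigt_profile(w, s, gamma), -window / 2, window / 2)
        return val

    p = buffer_params
    f_inc = windowed_voigt(p.gamma_inc)
    f_coh = windowed_voigt(p.coherent.gamma_coh)
    shape = np.exp(-((q_star - p.coherent.sq_peak_center) ** 2)
                   / (2.0 * p.coherent.sq_peak_width**2))
    return threshold * p.inc_amplitude * f_inc / (shape * f_coh)
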