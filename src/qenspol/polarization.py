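"""Neutron polarization analysis: channel separation and recombination.

For a nuclear-spin-incoherent scatterer measured with longitudinal
polarization analysis, 2/3 of the spin-incoherent intensity flips the
neutron spin while coherent (and isotope-incoherent) scattering does not.
The standard linear combinations therefore recover

    S_inc = (3/2) · sf
    S_coh = nsf − (1/2) · sf
    S_tot = nsf + sf

from the non-spin-flip (nsf) and spin-flip (sf) cross sections.  The
coefficients are exposed (``SeparationCoefficients``) for isotopic
variants, but the defaults implement the standard algebra.

A finite flipping ratio R mixes the two channels,
``observed = M · ideal`` with ``M = [[R, 1], [1, R]] / (R + 1)``;
:func:`correct_flipping_ratio` inverts this 2×2 leakage exactly.  Before
separation, intensities are converted to cross sections by the kinematic
k_i/k_f factor (:func:`kikf_correction`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .spectra_core import SqwMap, arithmetic, _check_grids

__all__ = [
    "PolarizedPair",
    "SeparatedSet",
    "SeparationCoefficients",
    "correct_flipping_ratio",
    "kikf_correction",
    "separate",
    "recombine",
]


@dataclass
class PolarizedPair:
    """Matched non-spin-flip / spin-flip maps plus channel metadata."""

    nsf: SqwMap
    sf: SqwMap
    flipping_ratio: float = math.inf  # ∞ = ideal channels
    kikf_applied: bool = False

    def __post_init__(self) -> None:
        _check_grids(self.nsf, self.sf)
        if not self.flipping_ratio > 1:
            raise ValueError(
                f"flipping_ratio must be > 1 (got {self.flipping_ratio})"
            )

    @property
    def is_ideal(self) -> bool:
        return math.isinf(self.flipping_ratio)


@dataclass
class SeparatedSet:
    """Incoherent, coherent and total dynamic structure factors."""

    inc: SqwMap
    coh: SqwMap
    tot: SqwMap

    def __post_init__(self) -> None:
        _check_grids(self.inc, self.coh)
        _check_grids(self.inc, self.tot)


@dataclass(frozen=True)
class SeparationCoefficients:
    """Fraction of spin-incoherent intensity in each channel.

    Defaults are the nuclear-spin-incoherent values (1/3 non-spin-flip,
    2/3 spin-flip); coherent scattering is entirely non-spin-flip.
    """

    inc_in_nsf: float = 1.0 / 3.0
    inc_in_sf: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if not (0 < self.inc_in_sf <= 1 and abs(self.inc_in_nsf + self.inc_in_sf - 1) < 1e-12):
            raise ValueError("channel fractions must be positive and sum to 1")


def correct_flipping_ratio(pair: PolarizedPair) -> PolarizedPair:
    """Invert finite-flipping-ratio channel leakage.

    With R = ∞ the input is returned unchanged (already ideal).  The 2×2
    mixing matrix is symmetric and the inverse is applied analytically;
    uncertainties propagate through the linear combination in quadrature.
    """
    if pair.is_ideal:
        return pair
    r = pair.flipping_ratio
    if not r > 1:
        raise ValueError(f"flipping ratio {r} ≤ 1: mixing matrix singular/unphysical")
    # inverse of [[R, 1], [1, R]]/(R+1)
    a = r * (r + 1.0) / (r**2 - 1.0)
    b = -(r + 1.0) / (r**2 - 1.0)
    nsf_i = a * pair.nsf.intensity + b * pair.sf.intensity
    sf_i = b * pair.nsf.intensity + a * pair.sf.intensity
    sig = np.sqrt(a**2 * pair.nsf.sigma**2 + b**2 * pair.sf.sigma**2)
    sig_sf = np.sqrt(b**2 * pair.nsf.sigma**2 + a**2 * pair.sf.sigma**2)
    nsf = pair.nsf.copy(intensity=nsf_i, sigma=sig, label=pair.nsf.label + " (R-corrected)")
    sf = pair.sf.copy(intensity=sf_i, sigma=sig_sf, label=pair.sf.label + " (R-corrected)")
    return PolarizedPair(nsf=nsf, sf=sf, flipping_ratio=math.inf,
                         kikf_applied=pair.kikf_applied)


def kikf_correction(m: SqwMap, e_incident: float) -> SqwMap:
    """Scale each ω bin by k_i/k_f = sqrt(E_i / (E_i − ω)).

    ``ω`` is the neutron energy transfer to the sample (energy-loss
    convention), so bins with ω ≥ E_i would require an imaginary final
    wavevector and are rejected.  Intensity and sigma scale identically.
    """
    if e_incident <= 0:
        raise ValueError("incident energy must be > 0")
    if np.any(m.omega >= e_incident):
        raise ValueError(
            f"energy transfer reaches E_i = {e_incident} meV on the grid "
            f"(max ω = {m.omega.max()} meV): k_f would be imaginary"
        )
    factor = np.sqrt(e_incident / (e_incident - m.omega))
    return m.copy(
        intensity=m.intensity * factor[None, :],
        sigma=m.sigma * factor[None, :],
        label=m.label + " (ki/kf)",
    )


def separate(
    pair: PolarizedPair, coeffs: SeparationCoefficients | None = None
) -> SeparatedSet:
    """Separate ideal channels into incoherent, coherent and total maps.

    Requires flipping-ratio-corrected (or ideal) channels.  Negative bins
    produced by counting noise are preserved — clipping them would bias
    downstream χ² statistics.
    """
    if not pair.is_ideal:
        raise ValueError(
            "channels must be flipping-ratio corrected before separation "
            "(call correct_flipping_ratio first)"
        )
    c = coeffs or SeparationCoefficients()
    inv_sf = 1.0 / c.inc_in_sf                     # 3/2 for the standard algebra
    leak = c.inc_in_nsf / c.inc_in_sf              # 1/2
    inc = pair.sf.copy(
        intensity=inv_sf * pair.sf.intensity,
        sigma=inv_sf * pair.sf.sigma,
        label="S_inc",
    )
    coh = arithmetic(pair.nsf, pair.sf, "subtract", scale_b=leak)
    coh.label = "S_coh"
    tot = arithmetic(pair.nsf, pair.sf, "add", scale_b=1.0)
    tot.label = "S_tot"
    return SeparatedSet(inc=inc, coh=coh, tot=tot)


def recombine(s: SeparatedSet) -> SqwMap:
    """Total dynamic structure factor ``inc + coh`` with quadrature errors."""
    out = arithmetic(s.inc, s.coh, "add", scale_b=1.0)
    out.label = "S_tot (recombined)"
    return out
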