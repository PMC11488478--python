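"""Empty-can and buffer subtraction, hydration-layer volume fraction.

The protein signal is isolated in two steps: the empty sample-can
spectrum is subtracted from every measured spectrum, then the (can-free)
buffer spectrum is removed with the volume-fraction-weighted,
attenuation-corrected subtraction

    S_protein = S_solution − (1 − ϕ) · f · S_buffer,

where ϕ = c·v̄ is the protein volume fraction (concentration times
partial specific volume) and f a scalar beam-attenuation factor near 1.

The hydration layer survives this subtraction because its water does not
follow bulk dynamics.  Its total volume fraction for a globular protein
is estimated from a spherical-shell construction: number density of
proteins (c·N_A/M_w) times the shell volume (4π/3)[(r+d)³ − r³].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import Avogadro

from .spectra_core import SqwMap, arithmetic

__all__ = [
    "SampleSpec",
    "protein_volume_fraction",
    "subtract_empty_can",
    "subtract_buffer",
    "hydration_volume_fraction",
]


@dataclass
class SampleSpec:
    """Sample composition entering the reduction formulas.

    ``c_protein`` in mg/mL, ``m_w`` in Da, ``v_bar`` in mL/g (0.73 is a
    typical globular-protein default, not a measured value),
    ``attenuation_factor`` dimensionless (≈ 1), ``r_protein`` and
    ``d_hydration`` in Å.
    """

    c_protein: float
    m_w: float
    v_bar: float = 0.73
    attenuation_factor: float = 1.0
    r_protein: float = 25.0
    d_hydration: float = 3.0

    def __post_init__(self) -> None:
        if self.c_protein <= 0 or self.m_w <= 0 or self.v_bar <= 0:
            raise ValueError("c_protein, m_w and v_bar must be > 0")
        if self.attenuation_factor <= 0:
            raise ValueError("attenuation_factor must be > 0")
        if self.r_protein <= 0 or self.d_hydration < 0:
            raise ValueError("r_protein must be > 0 and d_hydration ≥ 0")
        phi = protein_volume_fraction(self)
        if not 0.0 <= phi < 1.0:
            raise ValueError(f"derived volume fraction ϕ = {phi:.3g} outside [0, 1)")


def protein_volume_fraction(spec: SampleSpec) -> float:
    """ϕ = c·v̄, with mg/mL × mL/g → dimensionless (factor 10⁻³)."""
    return spec.c_protein * 1e-3 * spec.v_bar


def subtract_empty_can(sample: SqwMap, can: SqwMap) -> SqwMap:
    """``sample − can`` with quadrature uncertainties."""
    out = arithmetic(sample, can, "subtract", scale_b=1.0)
    out.label = sample.label + " − can"
    return out


def subtract_buffer(solution: SqwMap, buffer: SqwMap, spec: SampleSpec) -> SqwMap:
    """Volume-fraction-weighted buffer subtraction.

    ``S_protein = solution − (1−ϕ)·f·buffer`` with ϕ = c·v̄ and f the
    attenuation factor; uncertainties combine in quadrature.
    """
    phi = protein_volume_fraction(spec)
    weight = (1.0 - phi) * spec.attenuation_factor
    out = arithmetic(solution, buffer, "subtract", scale_b=weight)
    out.label = solution.label + f" − {weight:.4g}·buffer"
    return out


def hydration_volume_fraction(spec: SampleSpec) -> float:
    """Hydration-layer volume fraction for a globular protein.

    ϕ_hyd = (c·N_A/M_w)·(4π/3)·[(r+d)³ − r³], with the concentration
    converted to g/Å³ so the result is dimensionless.  A result ≥ 1 is
    unphysical and almost always signals a unit mistake, so it raises.
    """
    c_g_per_A3 = spec.c_protein * 1e-3 / 1e24  # mg/mL → g/cm³ → g/Å³
    n_density = c_g_per_A3 * Avogadro / spec.m_w  # proteins per Å³
    r, d = spec.r_protein, spec.d_hydration
    shell = 4.0 * np.pi / 3.0 * ((r + d) ** 3 - r**3)
    phi = n_density * shell
    if phi >= 1.0:
        raise ValueError(
            f"hydration volume fraction {phi:.3g} ≥ 1 is unphysical "
            "(check concentration / radius units)"
        )
    return float(phi)
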