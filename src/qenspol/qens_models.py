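"""Resolution-convolved quasi-elastic models, per-q fitting, width analysis.

Two fit functions form the model ladder for protein-in-solution QENS:

* **elastic + one Lorentzian** — ``amp·[A₀·δ(ω) + (1−A₀)·L(ω; Γ)]`` plus a
  linear background, all convolved with the instrument resolution.  A₀(q)
  is the elastic incoherent structure factor (EISF); this is the model for
  locally confined internal dynamics with no resolvable global diffusion.

* **two Lorentzians, no elastic line** —
  ``amp₁·L(Γ₁) + amp₂·L(Γ₁+Γ₂)`` plus linear background, convolved.  Γ₁
  is the global-diffusion width and the second component carries the
  internal dynamics on top of diffusion; because the convolution of two
  Lorentzians is a Lorentzian whose half-widths add, the second width is
  Γ₁+Γ₂ exactly.

Fits are weighted least squares per q slice with a deterministic
multi-start over the quasi-elastic width (a decade bracketing the
resolution FWHM); confidence intervals come from the diagonal of the
unscaled covariance matrix, so σ entries are treated as true 1σ counting
errors.  Width-vs-q analysis converts a fitted HWHM slope against q² to a
diffusion coefficient through Γ = ħ D q² (ħ = 0.6582119 meV·ps), with a
jump-diffusion alternative Γ = ħDq²/(1 + Dq²τ) and an
inverse-variance-weighted constant width for confined dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .spectra_core import ResolutionModel, SqwMap

__all__ = [
    "HBAR_MEV_PS",
    "ModelSpec",
    "QFitResult",
    "WidthAnalysis",
    "SelectionReport",
    "lorentzian",
    "convolve_resolution",
    "eval_elastic_lorentzian",
    "eval_two_lorentzian",
    "fit_q_slice",
    "fit_map",
    "analyze_widths",
    "select_model",
]

#: ħ in meV·ps — converts a relaxation rate in ps⁻¹ to a HWHM in meV.
HBAR_MEV_PS = 0.6582119

GAMMA_MIN, GAMMA_MAX = 1e-4, 10.0  # physical HWHM bounds (meV)


@dataclass(frozen=True)
class ModelSpec:
    """Which member of the model ladder to fit.

    ``kind`` is ``"elastic_lorentzian"`` (delta + 1 Lorentzian, the EISF
    model), ``"two_lorentzian"`` (no delta) or ``"n_lorentzian"`` for the
    general sum; a linear-in-ω background is always included.
    """

    kind: str = "elastic_lorentzian"
    n_components: int = 1
    background: str = "linear_in_omega"
    delta_included: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("elastic_lorentzian", "two_lorentzian", "n_lorentzian"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.n_components < 1:
            raise ValueError("n_components must be ≥ 1")
        if self.kind == "elastic_lorentzian" and self.n_components != 1:
            raise ValueError("elastic_lorentzian uses exactly one Lorentzian")
        if self.kind == "two_lorentzian" and (self.n_components != 2 or self.delta_included):
            raise ValueError("two_lorentzian has two components and no delta line")


@dataclass
class QFitResult:
    """Fitted parameters for one q slice."""

    q: float
    model: ModelSpec
    params: dict[str, float]
    ci: dict[str, float]               # 1σ from the covariance diagonal
    red_chi2: float
    n_points: int
    n_free: int
    converged: bool = True
    message: str = ""


@dataclass
class WidthAnalysis:
    """Fit of Γ(q) across q: linear in q², jump diffusion, or constant."""

    model: str
    d_eff: float | None = None          # Å²/ns (reported ≥ 0)
    d_eff_err: float | None = None
    d_eff_raw: float | None = None      # unclipped estimate
    tau: float | None = None            # ps
    tau_err: float | None = None
    gamma_bar: float | None = None      # meV
    gamma_bar_err: float | None = None
    intercept: float | None = None      # meV, free-intercept linear fit
    intercept_err: float | None = None
    slope: float | None = None          # meV·Å²  (dΓ/dq²)
    slope_err: float | None = None
    d_eff_origin: float | None = None   # through-origin variant
    d_eff_origin_err: float | None = None
    fit_quality: float | None = None    # reduced χ² of the width fit


@dataclass
class SelectionReport:
    """Outcome of the model-selection ladder on one data set."""

    chosen: str
    median_red_chi2: float
    chi2_ok: bool
    slope: float
    slope_err: float
    slope_flat: bool                    # consistent with 0 at 2σ
    ambiguous: bool
    detail: str = ""
    bic_elastic: float | None = None    # information-criterion cross-check
    bic_two_lorentzian: float | None = None


def lorentzian(omega: np.ndarray, gamma: float) -> np.ndarray:
    """Unit-area Lorentzian density ``(1/π)·γ/(γ² + ω²)``; γ is the HWHM."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    omega = np.asarray(omega, dtype=float)
    return (gamma / np.pi) / (gamma**2 + omega**2)


def _kernel_center_index(omega: np.ndarray) -> int:
    return int(np.argmin(np.abs(omega)))


def convolve_resolution(
    model_slice: np.ndarray, omega: np.ndarray, kernel: np.ndarray
) -> np.ndarray:
    """Discrete convolution with a unit-area kernel on a uniform ω grid.

    The full linear convolution is sliced so that the kernel's ω = 0 sample
    stays aligned with the model grid, and multiplied by the grid spacing,
    so unit-area ⊗ unit-area stays unit-area and a delta placed in the
    ω = 0 bin maps exactly to the kernel lineshape.
    """
    omega = np.asarray(omega, dtype=float)
    if omega.size >= 2:
        steps = np.diff(omega)
        if np.any(np.abs(steps - steps.mean()) > 1e-6 * abs(steps.mean())):
            raise ValueError("convolution requires a uniform omega grid")
    d = float(omega[1] - omega[0])
    j0 = _kernel_center_index(omega)
    full = np.convolve(model_slice, kernel)
    return full[j0 : j0 + omega.size] * d


def _background(omega: np.ndarray, intercept: float, slope: float) -> np.ndarray:
    return intercept + slope * omega


def eval_elastic_lorentzian(
    omega: np.ndarray,
    kernel: np.ndarray,
    a0: float,
    amp: float,
    gamma: float,
    bkg_intercept: float = 0.0,
    bkg_slope: float = 0.0,
) -> np.ndarray:
    """EISF model: ``amp·[a0·δ + (1−a0)·L(γ)] ⊗ R + linear bkg``.

    The delta convolves to the resolution lineshape itself, which is used
    analytically (no finite-bin spike).
    """
    if not 0.0 <= a0 <= 1.0:
        raise ValueError("EISF a0 must lie in [0, 1]")
    quasi = convolve_resolution(lorentzian(omega, gamma), omega, kernel)
    return amp * (a0 * kernel + (1.0 - a0) * quasi) + _background(
        omega, bkg_intercept, bkg_slope
    )


def eval_two_lorentzian(
    omega: np.ndarray,
    kernel: np.ndarray,
    amp1: float,
    gamma1: float,
    amp2: float,
    gamma2: float,
    bkg_intercept: float = 0.0,
    bkg_slope: float = 0.0,
) -> np.ndarray:
    """Two-process model ``[amp1·L(γ₁) + amp2·L(γ₁+γ₂)] ⊗ R + linear bkg``.

    The second width is γ₁+γ₂ because the internal relaxation rides on the
    global diffusion (Lorentzian HWHMs add under convolution); γ₂ = 0
    collapses both components onto a single Lorentzian of width γ₁.
    """
    slice_ = amp1 * lorentzian(omega, gamma1)
    g2 = gamma1 + gamma2
    if g2 > 0:
        slice_ = slice_ + amp2 * lorentzian(omega, g2)
    out = convolve_resolution(slice_, omega, kernel)
    return out + _background(omega, bkg_intercept, bkg_slope)


# ---------------------------------------------------------------------------
# per-q weighted fitting with a deterministic multi-start

_ELASTIC_NAMES = ("a0", "amp", "gamma1", "bkg_intercept", "bkg_slope")
_TWOLOR_NAMES = ("amp1", "gamma1", "amp2", "gamma2", "bkg_intercept", "bkg_slope")


def _fit_once(residual, p0, bounds):
    return least_squares(
        residual, p0, bounds=bounds, method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
        max_nfev=2000,
    )


def _covariance(res) -> np.ndarray:
    # residuals are already σ-scaled → unscaled (JᵀJ)⁻¹ is the parameter covariance
    j = res.jac
    try:
        cov = np.linalg.pinv(j.T @ j)
    except np.linalg.LinAlgError:
        cov = np.full((j.shape[1], j.shape[1]), np.nan)
    return cov


def fit_q_slice(
    data: SqwMap,
    q_index: int,
    model: ModelSpec,
    res: ResolutionModel,
) -> QFitResult:
    """Weighted least-squares fit of one q row.

    Minimizes Σ[(data − model)/σ]².  A fixed grid of quasi-elastic width
    starts spanning a decade around the resolution FWHM makes the result
    deterministic; among equal-χ² minima the smallest γ₁ wins.
    """
    omega = data.omega
    y = data.intensity[q_index]
    sig = data.sigma[q_index]
    kernel = res.kernel(omega, q_index)
    fwhm = res.fwhm if res.kind == "gaussian" else _tabulated_fwhm(omega, kernel)

    n = omega.size
    area = max(float(np.trapezoid(np.clip(y, 0, None), omega)), 1e-12)

    if model.kind == "elastic_lorentzian":
        names = _ELASTIC_NAMES
        lo = np.array([0.0, 0.0, GAMMA_MIN, -np.inf, -np.inf])
        hi = np.array([1.0, np.inf, GAMMA_MAX, np.inf, np.inf])

        def model_fn(p):
            return eval_elastic_lorentzian(omega, kernel, *p)

        starts = [
            np.array([0.5, area, g, 0.0, 0.0])
            for g in (fwhm / 3.0, fwhm, 3.0 * fwhm)
        ]
        gamma_of = lambda p: p[2]
    elif model.kind == "two_lorentzian":
        names = _TWOLOR_NAMES
        lo = np.array([0.0, GAMMA_MIN, 0.0, GAMMA_MIN, -np.inf, -np.inf])
        hi = np.array([np.inf, GAMMA_MAX, np.inf, GAMMA_MAX, np.inf, np.inf])

        def model_fn(p):
            return eval_two_lorentzian(omega, kernel, *p)

        starts = [
            np.array([0.5 * area, g1, 0.5 * area, g2, 0.0, 0.0])
            for g1 in (fwhm / 10.0, fwhm / 2.0)
            for g2 in (fwhm / 2.0, 2.0 * fwhm)
        ]
        gamma_of = lambda p: p[1]
    else:
        raise NotImplementedError("general n_lorentzian fitting is not implemented")

    n_free = len(names)
    if n < 2 * n_free:
        raise ValueError(
            f"q slice has {n} points for {n_free} free parameters "
            "(need at least a factor 2)"
        )

    def residual(p):
        return (model_fn(p) - y) / sig

    best = None
    for p0 in starts:
        try:
            r = _fit_once(residual, p0, (lo, hi))
        except Exception:
            continue
        if best is None or r.cost < best.cost - 1e-12 or (
            abs(r.cost - best.cost) <= 1e-12 and gamma_of(r.x) < gamma_of(best.x)
        ):
            best = r
    q = float(data.q_centers[q_index])
    if best is None:
        return QFitResult(
            q=q, model=model, params={}, ci={}, red_chi2=np.inf,
            n_points=n, n_free=n_free, converged=False,
            message="no start converged",
        )
    cov = _covariance(best)
    chi2 = 2.0 * best.cost
    return QFitResult(
        q=q,
        model=model,
        params=dict(zip(names, best.x)),
        ci=dict(zip(names, np.sqrt(np.clip(np.diag(cov), 0, None)))),
        red_chi2=chi2 / max(n - n_free, 1),
        n_points=n,
        n_free=n_free,
        converged=bool(best.success),
        message=str(best.message),
    )


def _tabulated_fwhm(omega: np.ndarray, kernel: np.ndarray) -> float:
    half = kernel.max() / 2.0
    above = omega[kernel >= half]
    return float(above[-1] - above[0]) if above.size >= 2 else float(
        omega[1] - omega[0]
    )


def fit_map(
    data: SqwMap,
    model: ModelSpec,
    res: ResolutionModel,
    q_min: float | None = None,
    q_max: float | None = None,
) -> list[QFitResult]:
    """Fit every q slice inside an optional q window."""
    out = []
    for i, q in enumerate(data.q_centers):
        if q_min is not None and q < q_min:
            continue
        if q_max is not None and q > q_max:
            continue
        out.append(fit_q_slice(data, i, model, res))
    return out


# ---------------------------------------------------------------------------
# width-vs-q analysis

def _width_points(results: list[QFitResult]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ok = [r for r in results if r.converged and "gamma1" in r.params]
    q = np.array([r.q for r in ok])
    g = np.array([r.params["gamma1"] for r in ok])
    s = np.array([r.ci.get("gamma1", np.nan) for r in ok])
    s = np.where(np.isfinite(s) & (s > 0), s, np.nanmax(s[np.isfinite(s)]) if np.any(np.isfinite(s) & (s > 0)) else 1.0)
    return q, g, s


def _weighted_linear(x, y, w):
    """Weighted LSQ of y = a + b·x; returns (a, b, σ_a, σ_b, red_chi2).

    Parameter errors are scaled by √(max(red_chi2, 1)): the deviations of
    Γ(q) from any simple q dependence are usually systematic rather than
    statistical, and the quoted uncertainty should reflect the scatter of
    the points, never shrinking below the statistical floor.
    """
    sw, swx = w.sum(), (w * x).sum()
    swxx, swy, swxy = (w * x * x).sum(), (w * y).sum(), (w * x * y).sum()
    delta = sw * swxx - swx**2
    a = (swxx * swy - swx * swxy) / delta
    b = (sw * swxy - swx * swy) / delta
    var_a = swxx / delta
    var_b = sw / delta
    chi2 = (w * (y - a - b * x) ** 2).sum()
    dof = max(x.size - 2, 1)
    scale = np.sqrt(max(chi2 / dof, 1.0))
    return a, b, scale * np.sqrt(var_a), scale * np.sqrt(var_b), chi2 / dof


def analyze_widths(
    results: list[QFitResult], mode: str = "linear_q2"
) -> WidthAnalysis:
    """Fit the q dependence of the quasi-elastic HWHM Γ(q).

    ``linear_q2``: weighted straight line in q² (free intercept, with the
    through-origin variant reported alongside); the slope converts to an
    effective diffusion coefficient via Γ = ħ D q², reported in Å²/ns.  A
    negative estimate is reported as 0 with its uncertainty (and the raw
    value kept).  ``jump_diffusion``: Γ = ħDq²/(1 + Dq²τ).  ``constant``:
    inverse-variance-weighted mean width.
    """
    q, g, s = _width_points(results)
    need = 4 if mode == "jump_diffusion" else 3
    if q.size < need:
        raise ValueError(f"{mode} width analysis needs ≥ {need} q points, got {q.size}")
    w = 1.0 / s**2

    if mode == "constant":
        gamma_bar = float((w * g).sum() / w.sum())
        chi2 = float((w * (g - gamma_bar) ** 2).sum() / max(q.size - 1, 1))
        err = float(np.sqrt(max(chi2, 1.0)) / np.sqrt(w.sum()))
        # slope check retained so callers can test q²-independence
        _, b, _, sb, _ = _weighted_linear(q**2, g, w)
        return WidthAnalysis(
            model="constant", gamma_bar=gamma_bar, gamma_bar_err=err,
            slope=float(b), slope_err=float(sb), fit_quality=chi2,
        )

    if mode == "linear_q2":
        x = q**2
        a, b, sa, sb, red = _weighted_linear(x, g, w)
        # Γ[meV] = ħ[meV·ps] · D[Å²/ps] · q² → D[Å²/ns] = slope/ħ · 1000
        d_raw = b / HBAR_MEV_PS * 1000.0
        d_err = sb / HBAR_MEV_PS * 1000.0
        b0 = (w * x * g).sum() / (w * x * x).sum()
        chi0 = (w * (g - b0 * x) ** 2).sum() / max(x.size - 1, 1)
        sb0 = np.sqrt(max(chi0, 1.0) / (w * x * x).sum())
        return WidthAnalysis(
            model="linear_q2",
            d_eff=float(max(d_raw, 0.0)),
            d_eff_err=float(d_err),
            d_eff_raw=float(d_raw),
            intercept=float(a), intercept_err=float(sa),
            slope=float(b), slope_err=float(sb),
            d_eff_origin=float(max(b0 / HBAR_MEV_PS * 1000.0, 0.0)),
            d_eff_origin_err=float(sb0 / HBAR_MEV_PS * 1000.0),
            fit_quality=float(red),
        )

    if mode == "jump_diffusion":

        def resid(p):
            d_ps, tau = p
            model = HBAR_MEV_PS * d_ps * q**2 / (1.0 + d_ps * q**2 * tau)
            return (model - g) / s

        # start from the linear estimate
        _, b, _, _, _ = _weighted_linear(q**2, g, w)
        d0 = max(b / HBAR_MEV_PS, 1e-6)
        best = None
        for tau0 in (0.1, 1.0, 10.0, 100.0):
            r = least_squares(
                resid, [d0, tau0], bounds=([0.0, 0.0], [np.inf, np.inf]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            if best is None or r.cost < best.cost:
                best = r
        cov = _covariance(best)
        chi2 = 2.0 * best.cost / max(q.size - 2, 1)
        errs = np.sqrt(np.clip(np.diag(cov), 0, None)) * np.sqrt(max(chi2, 1.0))
        d_ns = best.x[0] * 1000.0
        return WidthAnalysis(
            model="jump_diffusion",
            d_eff=float(max(d_ns, 0.0)),
            d_eff_err=float(errs[0] * 1000.0),
            d_eff_raw=float(d_ns),
            tau=float(best.x[1]), tau_err=float(errs[1]),
            fit_quality=float(chi2),
        )

    raise ValueError(f"unknown width-analysis mode {mode!r}")


# ---------------------------------------------------------------------------
# model-selection ladder

def _bic(results: list[QFitResult]) -> float:
    chi2 = sum(r.red_chi2 * max(r.n_points - r.n_free, 1) for r in results)
    n = sum(r.n_points for r in results)
    k = sum(r.n_free for r in results)
    return chi2 + k * np.log(max(n, 1))


def select_model(
    results_elastic: list[QFitResult],
    results_two_lorentzian: list[QFitResult],
    widths_elastic: WidthAnalysis | None = None,
    chi2_threshold: float = 2.0,
) -> SelectionReport:
    """Apply the simplest-model-first ladder.

    The elastic+Lorentzian model is accepted iff its median reduced χ² is
    below ``chi2_threshold`` **and** its width shows no q² trend (slope
    consistent with 0 at 2σ, the signature of purely local dynamics).  A
    q²-linear width from this model is unphysical for confined internal
    motion, so either failure escalates to the two-Lorentzian model.  An
    information-criterion (BIC) comparison is reported as a cross-check
    but never overrides the ladder.
    """
    if widths_elastic is None:
        widths_elastic = analyze_widths(results_elastic, "linear_q2")
    med = float(np.median([r.red_chi2 for r in results_elastic]))
    chi2_ok = med < chi2_threshold
    slope = widths_elastic.slope
    slope_err = widths_elastic.slope_err
    slope_flat = abs(slope) <= 2.0 * slope_err
    chosen = "elastic_lorentzian" if (chi2_ok and slope_flat) else "two_lorentzian"
    ambiguous = chi2_ok != slope_flat
    detail = (
        f"median red_chi2 = {med:.3g} ({'<' if chi2_ok else '≥'} "
        f"{chi2_threshold}); width slope = {slope:.3g} ± {slope_err:.3g} meV·Å² "
        f"({'flat' if slope_flat else 'rising'} at 2σ)"
    )
    return SelectionReport(
        chosen=chosen,
        median_red_chi2=med,
        chi2_ok=chi2_ok,
        slope=float(slope),
        slope_err=float(slope_err),
        slope_flat=slope_flat,
        ambiguous=ambiguous,
        detail=detail,
        bic_elastic=float(_bic(results_elastic)),
        bic_two_lorentzian=float(_bic(results_two_lorentzian)),
    )
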