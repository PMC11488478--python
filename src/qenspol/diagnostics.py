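"""q-range contamination diagnostics for unpolarized QENS.

Coherent scattering from the (deuterated) buffer and hydration layer
peaks at high q and contaminates the "incoherent" analysis of total
spectra.  Two complementary diagnostics locate the largest safe q:

* **0.5-ratio rule** — integrate the separated buffer spectra over an
  elastic energy window, form the coherent/incoherent S(q) ratio, and
  discard every q beyond the first crossing of 0.5 (conservative
  first-crossing semantics; the crossing q is linearly interpolated
  between the bracketing bins).

* **sample/buffer sigmoid** — when no separated data exist, the ratio of
  integrated sample to integrated buffer intensity rises sigmoidally
  where coherent scattering takes over; a four-parameter logistic is
  fitted and the q at which its slope begins to increase (the maximum of
  the second derivative, q₀ − ln(2+√3)/k) marks the onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .polarization import SeparatedSet
from .spectra_core import SqwMap, integrate_window, _check_grids

__all__ = [
    "QRangeReport",
    "coh_inc_ratio",
    "qmax_from_ratio",
    "sample_buffer_sigmoid",
    "buffer_qrange_report",
    "LOGISTIC_ONSET_OFFSET",
]

#: the logistic's second derivative peaks at q0 − ln(2+√3)/k
LOGISTIC_ONSET_OFFSET = float(np.log(2.0 + np.sqrt(3.0)))


@dataclass
class QRangeReport:
    """Per-q diagnostic ratios and the derived q-range limits."""

    q: np.ndarray
    ratio_coh_inc: np.ndarray | None = None
    ratio_coh_inc_sigma: np.ndarray | None = None
    ratio_sample_buffer: np.ndarray | None = None
    ratio_sample_buffer_sigma: np.ndarray | None = None
    q_max_ratio: float | None = None
    q_max_flag: str = ""
    q_unity: float | None = None       # supplementary: where coh/inc = 1
    q_turning: float | None = None
    q_turning_ci: float | None = None
    q_turning_flag: str = ""
    window_used: float | None = None   # meV


def coh_inc_ratio(
    buffer: SeparatedSet, window: float, center: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-q coherent/incoherent integrated-buffer ratio.

    Returns ``(q, ratio, sigma)``; bins whose incoherent integral is not
    positive are NaN (undefined).  Raises if every bin is undefined.
    """
    coh, coh_s = integrate_window(buffer.coh, window, center)
    inc, inc_s = integrate_window(buffer.inc, window, center)
    ratio = np.full_like(coh, np.nan)
    sigma = np.full_like(coh, np.nan)
    ok = inc > 0
    ratio[ok] = coh[ok] / inc[ok]
    sigma[ok] = np.abs(ratio[ok]) * np.sqrt(
        (coh_s[ok] / np.where(coh[ok] != 0, coh[ok], np.inf)) ** 2
        + (inc_s[ok] / inc[ok]) ** 2
    )
    if not np.any(ok):
        raise ValueError("incoherent buffer integral non-positive at every q")
    return buffer.inc.q_centers.copy(), ratio, sigma


def _interp_crossing(q, r, i, threshold):
    """Linear interpolation of the threshold crossing between bins i-1, i."""
    q0, q1, r0, r1 = q[i - 1], q[i], r[i - 1], r[i]
    if r1 == r0:
        return float(q0)
    return float(q0 + (threshold - r0) * (q1 - q0) / (r1 - r0))


def qmax_from_ratio(
    q: np.ndarray, ratio: np.ndarray, threshold: float = 0.5
) -> tuple[float | None, str]:
    """Largest admissible q under the ratio rule (first-crossing semantics).

    Returns ``(q_max, flag)``.  q_max is the interpolated q of the first
    upward crossing of ``threshold``; q values beyond it are discarded
    even if the ratio later dips back (conservative).  If the ratio never
    exceeds the threshold the grid maximum is returned with flag
    ``"never-exceeds"``; if the very first bin already exceeds it, q_max
    is None with flag ``"exceeds-at-qmin"``.
    """
    q = np.asarray(q, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    ok = np.isfinite(ratio)
    q, ratio = q[ok], ratio[ok]
    if q.size < 2:
        raise ValueError("ratio must be defined on at least 2 q points")
    if ratio[0] > threshold:
        return None, "exceeds-at-qmin"
    above = np.nonzero(ratio > threshold)[0]
    if above.size == 0:
        return float(q[-1]), "never-exceeds"
    i = int(above[0])
    return _interp_crossing(q, ratio, i, threshold), ""


def _logistic(q, p):
    a, b, k, q0 = p
    return a + b / (1.0 + np.exp(-k * (q - q0)))


def sample_buffer_sigmoid(
    sample_tot: SqwMap,
    buffer_tot: SqwMap,
    window: float,
    center: float = 0.0,
) -> QRangeReport:
    """Sample/buffer integrated-intensity ratio and its sigmoid onset.

    Fits ``a + b/(1 + exp(−k(q−q₀)))`` to the per-q ratio and reports the
    q at which the curve's second derivative is maximal — where the slope
    begins to increase.  For a rising sigmoid (b > 0) that is the onset
    of the rising limb at ``q₀ − ln(2+√3)/k``; for a falling one (b < 0,
    the typical shape when the buffer's coherent bump takes over the
    denominator) it is the onset of the flattening at ``q₀ + ln(2+√3)/k``.
    If the logistic fit fails, falls back to the maximum discrete second
    difference (flagged); a flat ratio yields no turning point.
    """
    _check_grids(sample_tot, buffer_tot)
    s, s_sig = integrate_window(sample_tot, window, center)
    b, b_sig = integrate_window(buffer_tot, window, center)
    ratio = np.where(b > 0, s / np.where(b > 0, b, 1.0), np.nan)
    sigma = np.abs(ratio) * np.sqrt(
        (s_sig / np.where(s != 0, s, np.inf)) ** 2
        + (b_sig / np.where(b > 0, b, np.inf)) ** 2
    )
    q = sample_tot.q_centers
    report = QRangeReport(
        q=q.copy(), ratio_sample_buffer=ratio, ratio_sample_buffer_sigma=sigma,
        window_used=window,
    )
    ok = np.isfinite(ratio)
    qf, rf = q[ok], ratio[ok]
    wf = np.where(np.isfinite(sigma[ok]) & (sigma[ok] > 0), sigma[ok], np.nanmax(sigma[ok]))
    if qf.size < 5 or np.ptp(rf) < 1e-9 * max(abs(rf).max(), 1.0):
        report.q_turning_flag = "flat-ratio"
        return report

    span = np.ptp(rf)
    rising = rf[-1] >= rf[0]
    mid = qf[np.argmin(np.abs(rf - (rf.min() + span / 2)))]
    p0 = np.array([rf.min() if rising else rf.max(),
                   span if rising else -span,
                   4.0 / max(np.ptp(qf), 1e-6), mid])
    try:
        fit = least_squares(
            lambda p: (_logistic(qf, p) - rf) / wf,
            p0,
            bounds=([-np.inf, -np.inf, 1e-3, qf[0] - np.ptp(qf)],
                    [np.inf, np.inf, 1e3, qf[-1] + np.ptp(qf)]),
            xtol=1e-12, ftol=1e-12,
        )
        if not fit.success:
            raise RuntimeError(fit.message)
        a, bamp, k, q0 = fit.x
        # rising limb: the slope starts increasing at the onset of the limb,
        # q0 − ln(2+√3)/k (max curvature); falling limb: the (negative)
        # slope begins to increase at the inflection point q0 itself.
        side = -1.0 if bamp > 0 else 0.0
        turning = q0 + side * LOGISTIC_ONSET_OFFSET / k
        # CI on the turning point from the covariance of (k, q0)
        jtj = fit.jac.T @ fit.jac
        cov = np.linalg.pinv(jtj)
        grad = np.zeros(4)
        grad[2] = -side * LOGISTIC_ONSET_OFFSET / k**2
        grad[3] = 1.0
        report.q_turning = float(turning)
        report.q_turning_ci = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    except Exception:
        # discrete fallback: maximum second difference of the ratio
        d2 = np.diff(rf, 2)
        report.q_turning = float(qf[1 + int(np.argmax(d2))])
        report.q_turning_flag = "discrete-fallback"
    return report


def buffer_qrange_report(
    buffer: SeparatedSet,
    window: float,
    threshold: float = 0.5,
    sample_tot: SqwMap | None = None,
    center: float = 0.0,
) -> QRangeReport:
    """Full diagnostic report: 0.5-rule cutoff plus optional sigmoid onset."""
    q, ratio, sigma = coh_inc_ratio(buffer, window, center)
    q_max, flag = qmax_from_ratio(q, ratio, threshold)
    q_unity, _ = qmax_from_ratio(q, ratio, 1.0)
    report = QRangeReport(
        q=q, ratio_coh_inc=ratio, ratio_coh_inc_sigma=sigma,
        q_max_ratio=q_max, q_max_flag=flag, q_unity=q_unity, window_used=window,
    )
    if sample_tot is not None:
        sig = sample_buffer_sigmoid(sample_tot, buffer.tot, window, center)
        report.ratio_sample_buffer = sig.ratio_sample_buffer
        report.ratio_sample_buffer_sigma = sig.ratio_sample_buffer_sigma
        report.q_turning = sig.q_turning
        report.q_turning_ci = sig.q_turning_ci
        report.q_turning_flag = sig.q_turning_flag
    return report
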