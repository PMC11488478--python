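"""Shared data model for dynamic structure factor maps.

The universal currency of the pipeline is the :class:`SqwMap`: a dynamic
structure factor S(q, ω) sampled on a fixed momentum-transfer grid
(bin centers ``q_centers``, constant integration step ``dq``, Å⁻¹) and a
uniform energy-transfer grid (``omega``, meV), with a per-bin
1-standard-deviation uncertainty.  Energies are stored in meV internally;
CLI entry points accept μeV and convert, so that resolution widths quoted
in μeV and quasi-elastic widths on the meV scale never mix units silently.

The instrument lineshape is carried by :class:`ResolutionModel`, either a
parametric Gaussian of given FWHM or per-q tabulated lineshapes (as
obtained from a low-temperature measurement where no quasi-elastic
broadening is present).  Every lineshape is normalized to unit integral on
its grid, which is what the convolution contract downstream relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import h5py
import numpy as np

__all__ = [
    "SqwMap",
    "ResolutionModel",
    "GridMismatchError",
    "arithmetic",
    "integrate_window",
    "read_sqw",
    "write_sqw",
    "MICRO_EV",
]

logger = logging.getLogger(__name__)

#: 1 μeV expressed in meV (CLI unit conversion factor).
MICRO_EV = 1e-3

_SIGMA_FLOOR_FRACTION = 1e-12
_OMEGA_UNIFORMITY_RTOL = 1e-6


class GridMismatchError(ValueError):
    """Raised when two maps that must share axes do not."""


def _check_grids(a: "SqwMap", b: "SqwMap") -> None:
    if a.q_centers.shape != b.q_centers.shape or not np.allclose(
        a.q_centers, b.q_centers, rtol=0, atol=0
    ):
        diff = (
            np.argmin(a.q_centers == b.q_centers)
            if a.q_centers.shape == b.q_centers.shape
            else 0
        )
        raise GridMismatchError(
            f"q grids differ (first differing q: "
            f"{a.q_centers[diff] if diff < a.q_centers.size else 'length'} vs "
            f"{b.q_centers[diff] if diff < b.q_centers.size else len(b.q_centers)})"
        )
    if a.omega.shape != b.omega.shape or not np.allclose(a.omega, b.omega, rtol=0, atol=0):
        if a.omega.shape == b.omega.shape:
            diff = int(np.argmax(a.omega != b.omega))
            raise GridMismatchError(
                f"omega grids differ (first differing omega: "
                f"{a.omega[diff]} vs {b.omega[diff]} meV)"
            )
        raise GridMismatchError(
            f"omega grids differ in length ({a.omega.size} vs {b.omega.size})"
        )


@dataclass
class SqwMap:
    """A 2-D dynamic structure factor S(q, ω) with per-bin uncertainties.

    Parameters
    ----------
    q_centers
        Momentum-transfer bin centers in Å⁻¹, strictly ascending.
    omega
        Energy-transfer grid in meV, ascending with uniform spacing.
    intensity
        S values (counts-like arbitrary units), shape ``(len(q), len(omega))``.
    sigma
        1σ uncertainties, same shape.  Non-positive or non-finite entries
        are floored at 1e-12 of the maximum intensity (a logged warning)
        so that weighted fits never see infinite weights.
    dq
        q-integration step in Å⁻¹ (constant-width q bins).
    label
        Free-text provenance tag.
    """

    q_centers: np.ndarray
    omega: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    dq: float = 0.1
    label: str = ""

    def __post_init__(self) -> None:
        self.q_centers = np.asarray(self.q_centers, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q_centers.ndim != 1 or self.omega.ndim != 1:
            raise ValueError("q_centers and omega must be 1-D")
        shape = (self.q_centers.size, self.omega.size)
        if self.intensity.shape != shape:
            raise ValueError(
                f"intensity has shape {self.intensity.shape}, expected {shape}"
            )
        if self.sigma.shape != shape:
            raise ValueError(f"sigma has shape {self.sigma.shape}, expected {shape}")
        if np.any(np.diff(self.q_centers) <= 0):
            raise ValueError("q_centers must be strictly increasing")
        if self.dq <= 0:
            raise ValueError("dq must be > 0")
        steps = np.diff(self.omega)
        if self.omega.size >= 2:
            if np.any(steps <= 0):
                raise ValueError("omega must be strictly increasing")
            mean = steps.mean()
            if np.any(np.abs(steps - mean) > _OMEGA_UNIFORMITY_RTOL * abs(mean)):
                raise ValueError(
                    "omega spacing is not uniform (required by the convolution "
                    "contract): max deviation "
                    f"{np.max(np.abs(steps - mean)):.3g} meV"
                )
        bad = ~(self.sigma > 0) & np.isfinite(self.intensity)
        if np.any(bad):
            floor = _SIGMA_FLOOR_FRACTION * max(
                np.nanmax(np.abs(self.intensity)), 1.0
            )
            logger.warning(
                "flooring %d non-positive sigma entries at %.3g", bad.sum(), floor
            )
            self.sigma = np.where(bad, floor, self.sigma)

    @property
    def domega(self) -> float:
        """Uniform energy-grid spacing (meV)."""
        return float(self.omega[1] - self.omega[0]) if self.omega.size > 1 else 0.0

    def copy(self, **changes) -> "SqwMap":
        out = replace(self, **changes)
        out.intensity = out.intensity.copy()
        out.sigma = out.sigma.copy()
        return out


@dataclass
class ResolutionModel:
    """Instrument lineshape used as the convolution kernel.

    ``kind="gaussian"`` uses a Gaussian of full width at half maximum
    ``fwhm`` (meV); ``kind="tabulated"`` carries per-q lineshapes sampled
    on the analysis ω grid (e.g. from a T = 2 K measurement).  Kernels are
    normalized to unit trapezoidal integral on their grid.
    """

    kind: str = "gaussian"
    fwhm: float | None = None
    omega: np.ndarray | None = None
    lineshapes: np.ndarray | None = None  # (n_q, n_omega) or (n_omega,)

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "tabulated"):
            raise ValueError(f"unknown resolution kind {self.kind!r}")
        if self.kind == "gaussian":
            if self.fwhm is None or self.fwhm <= 0:
                raise ValueError("gaussian resolution requires fwhm > 0")
        else:
            if self.omega is None or self.lineshapes is None:
                raise ValueError("tabulated resolution requires omega and lineshapes")
            self.omega = np.asarray(self.omega, dtype=float)
            shapes = np.atleast_2d(np.asarray(self.lineshapes, dtype=float))
            norm = np.trapezoid(shapes, self.omega, axis=1)
            if np.any(norm <= 0):
                raise ValueError("tabulated lineshape with non-positive area")
            self.lineshapes = shapes / norm[:, None]

    @classmethod
    def from_map(cls, m: SqwMap) -> "ResolutionModel":
        """Build a tabulated model from a measured (elastic-only) map."""
        return cls(kind="tabulated", omega=m.omega, lineshapes=m.intensity)

    def kernel(self, omega: np.ndarray, q_index: int = 0) -> np.ndarray:
        """Unit-area lineshape sampled on ``omega``."""
        omega = np.asarray(omega, dtype=float)
        if self.kind == "gaussian":
            s = self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            k = np.exp(-0.5 * (omega / s) ** 2)
        else:
            if omega.shape == self.omega.shape and np.allclose(omega, self.omega):
                k = self.lineshapes[min(q_index, self.lineshapes.shape[0] - 1)]
            else:
                k = np.interp(
                    omega,
                    self.omega,
                    self.lineshapes[min(q_index, self.lineshapes.shape[0] - 1)],
                    left=0.0,
                    right=0.0,
                )
        area = np.trapezoid(k, omega)
        if area <= 0:
            raise ValueError("resolution kernel has non-positive area on this grid")
        return k / area


def arithmetic(a: SqwMap, b: SqwMap, op: str, scale_b: float = 1.0) -> SqwMap:
    """Elementwise ``a ± scale_b·b`` with quadrature uncertainty propagation.

    The two maps must share identical q and ω grids; the output keeps them.
    ``sigma = sqrt(σ_a² + scale_b²·σ_b²)``.
    """
    if op not in ("add", "subtract"):
        raise ValueError(f"op must be 'add' or 'subtract', got {op!r}")
    _check_grids(a, b)
    sign = 1.0 if op == "add" else -1.0
    intensity = a.intensity + sign * scale_b * b.intensity
    sigma = np.sqrt(a.sigma**2 + scale_b**2 * b.sigma**2)
    return SqwMap(
        q_centers=a.q_centers.copy(),
        omega=a.omega.copy(),
        intensity=intensity,
        sigma=sigma,
        dq=a.dq,
        label=f"{a.label}{'+' if sign > 0 else '-'}{scale_b:g}*{b.label}",
    )


def integrate_window(
    m: SqwMap, window: float, center: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-q trapezoidal integral of S(q, ω) over an energy window.

    The window is a full width ``window`` (meV) centered on ``center``;
    partial bins at the window edges are clipped by linear interpolation.
    Returns ``(s_q, s_q_sigma)`` with uncertainties propagated through the
    trapezoid weights in quadrature.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    lo, hi = center - window / 2.0, center + window / 2.0
    om = m.omega
    if hi < om[0] or lo > om[-1]:
        raise ValueError(
            f"integration window [{lo:g}, {hi:g}] meV does not intersect the "
            f"energy grid [{om[0]:g}, {om[-1]:g}] meV"
        )
    lo_c, hi_c = max(lo, om[0]), min(hi, om[-1])
    inside = (om > lo_c) & (om < hi_c)
    # node positions: clipped edges plus interior grid points
    nodes = np.concatenate(([lo_c], om[inside], [hi_c]))
    # trapezoid weights on the node set
    w = np.zeros_like(nodes)
    dx = np.diff(nodes)
    w[:-1] += dx / 2.0
    w[1:] += dx / 2.0

    n_q = m.q_centers.size
    s = np.empty(n_q)
    s_sig = np.empty(n_q)
    for i in range(n_q):
        y = np.interp(nodes, om, m.intensity[i])
        ysig = np.interp(nodes, om, m.sigma[i])
        s[i] = float(np.dot(w, y))
        s_sig[i] = float(np.sqrt(np.dot(w**2, ysig**2)))
    return s, s_sig


# ---------------------------------------------------------------------------
# I/O: a self-describing delimited text dialect plus an HDF5 dialect.

_TEXT_MAGIC = "# qenspol sqw v1"


def write_sqw(m: SqwMap, path) -> None:
    """Write a map; ``.h5``/``.hdf5`` selects the HDF5 dialect, else text."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            f.create_dataset("q_centers", data=m.q_centers)
            f.create_dataset("omega", data=m.omega)
            f.create_dataset("intensity", data=m.intensity)
            f.create_dataset("sigma", data=m.sigma)
            f.attrs["dq"] = m.dq
            f.attrs["label"] = m.label
            f.attrs["units"] = "q:1/angstrom omega:meV"
        return
    with open(path, "w") as f:
        f.write(_TEXT_MAGIC + "\n")
        f.write(f"# label: {m.label}\n")
        f.write(f"# dq: {m.dq!r}\n")
        f.write("# q_centers: " + " ".join(repr(float(q)) for q in m.q_centers) + "\n")
        f.write(
            "# columns: omega"
            + "".join(f" I(q{i}) sigma(q{i})" for i in range(m.q_centers.size))
            + "\n"
        )
        for j, w in enumerate(m.omega):
            row = [repr(float(w))]
            for i in range(m.q_centers.size):
                row.append(repr(float(m.intensity[i, j])))
                row.append(repr(float(m.sigma[i, j])))
            f.write("\t".join(row) + "\n")


class SqwParseError(ValueError):
    """Malformed S(q, ω) text file (carries the offending line number)."""


def read_sqw(path) -> SqwMap:
    """Read a map written by :func:`write_sqw` (either dialect)."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            return SqwMap(
                q_centers=f["q_centers"][...],
                omega=f["omega"][...],
                intensity=f["intensity"][...],
                sigma=f["sigma"][...],
                dq=float(f.attrs["dq"]),
                label=str(f.attrs.get("label", "")),
            )
    with open(path) as f:
        lines = f.readlines()
    if not lines or lines[0].strip() != _TEXT_MAGIC:
        raise SqwParseError(f"{path}:1: missing header line {_TEXT_MAGIC!r}")
    label, dq, q_centers = "", None, None
    body_start = None
    for ln, line in enumerate(lines[1:], start=2):
        if not line.startswith("#"):
            body_start = ln
            break
        content = line[1:].strip()
        if content.startswith("label:"):
            label = content[len("label:"):].strip()
        elif content.startswith("dq:"):
            dq = float(content[len("dq:"):])
        elif content.startswith("q_centers:"):
            try:
                q_centers = np.array(
                    [float(x) for x in content[len("q_centers:"):].split()]
                )
            except ValueError as e:
                raise SqwParseError(f"{path}:{ln}: bad q_centers ({e})") from e
    if dq is None or q_centers is None or body_start is None:
        raise SqwParseError(f"{path}: header incomplete (need dq, q_centers, data)")
    n_q = q_centers.size
    n_cols = 1 + 2 * n_q
    omega, inten, sig = [], [], []
    for ln, line in enumerate(lines[body_start - 1:], start=body_start):
        if not line.strip():
            continue
        cells = line.split()
        if len(cells) != n_cols:
            raise SqwParseError(
                f"{path}:{ln}: expected {n_cols} columns, found {len(cells)}"
            )
        try:
            vals = [float(c) for c in cells]
        except ValueError as e:
            raise SqwParseError(f"{path}:{ln}: non-numeric cell ({e})") from e
        omega.append(vals[0])
        inten.append(vals[1::2])
        sig.append(vals[2::2])
    return SqwMap(
        q_centers=q_centers,
        omega=np.array(omega),
        intensity=np.array(inten).T,
        sigma=np.array(sig).T,
        dq=dq,
        label=label,
    )
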