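"""Optical model behind calcite mass estimation under circular polarizers.

A thin calcite plate of thickness ``t`` (μm) between crossed circular
polarizers retards light by ``Γ = t · Δn_eff · 1000`` nanometres and, in the
first interference order, appears with a grey value that increases
monotonically with retardation.  This module provides the forward model
(retardation → grey), its calibrated inverse (grey → retardation), and the
conversion of retardation to calcite thickness and per-pixel mass:

    t  = Γ / (1000 · Δn_eff)            [μm]
    m  = t · A_px · d                   [pg]

where ``Δn_eff`` is the effective birefringence, ``A_px`` the pixel area in
μm², and ``d`` the density of calcite (2.71 pg μm⁻³).

Two calibration models are available:

``sin2``
    Single-wavelength crossed-circular-polarizer intensity,
    ``g(Γ) = offset + (gain − offset) · sin²(π Γ / λ)``, invertible on
    ``Γ ∈ [0, λ/2]`` (the first-order regime).
``piecewise``
    Monotone piecewise-linear interpolation through the reference points,
    linearly extrapolated to the ends of the working range.

Calibrations are anchored on reference retardation films (conventionally
31 nm and 129 nm) and serialize to JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Density of calcite in pg μm⁻³.
CALCITE_DENSITY = 2.71

#: Maximum birefringence of calcite (used as the default effective value).
CALCITE_BIREFRINGENCE = 0.172

#: Default pixel area in μm².
DEFAULT_PIXEL_AREA = 0.0003


class CalibrationError(ValueError):
    """Raised when a retardation calibration cannot be built or applied."""


@dataclass(frozen=True)
class OpticalConstants:
    """Physical constants of the imaging setup.

    Parameters
    ----------
    birefringence : float
        Effective birefringence Δn_eff (dimensionless, > 0).  Default is
        the calcite maximum, 0.172.
    density : float
        Density of calcite in pg μm⁻³.  Default 2.71.
    pixel_area : float
        Area of one image pixel in μm².  Default 0.0003.
    """

    birefringence: float = CALCITE_BIREFRINGENCE
    density: float = CALCITE_DENSITY
    pixel_area: float = DEFAULT_PIXEL_AREA

    def __post_init__(self) -> None:
        for name in ("birefringence", "density", "pixel_area"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def pixel_size(self) -> float:
        """Linear pixel size in μm (side of a square pixel)."""
        return float(np.sqrt(self.pixel_area))


@dataclass
class RetardationCalibration:
    """Monotone map between optical retardation (nm) and image grey value.

    Attributes
    ----------
    model : str
        Either ``"sin2"`` or ``"piecewise"``.
    wavelength : float
        Effective wavelength λ in nm (sets the first-order range).
    dark_offset : float
        Grey value at zero retardation.
    gain : float
        Grey value at the top of the working range (Γ = λ/2 for ``sin2``).
    working_range : tuple of float
        Closed retardation interval (nm) on which the map is invertible.
    references : list of (float, float)
        The (retardation nm, grey) anchors the calibration was fitted to.
    tolerance : float
        Maximum allowed absolute grey misfit at any reference point.
    """

    model: str
    wavelength: float
    dark_offset: float
    gain: float
    working_range: tuple[float, float]
    references: list[tuple[float, float]] = field(default_factory=list)
    tolerance: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.working_range
        if self.model not in ("sin2", "piecewise"):
            raise CalibrationError(f"unknown calibration model {self.model!r}")
        if not (0 <= lo < hi):
            raise CalibrationError("working range must be a non-degenerate "
                                   "interval with non-negative lower bound")
        if hi > self.wavelength / 2 + 1e-9:
            raise CalibrationError(
                "working range extends beyond the first-order regime (λ/2)")
        if self.gain <= self.dark_offset:
            raise CalibrationError("gain grey must exceed the dark offset")
        if self.model == "piecewise" and len(self.references) < 2:
            raise CalibrationError("piecewise model needs ≥2 references")

    # ------------------------------------------------------------------
    # forward / inverse maps
    # ------------------------------------------------------------------
    def _piecewise_nodes(self) -> tuple[np.ndarray, np.ndarray]:
        """Reference nodes extended to the full working range by linear
        extrapolation of the end segments."""
        pts = sorted(self.references)
        r = np.array([p[0] for p in pts], dtype=float)
        g = np.array([p[1] for p in pts], dtype=float)
        lo, hi = self.working_range
        if r[0] > lo:
            slope = (g[1] - g[0]) / (r[1] - r[0])
            r = np.insert(r, 0, lo)
            g = np.insert(g, 0, g[1] - slope * (r[2] - lo))
        if r[-1] < hi:
            slope = (g[-1] - g[-2]) / (r[-1] - r[-2])
            r = np.append(r, hi)
            g = np.append(g, g[-2] + slope * (hi - r[-2]))
        return r, g

    def grey(self, retardation):
        """Forward model: retardation (nm) → continuous grey value.

        Raises :class:`CalibrationError` if any retardation is negative or
        above the working range.
        """
        ret = np.asarray(retardation, dtype=float)
        lo, hi = self.working_range
        if np.any(ret < -1e-12) or np.any(ret > hi + 1e-9):
            raise CalibrationError(
                f"retardation outside working range [{lo}, {hi}] nm")
        if self.model == "sin2":
            span = self.gain - self.dark_offset
            out = self.dark_offset + span * np.sin(
                np.pi * ret / self.wavelength) ** 2
        else:
            r, g = self._piecewise_nodes()
            out = np.interp(ret, r, g)
        return out if out.ndim else float(out)

    def retardation(self, grey):
        """Inverse model: grey value → retardation (nm).

        Greys below the dark offset clamp to zero retardation (background
        noise policy; the clamped count is logged).  Greys above the gain
        are outside the first-order regime and raise.
        """
        g = np.asarray(grey, dtype=float)
        if np.any(g > self.gain + 1e-9):
            raise CalibrationError(
                "grey above gain: pixel outside the first-order regime")
        n_clamped = int(np.sum(g < self.dark_offset))
        if n_clamped:
            logger.warning(
                "%d grey value(s) below dark offset clamped to 0 nm",
                n_clamped)
        g = np.clip(g, self.dark_offset, self.gain)
        if self.model == "sin2":
            span = self.gain - self.dark_offset
            frac = np.clip((g - self.dark_offset) / span, 0.0, 1.0)
            out = (self.wavelength / np.pi) * np.arcsin(np.sqrt(frac))
        else:
            r, nodes = self._piecewise_nodes()
            out = np.interp(g, nodes, r)
        out = np.clip(out, *self.working_range)
        return out if out.ndim else float(out)

    def slope(self, retardation: float, h: float = 0.05) -> float:
        """Numerical derivative d(grey)/d(Γ) at ``retardation`` (grey/nm)."""
        lo, hi = self.working_range
        a = max(lo, retardation - h)
        b = min(hi, retardation + h)
        return float((self.grey(b) - self.grey(a)) / (b - a))

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "wavelength": self.wavelength,
            "dark_offset": self.dark_offset,
            "gain": self.gain,
            "working_range": list(self.working_range),
            "references": [list(p) for p in self.references],
            "tolerance": self.tolerance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RetardationCalibration":
        return cls(
            model=d["model"],
            wavelength=float(d["wavelength"]),
            dark_offset=float(d["dark_offset"]),
            gain=float(d["gain"]),
            working_range=tuple(d["working_range"]),
            references=[tuple(p) for p in d.get("references", [])],
            tolerance=float(d.get("tolerance", 1.0)),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RetardationCalibration":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def default_calibration(bit_depth: int = 16,
                        wavelength: float = 550.0) -> RetardationCalibration:
    """A sin² calibration spanning most of the sensor range.

    The dark offset sits a little above zero (camera black level) and the
    gain a little below the dtype maximum, leaving head/foot room for noise.
    """
    top = float(2 ** bit_depth - 1)
    offset, gain = 0.015 * top, 0.95 * top
    refs = [(31.0, None), (129.0, None)]
    cal = RetardationCalibration(
        model="sin2", wavelength=wavelength, dark_offset=offset, gain=gain,
        working_range=(0.0, wavelength / 2.0))
    cal.references = [(r, float(cal.grey(r))) for r, _ in refs]
    return cal


def fit_retardation_curve(references, model: str = "sin2",
                          wavelength: float = 550.0,
                          tolerance: float | None = None
                          ) -> RetardationCalibration:
    """Fit a retardation → grey calibration through reference films.

    Parameters
    ----------
    references : sequence of (retardation nm, grey)
        At least two anchors with distinct retardations, all within the
        first-order range ``[0, λ/2]`` and with grey increasing in
        retardation.
    model : {"sin2", "piecewise"}
        Functional form of the calibration curve.
    wavelength : float
        Effective wavelength λ in nm.
    tolerance : float, optional
        Maximum allowed grey misfit at any reference.  Defaults to 0.5 % of
        the fitted grey span.

    Returns
    -------
    RetardationCalibration

    Raises
    ------
    CalibrationError
        On fewer than two references, duplicated retardations, references
        outside the first-order range, grey not increasing with retardation,
        or a fit that misses a reference by more than ``tolerance``.
    """
    refs = sorted((float(r), float(g)) for r, g in references)
    if len(refs) < 2:
        raise CalibrationError("need at least 2 reference points")
    rets = np.array([r for r, _ in refs])
    greys = np.array([g for _, g in refs])
    if np.any(np.diff(rets) <= 0):
        raise CalibrationError("reference retardations must be distinct")
    if np.any(rets < 0) or np.any(rets > wavelength / 2):
        raise CalibrationError("references must lie in the first-order "
                               f"range [0, {wavelength / 2}] nm")
    if np.any(np.diff(greys) <= 0):
        raise CalibrationError(
            "reference greys must increase with retardation "
            "(monotonicity of the first-order regime violated)")

    if model == "sin2":
        s = np.sin(np.pi * rets / wavelength) ** 2
        design = np.column_stack([1.0 - s, s])  # grey = offset·(1−s) + gain·s
        (offset, gain), *_ = np.linalg.lstsq(design, greys, rcond=None)
        if gain <= offset:
            raise CalibrationError("fitted gain does not exceed dark offset")
        cal = RetardationCalibration(
            model="sin2", wavelength=wavelength, dark_offset=float(offset),
            gain=float(gain), working_range=(0.0, wavelength / 2.0),
            references=refs)
    elif model == "piecewise":
        cal = RetardationCalibration(
            model="piecewise", wavelength=wavelength,
            dark_offset=np.nan, gain=np.nan,  # placeholders, fixed below
            working_range=(0.0, wavelength / 2.0), references=refs)
        # bypass __post_init__ ordering: compute end values from the nodes
        cal.dark_offset, cal.gain = -np.inf, np.inf
        nodes_r, nodes_g = cal._piecewise_nodes()
        cal.dark_offset = float(nodes_g[0])
        cal.gain = float(nodes_g[-1])
        if cal.gain <= cal.dark_offset:
            raise CalibrationError("piecewise calibration is not increasing")
    else:
        raise CalibrationError(f"unknown calibration model {model!r}")

    tol = (0.005 * (cal.gain - cal.dark_offset)
           if tolerance is None else float(tolerance))
    cal.tolerance = tol
    misfit = np.max(np.abs(np.asarray(cal.grey(rets)) - greys))
    if misfit > tol + 1e-9:
        raise CalibrationError(
            f"calibration misses a reference by {misfit:.3g} grey "
            f"(tolerance {tol:.3g})")
    return cal


# ----------------------------------------------------------------------
# module-level convenience wrappers
# ----------------------------------------------------------------------
def retardation_to_grey(cal: RetardationCalibration, retardation):
    """Forward model: retardation (nm) → grey value."""
    return cal.grey(retardation)


def grey_to_retardation(cal: RetardationCalibration, grey):
    """Calibrated inverse: grey value → retardation (nm)."""
    return cal.retardation(grey)


def retardation_to_thickness(retardation, constants: OpticalConstants):
    """Convert retardation (nm) to calcite thickness (μm): t = Γ/(1000·Δn)."""
    ret = np.asarray(retardation, dtype=float)
    if np.any(ret < 0):
        raise ValueError("retardation must be non-negative")
    out = ret / (1000.0 * constants.birefringence)
    return out if out.ndim else float(out)


def thickness_to_retardation(thickness, constants: OpticalConstants):
    """Convert calcite thickness (μm) to retardation (nm): Γ = 1000·Δn·t."""
    t = np.asarray(thickness, dtype=float)
    if np.any(t < 0):
        raise ValueError("thickness must be non-negative")
    out = t * 1000.0 * constants.birefringence
    return out if out.ndim else float(out)


def pixel_mass(thickness, constants: OpticalConstants):
    """Calcite mass of one pixel (pg): m = t · A_px · d."""
    t = np.asarray(thickness, dtype=float)
    if np.any(t < 0):
        raise ValueError("thickness must be non-negative")
    out = t * constants.pixel_area * constants.density
    return out if out.ndim else float(out)
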