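"""Synthetic coccolith populations with known ground truth.

Stand-in for cultured coccolithophore samples: model placoliths are built as
two concentric ellipses (outer shield, inner central-area opening) carrying a
smooth radial thickness profile, discretized on the instrument's pixel grid,
and optionally rendered into grey-scale micrographs through the forward
optical model.  Every generated particle comes with exact ground truth
(length, area, mean thickness, mass, thickness skewness, k_s), so the whole
measurement pipeline can be audited against known values.

The default study conditions emulate laboratory salinity experiments on
*Emiliania huxleyi* and *Gephyrocapsa oceanica*: 30 coccoliths per sample,
salinities of 25/34/44, mean lengths of 2.5–3.4 μm (E. huxleyi) or
4.5–5.1 μm (G. oceanica) and mean thicknesses of 0.064–0.158 μm.

Thickness–length coupling is configurable:

``isometric``   mean thickness T̄ = c·L (the k_s model's assumption)
``allometric``  T̄ = c·L^b with exponent b ≠ 1
``decoupled``   T̄ ~ Normal(T₀, σ_T), independent of length
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .optics import (OpticalConstants, RetardationCalibration,
                     default_calibration, thickness_to_retardation)

logger = logging.getLogger(__name__)

COUPLING_MODES = ("isometric", "allometric", "decoupled")

#: Column order of ground-truth / measurement tables throughout the package.
TABLE_COLUMNS = [
    "strain", "salinity", "coccolith_id", "length_um", "width_um",
    "aspect_ratio", "mean_thickness_um", "mass_pg", "skewness",
    "area_um2", "ks",
]


@dataclass(frozen=True)
class CoccolithSpec:
    """Geometry of one model placolith.

    ``length`` is the outer major axis (μm); ``aspect_ratio`` the major/minor
    ratio (≥ 1); ``central_fraction`` the linear fraction of the outer
    semi-axes occupied by the central-area opening; ``peak_thickness`` the
    profile maximum T_s (μm); ``rim_floor`` the fraction of T_s retained at
    the shield edges (a placolith shield has finite edge thickness, which
    also gives the rendered particle a sharp boundary); ``profile_exponent``
    the exponent p of the sin^p radial profile.
    """

    length: float
    aspect_ratio: float = 1.25
    central_fraction: float = 0.4
    peak_thickness: float = 0.12
    rim_floor: float = 0.3
    profile_exponent: float = 8.0
    position: tuple[float, float] = (0.0, 0.0)
    orientation: float = 0.0

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError("length must be positive")
        if self.aspect_ratio < 1:
            raise ValueError("aspect ratio must be ≥ 1")
        if not 0 <= self.central_fraction < 1:
            raise ValueError("central fraction must be in [0, 1)")
        if self.peak_thickness < 0:
            raise ValueError("peak thickness must be ≥ 0")
        if not 0 <= self.rim_floor <= 1:
            raise ValueError("rim floor must be in [0, 1]")


@dataclass(frozen=True)
class PopulationSpec:
    """Sampling distribution of one culture's coccoliths.

    Lengths are drawn from a normal truncated at zero with mean
    ``mean_length + salinity_slope · (salinity − reference_salinity)``.
    Thickness targets follow the configured coupling mode; aspect ratio and
    central fraction are drawn from clipped normals.
    """

    n: int = 30
    mean_length: float = 2.7
    sd_length: float = 0.27
    salinity_slope: float = 0.0          # μm per salinity unit
    reference_salinity: float = 34.0
    coupling: str = "decoupled"
    coupling_c: float = 0.025            # T̄ = c·L (isometric) / c·L^b (allometric)
    coupling_exponent: float = 1.0
    thickness_intercept: float = 0.07    # T₀ for decoupled mode
    sd_thickness: float = 0.005          # residual sd of T̄
    mean_aspect_ratio: float = 1.25
    sd_aspect_ratio: float = 0.06
    mean_central_fraction: float = 0.4
    sd_central_fraction: float = 0.04

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be ≥ 1")
        if self.coupling not in COUPLING_MODES:
            raise ValueError(
                f"coupling must be one of {COUPLING_MODES}, "
                f"got {self.coupling!r}")
        if self.sd_length < 0 or self.sd_thickness < 0:
            raise ValueError("standard deviations must be ≥ 0")


@dataclass
class GroundTruth:
    """Exact per-coccolith truth computed from the discrete thickness map."""

    length: float
    width: float
    aspect_ratio: float
    area: float                 # μm², support of the outer ellipse
    mean_thickness: float       # μm, mass/(d·area)
    mass: float                 # pg, d·A_px·Σ thickness
    skewness: float             # Fisher–Pearson g₁ of pixel thicknesses
    ks: float                   # m/(l³·d)

    def as_row(self) -> dict:
        return {
            "length_um": self.length, "width_um": self.width,
            "aspect_ratio": self.aspect_ratio, "area_um2": self.area,
            "mean_thickness_um": self.mean_thickness, "mass_pg": self.mass,
            "skewness": self.skewness, "ks": self.ks,
        }


@dataclass
class ThicknessMap:
    """2-D calcite thickness field (μm) on the instrument pixel grid."""

    thickness: np.ndarray       # μm per pixel
    support: np.ndarray         # bool, inside the outer ellipse
    pixel_area: float           # μm²
    truth: GroundTruth | None = None


def _moment_skewness(values: np.ndarray) -> float:
    """Biased Fisher–Pearson moment skewness g₁ = m₃ / m₂^{3/2}."""
    v = np.asarray(values, dtype=float)
    m2 = np.mean((v - v.mean()) ** 2)
    # guard against float cancellation on (near-)constant inputs
    if m2 <= (1e-9 * max(np.max(np.abs(v)), 1e-30)) ** 2:
        return 0.0
    m3 = np.mean((v - v.mean()) ** 3)
    return float(m3 / m2 ** 1.5)


def make_thickness_map(spec: CoccolithSpec,
                       constants: OpticalConstants | None = None,
                       pad_px: int = 2) -> tuple[ThicknessMap, GroundTruth]:
    """Rasterize one model placolith onto the pixel grid.

    The thickness at elliptical radius ρ (ρ=1 at the outer rim, ρ=f_c at the
    central-area edge) is::

        t(ρ) = T_s · (floor + (1 − floor) · sin(π u)^p),  u = (ρ−f_c)/(1−f_c)

    for f_c ≤ ρ ≤ 1 and zero inside the central area.  Ground-truth mass is
    the exact discrete sum ``d · A_px · Σ thickness``.

    Raises ``ValueError`` for particles smaller than 3 pixels across.
    """
    constants = constants or OpticalConstants()
    px = constants.pixel_size
    a = spec.length / 2.0
    b = a / spec.aspect_ratio
    if spec.length < 3 * px:
        raise ValueError(
            f"length {spec.length} μm spans fewer than 3 pixels "
            f"({px} μm each): unresolvable")

    # bounding half-extent of the rotated ellipse
    c, s = np.cos(spec.orientation), np.sin(spec.orientation)
    hx = np.sqrt((a * c) ** 2 + (b * s) ** 2)
    hy = np.sqrt((a * s) ** 2 + (b * c) ** 2)
    nx = int(np.ceil(hx / px)) + pad_px
    ny = int(np.ceil(hy / px)) + pad_px
    # pixel-centre coordinates (μm), origin at the particle centre
    xs = (np.arange(-nx, nx + 1)) * px
    ys = (np.arange(-ny, ny + 1)) * px
    X, Y = np.meshgrid(xs, ys)
    Xr = X * c + Y * s
    Yr = -X * s + Y * c
    rho = np.sqrt((Xr / a) ** 2 + (Yr / b) ** 2)

    support = rho <= 1.0
    f_c = spec.central_fraction
    shield = support & (rho >= f_c)
    u = np.zeros_like(rho)
    u[shield] = (rho[shield] - f_c) / (1.0 - f_c)
    profile = np.zeros_like(rho)
    profile[shield] = (spec.rim_floor + (1.0 - spec.rim_floor)
                       * np.sin(np.pi * u[shield]) ** spec.profile_exponent)
    thickness = spec.peak_thickness * profile

    n_support = int(support.sum())
    mass = float(constants.density * constants.pixel_area * thickness.sum())
    area = n_support * constants.pixel_area
    if mass == 0:
        logger.warning("empty particle: zero-mass thickness map")
    mean_t = mass / (constants.density * area) if area > 0 else 0.0
    truth = GroundTruth(
        length=spec.length, width=spec.length / spec.aspect_ratio,
        aspect_ratio=spec.aspect_ratio, area=area, mean_thickness=mean_t,
        mass=mass, skewness=_moment_skewness(thickness[support]),
        ks=mass / (spec.length ** 3 * constants.density),
    )
    tmap = ThicknessMap(thickness=thickness, support=support,
                        pixel_area=constants.pixel_area, truth=truth)
    return tmap, truth


def scale_to_mean_thickness(spec: CoccolithSpec, target_mean: float,
                            constants: OpticalConstants | None = None
                            ) -> CoccolithSpec:
    """Rescale ``peak_thickness`` so the discrete map's mean thickness over
    its support equals ``target_mean`` exactly (the map is linear in T_s)."""
    probe = replace(spec, peak_thickness=1.0)
    _, truth = make_thickness_map(probe, constants)
    if truth.mean_thickness <= 0:
        raise ValueError("degenerate geometry: zero mean thickness at unit peak")
    return replace(spec, peak_thickness=target_mean / truth.mean_thickness)


def sample_population(pop: PopulationSpec, salinity: float,
                      seed, constants: OpticalConstants | None = None
                      ) -> tuple[list[CoccolithSpec], pd.DataFrame]:
    """Draw one sample of coccolith geometries and their ground truth.

    Returns the list of :class:`CoccolithSpec` and a ground-truth table with
    the shared column schema (strain/salinity columns left to the caller).
    All randomness flows from ``seed`` (an int or ``numpy`` SeedSequence).
    """
    constants = constants or OpticalConstants()
    rng = np.random.default_rng(seed)
    mu = pop.mean_length + pop.salinity_slope * (
        salinity - pop.reference_salinity)
    if mu <= 0:
        raise ValueError("salinity-shifted mean length is non-positive")

    # truncated-at-zero normal via rejection (tail mass is negligible here)
    lengths = np.empty(pop.n)
    filled = 0
    while filled < pop.n:
        draw = rng.normal(mu, pop.sd_length, size=pop.n - filled)
        draw = draw[draw > 3 * constants.pixel_size]
        lengths[filled:filled + draw.size] = draw
        filled += draw.size

    if pop.coupling == "isometric":
        t_mean = pop.coupling_c * lengths
    elif pop.coupling == "allometric":
        t_mean = pop.coupling_c * lengths ** pop.coupling_exponent
    else:  # decoupled
        t_mean = np.full(pop.n, pop.thickness_intercept)
    t_targets = t_mean + rng.normal(0.0, pop.sd_thickness, size=pop.n)
    t_targets = np.clip(t_targets, 1e-3, None)

    ars = np.clip(rng.normal(pop.mean_aspect_ratio, pop.sd_aspect_ratio,
                             size=pop.n), 1.0, None)
    fcs = np.clip(rng.normal(pop.mean_central_fraction,
                             pop.sd_central_fraction, size=pop.n), 0.0, 0.9)

    specs, rows = [], []
    for i in range(pop.n):
        spec = CoccolithSpec(length=float(lengths[i]),
                             aspect_ratio=float(ars[i]),
                             central_fraction=float(fcs[i]))
        spec = scale_to_mean_thickness(spec, float(t_targets[i]), constants)
        _, truth = make_thickness_map(spec, constants)
        specs.append(spec)
        row = truth.as_row()
        row["coccolith_id"] = i
        rows.append(row)
    table = pd.DataFrame(rows)
    return specs, table


# ----------------------------------------------------------------------
# rendering
# ----------------------------------------------------------------------
def render_image(maps: list[ThicknessMap],
                 cal: RetardationCalibration | None = None,
                 constants: OpticalConstants | None = None,
                 noise_sd: float = 40.0,
                 bit_depth: int = 16,
                 margin_px: int = 30,
                 reference_patches: bool = False,
                 patch_size_px: int = 40,
                 rng=None) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Render thickness maps into one quantized grey-scale image.

    Particles are laid out on a non-overlapping grid with ``margin_px``
    spacing.  Per-pixel grey is the forward optical model of the local
    retardation plus Gaussian noise, quantized to ``bit_depth``.  When
    ``reference_patches`` is set, two square patches at 31 nm and 129 nm
    retardation are rendered in the top-left corner (calibration films).

    Returns the image and the (row, col) pixel offset of each map's origin,
    in input order, for matching measurements back to ground truth.
    """
    constants = constants or OpticalConstants()
    cal = cal or default_calibration(bit_depth)
    rng = np.random.default_rng(rng)

    if not maps:
        shape = (4 * margin_px, 4 * margin_px)
        canvas_ret = np.zeros(shape)
    else:
        ncols = int(np.ceil(np.sqrt(len(maps))))
        nrows = int(np.ceil(len(maps) / ncols))
        cell_h = max(m.thickness.shape[0] for m in maps) + margin_px
        cell_w = max(m.thickness.shape[1] for m in maps) + margin_px
        extra_top = (patch_size_px + margin_px) if reference_patches else 0
        shape = (nrows * cell_h + margin_px + extra_top,
                 ncols * cell_w + margin_px)
        canvas_t = np.zeros(shape)
        offsets = []
        for i, m in enumerate(maps):
            r, c = divmod(i, ncols)
            r0 = margin_px + extra_top + r * cell_h
            c0 = margin_px + c * cell_w
            h, w = m.thickness.shape
            region = canvas_t[r0:r0 + h, c0:c0 + w]
            if np.any(region[m.thickness > 0] > 0):
                raise ValueError("particle overlap detected in layout")
            region += m.thickness
            offsets.append((r0, c0))
        canvas_ret = thickness_to_retardation(canvas_t, constants)

    top = cal.working_range[1]
    if np.any(canvas_ret > top):
        raise ValueError("thickness exceeds the calibration working range "
                         "(first-order regime)")
    if reference_patches:
        p = patch_size_px
        canvas_ret[margin_px // 2:margin_px // 2 + p,
                   margin_px // 2:margin_px // 2 + p] = 31.0
        canvas_ret[margin_px // 2:margin_px // 2 + p,
                   margin_px + p:margin_px + 2 * p] = 129.0

    grey = np.asarray(cal.grey(canvas_ret), dtype=float)
    if noise_sd > 0:
        grey = grey + rng.normal(0.0, noise_sd, size=grey.shape)
    top_grey = 2 ** bit_depth - 1
    grey = np.clip(np.rint(grey), 0, top_grey)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    image = grey.astype(dtype)
    return image, (offsets if maps else [])


# ----------------------------------------------------------------------
# study simulation
# ----------------------------------------------------------------------
#: 95% measurement noise, halved to standard (1σ) values, for table mode.
TABLE_NOISE_SD = {"length_um": 0.1, "mean_thickness_um": 0.0035}
TABLE_NOISE_REL_SD = {"mass_pg": 0.085}


@dataclass
class StudyBundle:
    """Output of :func:`simulate_study`.

    ``tables`` holds the noisy measured-style tables (one DataFrame per
    design cell, concatenated), ``truth`` the exact ground truth, and in
    image mode ``images`` maps (strain, salinity) to rendered micrographs
    with the per-particle pixel offsets.
    """

    tables: pd.DataFrame
    truth: pd.DataFrame
    manifest: dict
    images: dict = field(default_factory=dict)


def simulate_study(design, seed, mode: str = "tables",
                   constants: OpticalConstants | None = None,
                   cal: RetardationCalibration | None = None,
                   noise_sd: float = 40.0,
                   bit_depth: int = 16) -> StudyBundle:
    """Simulate a strain × salinity culture study.

    Parameters
    ----------
    design : sequence of (strain, salinity, PopulationSpec)
        One entry per sample; duplicate (strain, salinity) labels raise.
    seed : int
        Master seed; every cell gets an independent child stream.
    mode : {"tables", "images"}
        ``tables`` bypasses imaging and emits ground truth plus Gaussian
        measurement noise at the stated standard uncertainties;
        ``images`` renders one micrograph per cell.
    """
    design = list(design)
    if not design:
        raise ValueError("design must contain at least one cell")
    labels = [(s, sal) for s, sal, _ in design]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate (strain, salinity) labels in design")
    if mode not in ("tables", "images"):
        raise ValueError("mode must be 'tables' or 'images'")

    constants = constants or OpticalConstants()
    if mode == "images":
        cal = cal or default_calibration(bit_depth)
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(design))

    truth_frames, table_frames, images = [], [], {}
    manifest_cells = []
    for (strain, salinity, pop), child in zip(design, children):
        specs, truth = sample_population(pop, salinity, child, constants)
        truth.insert(0, "strain", strain)
        truth.insert(1, "salinity", salinity)
        truth = truth[TABLE_COLUMNS]
        truth_frames.append(truth)
        noise_rng = np.random.default_rng(child.spawn(1)[0])
        if mode == "tables":
            noisy = truth.copy()
            for col, sd in TABLE_NOISE_SD.items():
                noisy[col] = noisy[col] + noise_rng.normal(0, sd, len(noisy))
            for col, rel in TABLE_NOISE_REL_SD.items():
                noisy[col] = noisy[col] * (
                    1.0 + noise_rng.normal(0, rel, len(noisy)))
            noisy["length_um"] = noisy["length_um"].clip(lower=0.05)
            noisy["mean_thickness_um"] = noisy["mean_thickness_um"].clip(
                lower=1e-4)
            noisy["mass_pg"] = noisy["mass_pg"].clip(lower=0.0)
            noisy["ks"] = noisy["mass_pg"] / (
                noisy["length_um"] ** 3 * constants.density)
            table_frames.append(noisy)
        else:
            maps = [make_thickness_map(s, constants)[0] for s in specs]
            image, offsets = render_image(
                maps, cal, constants, noise_sd=noise_sd,
                bit_depth=bit_depth, rng=noise_rng)
            images[(strain, salinity)] = {"image": image, "offsets": offsets}
        manifest_cells.append({
            "strain": strain, "salinity": salinity,
            "n": pop.n, "coupling": pop.coupling,
            "seed_entropy": int(child.entropy),
            "spawn_key": [int(k) for k in child.spawn_key],
        })

    truth_all = pd.concat(truth_frames, ignore_index=True)
    tables = (pd.concat(table_frames, ignore_index=True)
              if table_frames else truth_all.copy())
    manifest = {"seed": int(seed), "mode": mode, "cells": manifest_cells,
                "n_samples": len(design), "n_coccoliths": len(truth_all)}
    return StudyBundle(tables=tables, truth=truth_all,
                       manifest=manifest, images=images)
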