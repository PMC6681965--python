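"""Inverse pipeline: from calibrated grey images to coccolith morphometrics.

Coccoliths are segmented from the background with a Canny edge detector
(Gaussian-derivative gradient with hysteresis thresholding), edge contours
are closed and filled, and each particle is measured:

* length / width — major and minor axes of the moment-based best-fit
  ellipse, scaled to μm (maximum Feret diameter available as an option);
* mean thickness T̄ — mean of the calibrated per-pixel thickness over the
  mask (central-area holes are retained as zero-thickness pixels);
* mass — ``d · A_px · Σ thickness``, so the identity
  ``m = d · area · T̄`` holds to machine precision;
* skewness g₁ — biased Fisher–Pearson moment skewness of the within-mask
  thickness values (raw grey values optionally);
* standard uncertainties at 95 % confidence by first-order (quadrature)
  propagation of an explicit uncertainty budget.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import t as t_dist
from skimage import feature, measure as skmeasure, morphology, segmentation

from .optics import (CalibrationError, OpticalConstants,
                     RetardationCalibration, grey_to_retardation,
                     retardation_to_thickness, thickness_to_retardation)
from .synth import TABLE_COLUMNS, _moment_skewness

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationParams:
    """Canny segmentation settings.

    ``sigma`` is the Gaussian smoothing scale in pixels; the hysteresis
    thresholds act on the gradient of the [0, 1]-normalized image.  Area
    bounds are in μm²; ``exclude_border`` drops particles touching the
    image edge.
    """

    sigma: float = 1.4
    low_threshold: float = 8e-4
    high_threshold: float = 1.5e-3
    min_area: float = 0.5
    max_area: float = 100.0
    exclude_border: bool = True

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.low_threshold <= 0 \
                or self.high_threshold <= 0:
            raise ValueError("segmentation parameters must be positive")
        if self.min_area <= 0 or self.max_area <= self.min_area:
            raise ValueError("need 0 < min_area < max_area")


@dataclass(frozen=True)
class UncertaintyBudget:
    """Components of the measurement uncertainty budget (all 1σ).

    ``grey_noise_sd`` — image grey noise (sensor + illumination variation),
    in grey levels of the calibrated image;
    ``calibration_rel_sd`` — relative uncertainty of the grey→thickness
    calibration (fit differences, curve resolution);
    ``pixel_size_rel_sd`` — relative uncertainty of the linear pixel-size
    calibration (stage micrometer);
    ``edge_localization_px`` — 1σ localization of a segmented edge, pixels.
    """

    grey_noise_sd: float = 40.0
    calibration_rel_sd: float = 0.05
    pixel_size_rel_sd: float = 0.005
    edge_localization_px: float = 4.0

    def __post_init__(self) -> None:
        for name in ("grey_noise_sd", "calibration_rel_sd",
                     "pixel_size_rel_sd", "edge_localization_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")


@dataclass
class ParticleMeasurement:
    """Morphometrics of one segmented coccolith (lengths μm, mass pg).

    ``u_length``, ``u_thickness``, ``u_mass`` are standard uncertainties at
    95 % confidence (zero until a budget is propagated).
    """

    length: float
    width: float
    aspect_ratio: float
    area: float
    mean_thickness: float
    mass: float
    skewness: float
    pixel_count: int
    centroid: tuple[float, float] = (0.0, 0.0)   # (row, col) in pixels
    feret_max: float | None = None
    u_length: float = 0.0
    u_thickness: float = 0.0
    u_mass: float = 0.0
    mean_retardation: float = 0.0                # nm, kept for propagation

    def as_row(self) -> dict:
        return {
            "length_um": self.length, "width_um": self.width,
            "aspect_ratio": self.aspect_ratio,
            "mean_thickness_um": self.mean_thickness, "mass_pg": self.mass,
            "skewness": self.skewness, "area_um2": self.area,
            "pixel_count": self.pixel_count,
            "u_length_um": self.u_length, "u_thickness_um": self.u_thickness,
            "u_mass_pg": self.u_mass,
        }


@dataclass
class SampleTable:
    """Labelled collection of particle measurements for one culture."""

    strain: str
    salinity: float
    data: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.data)

    def summary(self, metrics=("length_um", "mean_thickness_um", "mass_pg",
                               "skewness", "ks")) -> dict:
        """Per-metric n, mean and t-based 95 % CI half-width of the mean."""
        out = {}
        for m in metrics:
            if m not in self.data:
                continue
            vals = self.data[m].dropna().to_numpy(dtype=float)
            n = vals.size
            entry = {"n": n, "mean": float(np.mean(vals)) if n else np.nan,
                     "ci95": np.nan}
            if n >= 2:
                half = t_dist.ppf(0.975, n - 1) * np.std(vals, ddof=1) / np.sqrt(n)
                entry["ci95"] = float(half)
            out[m] = entry
        return out


# pixel area used for the area filter inside segment_particles; callers with
# non-default optics should filter masks themselves or rescale the bounds.
DEFAULT_SEG_PIXEL_AREA = OpticalConstants().pixel_area


def segment_particles(image: np.ndarray,
                      params: SegmentationParams | None = None
                      ) -> list[np.ndarray]:
    """Segment coccoliths from the background of a grey image.

    Canny edges on the dtype-normalized image are morphologically closed,
    filled, and lightly eroded back (so the mask boundary tracks the edge
    locus); connected components are filtered by area and, optionally,
    border contact.  Returns boolean masks in scan order.
    """
    params = params or SegmentationParams()
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if np.issubdtype(img.dtype, np.integer):
        norm = img.astype(float) / np.iinfo(img.dtype).max
    else:
        norm = img.astype(float)
        if norm.max() > 1.0:
            norm = norm / norm.max()

    # pad with the background level so particles cut by the image border
    # still produce closed contours (the cut line becomes an edge)
    pad = int(np.ceil(3 * params.sigma)) + 2
    norm = np.pad(norm, pad, mode="constant",
                  constant_values=float(np.median(norm)))
    edges = feature.canny(norm, sigma=params.sigma,
                          low_threshold=params.low_threshold,
                          high_threshold=params.high_threshold)
    disk = morphology.disk(1)
    closed = ndimage.binary_dilation(edges, structure=disk)
    filled = ndimage.binary_fill_holes(closed)
    filled = ndimage.binary_erosion(filled, structure=disk)
    filled = filled[pad:-pad, pad:-pad]

    if params.exclude_border:
        kept = segmentation.clear_border(filled)
        n_border = ndimage.label(filled)[1] - ndimage.label(kept)[1]
        if n_border:
            logger.info("excluded %d border-touching particle(s)", n_border)
        filled = kept

    labels, n = ndimage.label(filled)
    masks = []
    px_area = DEFAULT_SEG_PIXEL_AREA
    for lab in range(1, n + 1):
        mask = labels == lab
        area_um2 = mask.sum() * px_area
        if area_um2 < params.min_area or area_um2 > params.max_area:
            logger.info("dropped particle with area %.3g μm²", area_um2)
            continue
        masks.append(mask)
    if not masks:
        logger.warning("no particles found in image")
    return masks


def measure_particle(mask: np.ndarray, image: np.ndarray,
                     cal: RetardationCalibration,
                     constants: OpticalConstants | None = None,
                     budget: UncertaintyBudget | None = None,
                     skewness_on: str = "thickness",
                     include_feret: bool = False) -> ParticleMeasurement:
    """Measure one segmented coccolith.

    ``skewness_on`` selects whether g₁ is computed on calibrated thickness
    values (default) or on raw grey values — the two differ under the
    nonlinear grey→retardation calibration.
    """
    constants = constants or OpticalConstants()
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 4:
        raise ValueError("mask smaller than 4 pixels")
    if mask.shape != image.shape:
        raise ValueError("mask and image shapes differ")
    if skewness_on not in ("thickness", "grey"):
        raise ValueError("skewness_on must be 'thickness' or 'grey'")

    greys = np.asarray(image, dtype=float)[mask]
    ret = np.asarray(grey_to_retardation(cal, greys))
    thick = np.asarray(retardation_to_thickness(ret, constants))

    px = constants.pixel_size
    props = skmeasure.regionprops(mask.astype(np.uint8))[0]
    length = props.axis_major_length * px
    width = props.axis_minor_length * px
    if width <= 0:
        raise ValueError("degenerate particle: zero minor axis")
    n_px = int(mask.sum())
    area = n_px * constants.pixel_area
    mass = float(constants.density * constants.pixel_area * thick.sum())
    mean_t = mass / (constants.density * area)
    skew_vals = thick if skewness_on == "thickness" else greys
    meas = ParticleMeasurement(
        length=float(length), width=float(width),
        aspect_ratio=float(length / width), area=float(area),
        mean_thickness=float(mean_t), mass=mass,
        skewness=_moment_skewness(skew_vals), pixel_count=n_px,
        centroid=tuple(map(float, props.centroid)),
        feret_max=(float(props.feret_diameter_max * px)
                   if include_feret else None),
        mean_retardation=float(np.mean(ret)),
    )
    if budget is not None:
        u_l, u_t, u_m = propagate_uncertainty(meas, budget, cal, constants)
        meas.u_length, meas.u_thickness, meas.u_mass = u_l, u_t, u_m
    return meas


def propagate_uncertainty(measurement: ParticleMeasurement,
                          budget: UncertaintyBudget,
                          cal: RetardationCalibration,
                          constants: OpticalConstants | None = None
                          ) -> tuple[float, float, float]:
    """First-order uncertainty propagation, scaled to 95 % (×1.96).

    * length: two independently localized edges plus the relative pixel-size
      calibration, in quadrature;
    * mean thickness: relative calibration uncertainty plus per-pixel grey
      noise averaged over the N mask pixels (independent noise);
    * mass: relative calibration uncertainty, relative pixel-area
      uncertainty (2× the linear pixel-size term) and the grey-noise term
      taken as common mode across the particle (illumination variation does
      not average out), in quadrature.

    The grey noise is converted to thickness through the local slope of the
    calibration curve at the particle's mean retardation, so thin (dim)
    particles carry a larger relative mass uncertainty than thick ones.
    """
    constants = constants or OpticalConstants()
    if measurement.pixel_count < 1:
        raise ValueError("empty measurement")
    px = constants.pixel_size
    k95 = 1.96

    sigma_edge = budget.edge_localization_px * px
    u_l = k95 * np.sqrt(2 * sigma_edge ** 2
                        + (budget.pixel_size_rel_sd * measurement.length) ** 2)

    # grey noise → thickness noise per pixel, via the local calibration slope
    ret = max(measurement.mean_retardation, 1e-6)
    slope = cal.slope(ret)  # grey per nm
    if slope > 0 and budget.grey_noise_sd > 0:
        sigma_t_px = (budget.grey_noise_sd / slope) / (
            1000.0 * constants.birefringence)
    else:
        sigma_t_px = 0.0

    n = measurement.pixel_count
    u_t = k95 * np.sqrt((budget.calibration_rel_sd
                         * measurement.mean_thickness) ** 2
                        + sigma_t_px ** 2 / n)

    if measurement.mean_thickness > 0:
        rel_noise = sigma_t_px / measurement.mean_thickness
    else:
        rel_noise = 0.0
    u_m_rel = k95 * np.sqrt(budget.calibration_rel_sd ** 2
                            + (2 * budget.pixel_size_rel_sd) ** 2
                            + rel_noise ** 2)
    u_m = u_m_rel * measurement.mass
    return float(u_l), float(u_t), float(u_m)


def measure_sample(images, cal: RetardationCalibration,
                   constants: OpticalConstants | None = None,
                   params: SegmentationParams | None = None,
                   budget: UncertaintyBudget | None = None,
                   strain: str = "", salinity: float = np.nan,
                   skewness_on: str = "thickness") -> SampleTable:
    """Segment and measure every particle in a list of images.

    Rows are ordered deterministically by (image index, centroid row, col).
    Empty images contribute nothing (a warning is logged).
    """
    constants = constants or OpticalConstants()
    images = list(images)
    if not images:
        raise ValueError("need at least one image")
    rows = []
    cid = 0
    for i, image in enumerate(images):
        try:
            masks = segment_particles(image, params)
        except Exception as exc:  # re-raise with image context
            raise RuntimeError(f"segmentation failed on image {i}") from exc
        parts = []
        for mask in masks:
            try:
                parts.append(measure_particle(
                    mask, image, cal, constants, budget,
                    skewness_on=skewness_on))
            except (ValueError, CalibrationError) as exc:
                logger.warning("image %d: skipped particle (%s)", i, exc)
        parts.sort(key=lambda p: p.centroid)
        for p in parts:
            row = p.as_row()
            row["image_index"] = i
            row["coccolith_id"] = cid
            row["ks"] = (row["mass_pg"]
                         / (row["length_um"] ** 3 * constants.density))
            rows.append(row)
            cid += 1
    if not rows:
        logger.warning("sample %s/%s: no particles measured", strain, salinity)
        data = pd.DataFrame(columns=TABLE_COLUMNS[2:])
    else:
        data = pd.DataFrame(rows)
    return SampleTable(strain=strain, salinity=salinity, data=data)
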