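"""The k_s shape-factor model and its audit.

Under isometric coccolith growth, coccolith mass scales with the cube of its
length through a species-specific dimensionless shape constant k_s:

    m = k_s · l³ · d          (mass model)
    k_s = m / (l³ · d)        (shape factor from measured mass and length)

with ``d`` the density of calcite (2.71 pg μm⁻³).  This module provides both
directions, sample-level k_s estimation (mean of per-coccolith ratios, and
the ratio of sample means), the percent bias of a model-estimated mass
against a measured one, and exponential-phase growth rate
μ = (ln c₁ − ln c₀)/t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .optics import CALCITE_DENSITY


def mass_from_length(length, ks, density: float = CALCITE_DENSITY):
    """Coccolith mass (pg) from length (μm): m = k_s · l³ · d."""
    l = np.asarray(length, dtype=float)
    if np.any(l <= 0):
        raise ValueError("length must be positive")
    if np.any(np.asarray(ks) < 0) or density <= 0:
        raise ValueError("k_s must be ≥ 0 and density > 0")
    out = np.asarray(ks) * l ** 3 * density
    return out if out.ndim else float(out)


def ks_from_mass_length(mass, length, density: float = CALCITE_DENSITY):
    """Shape factor from measured mass and length: k_s = m / (l³ · d)."""
    l = np.asarray(length, dtype=float)
    m = np.asarray(mass, dtype=float)
    if np.any(l <= 0):
        raise ValueError("length must be positive")
    if np.any(m < 0):
        raise ValueError("mass must be ≥ 0")
    out = m / (l ** 3 * density)
    return out if out.ndim else float(out)


def model_bias_percent(measured_mass, estimated_mass):
    """Percent overestimation of a model mass against the measured one:
    100 · (estimated − measured) / measured."""
    meas = np.asarray(measured_mass, dtype=float)
    if np.any(meas <= 0):
        raise ValueError("measured mass must be positive")
    out = 100.0 * (np.asarray(estimated_mass, dtype=float) - meas) / meas
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class GrowthRateInput:
    """Cell densities (cells/mL) bounding the exponential phase and its
    duration in days."""

    c0: float
    c1: float
    t: float

    def __post_init__(self) -> None:
        if self.c0 <= 0 or self.c1 <= 0:
            raise ValueError("cell densities must be positive")
        if self.t <= 0:
            raise ValueError("duration must be positive")


def growth_rate(inp: GrowthRateInput) -> float:
    """Exponential growth rate μ = (ln c₁ − ln c₀) / t, in day⁻¹."""
    return float((np.log(inp.c1) - np.log(inp.c0)) / inp.t)


@dataclass
class KsEstimate:
    """Sample-level k_s by two estimators.

    ``mean_of_ratios`` averages the per-coccolith k_s values (with a t-based
    95 % CI half-width); ``ratio_of_means`` applies the shape-factor formula
    to the sample mean mass and mean length.  The two agree exactly when all
    coccoliths are identical and diverge under length dispersion (Jensen's
    inequality on 1/l³).
    """

    per_coccolith: np.ndarray
    mean_of_ratios: float
    ratio_of_means: float
    ci95: float
    n: int


def sample_ks(table, density: float = CALCITE_DENSITY,
              mass_col: str = "mass_pg",
              length_col: str = "length_um") -> KsEstimate:
    """Estimate k_s for one sample.

    ``table`` is a DataFrame (or an object with a ``.data`` DataFrame, such
    as a :class:`~cocomorph.measure.SampleTable`) with mass and length
    columns.
    """
    data = getattr(table, "data", table)
    if len(data) < 1:
        raise ValueError("empty sample table")
    m = data[mass_col].to_numpy(dtype=float)
    l = data[length_col].to_numpy(dtype=float)
    per = np.asarray(ks_from_mass_length(m, l, density))
    n = per.size
    mean_ratios = float(per.mean())
    ratio_means = float(ks_from_mass_length(m.mean(), l.mean(), density))
    ci = 0.0
    if n >= 2:
        ci = float(t_dist.ppf(0.975, n - 1) * per.std(ddof=1) / np.sqrt(n))
    return KsEstimate(per_coccolith=per, mean_of_ratios=mean_ratios,
                      ratio_of_means=ratio_means, ci95=ci, n=n)


def ks_audit(tables, reference_ks: float | None = None,
             density: float = CALCITE_DENSITY) -> pd.DataFrame:
    """k_s audit across samples.

    For each sample both estimators are reported along with, when a
    reference k_s is supplied, the percent bias of the reference-model mean
    mass (k_s·l̄³·d at the sample mean length) against the measured mean
    mass — the divergence that accumulates when thickness does not track
    length.
    """
    rows = []
    for tab in tables:
        data = getattr(tab, "data", tab)
        est = sample_ks(tab, density)
        row = {
            "strain": getattr(tab, "strain", ""),
            "salinity": getattr(tab, "salinity", np.nan),
            "n": est.n,
            "ks_mean_of_ratios": est.mean_of_ratios,
            "ks_ratio_of_means": est.ratio_of_means,
            "ks_ci95": est.ci95,
        }
        if reference_ks is not None:
            mean_l = float(data["length_um"].mean())
            mean_m = float(data["mass_pg"].mean())
            est_m = mass_from_length(mean_l, reference_ks, density)
            row["reference_ks"] = reference_ks
            row["model_mass_pg"] = est_m
            row["measured_mass_pg"] = mean_m
            row["bias_percent"] = model_bias_percent(mean_m, est_m)
        rows.append(row)
    return pd.DataFrame(rows)
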