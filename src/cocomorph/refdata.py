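"""Reference summary statistics from a published salinity culture study.

A laboratory experiment grew seven *Emiliania huxleyi* strains and one
*Gephyrocapsa oceanica* strain (RCC 1223) at salinities of 25, 34 and 44 and
measured length, mean thickness, mass, thickness-distribution skewness and
k_s of 30 coccoliths per sample under calibrated circular polarized light.
The per-sample means and 95 % confidence intervals of those measurements are
embedded here as a fixture: they anchor the synthetic generator's default
study conditions and serve as inputs for k_s model audits.

Also recorded: the literature k_s recommendations the study evaluated
(0.020 for *E. huxleyi* Type A, 0.05 for *G. oceanica*) and the stated
measurement uncertainties of the imaging method.
"""

from __future__ import annotations

import io

import pandas as pd

from .synth import PopulationSpec

#: Literature k_s recommendation for E. huxleyi Type A coccoliths.
KS_EHUX_LITERATURE = 0.020
#: Literature k_s recommendation for G. oceanica coccoliths.
KS_GOCEANICA_LITERATURE = 0.05

#: Standard measurement uncertainties at 95 % confidence.
UNCERTAINTY_95 = {"length_um": 0.2, "mean_thickness_um": 0.007,
                  "mass_rel": (0.13, 0.20)}

# per-sample means and 95% CI half-widths, 30 coccoliths each
_SUMMARY_CSV = """\
strain,species,salinity,n,length_mean,length_ci,thickness_mean,thickness_ci,mass_mean,mass_ci,skewness_mean,skewness_ci,ks_mean,ks_ci
PLY B11,E. huxleyi,25,30,2.7,0.1,0.067,0.002,0.8,0.1,0.446,0.100,0.014,0.001
PLY B11,E. huxleyi,34,30,2.6,0.1,0.068,0.002,0.8,0.1,0.518,0.100,0.015,0.001
PLY B11,E. huxleyi,44,30,2.9,0.1,0.070,0.002,1.0,0.1,0.478,0.100,0.015,0.001
RCC 868,E. huxleyi,25,30,2.5,0.1,0.077,0.005,0.8,0.1,0.509,0.100,0.018,0.001
RCC 868,E. huxleyi,34,30,2.9,0.1,0.081,0.004,1.2,0.1,0.693,0.100,0.018,0.001
RCC 868,E. huxleyi,44,30,3.2,0.2,0.075,0.004,1.3,0.2,0.719,0.100,0.015,0.001
RCC 1210,E. huxleyi,25,30,2.5,0.1,0.073,0.003,0.8,0.1,0.503,0.100,0.018,0.001
RCC 1210,E. huxleyi,34,30,2.6,0.1,0.078,0.004,0.9,0.1,0.458,0.100,0.018,0.001
RCC 1210,E. huxleyi,44,30,2.9,0.1,0.071,0.003,1.0,0.1,0.604,0.100,0.015,0.001
RCC 1223,G. oceanica,25,30,4.5,0.2,0.142,0.006,5.3,0.5,0.868,0.100,0.021,0.001
RCC 1223,G. oceanica,34,30,4.7,0.2,0.150,0.009,6.1,0.8,0.914,0.100,0.021,0.001
RCC 1223,G. oceanica,44,30,5.1,0.2,0.158,0.009,7.4,0.8,0.802,0.100,0.021,0.001
RCC 1232,E. huxleyi,25,30,2.6,0.1,0.078,0.004,0.9,0.1,0.789,0.100,0.019,0.001
RCC 1232,E. huxleyi,34,30,2.5,0.1,0.076,0.003,0.8,0.1,0.559,0.100,0.019,0.001
RCC 1232,E. huxleyi,44,30,2.6,0.1,0.072,0.003,0.8,0.1,0.723,0.100,0.017,0.001
RCC 1824,E. huxleyi,25,30,2.7,0.1,0.067,0.003,0.8,0.1,0.820,0.100,0.014,0.001
RCC 1824,E. huxleyi,34,30,3.1,0.1,0.080,0.003,1.3,0.1,0.868,0.100,0.016,0.001
RCC 1824,E. huxleyi,44,30,3.1,0.1,0.079,0.005,1.3,0.1,0.771,0.100,0.016,0.001
RCC 1843,E. huxleyi,25,30,2.5,0.1,0.083,0.005,0.9,0.1,0.764,0.100,0.021,0.001
RCC 1843,E. huxleyi,34,30,2.7,0.1,0.092,0.006,1.2,0.2,0.696,0.100,0.022,0.001
RCC 1843,E. huxleyi,44,30,2.7,0.1,0.086,0.006,1.0,0.2,0.614,0.100,0.019,0.001
SAG 33.90,E. huxleyi,25,30,2.7,0.1,0.064,0.002,0.8,0.1,0.446,0.100,0.014,0.001
SAG 33.90,E. huxleyi,34,30,3.1,0.2,0.069,0.002,1.1,0.1,0.843,0.100,0.014,0.001
SAG 33.90,E. huxleyi,44,30,3.4,0.3,0.066,0.001,1.3,0.3,0.631,0.100,0.012,0.001
"""


def reference_summary() -> pd.DataFrame:
    """The published per-sample summary table (24 samples, n = 30 each)."""
    return pd.read_csv(io.StringIO(_SUMMARY_CSV))


# t(0.975, 29) ≈ 2.045: converts a 95% CI half-width (n=30) back to an sd
_T29 = 2.0452


def default_study_design() -> list[tuple[str, float, PopulationSpec]]:
    """Generator design emulating the published study conditions.

    One design cell per (strain, salinity) with the published sample mean
    length as the population mean and the published CI converted back to a
    population sd.  *E. huxleyi* cells use decoupled thickness (the study's
    finding: thickness does not track length) centred on the published mean
    thickness; the *G. oceanica* cells use isometric coupling at
    c = T̄/L̄ (its length and thickness rose together, consistent with a
    constant k_s ≈ 0.02).
    """
    design = []
    for _, row in reference_summary().iterrows():
        n = int(row["n"])
        sd_l = row["length_ci"] * (n ** 0.5) / _T29
        sd_t = row["thickness_ci"] * (n ** 0.5) / _T29
        if row["species"] == "G. oceanica":
            pop = PopulationSpec(
                n=n, mean_length=row["length_mean"], sd_length=sd_l,
                coupling="isometric",
                coupling_c=row["thickness_mean"] / row["length_mean"],
                sd_thickness=sd_t)
        else:
            pop = PopulationSpec(
                n=n, mean_length=row["length_mean"], sd_length=sd_l,
                coupling="decoupled",
                thickness_intercept=row["thickness_mean"],
                sd_thickness=sd_t)
        design.append((row["strain"], float(row["salinity"]), pop))
    return design
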