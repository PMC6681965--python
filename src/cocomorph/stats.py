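"""Statistical layer: ANOVA, Tukey HSD, regression with global assumption
validation, influence diagnostics, and the resolvability rule.

The analysis mirrors a standard morphometric workflow: a one-way ANOVA per
strain and metric tests for a salinity effect; significant ANOVAs are
followed by an all-pairs Tukey HSD (familywise control through the
studentized range distribution); a pairwise difference only counts as
*resolved* if it is at least twice the measurement's standard uncertainty.
Within each sample, ordinary least squares quantifies the length–thickness,
length–mass, length–skewness and length–aspect-ratio relationships.  Each
regression is screened by a global assumption validation: four directional
statistics (residual skewness, residual kurtosis, link misspecification,
heteroscedasticity), each asymptotically χ²(1), summing to a global χ²(4)
statistic.  A violated model is refit on the log-log scale; if the violation
persists the untransformed fit is kept and flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.outliers_influence import OLSInfluence

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# one-way ANOVA
# ----------------------------------------------------------------------
@dataclass
class AnovaResult:
    """Standard one-way decomposition: SS_total = SS_between + SS_within."""

    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float
    f: float
    p: float

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within


def _clean_groups(groups):
    out = []
    for g in groups:
        arr = np.asarray(g, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size < len(np.asarray(g)):
            logger.warning("dropped %d non-finite value(s) from a group",
                           len(np.asarray(g)) - arr.size)
        out.append(arr)
    return out


def one_way_anova(groups) -> AnovaResult:
    """One-way fixed-effects ANOVA over ≥2 groups of n ≥ 2 each."""
    groups = _clean_groups(groups)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs n ≥ 2")
    k = len(groups)
    ns = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(np.sum((g - m) ** 2) for g, m in zip(groups, means)))
    dfb, dfw = k - 1, int(ns.sum()) - k
    msb, msw = ssb / dfb, ssw / dfw
    if ssw == 0 and ssb == 0:
        logger.warning("zero total variance: F = 0, p = 1 by convention")
        return AnovaResult(ssb, ssw, dfb, dfw, msb, msw, 0.0, 1.0)
    if msw == 0:
        return AnovaResult(ssb, ssw, dfb, dfw, msb, msw, np.inf, 0.0)
    f = msb / msw
    p = float(sps.f.sf(f, dfb, dfw))
    return AnovaResult(ssb, ssw, dfb, dfw, msb, msw, float(f), p)


# ----------------------------------------------------------------------
# studentized range / Tukey HSD
# ----------------------------------------------------------------------
def studentized_range_cdf(q: float, k: int, df: float) -> float:
    """CDF of the studentized range of k group means at df error degrees of
    freedom, by numerical integration."""
    if k < 2 or df < 1:
        raise ValueError("need k ≥ 2 and df ≥ 1")
    if q < 0:
        raise ValueError("q must be ≥ 0")
    if q == 0:
        return 0.0
    return float(sps.studentized_range.cdf(q, k, df))


@dataclass
class TukeyResult:
    """All-pairs Tukey HSD comparisons.

    ``pairs`` has one row per (i, j) pair, i < j, with the difference of
    means (mean_j − mean_i), 95 % confidence limits and the adjusted p
    value from the studentized range distribution (Tukey–Kramer SE for
    unequal n).
    """

    pairs: pd.DataFrame
    k: int
    df_within: int
    ms_within: float
    q_crit: float


def tukey_hsd(groups, labels=None, alpha: float = 0.05) -> TukeyResult:
    """Tukey HSD post-hoc test on the groups of a one-way layout."""
    cleaned = _clean_groups(groups)
    an = one_way_anova(cleaned)
    k = len(cleaned)
    labels = list(labels) if labels is not None else list(range(k))
    ns = [g.size for g in cleaned]
    means = [g.mean() for g in cleaned]
    q_crit = float(sps.studentized_range.ppf(1 - alpha, k, an.df_within))
    rows = []
    for i, j in combinations(range(k), 2):
        diff = means[j] - means[i]
        se_q = np.sqrt(an.ms_within / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        if se_q == 0:
            p_adj = 1.0 if diff == 0 else 0.0
            half = 0.0
        else:
            p_adj = float(sps.studentized_range.sf(abs(diff) / se_q, k,
                                                   an.df_within))
            half = q_crit * se_q
        rows.append({
            "pair": f"{labels[j]}-{labels[i]}",
            "group_i": labels[i], "group_j": labels[j],
            "diff": float(diff), "lower": float(diff - half),
            "upper": float(diff + half), "p_adj": min(max(p_adj, 0.0), 1.0),
        })
    return TukeyResult(pairs=pd.DataFrame(rows), k=k,
                       df_within=an.df_within, ms_within=an.ms_within,
                       q_crit=q_crit)


# ----------------------------------------------------------------------
# regression + assumption validation
# ----------------------------------------------------------------------
@dataclass
class RegressionResult:
    """OLS fit of y on x with an intercept."""

    slope: float
    intercept: float
    r2: float
    slope_p: float
    residuals: np.ndarray
    fitted: np.ndarray
    x: np.ndarray
    y: np.ndarray
    n: int
    transform: str = "none"          # "none" | "log-log"
    model: object = field(default=None, repr=False)


def linear_regression(x, y, transform: str = "none") -> RegressionResult:
    """Ordinary least squares of y on x (optionally on the log-log scale)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    if keep.sum() < len(x):
        logger.warning("dropped %d non-finite observation(s)",
                       len(x) - int(keep.sum()))
    x, y = x[keep], y[keep]
    if transform == "log-log":
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log-log transform needs positive data")
        x, y = np.log(x), np.log(y)
    elif transform != "none":
        raise ValueError("transform must be 'none' or 'log-log'")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    r2 = float(res.rsquared) if np.ptp(y) > 0 else 0.0  # constant y: no TSS
    slope_p = float(res.pvalues[1])
    if not np.isfinite(slope_p):  # zero residual variance
        slope_p = 1.0 if np.isclose(res.params[1], 0) else 0.0
    return RegressionResult(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        r2=r2, slope_p=slope_p,
        residuals=np.asarray(res.resid), fitted=np.asarray(res.fittedvalues),
        x=x, y=y, n=n, transform=transform, model=res)


@dataclass
class AssumptionReport:
    """Global validation of the linear-model assumptions.

    Four directional statistics — residual skewness, residual kurtosis,
    link misspecification (score test for a squared-fitted-values term) and
    heteroscedasticity (squared residuals on fitted values) — each referred
    to χ²(1); their sum is the global χ²(4) statistic.  Independence of the
    observations cannot be tested from a single unordered sample and is
    recorded as assumed.
    """

    stat_skewness: float
    stat_kurtosis: float
    stat_link: float
    stat_heteroscedasticity: float
    p_skewness: float
    p_kurtosis: float
    p_link: float
    p_heteroscedasticity: float
    global_stat: float
    global_p: float
    influential: list[int]
    decision: str = "keep"           # keep | log-transform | flag-unfixable
    independence: str = "assumed"


def _aux_nr2(response: np.ndarray, regressors: np.ndarray, m: int) -> float:
    """Score-type statistic m·R² of an auxiliary OLS (χ²(1) per added
    regressor beyond those already in the main fit)."""
    res = sm.OLS(response, sm.add_constant(regressors)).fit()
    return float(m * res.rsquared)


def validate_assumptions(reg: RegressionResult,
                         alpha: float = 0.05) -> AssumptionReport:
    """Compute the four-component global assumption statistic for a fit.

    The statistics are computed on OLS residuals, so they are standardized
    with the residual degrees of freedom m = n − 2 rather than n (exact
    null moments of skewness/kurtosis at size m; m·R² for the score-type
    components).  This keeps the components close to their nominal χ²(1)
    level at the study's sample size of n ≈ 30.
    """
    n = reg.n
    if n < 8:
        raise ValueError("need n ≥ 8 for the asymptotic assumption tests")
    e = reg.residuals
    m = n - 2  # residual degrees of freedom of the simple regression
    g1 = float(sps.skew(e, bias=True))
    g2 = float(sps.kurtosis(e, fisher=False, bias=True))
    var_g1 = 6.0 * (m - 2) / ((m + 1) * (m + 3))
    mean_g2 = 3.0 * (m - 1) / (m + 1)
    var_g2 = (24.0 * m * (m - 2) * (m - 3)
              / ((m + 1) ** 2 * (m + 3) * (m + 5)))
    s_skew = g1 ** 2 / var_g1
    s_kurt = (g2 - mean_g2) ** 2 / var_g2

    # link: does fitted² explain the residuals? (RESET-type score test)
    aug = np.column_stack([reg.x, reg.fitted ** 2])
    s_link = _aux_nr2(e, aug, m)
    # heteroscedasticity: do squared residuals trend with the fit?
    s_het = _aux_nr2(e ** 2, reg.fitted, m)

    stats4 = np.array([s_skew, s_kurt, s_link, s_het])
    ps = sps.chi2.sf(stats4, 1)
    g = float(stats4.sum())
    gp = float(sps.chi2.sf(g, 4))
    return AssumptionReport(
        stat_skewness=s_skew, stat_kurtosis=s_kurt, stat_link=s_link,
        stat_heteroscedasticity=s_het,
        p_skewness=float(ps[0]), p_kurtosis=float(ps[1]),
        p_link=float(ps[2]), p_heteroscedasticity=float(ps[3]),
        global_stat=g, global_p=gp,
        influential=influential_points(reg, alpha),
        decision="keep" if gp >= alpha else "log-transform")


def regress_with_validation(x, y, alpha: float = 0.05
                            ) -> tuple[RegressionResult, AssumptionReport]:
    """OLS with the transform policy applied.

    If the global assumption test rejects at ``alpha`` and the data are
    positive, the model is refit on the log-log scale; if the refit still
    rejects (or the data cannot be logged), the untransformed fit is kept
    and flagged unfixable.
    """
    reg = linear_regression(x, y)
    report = validate_assumptions(reg, alpha)
    if report.global_p >= alpha:
        return reg, report
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if np.any(x_arr <= 0) or np.any(y_arr <= 0):
        report.decision = "flag-unfixable"
        return reg, report
    reg_log = linear_regression(x, y, transform="log-log")
    report_log = validate_assumptions(reg_log, alpha)
    if report_log.global_p >= alpha:
        report_log.decision = "log-transform"
        return reg_log, report_log
    report.decision = "flag-unfixable"
    return reg, report


def influential_points(reg: RegressionResult, alpha: float = 0.05) -> list[int]:
    """Indices of observations whose studentized residuals leave the
    pointwise (1−alpha) normal quantile–quantile envelope.

    Points are reported, never removed: the flag records whether deleting
    them would fix an assumption violation, not a cleaning step.
    """
    if reg.model is not None and reg.n > reg.model.df_model + 2:
        stud = np.asarray(OLSInfluence(reg.model).resid_studentized_external)
    else:
        sd = reg.residuals.std(ddof=2) if reg.n > 2 else 0.0
        if sd == 0:
            return []
        stud = reg.residuals / sd
    if not np.all(np.isfinite(stud)):
        stud = np.nan_to_num(stud)
    n = stud.size
    order = np.argsort(stud)
    srt = stud[order]
    i = np.arange(1, n + 1)
    p = (i - 0.5) / n
    z = sps.norm.ppf(p)
    se = np.sqrt(p * (1 - p) / n) / sps.norm.pdf(z)
    zc = sps.norm.ppf(1 - alpha / 2)
    outside = (srt < z - zc * se) | (srt > z + zc * se)
    return sorted(int(ix) for ix in order[outside])


# ----------------------------------------------------------------------
# resolvability + study-level analysis
# ----------------------------------------------------------------------
def resolvable_difference(diff: float, standard_uncertainty: float,
                          factor: float = 2.0) -> bool:
    """A difference counts as resolved only when |diff| is at least
    ``factor`` times the measurement's standard uncertainty."""
    if standard_uncertainty < 0:
        raise ValueError("uncertainty must be ≥ 0")
    return bool(abs(diff) >= factor * standard_uncertainty)


#: Metrics analysed per strain and the 95 %-level standard uncertainty used
#: by the resolvability rule.  Mass uses a relative uncertainty.
DEFAULT_METRIC_UNCERTAINTY = {
    "length_um": ("absolute", 0.2),
    "mean_thickness_um": ("absolute", 0.007),
    "mass_pg": ("relative", 0.16),
}

REGRESSION_PAIRS = [
    ("length_um", "mean_thickness_um"),
    ("length_um", "mass_pg"),
    ("length_um", "skewness"),
    ("length_um", "aspect_ratio"),
]


@dataclass
class StatReport:
    """Study-level inference output.

    ``anova`` — one row per (strain, metric) with the ANOVA decomposition;
    ``tukey`` — one row per significant-ANOVA pair with adjusted p,
    significance and resolvability flags;
    ``regressions`` — one row per (strain, salinity, x, y) OLS with the
    assumption-validation outcome;
    ``assumption_details`` — the four χ²(1) components per regression.
    """

    anova: pd.DataFrame
    tukey: pd.DataFrame
    regressions: pd.DataFrame
    assumption_details: pd.DataFrame
    alpha: float = 0.05

    def to_csv(self, prefix) -> list[str]:
        paths = []
        for name in ("anova", "tukey", "regressions", "assumption_details"):
            path = f"{prefix}_{name}.csv"
            getattr(self, name).to_csv(path, index=False,
                                       float_format="%.10g")
            paths.append(path)
        return paths


def analyze_study(tables, metric_uncertainty=None, alpha: float = 0.05,
                  regression_pairs=None) -> StatReport:
    """Full inference over a study of labelled sample tables.

    ``tables`` is an iterable of objects with ``strain``, ``salinity`` and a
    ``data`` DataFrame (e.g. :class:`~cocomorph.measure.SampleTable`).
    Strains with fewer than two salinity levels are skipped with a warning.
    """
    metric_uncertainty = metric_uncertainty or DEFAULT_METRIC_UNCERTAINTY
    regression_pairs = regression_pairs or REGRESSION_PAIRS
    tables = list(tables)
    by_strain: dict[str, list] = {}
    for t in tables:
        by_strain.setdefault(t.strain, []).append(t)

    anova_rows, tukey_rows, reg_rows, assum_rows = [], [], [], []
    for strain, cells in by_strain.items():
        cells = sorted(cells, key=lambda t: t.salinity)
        if len(cells) < 2:
            logger.warning("strain %s has <2 salinity levels: skipped", strain)
            continue
        sal_labels = [c.salinity for c in cells]
        for metric, (kind, u95) in metric_uncertainty.items():
            groups = [c.data[metric].to_numpy(dtype=float) for c in cells]
            an = one_way_anova(groups)
            anova_rows.append({
                "strain": strain, "metric": metric,
                "ss_between": an.ss_between, "ss_within": an.ss_within,
                "df_between": an.df_between, "df_within": an.df_within,
                "ms_between": an.ms_between, "ms_within": an.ms_within,
                "F": an.f, "p": an.p, "significant": an.p < alpha,
            })
            if an.p >= alpha:
                continue
            tk = tukey_hsd(groups, labels=[f"{s:g}" for s in sal_labels],
                           alpha=alpha)
            for _, pair in tk.pairs.iterrows():
                if kind == "relative":
                    gi = groups[[f"{s:g}" for s in sal_labels].index(
                        pair["group_i"])]
                    gj = groups[[f"{s:g}" for s in sal_labels].index(
                        pair["group_j"])]
                    u = u95 * 0.5 * (gi.mean() + gj.mean())
                else:
                    u = u95
                sig = pair["p_adj"] < alpha
                tukey_rows.append({
                    "strain": strain, "metric": metric, "pair": pair["pair"],
                    "diff": pair["diff"], "lower": pair["lower"],
                    "upper": pair["upper"], "p_adj": pair["p_adj"],
                    "significant": sig,
                    "resolved": sig and resolvable_difference(pair["diff"], u),
                })
        for cell in cells:
            for xcol, ycol in regression_pairs:
                if xcol not in cell.data or ycol not in cell.data:
                    continue
                x = cell.data[xcol].to_numpy(dtype=float)
                y = cell.data[ycol].to_numpy(dtype=float)
                try:
                    reg, report = regress_with_validation(x, y, alpha)
                except ValueError as exc:
                    logger.warning("%s/%s %s~%s: %s", strain, cell.salinity,
                                   ycol, xcol, exc)
                    continue
                reg_rows.append({
                    "strain": strain, "salinity": cell.salinity,
                    "x": xcol, "y": ycol, "n": reg.n,
                    "slope": reg.slope, "intercept": reg.intercept,
                    "r2": reg.r2, "slope_p": reg.slope_p,
                    "significant": reg.slope_p < alpha,
                    "transform": reg.transform,
                    "decision": report.decision,
                    "n_influential": len(report.influential),
                })
                assum_rows.append({
                    "strain": strain, "salinity": cell.salinity,
                    "x": xcol, "y": ycol,
                    "stat_skewness": report.stat_skewness,
                    "stat_kurtosis": report.stat_kurtosis,
                    "stat_link": report.stat_link,
                    "stat_heteroscedasticity":
                        report.stat_heteroscedasticity,
                    "global_stat": report.global_stat,
                    "global_p": report.global_p,
                    "independence": report.independence,
                    "influential": ";".join(map(str, report.influential)),
                })
    return StatReport(
        anova=pd.DataFrame(anova_rows), tukey=pd.DataFrame(tukey_rows),
        regressions=pd.DataFrame(reg_rows),
        assumption_details=pd.DataFrame(assum_rows), alpha=alpha)
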