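"""Pipeline orchestration: config, file I/O, reports and figures.

One :func:`run_pipeline` call chains generator → measurement → k_s audit →
statistics into a reproducible run: per-particle CSV, per-sample summary
CSV, a k_s audit, ANOVA/Tukey/regression reports, optional figures, and a
manifest recording config, seeds and output hashes.  Identical config and
seed give byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

from . import __version__
from .measure import (SampleTable, SegmentationParams, UncertaintyBudget,
                      measure_sample)
from .morphmodel import ks_audit, mass_from_length
from .optics import (OpticalConstants, RetardationCalibration,
                     default_calibration)
from .refdata import KS_EHUX_LITERATURE, default_study_design
from .stats import StatReport, analyze_study
from .synth import PopulationSpec, StudyBundle, TABLE_COLUMNS, simulate_study

logger = logging.getLogger(__name__)

CSV_FLOAT_FORMAT = "%.10g"

#: Printed precision of the per-sample summary (decimal places).
DEFAULT_PRECISION = {"length_um": 1, "mean_thickness_um": 3, "mass_pg": 1,
                     "skewness": 3, "ks": 3}


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML/JSON serializable)."""

    mode: str = "tables"                   # "tables" | "images"
    design: list = field(default_factory=list)  # (strain, salinity, PopulationSpec)
    constants: OpticalConstants = field(default_factory=OpticalConstants)
    calibration_path: str | None = None    # JSON; None → default sin² curve
    bit_depth: int = 16
    noise_sd: float = 40.0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    budget: UncertaintyBudget = field(default_factory=UncertaintyBudget)
    alpha: float = 0.05
    reference_ks: float = KS_EHUX_LITERATURE
    outdir: str = "cocomorph_run"
    seed: int = 0
    make_figures: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("tables", "images"):
            raise ValueError("mode must be 'tables' or 'images'")
        if not self.design:
            self.design = default_study_design()
        if self.calibration_path is not None \
                and not Path(self.calibration_path).exists():
            raise FileNotFoundError(
                f"calibration file not found: {self.calibration_path}")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "design": [
                {"strain": s, "salinity": sal,
                 "population": dataclasses.asdict(pop)}
                for s, sal, pop in self.design],
            "constants": dataclasses.asdict(self.constants),
            "calibration_path": self.calibration_path,
            "bit_depth": self.bit_depth, "noise_sd": self.noise_sd,
            "segmentation": dataclasses.asdict(self.segmentation),
            "budget": dataclasses.asdict(self.budget),
            "alpha": self.alpha, "reference_ks": self.reference_ks,
            "outdir": self.outdir, "seed": self.seed,
            "make_figures": self.make_figures,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        kwargs["design"] = [
            (c["strain"], float(c["salinity"]),
             PopulationSpec(**c["population"]))
            for c in d.get("design", [])]
        kwargs["constants"] = OpticalConstants(**d.get("constants", {}))
        kwargs["segmentation"] = SegmentationParams(
            **d.get("segmentation", {}))
        kwargs["budget"] = UncertaintyBudget(**d.get("budget", {}))
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ----------------------------------------------------------------------
# summaries and CSV I/O
# ----------------------------------------------------------------------
def summarize_sample(table: SampleTable,
                     precision: dict | None = None) -> dict:
    """One summary row per sample: mean and t-based 95 % CI half-width per
    metric, rounded to the configured printed precision.

    With n < 2 the CI is reported absent (NaN) with a warning.
    """
    precision = precision or DEFAULT_PRECISION
    row = {"strain": table.strain, "salinity": table.salinity, "n": table.n}
    summ = table.summary(metrics=tuple(precision))
    for metric, digits in precision.items():
        entry = summ.get(metric)
        if entry is None:
            continue
        if entry["n"] < 2:
            logger.warning("sample %s/%s: n<2, CI absent for %s",
                           table.strain, table.salinity, metric)
        row[f"{metric}_mean"] = (round(entry["mean"], digits)
                                 if np.isfinite(entry["mean"]) else np.nan)
        row[f"{metric}_ci95"] = (round(entry["ci95"], digits)
                                 if np.isfinite(entry["ci95"]) else np.nan)
    return row


def tables_from_dataframe(df: pd.DataFrame) -> list[SampleTable]:
    """Split a particle table into per-(strain, salinity) SampleTables."""
    out = []
    for (strain, sal), grp in df.groupby(["strain", "salinity"], sort=True):
        out.append(SampleTable(strain=str(strain), salinity=float(sal),
                               data=grp.reset_index(drop=True)))
    return out


def write_measurement_csv(tables, path) -> None:
    """Write per-particle measurements of many samples to one CSV."""
    frames = []
    for t in tables:
        d = t.data.copy()
        for col, val in (("salinity", t.salinity), ("strain", t.strain)):
            if col in d.columns:
                d = d.drop(columns=col)
            d.insert(0, col, val)
        frames.append(d)
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=CSV_FLOAT_FORMAT)


def read_measurement_csv(path, column_map: dict | None = None,
                         sep: str = ",") -> list[SampleTable]:
    """Read a per-particle CSV into labelled SampleTables.

    ``column_map`` maps the package's column names (``strain``,
    ``salinity``, ``length_um``, ``mass_pg``, ...) to the file's headers;
    identity by default.  A missing mapped column raises with the available
    headers listed; unparseable numeric cells drop their row with a logged
    count.  Unknown columns are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, sep=sep)
    column_map = column_map or {}
    missing = [src for src in column_map.values() if src not in df.columns]
    if missing:
        raise KeyError(
            f"column(s) {missing} not in {path.name}; available headers: "
            f"{list(df.columns)}")
    df = df.rename(columns={v: k for k, v in column_map.items()})
    for required in ("strain", "salinity"):
        if required not in df.columns:
            raise KeyError(
                f"column {required!r} missing after mapping; available: "
                f"{list(df.columns)}")
    numeric = [c for c in TABLE_COLUMNS
               if c in df.columns and c not in ("strain", "salinity")]
    before = len(df)
    for col in numeric + ["salinity"]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=["salinity"] + [c for c in numeric
                                          if c in ("length_um", "mass_pg")
                                          and c in df.columns])
    if len(df) < before:
        logger.warning("dropped %d unparseable row(s)", before - len(df))
    logger.info("read %d rows from %s", len(df), path.name)
    return tables_from_dataframe(df)


# ----------------------------------------------------------------------
# figures
# ----------------------------------------------------------------------
def report_figures(summary: pd.DataFrame, particles: pd.DataFrame,
                   regressions: pd.DataFrame, outdir,
                   reference_ks: float = KS_EHUX_LITERATURE,
                   density: float = 2.71) -> list[str]:
    """Diagnostic figure files for a completed run.

    Per strain: salinity trend panels (length / thickness / mass with 95 %
    CIs), a length-vs-thickness and length-vs-mass scatter with regression
    lines (starred when significant), and a measured-vs-model mean mass
    comparison at the reference k_s.
    """
    if summary.empty:
        raise ValueError("empty outputs: nothing to plot")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for strain, sdf in summary.groupby("strain"):
        sdf = sdf.sort_values("salinity")
        fig, axes = plt.subplots(1, 4, figsize=(14, 3.2))
        for ax, metric, label in zip(
                axes[:3],
                ("length_um", "mean_thickness_um", "mass_pg"),
                ("length (μm)", "mean thickness (μm)", "mass (pg)")):
            ax.errorbar(sdf["salinity"], sdf[f"{metric}_mean"],
                        yerr=sdf[f"{metric}_ci95"], fmt="o-", capsize=3)
            ax.set_xlabel("salinity")
            ax.set_ylabel(label)
        ax = axes[3]
        ax.plot(sdf["salinity"], sdf["mass_pg_mean"], "s-", color="grey",
                label="measured")
        model_mass = mass_from_length(
            sdf["length_um_mean"].to_numpy(), reference_ks, density)
        ax.plot(sdf["salinity"], model_mass, "s--", color="red",
                label=f"k_s={reference_ks:g} model")
        ax.set_xlabel("salinity")
        ax.set_ylabel("mean mass (pg)")
        ax.legend(fontsize=7)
        fig.suptitle(strain)
        fig.tight_layout()
        path = outdir / f"trends_{strain.replace(' ', '_')}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        paths.append(str(path))

        pdf = particles[particles["strain"] == strain]
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.2))
        for ax, ycol, label in zip(
                axes, ("mean_thickness_um", "mass_pg"),
                ("mean thickness (μm)", "mass (pg)")):
            for sal, grp in pdf.groupby("salinity"):
                ax.scatter(grp["length_um"], grp[ycol], s=8, label=f"{sal:g}")
                rrow = regressions[
                    (regressions["strain"] == strain)
                    & (regressions["salinity"] == sal)
                    & (regressions["y"] == ycol)]
                if len(rrow):
                    r = rrow.iloc[0]
                    xs = np.linspace(grp["length_um"].min(),
                                     grp["length_um"].max(), 20)
                    if r["transform"] == "log-log":
                        ys = np.exp(r["intercept"]) * xs ** r["slope"]
                    else:
                        ys = r["intercept"] + r["slope"] * xs
                    star = "*" if r["significant"] else ""
                    ax.plot(xs, ys, lw=1,
                            label=f"{sal:g} r²={r['r2']:.2f}{star}")
            ax.set_xlabel("length (μm)")
            ax.set_ylabel(label)
            ax.legend(fontsize=6)
        fig.suptitle(strain)
        fig.tight_layout()
        path = outdir / f"scatter_{strain.replace(' ', '_')}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        paths.append(str(path))
    return paths


# ----------------------------------------------------------------------
# the run
# ----------------------------------------------------------------------
def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one run: config snapshot, outputs and their hashes."""

    config: dict
    version: str
    outputs: dict
    warnings: list
    started: str
    finished: str
    complete: bool = True

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute a full generator → measurement → statistics run.

    Writes, under ``config.outdir``: ``calibration.json``,
    ``particles.csv``, ``truth.csv``, ``summary.csv``, ``ks_audit.csv``,
    ``stats_*.csv`` and ``manifest.json`` (plus figures when requested).
    """
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []
    outputs: dict[str, str] = {}
    stage = "calibrate"
    try:
        if config.calibration_path:
            cal = RetardationCalibration.from_json(config.calibration_path)
        else:
            cal = default_calibration(config.bit_depth)
        cal.to_json(outdir / "calibration.json")

        stage = "simulate"
        bundle: StudyBundle = simulate_study(
            config.design, seed=config.seed, mode=config.mode,
            constants=config.constants, cal=cal,
            noise_sd=config.noise_sd, bit_depth=config.bit_depth)
        bundle.truth.to_csv(outdir / "truth.csv", index=False,
                            float_format=CSV_FLOAT_FORMAT)

        stage = "measure"
        if config.mode == "images":
            tables = []
            for (strain, sal), cell in bundle.images.items():
                tab = measure_sample(
                    [cell["image"]], cal, config.constants,
                    config.segmentation, config.budget,
                    strain=strain, salinity=sal)
                tables.append(tab)
        else:
            tables = tables_from_dataframe(bundle.tables)
        write_measurement_csv(tables, outdir / "particles.csv")

        stage = "summarize"
        summary = pd.DataFrame([summarize_sample(t) for t in tables])
        summary.to_csv(outdir / "summary.csv", index=False,
                       float_format=CSV_FLOAT_FORMAT)

        stage = "audit-ks"
        audit = ks_audit(tables, reference_ks=config.reference_ks,
                         density=config.constants.density)
        audit.to_csv(outdir / "ks_audit.csv", index=False,
                     float_format=CSV_FLOAT_FORMAT)

        stage = "analyze"
        report: StatReport = analyze_study(tables, alpha=config.alpha)
        for p in report.to_csv(str(outdir / "stats")):
            outputs[Path(p).name] = _sha256(p)

        if config.make_figures:
            stage = "figures"
            particles = pd.concat(
                [t.data.assign(strain=t.strain, salinity=t.salinity)
                 for t in tables], ignore_index=True)
            for p in report_figures(summary, particles, report.regressions,
                                    outdir / "figures",
                                    reference_ks=config.reference_ks,
                                    density=config.constants.density):
                outputs[str(Path(p).relative_to(outdir))] = _sha256(p)
    except Exception as exc:
        manifest = RunManifest(
            config=config.to_dict(), version=__version__, outputs=outputs,
            warnings=warnings_log + [f"stage '{stage}' failed: {exc}"],
            started=started, finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
            complete=False)
        manifest.to_json(outdir / "manifest.json")
        raise RuntimeError(f"pipeline stage '{stage}' failed") from exc

    for name in ("calibration.json", "truth.csv", "particles.csv",
                 "summary.csv", "ks_audit.csv"):
        outputs[name] = _sha256(outdir / name)
    manifest = RunManifest(
        config=config.to_dict(), version=__version__, outputs=outputs,
        warnings=warnings_log, started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"))
    manifest.to_json(outdir / "manifest.json")
    return manifest
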