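"""File formats, configuration and report assembly for the crowding pipeline.

Two plain CSV formats tie the stages together:

* thresholds: ``observer,meridian,eccentricity_deg,session,spacing_threshold_deg``
  with meridian in {upper, lower, left, right}; one row per measured
  spacing threshold (deg of visual angle).
* areas: ``observer,map,hemisphere,area_mm2`` with map in {V1..V4} and
  hemisphere in {L, R}; areas are mm² restricted to 10 deg eccentricity and
  are summed across hemispheres on read.

``run_pipeline`` turns the two tables into a JSON report (per-map
conservation fit, cortical crowding distance, correlations, bootstrap CIs,
test-retest summary) with the effective configuration echoed, so every
number is traceable to the constants that produced it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .bouma import DEFAULT_A, DEFAULT_PHI0, DEFAULT_PHI_MAX
from .conservation import MAPS, covariance_ellipse, fit_conservation, map_comparison_report
from .psychophysics import MERIDIANS, bouma_table, test_retest_correlation
from .synthetic import PopulationParams, QuestConfig

logger = logging.getLogger(__name__)

__all__ = [
    "THRESHOLD_COLUMNS",
    "AREA_COLUMNS",
    "PipelineConfig",
    "read_thresholds",
    "write_thresholds",
    "read_areas",
    "write_areas",
    "run_pipeline",
    "plot_conservation_map",
]

THRESHOLD_COLUMNS = [
    "observer",
    "meridian",
    "eccentricity_deg",
    "session",
    "spacing_threshold_deg",
]
AREA_COLUMNS = ["observer", "map", "hemisphere", "area_mm2"]
HEMISPHERES = ("L", "R")


@dataclass(frozen=True)
class PipelineConfig:
    """Effective configuration of one pipeline run.

    Field constants default to phi0 = 0.24 deg, a = 2, phi_max = 10 deg and
    the bootstrap to n = 10000 resamples at 68% and 95% coverage.
    """

    phi0: float = DEFAULT_PHI0
    a: float = DEFAULT_A
    phi_max: float = DEFAULT_PHI_MAX
    n_boot: int = 10000
    bootstrap_levels: tuple[int, ...] = (68, 95)
    seed: int = 0
    population: PopulationParams = field(default_factory=PopulationParams)
    quest: QuestConfig = field(default_factory=QuestConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bootstrap_levels"] = list(self.bootstrap_levels)
        d["population"]["v123_area_medians"] = dict(
            self.population.v123_area_medians
        )
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        data = dict(data)
        if "population" in data and not isinstance(data["population"], PopulationParams):
            data["population"] = PopulationParams(**data["population"])
        if "quest" in data and not isinstance(data["quest"], QuestConfig):
            data["quest"] = QuestConfig(**data["quest"])
        if "bootstrap_levels" in data:
            data["bootstrap_levels"] = tuple(data["bootstrap_levels"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _raise_rows(bad: pd.Series, path, message: str) -> None:
    """Report offending CSV rows by file line number (header is line 1)."""
    if bad.any():
        lines = [int(i) + 2 for i in bad[bad].index[:20]]
        raise ValueError(f"{path}: {message} at line(s) {lines}")


def read_thresholds(path: str | Path) -> pd.DataFrame:
    """Read and validate a thresholds CSV."""
    df = pd.read_csv(path)
    missing = [c for c in THRESHOLD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[THRESHOLD_COLUMNS].copy()
    _raise_rows(~df["meridian"].isin(MERIDIANS), path, "unknown meridian")
    _raise_rows(
        ~(pd.to_numeric(df["spacing_threshold_deg"], errors="coerce") > 0),
        path,
        "non-positive or malformed spacing threshold",
    )
    _raise_rows(
        ~(pd.to_numeric(df["eccentricity_deg"], errors="coerce") > 0),
        path,
        "non-positive or malformed eccentricity",
    )
    df["observer"] = df["observer"].astype(str)
    df["session"] = df["session"].astype(int)
    logger.info("read %d threshold rows (%d observers) from %s",
                len(df), df["observer"].nunique(), path)
    return df


def write_thresholds(df: pd.DataFrame, path: str | Path) -> None:
    df[THRESHOLD_COLUMNS].to_csv(path, index=False)


def read_areas(path: str | Path) -> pd.DataFrame:
    """Read an areas CSV and sum across hemispheres.

    Returns a wide table with one row per observer and one bilateral-area
    column per map.  Duplicate (observer, map, hemisphere) rows are
    rejected; observer-maps with a single hemisphere are kept with a logged
    warning and listed in ``result.attrs["single_hemisphere"]``; observers
    missing a map entirely get NaN and are listed in
    ``result.attrs["missing_map"]``.
    """
    df = pd.read_csv(path)
    missing = [c for c in AREA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[AREA_COLUMNS].copy()
    df["observer"] = df["observer"].astype(str)
    _raise_rows(~df["map"].isin(MAPS), path, "unknown map name")
    _raise_rows(~df["hemisphere"].isin(HEMISPHERES), path, "unknown hemisphere")
    _raise_rows(
        ~(pd.to_numeric(df["area_mm2"], errors="coerce") > 0),
        path,
        "non-positive or malformed area",
    )
    dup = df.duplicated(subset=["observer", "map", "hemisphere"], keep=False)
    if dup.any():
        raise ValueError(
            f"{path}: duplicate observer-map-hemisphere rows at line(s) "
            f"{[int(i) + 2 for i in dup[dup].index[:20]]}"
        )

    counts = df.groupby(["observer", "map"])["hemisphere"].count()
    single = [tuple(idx) for idx in counts[counts < 2].index]
    for observer, m in single:
        logger.warning("%s %s: only one hemisphere present; using it alone",
                       observer, m)
    wide = (
        df.groupby(["observer", "map"])["area_mm2"].sum().unstack("map")
        .reindex(columns=list(MAPS))
    )
    missing_map = [
        (obs, m) for obs in wide.index for m in MAPS if pd.isna(wide.loc[obs, m])
    ]
    for obs, m in missing_map:
        logger.warning("%s: missing map %s", obs, m)
    wide = wide.reset_index()
    wide.attrs["single_hemisphere"] = single
    wide.attrs["missing_map"] = missing_map
    logger.info("read areas for %d observers from %s", len(wide), path)
    return wide


def write_areas(df_long: pd.DataFrame, path: str | Path) -> None:
    df_long[AREA_COLUMNS].to_csv(path, index=False)


def _ci_list(ci: tuple[float, float] | None):
    return None if ci is None else [ci[0], ci[1]]


def run_pipeline(
    config: PipelineConfig,
    thresholds: str | Path | pd.DataFrame,
    areas: str | Path | pd.DataFrame,
    out_json: str | Path | None = None,
    figures_dir: str | Path | None = None,
) -> dict:
    """Run thresholds + areas through the full analysis and assemble a report.

    Deterministic given the config seed; the report echoes the effective
    configuration.  Observer sets of the two inputs must match exactly.
    """
    thr = thresholds if isinstance(thresholds, pd.DataFrame) else read_thresholds(thresholds)
    ar = areas if isinstance(areas, pd.DataFrame) else read_areas(areas)

    per_obs = bouma_table(thr, phi0=config.phi0, a=config.a, phi_max=config.phi_max)
    thr_ids = set(per_obs["observer"])
    area_ids = set(ar["observer"])
    if thr_ids != area_ids:
        raise ValueError(
            "observer sets differ between thresholds and areas; "
            f"thresholds-only={sorted(thr_ids - area_ids)}, "
            f"areas-only={sorted(area_ids - thr_ids)}"
        )
    cohort = per_obs.merge(ar, on="observer", validate="one_to_one")

    report_df = map_comparison_report(
        cohort, maps=MAPS, n_boot=config.n_boot, seed=config.seed
    )
    maps_out = {}
    for m, row in report_df.iterrows():
        maps_out[m] = {
            "n": int(row["n"]),
            "k": row["k"],
            "c": row["c"],
            "r": row["r"],
            "r_squared": row["r_squared"],
            "k_ci_68": _ci_list(row["k_ci_68"]),
            "k_ci_95": _ci_list(row["k_ci_95"]),
            "c_ci_68": _ci_list(row["c_ci_68"]),
            "c_ci_95": _ci_list(row["c_ci_95"]),
            "r_ci_68": _ci_list(row["r_ci_68"]),
            "r_ci_95": _ci_list(row["r_ci_95"]),
            "r_squared_ci_68": _ci_list(row["r_squared_ci_68"]),
            "r_squared_ci_95": _ci_list(row["r_squared_ci_95"]),
        }

    report: dict = {
        "config": config.to_dict(),
        "n_observers": int(len(cohort)),
        "maps": maps_out,
        "best_map_by_r_squared": str(report_df["r_squared"].idxmax()),
    }
    try:
        trt = test_retest_correlation(per_obs, on="lambda")
        report["test_retest"] = {
            "r": trt.r, "session_ratio": trt.session_ratio, "n": trt.n,
        }
    except ValueError as exc:  # e.g. single-session data
        report["test_retest"] = {"error": str(exc)}

    if out_json is not None:
        Path(out_json).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        logger.info("wrote report to %s", out_json)
    if figures_dir is not None:
        figures_dir = Path(figures_dir)
        figures_dir.mkdir(parents=True, exist_ok=True)
        for m in MAPS:
            fig = plot_conservation_map(cohort, m, n_boot=None)
            fig.savefig(figures_dir / f"conservation_{m}.png", dpi=150)
    return report


def plot_conservation_map(cohort: pd.DataFrame, visual_map: str, n_boot=None):
    """Scatter of lambda vs map area with covariance ellipses and the
    conservation line through the origin."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    lam = cohort["lambda"].to_numpy(dtype=float)
    area = cohort[visual_map].to_numpy(dtype=float)
    fit = fit_conservation(cohort, visual_map, n_boot=n_boot)

    fig, ax = plt.subplots(figsize=(4.2, 4.0))
    ax.scatter(area, lam, s=18, color="tab:blue", zorder=3)
    x_line = np.linspace(0, area.max() * 1.1, 50)
    ax.plot(x_line, fit.k * x_line, "k--",
            label=f"$\\lambda = {fit.k:.2f}\\,A$ ($c$ = {fit.c:.2f} mm)")
    sd_a, sd_l = area.std(), lam.std()
    for n_sd in (1, 2):
        ell = covariance_ellipse(cohort, visual_map, n_sd=n_sd)
        t = np.linspace(0, 2 * math.pi, 200)
        # standardized-frame ellipse mapped back to raw units
        u = ell.ellipse_axes[0] * np.cos(t)
        v = ell.ellipse_axes[1] * np.sin(t)
        ca, sa = math.cos(ell.ellipse_angle), math.sin(ell.ellipse_angle)
        xs = ell.ellipse_center[0] + (u * ca - v * sa) * sd_a
        ys = ell.ellipse_center[1] + (u * sa + v * ca) * sd_l
        ax.plot(xs, ys, color="tab:orange", lw=1, alpha=0.8)
    ax.set_xlabel(f"{visual_map} surface area $A$ (mm$^2$)")
    ax.set_ylabel("uncrowded letters $\\lambda$")
    ax.set_title(f"{visual_map}: r = {covariance_ellipse(cohort, visual_map).pearson_r:.2f}, "
                 f"$R^2$ = {fit.r_squared:.2f}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
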