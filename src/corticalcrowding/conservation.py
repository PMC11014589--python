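"""Conservation of crowding distance on retinotopic cortical maps.

The conservation hypothesis states that the number of letters lambda that
fit uncrowded into an observer's visual field is proportional to the
surface area A (mm²) of some retinotopic map:

    lambda = k * A,

with ``k`` (letters per mm²) a constant across observers.  Re-expressed as
``A = lambda * c**2``, the constant becomes the *cortical crowding
distance* ``c = k**(-1/2)`` (mm): the center-to-center letter spacing on
the cortical surface at the crowding threshold.

The fit is least squares through the origin of lambda on A; its variance
explained, R² = 1 - SS_res / SS_tot with SS_tot about the mean of lambda,
can be negative because the origin line is not nested in the mean-only
model.  Association strength is summarized symmetrically by Pearson's r
and by covariance ellipses in standardized coordinates.  All uncertainties
are percentile bootstrap intervals over observers, resampled pairwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

logger = logging.getLogger(__name__)

__all__ = [
    "MAPS",
    "ConservationRegressor",
    "ConservationFit",
    "AssociationStats",
    "fit_conservation",
    "variance_explained_origin",
    "cortical_crowding_distance",
    "cortical_letter_area",
    "pearson_correlation",
    "covariance_ellipse",
    "bootstrap_ci",
    "map_comparison_report",
    "observer_pair_summary",
]

MAPS = ("V1", "V2", "V3", "V4")

BOOTSTRAP_LEVELS = (68, 95)


class ConservationRegressor(RegressorMixin, BaseEstimator):
    """Least-squares regression through the origin, ``y = k * x``.

    scikit-learn estimator for the conservation fit: ``X`` is the map
    surface area (single feature, mm²) and ``y`` the per-observer letter
    count lambda.

    Attributes
    ----------
    k_ : float
        Fitted slope, letters per mm²: ``sum(x*y) / sum(x**2)``.
    c_ : float
        Cortical crowding distance ``k_**(-1/2)`` in mm (NaN if ``k_ <= 0``).
    r_squared_ : float
        Variance explained on the training data, relative to the mean of
        ``y``; may be negative.
    """

    def fit(self, X, y) -> "ConservationRegressor":
        X, y = check_X_y(X, y, ensure_min_samples=2)
        if X.shape[1] != 1:
            raise ValueError("ConservationRegressor expects a single feature (area)")
        x = X[:, 0]
        ssx = float(np.sum(x * x))
        if ssx == 0:
            raise ValueError("all areas are zero; slope is undefined")
        self.n_features_in_ = 1
        self.k_ = float(np.sum(x * y) / ssx)
        self.c_ = float(self.k_ ** -0.5) if self.k_ > 0 else float("nan")
        if np.ptp(y) == 0:  # degenerate cohort: slope defined, R² is not
            self.r_squared_ = float("nan")
        else:
            self.r_squared_ = variance_explained_origin(y, x, self.k_)
        return self

    def predict(self, X):
        check_is_fitted(self, "k_")
        X = check_array(X)
        return self.k_ * X[:, 0]


@dataclass(frozen=True)
class ConservationFit:
    """Result of the through-origin conservation fit for one map."""

    map: str
    k: float
    c: float
    r_squared: float
    n: int
    k_ci_68: tuple[float, float] | None = None
    k_ci_95: tuple[float, float] | None = None
    c_ci_68: tuple[float, float] | None = None
    c_ci_95: tuple[float, float] | None = None


@dataclass(frozen=True)
class AssociationStats:
    """Symmetric association summary: Pearson r and standardized ellipse.

    The ellipse lives in standardized coordinates (each variable divided by
    its SD); its semi-axes are ``n_sd * sqrt(1 +/- r)`` (eigenvalues of the
    correlation matrix) and its major axis lies on the +/-45 deg diagonal.
    An uncorrelated pair yields a circle.
    """

    map: str
    pearson_r: float
    ellipse_center: tuple[float, float]  # (mean area, mean lambda), raw units
    ellipse_axes: tuple[float, float]  # (major, minor) in standardized units
    ellipse_angle: float  # radians in standardized coordinates
    n_sd: float


def _cohort_arrays(cohort: pd.DataFrame, visual_map: str) -> tuple[np.ndarray, np.ndarray]:
    if visual_map not in cohort.columns:
        raise KeyError(f"cohort has no area column {visual_map!r}")
    lam = cohort["lambda"].to_numpy(dtype=float)
    area = cohort[visual_map].to_numpy(dtype=float)
    if np.any(lam <= 0) or np.any(area <= 0):
        raise ValueError("lambda and areas must be positive")
    return lam, area


def variance_explained_origin(lam, area, k: float) -> float:
    """R² of the origin line ``lambda = k*A`` relative to the mean of lambda.

    ``1 - sum((lam - k*A)**2) / sum((lam - mean(lam))**2)``; at most 1,
    unbounded below.
    """
    lam = np.asarray(lam, dtype=float)
    area = np.asarray(area, dtype=float)
    ss_tot = float(np.sum((lam - lam.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("lambda has zero variance; variance explained undefined")
    ss_res = float(np.sum((lam - k * area) ** 2))
    return 1.0 - ss_res / ss_tot


def cortical_crowding_distance(k: float) -> float:
    """Cortical crowding distance ``c = k**(-1/2)`` in mm for slope ``k`` > 0."""
    if not k > 0:
        raise ValueError(f"slope k must be > 0 to define a cortical distance, got {k}")
    return k ** -0.5


def cortical_letter_area(k: float) -> float:
    """Cortical area per uncrowded letter, ``1/k`` in mm² (k > 0)."""
    if not k > 0:
        raise ValueError(f"slope k must be > 0, got {k}")
    return 1.0 / k


def fit_conservation(
    cohort: pd.DataFrame,
    visual_map: str,
    n_boot: int | None = None,
    seed: int | None = None,
) -> ConservationFit:
    """Fit ``lambda = k * A`` through the origin for one map.

    ``cohort`` has one row per observer with a ``lambda`` column and one
    area column per map.  If ``n_boot`` is given, percentile bootstrap CIs
    (68% and 95%) for ``k`` and ``c`` are attached.
    """
    lam, area = _cohort_arrays(cohort, visual_map)
    reg = ConservationRegressor().fit(area[:, None], lam)
    cis: dict[str, tuple[float, float] | None] = {
        "k_ci_68": None, "k_ci_95": None, "c_ci_68": None, "c_ci_95": None,
    }
    if n_boot is not None:
        boot = bootstrap_ci(
            cohort, visual_map, statistic=("k", "c"), n_boot=n_boot, seed=seed
        )
        for stat in ("k", "c"):
            for level in BOOTSTRAP_LEVELS:
                cis[f"{stat}_ci_{level}"] = boot[stat][level]
    return ConservationFit(
        map=visual_map,
        k=reg.k_,
        c=reg.c_,
        r_squared=reg.r_squared_,
        n=len(lam),
        **cis,
    )


def pearson_correlation(cohort: pd.DataFrame, visual_map: str) -> float:
    """Pearson product-moment correlation between lambda and the map area."""
    lam, area = _cohort_arrays(cohort, visual_map)
    if len(lam) < 3:
        raise ValueError("Pearson correlation needs >= 3 observers")
    if np.std(lam) == 0 or np.std(area) == 0:
        raise ValueError("zero variance in lambda or area; correlation undefined")
    r, _ = stats.pearsonr(lam, area)
    return float(r)


def covariance_ellipse(
    cohort: pd.DataFrame, visual_map: str, n_sd: float = 1.0
) -> AssociationStats:
    """Covariance ellipse of (A, lambda) in standardized coordinates.

    Dividing each variable by its SD turns the covariance matrix into the
    correlation matrix [[1, r], [r, 1]], whose eigenvalues are 1 + r and
    1 - r with eigenvectors on the diagonals; the ellipse semi-axes are
    ``n_sd`` times the square roots of the eigenvalues.  r = 0 gives a
    circle; |r| = 1 collapses the minor axis.
    """
    r = pearson_correlation(cohort, visual_map)
    lam, area = _cohort_arrays(cohort, visual_map)
    major = n_sd * math.sqrt(1 + abs(r))
    minor = n_sd * math.sqrt(max(1 - abs(r), 0.0))
    angle = math.pi / 4 if r >= 0 else -math.pi / 4
    return AssociationStats(
        map=visual_map,
        pearson_r=r,
        ellipse_center=(float(area.mean()), float(lam.mean())),
        ellipse_axes=(major, minor),
        ellipse_angle=angle,
        n_sd=n_sd,
    )


def _bootstrap_samples(
    lam: np.ndarray, area: np.ndarray, n_boot: int, seed: int | None
) -> dict[str, np.ndarray]:
    """Vectorized observer-wise resampling of all four statistics.

    Each resample draws observers with replacement (lambda and area move
    together).  Degenerate resamples (zero variance) produce NaN for r/R²
    and are dropped by the percentile step with a logged count.
    """
    rng = np.random.default_rng(seed)
    n = len(lam)
    idx = rng.integers(0, n, size=(n_boot, n))
    L = lam[idx]
    A = area[idx]
    k = (A * L).sum(axis=1) / (A * A).sum(axis=1)
    with np.errstate(invalid="ignore"):
        c = np.where(k > 0, k ** -0.5, np.nan)
        dL = L - L.mean(axis=1, keepdims=True)
        dA = A - A.mean(axis=1, keepdims=True)
        ss_tot = (dL ** 2).sum(axis=1)
        r2 = 1.0 - ((L - k[:, None] * A) ** 2).sum(axis=1) / ss_tot
        denom = np.sqrt((dL ** 2).sum(axis=1) * (dA ** 2).sum(axis=1))
        r = (dL * dA).sum(axis=1) / denom
    return {"k": k, "c": c, "r": r, "r_squared": r2}


def bootstrap_ci(
    cohort: pd.DataFrame,
    visual_map: str,
    statistic: str | Sequence[str] = "k",
    n_boot: int = 10000,
    levels: Sequence[int] = BOOTSTRAP_LEVELS,
    seed: int | None = None,
) -> Mapping[str, Mapping[int, tuple[float, float]]]:
    """Percentile bootstrap CIs over observers for per-map statistics.

    Parameters
    ----------
    statistic : str or sequence of str
        Any of ``"k"``, ``"c"``, ``"r"``, ``"r_squared"``; all requested
        statistics share the same resamples (k is refit inside each).
    levels : sequence of int
        Coverage levels in percent; 68 maps to the 16th–84th percentiles,
        95 to the 2.5th–97.5th.

    Returns
    -------
    dict mapping statistic -> {level: (lo, hi)}.  Deterministic given seed.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    names = (statistic,) if isinstance(statistic, str) else tuple(statistic)
    for name in names:
        if name not in ("k", "c", "r", "r_squared"):
            raise ValueError(f"unknown statistic {name!r}")
    lam, area = _cohort_arrays(cohort, visual_map)
    samples = _bootstrap_samples(lam, area, n_boot, seed)
    out: dict[str, dict[int, tuple[float, float]]] = {}
    for name in names:
        vals = samples[name]
        n_bad = int(np.isnan(vals).sum())
        if n_bad:
            logger.warning(
                "%s: dropped %d/%d degenerate bootstrap resamples for %s",
                visual_map, n_bad, n_boot, name,
            )
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                raise ValueError(f"all bootstrap resamples degenerate for {name}")
        out[name] = {}
        for level in levels:
            half = (100 - level) / 2
            lo, hi = np.percentile(vals, [half, 100 - half])
            out[name][int(level)] = (float(lo), float(hi))
    return out


def map_comparison_report(
    cohort: pd.DataFrame,
    maps: Sequence[str] = MAPS,
    n_boot: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-map table of r, conservation k, c, R² and their bootstrap CIs.

    One row per map; the map with maximal R² under conservation is flagged
    in the boolean ``best_r_squared`` column.
    """
    rows = []
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in seed_seq.spawn(len(maps))]
    for visual_map, map_seed in zip(maps, child_seeds):
        fit = fit_conservation(cohort, visual_map, n_boot=n_boot, seed=map_seed)
        boot = bootstrap_ci(
            cohort, visual_map, statistic=("r", "r_squared"),
            n_boot=n_boot, seed=map_seed,
        )
        rows.append(
            {
                "map": visual_map,
                "n": fit.n,
                "r": pearson_correlation(cohort, visual_map),
                "r_squared": fit.r_squared,
                "k": fit.k,
                "c": fit.c,
                "k_ci_68": fit.k_ci_68,
                "k_ci_95": fit.k_ci_95,
                "c_ci_68": fit.c_ci_68,
                "c_ci_95": fit.c_ci_95,
                "r_ci_68": boot["r"][68],
                "r_ci_95": boot["r"][95],
                "r_squared_ci_68": boot["r_squared"][68],
                "r_squared_ci_95": boot["r_squared"][95],
            }
        )
    report = pd.DataFrame(rows).set_index("map")
    report["best_r_squared"] = report["r_squared"] == report["r_squared"].max()
    return report


def observer_pair_summary(cohort: pd.DataFrame, maps: Sequence[str] = MAPS) -> pd.DataFrame:
    """Side-by-side lambda and map areas for exactly two observers.

    Returns a table with one row per observer plus a ``ratio`` row
    (first / second, rounded to 1 decimal), mirroring the two-observer
    worked example format.
    """
    if len(cohort) != 2:
        raise ValueError(f"observer_pair_summary needs exactly 2 observers, got {len(cohort)}")
    cols = ["lambda", *maps]
    table = cohort.set_index("observer")[cols].astype(float)
    ratio = (table.iloc[0] / table.iloc[1]).round(1)
    ratio.name = "ratio"
    return pd.concat([table, ratio.to_frame().T])
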