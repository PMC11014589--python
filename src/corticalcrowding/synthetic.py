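"""Synthetic observers for end-to-end testing and parameter recovery.

The generator emulates the statistical structure the conservation analysis
assumes, so every downstream stage can be exercised without real data:

* inter-observer Bouma factors are lognormal (healthy adults span roughly a
  2-fold range of crowding distance);
* each of the 16 spacing thresholds (4 meridians x 2 eccentricities x 2
  sessions) is the Bouma-law prediction times lognormal measurement noise,
  with a multiplicative session-2 practice gain applied symmetrically in
  the log domain so the session-combined Bouma factor stays centered on the
  observer's true value;
* V4 surface area is tied to the observer's true letter count lambda by a
  true cortical crowding distance ``c_true`` (A = lambda * c_true**2, up to
  lognormal scatter of log-SD ``v4_area_log_noise_sd``), whereas V1-V3
  areas are lognormal and statistically independent of lambda;
* optionally, each threshold "measurement" is produced by a trial-level
  QUEST staircase simulation instead of being read off directly.

The joint (lambda, A_V4) distribution is generated "area-first": V4 area is
lognormal, and lambda is ``A/c_true**2`` times mean-one lognormal
conservation scatter; the true Bouma factor is then derived from lambda.
This places the conservation scatter in the *dependent* variable of the
through-origin regression of lambda on A, which makes ``1/c_true**2`` the
exact population slope and lets the fit explain a substantial share of the
lambda variance at a given correlation (noise placed in A instead would
attenuate the slope and cap the origin-line R² near zero at any
correlation, a joint pattern incompatible with real cohorts).  The marginal
distribution of the Bouma factor remains exactly lognormal with median
``b_median`` and log-SD ``b_log_sd``.  All generators are pure functions of
(params, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bouma import (
    DEFAULT_A,
    DEFAULT_PHI0,
    DEFAULT_PHI_MAX,
    BoumaLawParams,
    VisualFieldSpec,
    uncrowded_letter_count,
)
from .conservation import MAPS, fit_conservation, pearson_correlation, bootstrap_ci
from .psychophysics import MERIDIANS, ThresholdMeasurement, bouma_table

__all__ = [
    "ECCENTRICITIES",
    "PopulationParams",
    "QuestConfig",
    "QuestResult",
    "SyntheticObserver",
    "generate_population",
    "simulate_thresholds",
    "simulate_quest_run",
    "thresholds_frame",
    "areas_frame",
    "cohort_from_observers",
    "recovery_experiment",
]

#: Target eccentricities of the crowding measurements, deg.
ECCENTRICITIES = (5.0, 10.0)

SESSIONS = (1, 2)


def _default_v123() -> dict[str, float]:
    # medians on the order of the worked two-observer table (mm², bilateral,
    # restricted to 10 deg eccentricity)
    return {"V1": 2800.0, "V2": 2790.0, "V3": 1980.0}


@dataclass(frozen=True)
class PopulationParams:
    """Generative settings for a synthetic cohort.

    Defaults describe a cohort of 49 observers with a median Bouma factor
    of 0.27 and log-SD 0.17 (about a 2-fold inter-observer range), per-
    location multiplicative threshold noise of 0.10 log-units (which yields
    a between-session lambda reliability near r = 0.96), a 10% session-2
    improvement in lambda, a true cortical crowding distance of 1.36 mm,
    and V4 conservation scatter of 0.25 log-units (calibrated via the
    bivariate-lognormal moment formulas so the cohort lambda-vs-A_V4
    Pearson r lands near 0.65 and the origin-line variance explained near
    0.43).  ``v4_area_log_noise_sd`` may not exceed ``2 * b_log_sd``, the
    total log-SD of lambda.
    """

    n_observers: int = 49
    b_median: float = 0.27
    b_log_sd: float = 0.17
    threshold_noise_log_sd: float = 0.10
    session2_lambda_gain: float = 1.10
    c_true: float = 1.36  # mm
    v4_area_log_noise_sd: float = 0.25
    v123_area_medians: Mapping[str, float] = field(default_factory=_default_v123)
    v123_area_log_sd: float = 0.15
    seed: int = 0
    # field constants used to evaluate lambda(true_b) for the V4 area link;
    # keep identical to the analysis configuration
    phi0: float = DEFAULT_PHI0
    a: float = DEFAULT_A
    phi_max: float = DEFAULT_PHI_MAX

    def __post_init__(self) -> None:
        if self.n_observers < 2:
            raise ValueError("n_observers must be >= 2")
        for name in ("b_median", "session2_lambda_gain", "c_true"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("b_log_sd", "threshold_noise_log_sd", "v4_area_log_noise_sd",
                     "v123_area_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if set(self.v123_area_medians) != {"V1", "V2", "V3"}:
            raise ValueError("v123_area_medians must give medians for V1, V2, V3")
        if self.v4_area_log_noise_sd > 2 * self.b_log_sd:
            raise ValueError(
                "v4_area_log_noise_sd may not exceed 2*b_log_sd (the total "
                "log-SD of lambda): the conservation scatter cannot be larger "
                "than the lambda spread it lives in"
            )

    @property
    def k_true(self) -> float:
        """Population through-origin slope implied by ``c_true``, letters/mm²."""
        return self.c_true ** -2


@dataclass(frozen=True)
class QuestConfig:
    """Settings for the trial-level QUEST staircase simulator.

    The staircase maintains a posterior over log10 threshold spacing on a
    discrete grid, tests each trial at the posterior mode, and reports the
    posterior mean after ``n_trials`` trials.  The simulated observer
    answers through a Weibull psychometric function on log10 spacing with
    guess rate ``guess_rate`` (1/alphabet size), lapse ("finger error")
    rate ``lapse_rate`` and steepness ``slope``.  The slope and prior are
    conventional choices and deliberately configurable.
    """

    n_trials: int = 35
    guess_rate: float = 1.0 / 9.0
    lapse_rate: float = 0.01
    prior_mean_log10: float | None = None  # log10 deg; None = set by caller
    prior_sd_log10: float = 0.6
    slope: float = 2.3
    grid_step: float = 0.01
    grid_halfwidth: float = 2.0  # log10 units around the prior mean
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for name in ("guess_rate", "lapse_rate"):
            p = getattr(self, name)
            if not 0 <= p < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.grid_step <= 0 or self.grid_halfwidth <= 0:
            raise ValueError("degenerate posterior grid (step and halfwidth must be > 0)")
        if not self.slope > 0 or not self.prior_sd_log10 > 0:
            raise ValueError("slope and prior_sd_log10 must be > 0")


@dataclass(frozen=True)
class QuestResult:
    """Outcome of one simulated staircase run."""

    threshold_deg: float  # posterior-mean estimate, deg
    intensities_log10: np.ndarray
    responses: np.ndarray  # boolean, correct/incorrect


@dataclass(frozen=True)
class SyntheticObserver:
    """One simulated observer: ground truth plus simulated measurements."""

    observer: str
    true_b: float
    true_lambda: float
    true_areas: Mapping[str, float]  # mm² bilateral per map
    measurements: tuple[ThresholdMeasurement, ...]


def _weibull(x_minus_t, guess: float, lapse: float, slope: float):
    """P(correct) at log-spacing offset ``x - T`` from the true log threshold."""
    core = 1.0 - (1.0 - guess) * np.exp(-np.power(10.0, slope * np.asarray(x_minus_t)))
    return lapse * guess + (1.0 - lapse) * core


def simulate_quest_run(
    true_threshold: float,
    config: QuestConfig = QuestConfig(),
    rng: np.random.Generator | None = None,
) -> QuestResult:
    """Simulate one QUEST staircase measuring a spacing threshold.

    A Bayesian adaptive procedure: the posterior over log10 threshold starts
    as a Gaussian prior, each trial is placed at the current posterior mode,
    the simulated response is Bernoulli with the Weibull probability at the
    tested spacing, and the posterior is updated by Bayes' rule.  The final
    estimate is the posterior mean, returned in deg.  Deterministic given
    the seed (``config.seed`` or an explicit ``rng``).
    """
    if not true_threshold > 0:
        raise ValueError("true_threshold must be > 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    prior_mean = (
        math.log10(true_threshold)
        if config.prior_mean_log10 is None
        else config.prior_mean_log10
    )
    n_grid = int(round(2 * config.grid_halfwidth / config.grid_step)) + 1
    if n_grid < 3:
        raise ValueError("degenerate posterior grid: fewer than 3 points")
    grid = prior_mean + np.linspace(-config.grid_halfwidth, config.grid_halfwidth, n_grid)
    log_true = math.log10(true_threshold)

    posterior = np.exp(-0.5 * ((grid - prior_mean) / config.prior_sd_log10) ** 2)
    posterior /= posterior.sum()

    intensities = np.empty(config.n_trials)
    responses = np.empty(config.n_trials, dtype=bool)
    for trial in range(config.n_trials):
        x = grid[int(np.argmax(posterior))]
        p_correct = float(
            _weibull(x - log_true, config.guess_rate, config.lapse_rate, config.slope)
        )
        correct = bool(rng.random() < p_correct)
        like = _weibull(x - grid, config.guess_rate, config.lapse_rate, config.slope)
        posterior = posterior * (like if correct else (1.0 - like))
        total = posterior.sum()
        if total <= 0:  # numerically impossible data; reset to flat
            posterior = np.full(n_grid, 1.0 / n_grid)
        else:
            posterior = posterior / total
        intensities[trial] = x
        responses[trial] = correct

    estimate = float(10.0 ** np.dot(posterior, grid))
    return QuestResult(estimate, intensities, responses)


def simulate_thresholds(
    observer: str,
    true_b: float,
    params: PopulationParams,
    rng: np.random.Generator,
    quest: QuestConfig | None = None,
) -> tuple[ThresholdMeasurement, ...]:
    """Simulate the 16 spacing thresholds of one observer.

    Each threshold is ``true_b * ecc * exp(noise)`` (the eccentricity-
    proportional form matches the analysis convention of dividing by
    eccentricity) times a session gain factor: session 1 thresholds are
    multiplied and session 2 thresholds divided by ``gain**(1/4)``, so the
    session-2/session-1 lambda ratio is exactly ``session2_lambda_gain``
    (lambda scales as b**-2) while the session-combined Bouma factor stays
    centered on ``true_b``.  With ``quest`` given, each threshold is instead
    *estimated* by a simulated 35-trial staircase around that true value.
    """
    if not true_b > 0:
        raise ValueError("true_b must be > 0")
    g = params.session2_lambda_gain
    out = []
    for session in SESSIONS:
        gain_factor = g ** 0.25 if session == 1 else g ** -0.25
        for ecc in ECCENTRICITIES:
            for meridian in MERIDIANS:
                s_true = (
                    true_b
                    * ecc
                    * math.exp(rng.normal(0.0, params.threshold_noise_log_sd))
                    * gain_factor
                )
                if quest is not None:
                    cfg = replace(quest, prior_mean_log10=math.log10(0.25 * ecc))
                    s_meas = simulate_quest_run(s_true, cfg, rng=rng).threshold_deg
                else:
                    s_meas = s_true
                out.append(
                    ThresholdMeasurement(
                        observer=observer,
                        meridian=meridian,
                        eccentricity_deg=ecc,
                        session=session,
                        spacing_threshold_deg=s_meas,
                    )
                )
    return tuple(out)


def generate_population(
    params: PopulationParams, quest: QuestConfig | None = None
) -> list[SyntheticObserver]:
    """Generate a synthetic cohort; deterministic given ``params.seed``.

    V4 area is lognormal with median near ``lambda(b_median) * c_true**2``;
    the true letter count is ``A_V4 / c_true**2`` times mean-one lognormal
    conservation scatter (log-SD ``v4_area_log_noise_sd``), and the true
    Bouma factor follows from lambda.  The log-mean shifts (+/- half the
    scatter variance) keep both E[lambda | A] = A / c_true**2 (so
    ``1/c_true**2`` is the exact population slope) and the Bouma-factor
    median at ``b_median``.  V1-V3 areas are lognormal and independent of
    crowding.  Observer ids are ``S01, S02, ...``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_observers
    bouma = BoumaLawParams(b=1.0, phi0=params.phi0, a=params.a)
    field_spec = VisualFieldSpec(params.phi_max)
    lam_unit = uncrowded_letter_count(bouma, field_spec)  # lambda at b = 1

    lam_median = lam_unit / params.b_median ** 2
    sd_lam = 2.0 * params.b_log_sd  # total log-SD of lambda
    sd_eta = params.v4_area_log_noise_sd  # conservation scatter
    sd_area = math.sqrt(max(sd_lam ** 2 - sd_eta ** 2, 0.0))

    z_area = rng.normal(0.5 * sd_eta ** 2, sd_area, size=n) if sd_area > 0 \
        else np.full(n, 0.5 * sd_eta ** 2)
    eta = rng.normal(-0.5 * sd_eta ** 2, sd_eta, size=n) if sd_eta > 0 \
        else np.zeros(n)
    area_v4 = lam_median * params.c_true ** 2 * np.exp(z_area)
    true_lambda = area_v4 / params.c_true ** 2 * np.exp(eta)
    true_b = np.sqrt(lam_unit / true_lambda)
    areas_123 = {
        m: med * np.exp(rng.normal(0.0, params.v123_area_log_sd, size=n))
        for m, med in params.v123_area_medians.items()
    }

    width = max(2, len(str(n)))
    observers = []
    for i in range(n):
        name = f"S{i + 1:0{width}d}"
        areas = {m: float(areas_123[m][i]) for m in ("V1", "V2", "V3")}
        areas["V4"] = float(area_v4[i])
        observers.append(
            SyntheticObserver(
                observer=name,
                true_b=float(true_b[i]),
                true_lambda=float(true_lambda[i]),
                true_areas=areas,
                measurements=simulate_thresholds(name, float(true_b[i]), params, rng, quest),
            )
        )
    return observers


def thresholds_frame(observers: Sequence[SyntheticObserver]) -> pd.DataFrame:
    """Tidy threshold table (the format the psychophysics stage reads)."""
    rows = [
        {
            "observer": m.observer,
            "meridian": m.meridian,
            "eccentricity_deg": m.eccentricity_deg,
            "session": m.session,
            "spacing_threshold_deg": m.spacing_threshold_deg,
        }
        for obs in observers
        for m in obs.measurements
    ]
    return pd.DataFrame(rows)


def areas_frame(
    observers: Sequence[SyntheticObserver],
    hemisphere_sd: float = 0.03,
    seed: int | None = None,
) -> pd.DataFrame:
    """Long-format area table (observer, map, hemisphere, area_mm2).

    The bilateral true area is split into L and R hemispheres with a small
    random left fraction around 0.5 (SD ``hemisphere_sd``); the two
    hemisphere rows always sum exactly to the bilateral area.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for obs in observers:
        for m, area in obs.true_areas.items():
            frac = float(np.clip(rng.normal(0.5, hemisphere_sd), 0.3, 0.7))
            left = frac * area
            rows.append({"observer": obs.observer, "map": m, "hemisphere": "L",
                         "area_mm2": left})
            rows.append({"observer": obs.observer, "map": m, "hemisphere": "R",
                         "area_mm2": area - left})
    return pd.DataFrame(rows)


def cohort_from_observers(
    observers: Sequence[SyntheticObserver],
    phi0: float | None = None,
    a: float | None = None,
    phi_max: float | None = None,
    params: PopulationParams | None = None,
) -> pd.DataFrame:
    """Run the psychophysics stage on the simulated thresholds and join areas.

    Returns the analysis cohort: one row per observer with ``lambda`` (as
    measured through the pipeline) and the V1-V4 bilateral areas.
    """
    if params is not None:
        phi0 = params.phi0 if phi0 is None else phi0
        a = params.a if a is None else a
        phi_max = params.phi_max if phi_max is None else phi_max
    phi0 = DEFAULT_PHI0 if phi0 is None else phi0
    a = DEFAULT_A if a is None else a
    phi_max = DEFAULT_PHI_MAX if phi_max is None else phi_max

    per_obs = bouma_table(thresholds_frame(observers), phi0=phi0, a=a, phi_max=phi_max)
    areas = pd.DataFrame(
        [{"observer": o.observer, **o.true_areas} for o in observers]
    )
    return per_obs.merge(areas, on="observer", validate="one_to_one")


def recovery_experiment(
    params: PopulationParams,
    n_replicates: int = 100,
    use_quest: bool = False,
    quest: QuestConfig | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Repeated end-to-end parameter recovery on fresh synthetic cohorts.

    For each replicate: generate a cohort, push the simulated thresholds
    through the Bouma pipeline, fit conservation per map, and bootstrap the
    68% CI of the V4 cortical crowding distance.  Returns the per-replicate
    table (k, c, r, R² per map; CI bounds and coverage flag for c in V4)
    and a summary dict with the bias and SD of k and c in V4, per-map mean
    r and median R², and the empirical CI coverage of ``c_true``.
    """
    root = np.random.SeedSequence(params.seed if seed is None else seed)
    children = root.spawn(n_replicates)
    if use_quest and quest is None:
        quest = QuestConfig()
    rows = []
    for child in children:
        # independent streams for data generation and bootstrap resampling
        gen_child, boot_child = child.spawn(2)
        rep_seed = int(gen_child.generate_state(1)[0] % (2 ** 31))
        boot_seed = int(boot_child.generate_state(1)[0] % (2 ** 31))
        rep_params = replace(params, seed=rep_seed)
        observers = generate_population(rep_params, quest=quest if use_quest else None)
        cohort = cohort_from_observers(observers, params=rep_params)
        row: dict[str, float] = {"seed": rep_seed}
        for m in MAPS:
            fit = fit_conservation(cohort, m)
            row[f"k_{m}"] = fit.k
            row[f"c_{m}"] = fit.c
            row[f"r_{m}"] = pearson_correlation(cohort, m)
            row[f"r_squared_{m}"] = fit.r_squared
        ci = bootstrap_ci(cohort, "V4", statistic="c", n_boot=n_boot,
                          levels=(68,), seed=boot_seed)["c"][68]
        row["c_ci68_lo"], row["c_ci68_hi"] = ci
        row["c_covered"] = float(ci[0] <= params.c_true <= ci[1])
        rows.append(row)
    results = pd.DataFrame(rows)
    summary = {
        "n_replicates": n_replicates,
        "c_true": params.c_true,
        "k_true": params.k_true,
        "k_V4_bias": float(results["k_V4"].mean() - params.k_true),
        "k_V4_sd": float(results["k_V4"].std()),
        "c_V4_bias": float(results["c_V4"].mean() - params.c_true),
        "c_V4_sd": float(results["c_V4"].std()),
        "c_ci68_coverage": float(results["c_covered"].mean()),
        "mean_r": {m: float(results[f"r_{m}"].mean()) for m in MAPS},
        "median_r_squared": {m: float(results[f"r_squared_{m}"].median()) for m in MAPS},
    }
    return results, summary
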