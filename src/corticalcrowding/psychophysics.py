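"""From raw spacing thresholds to per-observer Bouma factors and letter counts.

The study design measures one crowding spacing threshold per combination of
4 cardinal meridians x 2 eccentricities (5, 10 deg) x 2 sessions, i.e. 16
thresholds per observer.  Each threshold is converted to a Bouma factor by
dividing by the target eccentricity (the small foveal offset phi0 is
deliberately omitted in this conversion, being negligible relative to the
eccentricities used); per-session factors are geometric means over the 8
locations, and the per-observer factor is the geometric mean over sessions.
Because thresholds are multiplicative quantities, every aggregation here is
geometric.  The per-observer letter count lambda is then evaluated from the
combined Bouma factor with the configured field constants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .bouma import (
    DEFAULT_A,
    DEFAULT_PHI0,
    DEFAULT_PHI_MAX,
    BoumaLawParams,
    VisualFieldSpec,
    uncrowded_letter_count,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MERIDIANS",
    "ThresholdMeasurement",
    "ObserverBouma",
    "TestRetestSummary",
    "bouma_from_threshold",
    "session_bouma",
    "observer_bouma",
    "BoumaCalculator",
    "bouma_table",
    "test_retest_correlation",
]

MERIDIANS = ("upper", "lower", "left", "right")

#: Expected number of visual-field locations per session (4 meridians x 2 ecc).
LOCATIONS_PER_SESSION = 8


@dataclass(frozen=True)
class ThresholdMeasurement:
    """One crowding spacing threshold at one visual-field location."""

    observer: str
    meridian: str
    eccentricity_deg: float
    session: int
    spacing_threshold_deg: float

    def __post_init__(self) -> None:
        if self.meridian not in MERIDIANS:
            raise ValueError(
                f"unknown meridian {self.meridian!r}; expected one of {MERIDIANS}"
            )
        if not self.eccentricity_deg > 0:
            raise ValueError("eccentricity must be > 0")
        if not self.spacing_threshold_deg > 0:
            raise ValueError("spacing threshold must be > 0")


@dataclass(frozen=True)
class ObserverBouma:
    """Per-observer crowding summary: session and combined Bouma factors, lambda."""

    observer: str
    session_bouma: Mapping[int, float]
    combined_bouma: float
    lambda_value: float


@dataclass(frozen=True)
class TestRetestSummary:
    """Between-session agreement of the per-observer letter count."""

    r: float
    session_ratio: float  # geometric-mean session2/session1 ratio
    n: int


def bouma_from_threshold(m: ThresholdMeasurement) -> float:
    """Bouma factor of one measurement: ``spacing_threshold / eccentricity``.

    The foveal offset phi0 is omitted here on purpose: at the eccentricities
    of the study (>= 2.5 deg effective) it changes the factor by at most a
    few percent, and this mirrors the asymmetric convention under which
    lambda is still computed with phi0 > 0.
    """
    return m.spacing_threshold_deg / m.eccentricity_deg


def _geomean(values: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(values))))


def session_bouma(bouma_factors: Sequence[float]) -> float:
    """Geometric mean of the per-location Bouma factors of one session."""
    values = np.asarray(list(bouma_factors), dtype=float)
    if values.size == 0:
        raise ValueError("session_bouma requires at least one location")
    if np.any(values <= 0):
        raise ValueError("Bouma factors must be positive")
    if values.size < LOCATIONS_PER_SESSION:
        logger.warning(
            "session has %d of %d expected locations; geometric mean over the "
            "available ones",
            values.size,
            LOCATIONS_PER_SESSION,
        )
    return _geomean(values)


def observer_bouma(
    observer: str,
    session_values: Mapping[int, float],
    phi0: float = DEFAULT_PHI0,
    a: float = DEFAULT_A,
    phi_max: float = DEFAULT_PHI_MAX,
) -> ObserverBouma:
    """Combine session Bouma factors and evaluate the observer's lambda."""
    if not 1 <= len(session_values) <= 2:
        raise ValueError("expected 1 or 2 session Bouma factors")
    combined = _geomean(np.array(list(session_values.values())))
    lam = uncrowded_letter_count(
        BoumaLawParams(b=combined, phi0=phi0, a=a), VisualFieldSpec(phi_max)
    )
    return ObserverBouma(
        observer=observer,
        session_bouma=dict(session_values),
        combined_bouma=combined,
        lambda_value=lam,
    )


class BoumaCalculator(TransformerMixin, BaseEstimator):
    """Transform a tidy threshold table into a per-observer Bouma/lambda table.

    Stateless transformer (``fit`` only validates): ``transform`` takes a
    DataFrame with columns ``observer, meridian, eccentricity_deg, session,
    spacing_threshold_deg`` and returns one row per observer with columns
    ``observer, b_session1, b_session2, b_combined, lambda_session1,
    lambda_session2, lambda`` (session columns are NaN when a session is
    absent).

    Parameters
    ----------
    phi0, a, phi_max : float
        Field constants used to evaluate lambda from the combined Bouma
        factor (phi0 is *not* used in the threshold->Bouma division).
    """

    def __init__(
        self,
        phi0: float = DEFAULT_PHI0,
        a: float = DEFAULT_A,
        phi_max: float = DEFAULT_PHI_MAX,
    ):
        self.phi0 = phi0
        self.a = a
        self.phi_max = phi_max

    _required = [
        "observer",
        "meridian",
        "eccentricity_deg",
        "session",
        "spacing_threshold_deg",
    ]

    def fit(self, X: pd.DataFrame, y=None) -> "BoumaCalculator":
        self._validate(X)
        self.n_features_in_ = X.shape[1]
        return self

    def _validate(self, X: pd.DataFrame) -> None:
        missing = [c for c in self._required if c not in X.columns]
        if missing:
            raise ValueError(f"threshold table is missing columns {missing}")
        bad = ~X["meridian"].isin(MERIDIANS)
        if bad.any():
            raise ValueError(
                f"unknown meridian values {sorted(X.loc[bad, 'meridian'].unique())}"
            )
        if (X["spacing_threshold_deg"] <= 0).any() or (X["eccentricity_deg"] <= 0).any():
            raise ValueError("thresholds and eccentricities must be positive")

    def _lambda(self, b: float) -> float:
        return uncrowded_letter_count(
            BoumaLawParams(b=b, phi0=self.phi0, a=self.a),
            VisualFieldSpec(self.phi_max),
        )

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._validate(X)
        df = X.copy()
        df["bouma"] = df["spacing_threshold_deg"] / df["eccentricity_deg"]
        per_session = (
            df.groupby(["observer", "session"])["bouma"]
            .apply(lambda v: session_bouma(v.to_numpy()))
            .unstack("session")
        )
        rows = []
        for observer, sess in per_session.iterrows():
            sess = sess.dropna()
            ob = observer_bouma(
                str(observer), sess.to_dict(), phi0=self.phi0, a=self.a,
                phi_max=self.phi_max,
            )
            row = {
                "observer": observer,
                "b_session1": sess.get(1, np.nan),
                "b_session2": sess.get(2, np.nan),
                "b_combined": ob.combined_bouma,
                "lambda_session1": self._lambda(sess[1]) if 1 in sess else np.nan,
                "lambda_session2": self._lambda(sess[2]) if 2 in sess else np.nan,
                "lambda": ob.lambda_value,
            }
            rows.append(row)
        out = pd.DataFrame(rows).sort_values("observer").reset_index(drop=True)
        logger.info("computed Bouma factors for %d observers", len(out))
        return out


def bouma_table(
    thresholds: pd.DataFrame,
    phi0: float = DEFAULT_PHI0,
    a: float = DEFAULT_A,
    phi_max: float = DEFAULT_PHI_MAX,
) -> pd.DataFrame:
    """Thin functional wrapper over :class:`BoumaCalculator`."""
    return BoumaCalculator(phi0=phi0, a=a, phi_max=phi_max).fit_transform(thresholds)


def test_retest_correlation(
    per_observer: pd.DataFrame, on: str = "lambda"
) -> TestRetestSummary:
    """Between-session Pearson correlation of the observer summaries.

    Parameters
    ----------
    per_observer : DataFrame
        Output of :func:`bouma_table`.
    on : {"lambda", "b"}
        Whether to correlate the per-session letter counts (the headline
        reliability measure) or the per-session Bouma factors (diagnostic).

    Returns the Pearson r across observers with both sessions, together with
    the geometric-mean session2/session1 ratio (the multiplicative session
    improvement) and the number of complete observers.
    """
    if on == "lambda":
        c1, c2 = "lambda_session1", "lambda_session2"
    elif on == "b":
        c1, c2 = "b_session1", "b_session2"
    else:
        raise ValueError("on must be 'lambda' or 'b'")
    both = per_observer[[c1, c2]].dropna()
    if len(both) < 3:
        raise ValueError(
            f"test-retest correlation needs >= 3 observers with both sessions, "
            f"got {len(both)}"
        )
    r, _ = stats.pearsonr(both[c1], both[c2])
    ratio = _geomean((both[c2] / both[c1]).to_numpy())
    return TestRetestSummary(r=float(r), session_ratio=ratio, n=len(both))
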