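"""Conservation fit, cortical crowding distance, ellipses, bootstrap."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from corticalcrowding.conservation import (
    ConservationRegressor,
    bootstrap_ci,
    cortical_crowding_distance,
    cortical_letter_area,
    covariance_ellipse,
    fit_conservation,
    map_comparison_report,
    observer_pair_summary,
    pearson_correlation,
    variance_explained_origin,
)
from tests.conftest import make_random_cohort


def cohort_of(lam, v4, **extra):
    data = {"observer": [f"S{i}" for i in range(len(lam))], "lambda": lam, "V4": v4}
    data.update(extra)
    return pd.DataFrame(data)


class TestOriginFit:
    def test_exact_line(self):
        area = np.array([100.0, 400.0, 900.0])
        fit = fit_conservation(cohort_of(0.5 * area, area), "V4")
        assert fit.k == pytest.approx(0.5)
        assert fit.c == pytest.approx(math.sqrt(2))
        assert fit.r_squared == pytest.approx(1.0)

    def test_duplicated_pair_forces_the_ratio(self):
        fit = fit_conservation(cohort_of([540.0] * 5, [1000.0] * 5), "V4")
        assert fit.k == pytest.approx(0.54)

    def test_matches_grid_search_oracle(self, random_cohort):
        fit = fit_conservation(random_cohort, "V4")
        lam = random_cohort["lambda"].to_numpy()
        area = random_cohort["V4"].to_numpy()
        grid = np.linspace(0.5 * fit.k, 1.5 * fit.k, 200001)
        sse = ((lam[None, :] - grid[:, None] * area[None, :]) ** 2).sum(axis=1)
        assert fit.k == pytest.approx(grid[np.argmin(sse)], abs=grid[1] - grid[0])

    def test_scale_equivariance(self, random_cohort):
        fit = fit_conservation(random_cohort, "V4")
        t = 3.7
        scaled = random_cohort.copy()
        scaled["lambda"] *= t
        fit_l = fit_conservation(scaled, "V4")
        assert fit_l.k == pytest.approx(t * fit.k, rel=1e-12)
        assert fit_l.c == pytest.approx(fit.c / math.sqrt(t), rel=1e-12)
        scaled = random_cohort.copy()
        scaled["V4"] *= t
        assert fit_conservation(scaled, "V4").k == pytest.approx(fit.k / t, rel=1e-12)

    def test_sklearn_estimator_contract(self, random_cohort):
        X = random_cohort[["V4"]].to_numpy()
        y = random_cohort["lambda"].to_numpy()
        reg = ConservationRegressor().fit(X, y)
        assert reg.predict(X) == pytest.approx(reg.k_ * X[:, 0])
        assert reg.score(X, y) == pytest.approx(reg.r_squared_)
        assert clone(reg).fit(X, y).k_ == reg.k_
        with pytest.raises(ValueError):
            ConservationRegressor().fit(np.zeros((3, 1)), y[:3])


class TestVarianceExplained:
    def test_exact_line_is_one(self):
        area = np.array([10.0, 20.0, 30.0])
        assert variance_explained_origin(2 * area, area, 2.0) == pytest.approx(1.0)

    def test_near_constant_lambda_goes_negative(self):
        lam = np.array([500.0, 500.1, 499.9, 500.05])
        area = np.array([100.0, 900.0, 400.0, 1600.0])
        k = float((area * lam).sum() / (area * area).sum())
        assert variance_explained_origin(lam, area, k) < 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            variance_explained_origin([5.0, 5.0], [1.0, 2.0], 1.0)

    def test_matches_direct_residual_arithmetic(self, random_cohort):
        lam = random_cohort["lambda"].to_numpy()
        area = random_cohort["V4"].to_numpy()
        k = 0.47
        expected = 1 - ((lam - k * area) ** 2).sum() / ((lam - lam.mean()) ** 2).sum()
        assert variance_explained_origin(lam, area, k) == pytest.approx(expected)


class TestCorticalDistance:
    @pytest.mark.parametrize("k, expected", [(0.54, 1.36), (1.0, 1.0), (0.25, 2.0)])
    def test_inverse_square_root(self, k, expected):
        assert cortical_crowding_distance(k) == pytest.approx(expected, abs=5e-3)

    def test_letter_area_is_reciprocal_slope(self):
        assert cortical_letter_area(0.5) == pytest.approx(2.0)

    @pytest.mark.parametrize("k", [0.0, -1.0])
    def test_nonpositive_slope_rejected(self, k):
        with pytest.raises(ValueError):
            cortical_crowding_distance(k)


class TestAssociation:
    def test_perfect_proportionality(self):
        area = np.array([100.0, 400.0, 900.0, 1600.0])
        assert pearson_correlation(cohort_of(0.5 * area, area), "V4") == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation(cohort_of([5.0, 5.0, 5.0], [1.0, 2.0, 3.0]), "V4")

    def test_matches_covariance_over_sd(self, random_cohort):
        lam = random_cohort["lambda"].to_numpy()
        area = random_cohort["V4"].to_numpy()
        expected = np.cov(lam, area)[0, 1] / (lam.std(ddof=1) * area.std(ddof=1))
        assert pearson_correlation(random_cohort, "V4") == pytest.approx(expected)

    def test_ellipse_axes_are_correlation_eigenvalues(self, random_cohort):
        stats = covariance_ellipse(random_cohort, "V4", n_sd=2)
        r = stats.pearson_r
        eigvals = np.linalg.eigvalsh(np.array([[1, r], [r, 1]]))
        assert stats.ellipse_axes[0] == pytest.approx(2 * math.sqrt(eigvals[1]))
        assert stats.ellipse_axes[1] == pytest.approx(2 * math.sqrt(eigvals[0]))

    def test_uncorrelated_pair_gives_circle(self):
        # constructed so that sum((lam-mean)*(area-mean)) is exactly 0
        lam = np.array([1.0, 2.0, 1.0, 2.0]) * 100
        area = np.array([1.0, 1.0, 2.0, 2.0]) * 1000
        stats = covariance_ellipse(cohort_of(lam, area), "V4")
        assert stats.pearson_r == pytest.approx(0.0, abs=1e-12)
        assert stats.ellipse_axes[0] == pytest.approx(stats.ellipse_axes[1])

    def test_perfect_correlation_collapses_minor_axis(self):
        area = np.array([100.0, 400.0, 900.0])
        stats = covariance_ellipse(cohort_of(0.3 * area + 5, area), "V4")
        assert stats.pearson_r == pytest.approx(1.0)
        assert stats.ellipse_axes[1] == pytest.approx(0.0, abs=1e-7)
        assert stats.ellipse_angle == pytest.approx(math.pi / 4)


class TestBootstrap:
    def test_identical_observers_give_zero_width(self):
        cohort = cohort_of([540.0] * 6, [1000.0] * 6)
        ci = bootstrap_ci(cohort, "V4", statistic="k", n_boot=500, seed=0)["k"]
        assert ci[68] == pytest.approx((0.54, 0.54))
        assert ci[95] == pytest.approx((0.54, 0.54))

    def test_deterministic_given_seed_and_stable_across_seeds(self, random_cohort):
        a = bootstrap_ci(random_cohort, "V4", statistic="k", n_boot=4000, seed=7)
        b = bootstrap_ci(random_cohort, "V4", statistic="k", n_boot=4000, seed=7)
        assert a["k"][68] == b["k"][68] and a["k"][95] == b["k"][95]
        c = bootstrap_ci(random_cohort, "V4", statistic="k", n_boot=20000, seed=8)
        d = bootstrap_ci(random_cohort, "V4", statistic="k", n_boot=20000, seed=9)
        width = c["k"][68][1] - c["k"][68][0]
        assert c["k"][68][0] == pytest.approx(d["k"][68][0], abs=0.05 * width)

    def test_ci_width_shrinks_as_inverse_sqrt_n(self):
        # average 68% CI width over replicate cohorts should scale ~ n**-0.5
        widths = {}
        for n in (25, 100):
            w = []
            for seed in range(25):
                cohort = make_random_cohort(seed=seed, n=n)
                ci = bootstrap_ci(cohort, "V4", statistic="k", n_boot=800,
                                  seed=seed + 1000)["k"][68]
                w.append(ci[1] - ci[0])
            widths[n] = np.mean(w)
        assert widths[25] / widths[100] == pytest.approx(2.0, rel=0.25)

    def test_unknown_statistic_rejected(self, random_cohort):
        with pytest.raises(ValueError, match="statistic"):
            bootstrap_ci(random_cohort, "V4", statistic="slope")


class TestReports:
    def test_conserved_map_has_maximal_association(self, default_cohort):
        report = map_comparison_report(default_cohort, n_boot=300, seed=0)
        assert report["r"].idxmax() == "V4"
        assert report["r_squared"].idxmax() == "V4"
        assert report.loc["V4", "best_r_squared"]

    def test_shuffling_lambda_destroys_conservation(self, default_cohort):
        rng = np.random.default_rng(0)
        shuffled = default_cohort.copy()
        shuffled["lambda"] = rng.permutation(shuffled["lambda"].to_numpy())
        report = map_comparison_report(shuffled, n_boot=300, seed=0)
        assert (report["r_squared"] <= 0.1).all()

    def test_two_observer_slope_lies_between_the_ratios(self, table2_cohort):
        fit = fit_conservation(table2_cohort, "V4")
        ratios = (table2_cohort["lambda"] / table2_cohort["V4"]).to_numpy()
        assert min(ratios) <= fit.k <= max(ratios)


class TestObserverPairSummary:
    def test_printed_two_observer_ratios(self, table2_cohort):
        table = observer_pair_summary(table2_cohort)
        ratio = table.loc["ratio"]
        assert ratio["lambda"] == pytest.approx(2.5)
        assert ratio["V1"] == pytest.approx(1.2)
        assert ratio["V2"] == pytest.approx(1.0)
        assert ratio["V3"] == pytest.approx(1.1)
        assert ratio["V4"] == pytest.approx(2.4)

    def test_identical_observers_give_unit_ratios(self, table2_cohort):
        twin = table2_cohort.copy()
        twin.loc[1, twin.columns != "observer"] = twin.loc[0, twin.columns != "observer"]
        assert (observer_pair_summary(twin).loc["ratio"] == 1.0).all()

    def test_requires_exactly_two(self, table2_cohort):
        with pytest.raises(ValueError):
            observer_pair_summary(table2_cohort.iloc[:1])
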