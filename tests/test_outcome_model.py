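"""Polynomial repeated-measures fits: recovery, R-squared, battery."""
import numpy as np
import pandas as pd
import pytest

from mhengage.ffmq import FFMQScore
from mhengage.outcome_model import (
    ModelSpec,
    assemble_long_table,
    fit_battery,
    fit_polynomial,
    marginal_r_squared,
)
from mhengage.synthetic_data import OutcomeConfig, PopulationConfig, generate_outcome_table


def _table(x, y, groups):
    return pd.DataFrame({
        "install_id": groups,
        "total": y,
        "active_minutes": x,
        "weeks_since_install": x,
        "n_visits": 1,
        "n_events": 1,
        "level_achieved": 1,
    })


def _score(install_id, ts, total=57, weeks=1.0):
    return FFMQScore(
        install_id=install_id, timestamp=ts,
        subscales={"observing": 12, "acting_with_awareness": 15,
                   "nonjudging": 15, "nonreactivity": 15},
        total=total, weeks_since_install=weeks,
    )


class TestAssemble:
    def _profiles(self, ids):
        return pd.DataFrame({
            "install_id": ids, "active_minutes": 10.0, "n_visits": 2,
            "n_events": 20, "level_achieved": 1,
        })

    def test_row_per_occasion(self):
        scores = [_score(u, t) for u in ("a", "b", "c") for t in (1000, 2000)]
        table = assemble_long_table(scores, self._profiles(["a", "b", "c"]))
        assert len(table) == 6
        assert set(table.columns) >= {"total", "Obs", "AA", "NJIE", "NRIE",
                                      "active_minutes", "weeks_since_install"}

    def test_orphan_scores_rejected(self):
        with pytest.raises(ValueError, match="ghost"):
            assemble_long_table([_score("ghost", 1)], self._profiles(["a"]))

    def test_predictor_totals_from_profiles(self):
        table = assemble_long_table([_score("a", 1)], self._profiles(["a", "b"]))
        assert table["active_minutes"].iloc[0] == 10.0


class TestFit:
    def test_noiseless_cubic_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, size=200)
        beta = np.array([2.0, 1.5, -0.4, 0.05])
        y = np.vander(x, 4, increasing=True) @ beta
        groups = [f"u{i}" for i in range(200)]  # single occasion each -> OLS path
        fit = fit_polynomial(_table(x, y, groups), ModelSpec(degree=3))
        assert fit.method == "ols"
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-8)

    def test_pure_noise_has_negligible_r_squared(self):
        rng = np.random.default_rng(1)
        n = 1000
        x = rng.uniform(0, 10, size=n)
        y = rng.normal(size=n)
        groups = np.repeat([f"u{i}" for i in range(n // 2)], 2)
        fit = fit_polynomial(_table(x, y, groups), ModelSpec(degree=3))
        assert fit.r_squared < 0.02
        assert (fit.term_pvalues[1:] > 0.01).any()

    def test_mixed_fit_recovers_slope_within_ci(self):
        rng = np.random.default_rng(2)
        n_users, beta1 = 500, 2.0
        u = rng.normal(0, 3, size=n_users)
        rows = []
        for i in range(n_users):
            for _ in range(2):
                x = rng.uniform(0, 5)
                rows.append((f"u{i}", x, 50 + beta1 * x + u[i] + rng.normal(0, 2)))
        ids, xs, ys = zip(*rows)
        fit = fit_polynomial(_table(np.array(xs), np.array(ys), list(ids)),
                             ModelSpec(degree=1))
        assert fit.method == "mixed"
        assert abs(fit.coefficients[1] - beta1) < 3 * fit.se[1]
        assert fit.random_intercept_var == pytest.approx(9.0, rel=0.5)

    def test_orthogonal_and_raw_basis_predictions_agree(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 4, size=150)
        y = 1 + x - 0.3 * x**2 + rng.normal(0, 0.5, size=150)
        groups = [f"u{i}" for i in range(150)]
        fit = fit_polynomial(_table(x, y, groups), ModelSpec(degree=2))
        raw = np.polynomial.polynomial.polyfit(x, y, 2)
        np.testing.assert_allclose(fit.coefficients, raw, rtol=1e-6)
        np.testing.assert_allclose(fit.predict(x),
                                   np.vander(x, 3, increasing=True) @ raw, rtol=1e-6)

    def test_r_squared_affine_invariant_in_predictor(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 10, size=300)
        y = 3 + 0.5 * x + rng.normal(0, 1, size=300)
        groups = [f"u{i}" for i in range(300)]
        f1 = fit_polynomial(_table(x, y, groups), ModelSpec(degree=1))
        f2 = fit_polynomial(_table(5 * x - 7, y, groups), ModelSpec(degree=1))
        assert f1.r_squared == pytest.approx(f2.r_squared, abs=1e-9)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_polynomial(_table(np.array([1.0, 1.0, 2.0]),
                                  np.array([1.0, 2.0, 3.0]), ["a", "b", "c"]),
                           ModelSpec(degree=3))

    def test_zero_outcome_variance_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="variance"):
            fit_polynomial(_table(x, np.ones(10), [f"u{i}" for i in range(10)]),
                           ModelSpec(degree=1))


class TestRSquared:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 3.0])
        assert marginal_r_squared(y, y) == pytest.approx(1.0)

    def test_intercept_only(self):
        assert marginal_r_squared(np.array([1.0, 2.0, 3.0]), np.full(3, 2.0)) == 0.0

    def test_known_marginal_r_squared_recovered(self):
        # y = x + e with var(x)=1, var(e)=3 -> R^2 = 0.25
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, size=5000)
        y = x + rng.normal(0, np.sqrt(3), size=5000)
        groups = [f"u{i}" for i in range(5000)]
        fit = fit_polynomial(_table(x, y, groups), ModelSpec(degree=1))
        assert fit.r_squared == pytest.approx(0.25, abs=0.03)


@pytest.fixture(scope="module")
def battery_table():
    t, _ = generate_outcome_table(PopulationConfig(n_users=600), seed=6)
    return t


class TestBattery:

    def test_full_grid_runs(self, battery_table):
        out = fit_battery(battery_table)
        ok = out[out["error"] == ""]
        assert (out["error"] == "").all()
        # 5 time models + 4 engagement models, degree 3 -> 4 rows each
        assert len(out) == 9 * 4
        assert set(ok["outcome"]) == {"total", "Obs", "AA", "NJIE", "NRIE"}

    def test_noiseless_cubic_battery_flags_cubic_term(self):
        x = np.linspace(0, 32, 300)
        y = 50 + 0.01 * x**3
        df = pd.DataFrame({
            "install_id": [f"u{i}" for i in range(300)],
            "total": y, "Obs": y / 5, "AA": y / 5, "NJIE": y / 5, "NRIE": y / 5,
            "weeks_since_install": x, "active_minutes": x, "n_visits": 2,
            "n_events": 4, "level_achieved": 1,
        })
        out = fit_battery(df, engagement_predictors=["active_minutes"])
        cubic = out[(out["term"] == 3) & (out["predictor"] == "weeks_since_install")]
        assert (cubic["p_value"] < 1e-6).all()

    def test_row_count_matches_grid(self, battery_table):
        out = fit_battery(battery_table, degree=1, time_outcomes=["total"],
                          engagement_predictors=["n_visits"])
        assert len(out) == 2 * 2
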