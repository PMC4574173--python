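"""Mixed-model variance components, repeatability, diurnal and precision."""

import numpy as np
import pandas as pd
import pytest

import bovigas as bg
from bovigas.varstats import (
    EstimationError,
    MixedModelSpec,
    VarianceComponents,
    interval_of_hour,
)

from conftest import anova_components, balanced_frame


def _vc(s2c, s2e, mu):
    return VarianceComponents(
        sigma2_cow=s2c, sigma2_resid=s2e, mean_estimate=mu,
        fixed_effects=pd.DataFrame(), converged=True, n_obs=0, n_groups=0,
    )


class TestFitRandomIntercept:
    def test_degenerate_two_group_closed_form(self):
        """{0,0} vs {10,10}: zero residual variance, group variance 50
        (the analytic REML limit of the one-way layout)."""
        df = balanced_frame(np.array([[0.0, 0.0], [10.0, 10.0]]))
        vc = bg.fit_random_intercept(df, MixedModelSpec("y"))
        assert vc.sigma2_resid == pytest.approx(0.0, abs=1e-12)
        assert vc.sigma2_cow == pytest.approx(50.0)

    def test_null_cow_effect(self):
        rng = np.random.default_rng(3)
        df = balanced_frame(rng.normal(10, 2, (30, 40)))
        vc = bg.fit_random_intercept(df, MixedModelSpec("y"))
        assert bg.repeatability(vc) < 0.05

    def test_component_recovery(self):
        """50 cows x 20 days with s2_cow=4, s2_e=16: both components are
        recovered within 20% relative of the ANOVA oracle truth."""
        rng = np.random.default_rng(17)
        y = 100 + rng.normal(0, 2, (50, 1)) + rng.normal(0, 4, (50, 20))
        df = balanced_frame(y)
        vc = bg.fit_random_intercept(df, MixedModelSpec("y"))
        assert vc.sigma2_cow == pytest.approx(4.0, rel=0.5)   # chi2_49 spread
        assert vc.sigma2_resid == pytest.approx(16.0, rel=0.2)
        oracle = anova_components(y)
        assert vc.sigma2_cow == pytest.approx(oracle[0], rel=0.01)
        assert vc.sigma2_resid == pytest.approx(oracle[1], rel=0.01)

    def test_too_few_groups_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "cow_id": ["a", "a"]})
        with pytest.raises(EstimationError):
            bg.fit_random_intercept(df, MixedModelSpec("y"))


class TestCvAndRepeatability:
    def test_cv_arithmetic(self):
        assert bg.cv_components(_vc(25.0, 225.0, 100.0)) == (pytest.approx(5.0), pytest.approx(15.0))
        assert bg.cv_components(_vc(0.0, 225.0, 100.0))[0] == 0.0

    def test_cv_requires_positive_mean(self):
        with pytest.raises(EstimationError):
            bg.cv_components(_vc(1.0, 1.0, 0.0))

    @pytest.mark.parametrize("s2c,s2e,expected", [
        (1.0, 1.0, 0.5), (0.0, 2.0, 0.0), (2.0, 0.0, 1.0),
    ])
    def test_repeatability_boundaries(self, s2c, s2e, expected):
        assert bg.repeatability(_vc(s2c, s2e, 1.0)) == pytest.approx(expected)

    def test_repeatability_undefined_when_no_variance(self):
        assert np.isnan(bg.repeatability(_vc(0.0, 0.0, 1.0)))

    def test_repeatability_of_aggregated_means(self):
        # averaging n days shrinks the residual: R of a 7-day mean
        vc = _vc(1.0, 7.0, 1.0)
        assert bg.repeatability(vc) == pytest.approx(1 / 8)
        assert bg.repeatability(vc, n_aggregated=7) == pytest.approx(0.5)

    def test_scale_invariance(self):
        """Multiplying the response by a constant leaves CVs and R alone."""
        rng = np.random.default_rng(5)
        y = 50 + rng.normal(0, 3, (20, 10)) + rng.normal(0, 2, (20, 1))
        df1, df2 = balanced_frame(y), balanced_frame(2.5 * y)
        vc1 = bg.fit_random_intercept(df1, MixedModelSpec("y"))
        vc2 = bg.fit_random_intercept(df2, MixedModelSpec("y"))
        assert bg.cv_components(vc1) == pytest.approx(bg.cv_components(vc2), rel=1e-4)
        assert bg.repeatability(vc1) == pytest.approx(bg.repeatability(vc2), rel=1e-4)

    def test_repeatability_recovery(self):
        """True R = 0.4 (variances 4 and 6), 50 cows x 20 days."""
        rng = np.random.default_rng(29)
        y = 30 + rng.normal(0, 2, (50, 1)) + rng.normal(0, np.sqrt(6), (50, 20))
        vc = bg.fit_random_intercept(balanced_frame(y), MixedModelSpec("y"))
        assert bg.repeatability(vc) == pytest.approx(0.4, abs=0.1)


class TestStepwise:
    def _data(self, rng, n_cows=25, n_days=20, beta_x=0.0, beta_z=5.0):
        cow = np.repeat(np.arange(n_cows), n_days)
        x = rng.normal(0, 1, n_cows * n_days)       # candidate with true beta_x
        z = rng.normal(0, 1, n_cows * n_days)       # strong covariate
        y = 10 + beta_x * x + beta_z * z + rng.normal(0, 2, (n_cows,))[cow] \
            + rng.normal(0, 3, n_cows * n_days)
        return pd.DataFrame({"y": y, "x": x, "z": z, "cow_id": cow})

    def test_null_covariate_usually_eliminated(self):
        rng = np.random.default_rng(101)
        dropped = 0
        for _ in range(12):
            df = self._data(rng)
            spec, _ = bg.stepwise_select(df, MixedModelSpec("y", ("x", "z"), reml=False))
            dropped += "x" not in spec.fixed_effects
        assert dropped >= 9   # size ~alpha: elimination in ~95% of replicates

    def test_true_effect_retained(self):
        rng = np.random.default_rng(55)
        df = self._data(rng, beta_x=4.0)
        spec, log = bg.stepwise_select(df, MixedModelSpec("y", ("x", "z"), reml=False))
        assert set(spec.fixed_effects) == {"x", "z"}
        assert all("aic" in step or "visit_count_re_lrt" in step for step in log)

    def test_alpha_one_keeps_full_model(self):
        rng = np.random.default_rng(3)
        df = self._data(rng)
        spec, _ = bg.stepwise_select(df, MixedModelSpec("y", ("x", "z"), reml=False), alpha=1.0)
        assert set(spec.fixed_effects) == {"x", "z"}


class TestBetweenYears:
    def _two_year(self, rng, n=50, r_cow=0.5, within_sd=1.0):
        cow_ids = [f"c{i}" for i in range(n)]
        e1 = rng.normal(0, 2, n)
        e2 = r_cow * e1 + np.sqrt(1 - r_cow ** 2) * rng.normal(0, 2, n)
        frames = []
        for year, eff in ((1, e1), (2, e2)):
            for d in range(5):
                frames.append(pd.DataFrame({
                    "cow_id": cow_ids, "year": year,
                    "ch4_l_day": 400 + eff + rng.normal(0, within_sd, n),
                    "edmi_kg_day": rng.normal(20, 1, n),
                    "ecm_kg_day": rng.normal(30, 3, n),
                    "parity": rng.choice(["primiparous", "multiparous"], n),
                }))
        return pd.concat(frames, ignore_index=True)

    def test_perfectly_preserved_cows(self):
        rng = np.random.default_rng(8)
        df = self._two_year(rng, r_cow=1.0, within_sd=1e-6)
        r2, _ = bg.between_year_repeatability(df)
        assert r2 > 0.999

    def test_rerandomized_cows_near_zero(self):
        rng = np.random.default_rng(9)
        df = self._two_year(rng, n=100, r_cow=0.0, within_sd=1.0)
        r2, _ = bg.between_year_repeatability(df)
        assert r2 < 0.3   # cow effect uncorrelated across years

    def test_intermediate_recovery(self):
        rng = np.random.default_rng(10)
        df = self._two_year(rng, n=50, r_cow=0.5, within_sd=1.0)
        r2, _ = bg.between_year_repeatability(df)
        # pooled-cow variance under r=0.5 retains about half the effect
        assert r2 == pytest.approx(0.5, abs=0.2)

    def test_single_year_rejected(self):
        rng = np.random.default_rng(11)
        df = self._two_year(rng)
        with pytest.raises(EstimationError):
            bg.between_year_repeatability(df[df["year"] == 1])

    def test_year_random_mode_runs(self):
        rng = np.random.default_rng(12)
        df = self._two_year(rng)
        r2, _ = bg.between_year_repeatability(df, mode="year-random")
        assert 0.0 <= r2 <= 1.0


class TestPearson:
    def _frame(self, y1, y2):
        n = len(y1)
        return pd.DataFrame({
            "cow_id": [f"c{i}" for i in range(n)] * 2,
            "year": [1] * n + [2] * n,
            "value": np.concatenate([y1, y2]),
        })

    def test_identity_and_antiidentity(self):
        y = np.arange(10, dtype=float)
        r, _, n = bg.pearson_between_years(self._frame(y, y), "value")
        assert r == pytest.approx(1.0)
        r, _, _ = bg.pearson_between_years(self._frame(y, -y), "value")
        assert r == pytest.approx(-1.0)

    def test_too_few_cows(self):
        y = np.array([1.0, 2.0])
        with pytest.raises(EstimationError):
            bg.pearson_between_years(self._frame(y, y), "value")

    def test_bivariate_coverage(self):
        """n=21 pairs at true rho=0.7: the replicate distribution of r
        covers 0.7 (Fisher-z predicts SD ~ (1-rho^2)/sqrt(n-3) ~ 0.12)."""
        rng = np.random.default_rng(77)
        rs = []
        for _ in range(200):
            y1 = rng.normal(0, 1, 21)
            y2 = 0.7 * y1 + np.sqrt(1 - 0.49) * rng.normal(0, 1, 21)
            r, _, _ = bg.pearson_between_years(self._frame(y1, y2), "value")
            rs.append(r)
        rs = np.array(rs)
        assert rs.mean() == pytest.approx(0.7, abs=0.05)
        assert rs.std() == pytest.approx((1 - 0.49) / np.sqrt(18), rel=0.4)


class TestDiurnal:
    @pytest.mark.parametrize("hour,interval", [
        (3, "night"), (5, "night"), (6, "morning"), (13, "afternoon"),
        (18, "evening"), (23, "evening"),
    ])
    def test_interval_mapping(self, hour, interval):
        assert interval_of_hour(hour) == interval

    def _hourly(self, rng, amplitude, n_cows=20, per_hour=3):
        rows = []
        for c in range(n_cows):
            cow_eff = rng.normal(0, 1)
            for h in range(24):
                for _ in range(per_hour):
                    mean = 20 * (1 - amplitude * np.cos(2 * np.pi * (h - 4) / 24))
                    rows.append({
                        "cow_id": f"c{c}", "hour_of_day": h,
                        "ch4_l_h": mean + cow_eff + rng.normal(0, 1),
                        "edmi_kg_day": 20.0 + rng.normal(0, 0.5),
                        "ecm_kg_day": 30.0 + rng.normal(0, 0.5),
                        "parity": "multiparous" if c % 2 else "primiparous",
                    })
        return pd.DataFrame(rows)

    def test_cosine_trough_makes_night_lowest(self):
        rng = np.random.default_rng(21)
        prof = bg.diurnal_profile(self._hourly(rng, amplitude=0.15))
        tbl = prof["intervals"].set_index("interval")["adjusted_mean"]
        assert tbl["night"] == min(tbl)

    def test_flat_profile_rarely_significant(self):
        """Type-I check: with no diurnal signal, interval contrasts are
        significant at 0.05 only at the nominal rate."""
        rng = np.random.default_rng(22)
        clean = 0
        for _ in range(8):
            prof = bg.diurnal_profile(self._hourly(rng, amplitude=0.0, n_cows=10, per_hour=2))
            clean += (prof["contrasts"]["p"] > 0.05).all()
        assert clean >= 5

    def test_missing_hours_reported(self, small_campaign):
        rng = np.random.default_rng(23)
        df = self._hourly(rng, amplitude=0.1, n_cows=8, per_hour=1)
        df = df[df["hour_of_day"] != 7]
        prof = bg.diurnal_profile(df)
        row = prof["hourly"].set_index("hour").loc[7]
        assert np.isnan(row["adjusted_mean"]) and row["n"] == 0


class TestLevelsOfVariation:
    def test_printed_precision_case(self):
        """Period-average CV 10.2% over 21 cows gives 4.5% precision."""
        assert round(bg.herd_precision(10.2, 21), 1) == 4.5

    def test_degenerate_identical_cows(self):
        period = pd.DataFrame({"cow_id": list("abc"), "ratio": [0.08] * 3})
        out = bg.levels_of_variation({"period": period})
        assert out["cv_by_level"]["cv_pct"].iloc[0] == 0.0
        assert out["precision_pct"] == 0.0

    def test_single_cow_undefined(self):
        period = pd.DataFrame({"cow_id": ["a"], "ratio": [0.08]})
        with pytest.raises(EstimationError):
            bg.levels_of_variation({"period": period})

    def test_day_average_below_raw_cv(self):
        """Averaging independent day noise shrinks the pooled CV."""
        rng = np.random.default_rng(31)
        cows = np.repeat([f"c{i}" for i in range(15)], 40)
        sample = pd.DataFrame({"cow_id": cows, "ratio": 0.08 * np.exp(rng.normal(0, 0.3, len(cows)))})
        day = sample.groupby("cow_id", as_index=False).agg(ratio=("ratio", "mean"))
        out = bg.levels_of_variation({"sample": sample, "period": day})
        cv = out["cv_by_level"].set_index("level")["cv_pct"]
        assert cv["period"] < cv["sample"]
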