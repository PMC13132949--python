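import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from bpcentile.errors import ConfigurationError, DataError, SingularityError
from bpcentile.reference_fit import (
    TAU_GRID,
    QuantileFitSet,
    SplineSpec,
    build_reference_table,
    compare_models,
    fit_linear,
    fit_quantile,
    fit_quantile_set,
    pinball_loss,
    spline_basis,
    spline_spec_from_data,
)
from bpcentile.synthetic import BPModel, GeneratorConfig, generate_cohort
from tests.conftest import mean_last_two


class TestFitLinear:
    def test_perfect_fit(self):
        x = np.arange(10.0)
        fit = fit_linear(2 * x, x)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_intercept_only_null_model(self):
        fit = fit_linear([1.0, 2.0, 3.0, 4.0], None)
        assert fit.r2 == 0.0
        assert fit.adj_r2 == 0.0
        assert fit.intercept == pytest.approx(2.5)

    def test_hand_solved_normal_equations(self):
        # (0,0), (1,1), (2,4): Sxy=4, Sxx=2 -> slope 2, intercept -1/3
        fit = fit_linear([0.0, 1.0, 4.0], pd.DataFrame({"x": [0.0, 1.0, 2.0]}))
        assert fit.coefficients["x"] == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(-1.0 / 3.0)

    def test_adj_r2_formula(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        fit = fit_linear(y, pd.DataFrame({"x": x}))
        expected = 1 - (1 - fit.r2) * 49 / 48
        assert fit.adj_r2 == pytest.approx(expected)
        assert fit.adj_r2 <= fit.r2

    def test_rank_deficient_names_columns(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(SingularityError) as err:
            fit_linear(x, X)
        assert "a" in str(err.value) and "b" in str(err.value)

    def test_missing_values_rejected(self):
        with pytest.raises(DataError):
            fit_linear([1.0, np.nan, 3.0, 4.0], pd.DataFrame({"x": [1.0, 2, 3, 4]}))


class TestSplineBasis:
    def _truncated_power_oracle(self, x, knots):
        """Independent construction: full truncated-power cubic basis with the
        two natural (linear-tail) constraints imposed via its null space."""
        k1, k2, k3 = knots
        def p3(v):
            return np.clip(v, 0, None) ** 3
        # cubic-tail coefficients of [x^3, (x-k1)+^3, (x-k2)+^3, (x-k3)+^3]
        # must cancel beyond k3: sum d_i = 0 and sum d_i * k_i = 0 for the
        # truncated terms (x^3 excluded entirely for natural splines)
        A = np.array([[1.0, 1.0, 1.0], [k1, k2, k3]])
        ns = np.linalg.svd(A)[2][-1]  # 1-D null space
        col = ns[0] * p3(x - k1) + ns[1] * p3(x - k2) + ns[2] * p3(x - k3)
        return np.column_stack([x, col])

    def test_second_differences_continuous_at_knots(self):
        spec = SplineSpec("x", (1.0, 2.0, 4.0))
        x = np.linspace(0, 6, 6001)
        basis = spline_basis(x, spec)[:, 1]
        d2 = np.diff(basis, 2)
        assert np.max(np.abs(np.diff(d2))) < 1e-6  # third difference bounded

    def test_linear_beyond_boundary_knots(self):
        spec = SplineSpec("x", (1.0, 2.0, 4.0))
        for x0 in (5.0, -1.0):
            x = np.array([x0, x0 + 0.5, x0 + 1.0])
            col = spline_basis(x, spec)[:, 1]
            assert col[2] - col[1] == pytest.approx(col[1] - col[0], abs=1e-9)

    def test_agrees_with_truncated_power_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 10, 50)
        knots = (2.0, 5.0, 8.0)
        spec = SplineSpec("x", knots)
        y = np.sin(x) + rng.normal(size=50)

        # same column space -> identical least-squares fitted values
        def fitted(basis):
            design = np.column_stack([np.ones(50), basis])
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            return design @ beta

        np.testing.assert_allclose(
            fitted(spline_basis(x, spec)),
            fitted(self._truncated_power_oracle(x, knots)),
            atol=1e-8,
        )

    def test_knots_at_quartiles(self):
        x = np.arange(101.0)
        spec = spline_spec_from_data(x)
        assert spec.knots == (25.0, 50.0, 75.0)

    def test_degenerate_input(self):
        with pytest.raises(DataError):
            spline_spec_from_data([1.0, 1.0, 2.0, 2.0])

    def test_knots_must_increase(self):
        with pytest.raises(ConfigurationError):
            SplineSpec("x", (1.0, 1.0, 2.0))


class TestFitQuantile:
    def test_intercept_only_median(self):
        b0, coefs = fit_quantile([1.0, 2.0, 3.0, 4.0, 5.0], None, 0.5)
        assert b0 == pytest.approx(3.0)
        assert coefs == {}

    def test_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=10)
        b0, _ = fit_quantile(y, None, 0.2)
        grid = np.linspace(y.min() - 1, y.max() + 1, 40001)
        best = min(pinball_loss(y, g, 0.2) for g in grid)
        assert pinball_loss(y, b0, 0.2) <= best + 1e-9

    def test_translation_equivariance(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 10, 40)
        y = 2 * x + rng.normal(size=40)
        X = pd.DataFrame({"x": x})
        b0, c = fit_quantile(y, X, 0.3)
        b0s, cs = fit_quantile(y + 7.0, X, 0.3)
        assert b0s == pytest.approx(b0 + 7.0, abs=1e-6)
        assert cs["x"] == pytest.approx(c["x"], abs=1e-6)

    def test_invalid_tau(self):
        with pytest.raises(ConfigurationError):
            fit_quantile([1.0, 2.0, 3.0], None, 1.2)

    def test_median_matches_ols_under_symmetric_noise(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(4, 16, 5000)
        y = 90 + 1.5 * x + rng.normal(0, 5, 5000)
        X = pd.DataFrame({"age": x})
        b0_q, cq = fit_quantile(y, X, 0.5)
        ols = fit_linear(y, X)
        assert b0_q == pytest.approx(ols.intercept, abs=0.8)
        assert cq["age"] == pytest.approx(ols.coefficients["age"], abs=0.08)


class TestQuantileFitSet:
    def test_grid_enforced(self):
        with pytest.raises(ConfigurationError):
            QuantileFitSet("sbp", "F", taus=(0.1, 0.5, 0.9),
                           intercepts=(1, 2, 3), age_slopes=(0, 0, 0))

    def test_round_trip_json(self):
        fs = QuantileFitSet("sbp", "F", intercepts=tuple(range(19)),
                            age_slopes=(0.5,) * 19, n=100)
        assert QuantileFitSet.from_dict(fs.to_dict()) == fs

    def test_slope_recovery_tracks_tau(self):
        # per-tau age slope converges to slope + z_tau * sd_slope
        model = BPModel(intercept=90, age_slope=1.5, sd_intercept=2.0, sd_slope=0.3)
        cfg = GeneratorConfig(n_children=12000, seed=17, within_visit_sd=0.0,
                              sbp_model={"F": model, "M": model})
        df = generate_cohort(cfg)
        fs = fit_quantile_set(df["age_years"], mean_last_two(df, "sbp"), "sbp", "F")
        for tau in (0.05, 0.5, 0.95):
            i = list(TAU_GRID).index(tau)
            expected = 1.5 + norm.ppf(tau) * 0.3
            assert fs.age_slopes[i] == pytest.approx(expected, abs=0.12)


class TestBuildReferenceTable:
    def _const_fit(self, value=100.0):
        return QuantileFitSet("sbp", "F", intercepts=(value,) * 19,
                              age_slopes=(0.0,) * 19)

    def test_degenerate_fit_constant_table(self):
        table = build_reference_table([self._const_fit()], range(4, 16), (50, 90, 95))
        assert (table["value_mmhg"] == 100).all()

    def test_rearrangement_makes_columns_monotone(self):
        # deliberately crossing quantiles: decreasing intercepts across tau
        fit = QuantileFitSet("sbp", "F", intercepts=tuple(118.0 - i for i in range(19)),
                             age_slopes=(0.0,) * 19)
        table = build_reference_table([fit], [10], tuple(range(5, 100, 5)))
        vals = table.sort_values("percentile")["value_mmhg"].to_numpy()
        assert (np.diff(vals) >= 0).all()

    def test_off_grid_percentile_rejected(self):
        with pytest.raises(ConfigurationError):
            build_reference_table([self._const_fit()], [10], (50, 92))

    def test_rounding_half_away_from_zero(self):
        fit = QuantileFitSet("sbp", "F", intercepts=(100.5,) * 19, age_slopes=(0.0,) * 19)
        table = build_reference_table([fit], [10], (50,))
        assert table["value_mmhg"].iloc[0] == 101

    def test_gaussian_recovery_at_single_age(self):
        model = BPModel(intercept=90, age_slope=1.5, sd_intercept=2.0, sd_slope=0.3)
        cfg = GeneratorConfig(n_children=8000, seed=29, within_visit_sd=0.0,
                              sbp_model={"F": model, "M": model})
        df = generate_cohort(cfg)
        fs = fit_quantile_set(df["age_years"], mean_last_two(df, "sbp"), "sbp", "F")
        table = build_reference_table([fs], [10], (95,))
        assert table["value_mmhg"].iloc[0] == pytest.approx(113.0, abs=1.0)


class TestCompareModels:
    def _prepared(self, n, seed, height_coef):
        model_kwargs = dict(intercept=90, age_slope=1.5, sd_intercept=4.0, sd_slope=0.3)
        sbp = {s: BPModel(height_coef=height_coef, **model_kwargs) for s in ("F", "M")}
        cfg = GeneratorConfig(n_children=n, seed=seed, within_visit_sd=0.0, sbp_model=sbp)
        df = generate_cohort(cfg)
        from bpcentile.prep import zscore_from_table
        from bpcentile.synthetic import make_growth_reference
        growth = make_growth_reference(cfg, "height")
        df["height_z"] = [
            zscore_from_table(h, a, s, growth)
            for h, a, s in zip(df["height_cm"], df["age_years"], df["sex"])
        ]
        df["mean_sbp"] = mean_last_two(df, "sbp")
        df["mean_dbp"] = mean_last_two(df, "dbp")
        return df

    def test_zero_height_effect_limit(self):
        df = self._prepared(3000, 31, height_coef=0.0)
        rep = compare_models(df)
        assert rep["height_gap_mmhg"]["sbp"]["mean_abs"] < 0.6
        assert rep["detection"]["detection_fraction_pct"] >= 97.0

    def test_known_height_effect_recovered(self):
        b = 3.0
        df = self._prepared(6000, 37, height_coef=b)
        rep = compare_models(df)
        expected = b * norm.ppf(0.95)  # gap between median and 5th/95th height z
        assert rep["height_gap_mmhg"]["sbp"]["mean_abs"] == pytest.approx(expected, rel=0.15)

    def test_missing_height_errors_with_ids(self):
        df = self._prepared(100, 41, height_coef=0.0)
        df.loc[df.index[3], "height_z"] = np.nan
        with pytest.raises(DataError) as err:
            compare_models(df)
        assert df["id"].iloc[3] in str(err.value)


class TestPrintedTableStructure:
    """Structural sanity of the packaged printed reference table."""

    def test_monotone_within_age_and_sex(self, danish_lookup):
        for outcome in ("sbp", "dbp"):
            for sex in ("F", "M"):
                for age, row in danish_lookup.values[outcome][sex].items():
                    assert row[50] <= row[90] <= row[95], (outcome, sex, age)

    def test_systolic_95th_nondecreasing_in_age(self, danish_lookup):
        for sex in ("F", "M"):
            by_age = danish_lookup.values["sbp"][sex]
            vals = [by_age[a][95] for a in sorted(by_age)]
            assert vals == sorted(vals)
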