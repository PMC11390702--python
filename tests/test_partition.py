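"""Mixed-effects model, VIF diagnostics, and hierarchical partitioning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mdephen import (
    ClimateRecord,
    ModelFrame,
    RichnessCurve,
    TemporalDomain,
    assemble_frame,
    compute_vif,
    fit_lmm,
    hierarchical_partition,
    simulate_mde,
)


def _frame(df: pd.DataFrame, predictors) -> ModelFrame:
    return ModelFrame(df, predictors=tuple(predictors))


def _orthogonal_frame() -> ModelFrame:
    # exactly orthogonal unit-variance predictors, y = 2 x1 + x2, no noise
    x1 = np.array([1.0, -1.0, 1.0, -1.0] * 10)
    x2 = np.array([1.0, 1.0, -1.0, -1.0] * 10)
    y = 2 * x1 + x2
    df = pd.DataFrame(
        {"region": ["a"] * 20 + ["b"] * 20, "log_richness": y, "x1": x1, "x2": x2}
    )
    return _frame(df, ("x1", "x2"))


class TestAssembleFrame:
    @pytest.fixture
    def inputs(self):
        domain = TemporalDomain(4, 9)
        richness, predictions, climate = {}, {}, []
        for region in ("ra", "rb"):
            richness[region] = RichnessCurve(domain, (0, 2, 5, 6, 3, 1))
            predictions[region] = simulate_mde([2, 3, 4], 6, n_reps=50, seed=1, domain=domain)
            for m in range(1, 13):
                climate.append(ClimateRecord(region, m, t_min=float(m), mmp=10.0 * m, sunshine=100.0 + m))
        return richness, predictions, climate

    def test_row_count_is_regions_times_domain_months(self, inputs):
        frame = assemble_frame(*inputs)
        assert frame.n_obs == 12
        assert frame.n_groups == 2

    def test_zero_count_with_unit_offset_gives_zero_response(self, inputs):
        frame = assemble_frame(*inputs, offset=1.0)
        row = frame.data[(frame.data.region == "ra") & (frame.data.month == 4)]
        assert row.log_richness.iloc[0] == pytest.approx(0.0)

    def test_zero_offset_with_zero_count_rejected(self, inputs):
        with pytest.raises(ValueError, match="nonpositive value under log"):
            assemble_frame(*inputs, offset=0.0)

    def test_missing_climate_month_lists_gaps(self, inputs):
        richness, predictions, climate = inputs
        short = [c for c in climate if not (c.region_id == "rb" and c.month == 5)]
        with pytest.raises(ValueError, match=r"\('rb', 5\)"):
            assemble_frame(richness, predictions, short)


class TestFitLmm:
    def test_collapses_to_ols_when_group_variance_is_zero(self):
        # seed chosen so REML lands on the zero-variance boundary
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        z = rng.normal(size=200)
        y = 1.0 + 0.5 * x - 0.3 * z + rng.normal(0, 0.4, 200)
        df = pd.DataFrame({"region": ["a", "b", "c", "d"] * 50, "log_richness": y, "x1": x, "x2": z})
        res = fit_lmm(_frame(df, ("x1", "x2")))
        assert res.var_region == pytest.approx(0.0, abs=1e-8)
        import statsmodels.api as sm

        ols = sm.OLS(y, sm.add_constant(np.column_stack([x, z]))).fit()
        for est, ref in zip(res.params.values(), ols.params):
            assert est == pytest.approx(ref, abs=1e-6)

    def test_exact_response_caps_t(self):
        frame = _orthogonal_frame()
        res = fit_lmm(frame)
        assert res.t["x1"] == pytest.approx(1e6)
        assert res.p["x1"] == pytest.approx(0.0, abs=1e-100)
        assert res.singular

    def test_recovers_region_intercept_variance(self):
        rng = np.random.default_rng(5)
        regions = [f"r{i}" for i in range(20)]
        rows = []
        effects = rng.normal(0, 1.0, len(regions))
        for region, u in zip(regions, effects):
            x = rng.normal(size=10)
            y = 2.0 + 1.5 * x + u + rng.normal(0, 0.3, 10)
            for xi, yi in zip(x, y):
                rows.append({"region": region, "log_richness": yi, "x1": xi})
        res = fit_lmm(_frame(pd.DataFrame(rows), ("x1",)))
        assert res.params["x1"] == pytest.approx(1.5, abs=0.1)
        assert 0.3 < res.var_region < 3.0
        assert res.var_resid == pytest.approx(0.09, rel=0.5)

    def test_parameter_recovery_coverage(self):
        # known coefficients; the 95% Wald CI should cover each in >= 90% of fits
        betas = {"x1": 0.8, "x2": -0.5}
        n_regions, n_months = 27, 7
        hits = {k: 0 for k in betas}
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            rows = []
            for r in range(n_regions):
                u = rng.normal(0, 0.4)
                x1 = rng.normal(size=n_months)
                x2 = rng.normal(size=n_months)
                y = 1.0 + betas["x1"] * x1 + betas["x2"] * x2 + u + rng.normal(0, 0.5, n_months)
                for i in range(n_months):
                    rows.append(
                        {"region": f"r{r}", "log_richness": y[i], "x1": x1[i], "x2": x2[i]}
                    )
            res = fit_lmm(_frame(pd.DataFrame(rows), ("x1", "x2")))
            tcrit = stats.t.ppf(0.975, res.df_resid)
            for k, b in betas.items():
                if abs(res.params[k] - b) <= tcrit * res.se[k]:
                    hits[k] += 1
        for k in betas:
            assert hits[k] >= 0.90 * n_rep

    def test_rank_deficient_design_rejected(self):
        frame = _orthogonal_frame()
        df = frame.data.copy()
        df["x3"] = df["x1"]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_lmm(_frame(df, ("x1", "x2", "x3")))


class TestVif:
    def test_orthogonal_predictors(self):
        vif = compute_vif(_orthogonal_frame())
        assert vif["x1"] == pytest.approx(1.0)
        assert vif["x2"] == pytest.approx(1.0)

    def test_correlation_half_gives_four_thirds(self):
        # population correlation exactly 0.5 by construction
        x1 = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        e = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0])
        x2 = 0.5 * x1 + (np.sqrt(3) / 2) * e
        df = pd.DataFrame(
            {"region": ["a"] * 4 + ["b"] * 4, "log_richness": np.arange(8.0), "x1": x1, "x2": x2}
        )
        vif = compute_vif(_frame(df, ("x1", "x2")))
        assert vif["x1"] == pytest.approx(4 / 3)
        assert vif["x2"] == pytest.approx(4 / 3)

    def test_near_duplicate_blows_up(self):
        rng = np.random.default_rng(3)
        x1 = rng.normal(size=200)
        x2 = x1 + rng.normal(0, 0.02, 200)
        df = pd.DataFrame(
            {"region": ["a", "b"] * 100, "log_richness": rng.normal(size=200), "x1": x1, "x2": x2}
        )
        vif = compute_vif(_frame(df, ("x1", "x2")))
        assert vif["x1"] > 100

    def test_perfect_collinearity_rejected(self):
        frame = _orthogonal_frame()
        df = frame.data.copy()
        df["x2"] = 2.0 * df["x1"]
        with pytest.raises(ValueError, match="infinite VIF"):
            compute_vif(_frame(df, ("x1", "x2")))


class TestHierarchicalPartition:
    def test_single_predictor_gets_everything(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        y = x + rng.normal(0, 0.5, 60)
        df = pd.DataFrame({"region": ["a", "b", "c"] * 20, "log_richness": y, "x1": x})
        res = hierarchical_partition(_frame(df, ("x1",)))
        assert res.i_perc["x1"] == pytest.approx(100.0)

    def test_orthogonal_variance_shares(self):
        # variances 4:1 -> contributions (80, 20)
        res = hierarchical_partition(_orthogonal_frame())
        assert res.i_perc["x1"] == pytest.approx(80.0, abs=0.5)
        assert res.i_perc["x2"] == pytest.approx(20.0, abs=0.5)

    def test_duplicated_predictors_split_evenly(self):
        frame = _orthogonal_frame()
        df = frame.data.copy()
        df["x2"] = df["x1"]
        res = hierarchical_partition(_frame(df, ("x1", "x2")))
        assert res.i_perc["x1"] == pytest.approx(50.0)
        assert res.i_perc["x2"] == pytest.approx(50.0)

    def test_contributions_sum_to_marginal_r2(self):
        rng = np.random.default_rng(11)
        n = 120
        x1 = rng.normal(size=n)
        x2 = 0.6 * x1 + rng.normal(0, 0.8, n)
        x3 = rng.normal(size=n)
        y = 1.0 + x1 + 0.5 * x2 - 0.7 * x3 + rng.normal(0, 1.0, n)
        df = pd.DataFrame(
            {"region": ["a", "b", "c", "d"] * 30, "log_richness": y, "x1": x1, "x2": x2, "x3": x3}
        )
        res = hierarchical_partition(_frame(df, ("x1", "x2", "x3")))
        assert sum(res.contributions.values()) == pytest.approx(res.marginal_r2, abs=1e-8)

    def test_orthogonal_contributions_equal_single_increments(self):
        res = hierarchical_partition(_orthogonal_frame())
        from mdephen.partition import _subset_r2

        frame = _orthogonal_frame()
        # increments are order-independent up to the REML residual-variance
        # denominator (n-p vs n), so agreement is close but not exact
        for p in ("x1", "x2"):
            single = _subset_r2(frame, (p,), conditional=False)
            assert res.contributions[p] == pytest.approx(single, abs=0.01)

    def test_invariance_to_order_and_scale(self):
        rng = np.random.default_rng(21)
        n = 80
        x1 = rng.normal(size=n)
        x2 = 0.4 * x1 + rng.normal(0, 1.0, n)
        y = x1 + x2 + rng.normal(0, 0.8, n)
        df = pd.DataFrame({"region": ["a", "b"] * 40, "log_richness": y, "x1": x1, "x2": x2})
        a = hierarchical_partition(_frame(df, ("x1", "x2")))
        b = hierarchical_partition(_frame(df, ("x2", "x1")))
        assert a.i_perc["x1"] == pytest.approx(b.i_perc["x1"], abs=1e-6)
        df_scaled = df.copy()
        df_scaled["x1"] = 5.0 * df_scaled["x1"] - 2.0
        c = hierarchical_partition(_frame(df_scaled, ("x1", "x2")))
        assert c.i_perc["x1"] == pytest.approx(a.i_perc["x1"], abs=1e-4)

    def test_too_many_predictors_rejected(self):
        frame = _orthogonal_frame()
        df = frame.data.copy()
        for i in range(3, 10):
            df[f"x{i}"] = np.random.default_rng(i).normal(size=len(df))
        with pytest.raises(ValueError, match="limit is 6"):
            hierarchical_partition(_frame(df, tuple(f"x{i}" for i in range(1, 8))))
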