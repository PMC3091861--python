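import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_panel
from dynacyt import (
    SyntheticConfig,
    anova_two_way,
    baseline_altered_set,
    correlation_matrix,
    games_howell,
    generate_panel,
    levene_test,
    percent_modulated,
    pooled_t_test,
    t_difference_table,
    t_from_summary,
    trend_model_fit,
)
from dynacyt.errors import AnalysisError


class TestPooledT:
    def test_identical_groups(self):
        res = pooled_t_test([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 and res.p == 1.0

    def test_df_is_ten_for_six_per_group(self):
        res = pooled_t_test(np.arange(6), np.arange(6) + 1.0)
        assert res.df == 10

    def test_hand_computed_example(self):
        # pooled formula worked by hand for a fixed pair of samples
        a = np.array([4.0, 6.0, 8.0])
        b = np.array([9.0, 11.0, 16.0])
        sp2 = ((3 - 1) * a.var(ddof=1) + (3 - 1) * b.var(ddof=1)) / 4
        t_hand = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        res = pooled_t_test(a, b)
        assert abs(res.t - t_hand) < 1e-10
        ref = stats.ttest_ind(b, a, equal_var=True)
        assert abs(res.t - ref.statistic) < 1e-10
        assert abs(res.p - ref.pvalue) < 1e-10

    def test_zero_variance_conventions(self):
        res = pooled_t_test([2.0, 2.0], [2.0, 2.0])
        assert (res.t, res.p) == (0.0, 1.0)
        res = pooled_t_test([2.0, 2.0], [5.0, 5.0])
        assert np.isinf(res.t) and res.t > 0 and res.p == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=10),
        st.lists(st.floats(-100, 100), min_size=2, max_size=10),
    )
    def test_antisymmetry(self, a, b):
        ab = pooled_t_test(a, b)
        ba = pooled_t_test(b, a)
        assert np.isclose(ab.t, -ba.t, equal_nan=True)
        assert np.isclose(ab.p, ba.p, equal_nan=True)


def test_t_from_summary_matches_raw_and_scipy():
    rng = np.random.default_rng(0)
    a, b = rng.normal(10, 3, 6), rng.normal(14, 5, 6)
    raw = pooled_t_test(a, b)
    summ = t_from_summary(
        a.mean(), a.std(ddof=1) / np.sqrt(6), 6, b.mean(), b.std(ddof=1) / np.sqrt(6), 6
    )
    assert abs(raw.t - summ.t) < 1e-10 and abs(raw.p - summ.p) < 1e-12
    ref = stats.ttest_ind_from_stats(
        b.mean(), b.std(ddof=1), 6, a.mean(), a.std(ddof=1), 6, equal_var=True
    )
    assert abs(summ.t - ref.statistic) < 1e-10


class TestTDifferenceTable:
    def test_identical_arms_give_zero_t(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(3, 0.5, size=(6, 3))
        cells = {("UNTREATED", 0): vals}
        for t in (1, 2, 3, 4):
            block = rng.lognormal(3, 0.5, size=(6, 3))
            cells[("ST", t)] = block
            cells[("ST_HS", t)] = block
        panel = make_panel(cells, ["IL-6", "KC", "MIG"])
        tab = t_difference_table(panel)
        assert np.allclose(tab.t.to_numpy(), 0.0)
        assert (tab.df[[c for c in tab.df.columns if c != "overall"]] == 10).all().all()
        assert (tab.df["overall"] == 46).all()

    def test_planted_fold_change_dominates_its_time_point(self):
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            cells = {("UNTREATED", 0): rng.lognormal(3, 0.2, (6, 4))}
            for t in (1, 2, 3, 4):
                cells[("ST", t)] = rng.lognormal(3, 0.2, (6, 4))
                shs = rng.lognormal(3, 0.2, (6, 4))
                if t == 3:
                    shs[:, 0] *= 3.0
                cells[("ST_HS", t)] = shs
            panel = make_panel(cells, ["IL-12.total", "IL-6", "KC", "MIG"])
            tab = t_difference_table(panel)
            if tab.t["3 h"].abs().idxmax() == "IL-12.total":
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_missing_cell_is_named(self, study_panel):
        broken = study_panel.data
        broken = broken[~((broken["procedure"] == "ST") & (broken["time_h"] == 2))]
        from dynacyt.panel import MediatorPanel

        with pytest.raises(AnalysisError, match="2 h"):
            t_difference_table(MediatorPanel(broken.copy()))


class TestLevene:
    def test_degenerate_all_equal(self):
        w, p = levene_test([[3.0, 3.0, 3.0], [3.0, 3.0, 3.0]])
        assert w == 0.0 and p == 1.0

    def test_detects_variance_ratio_100(self):
        rejections = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            _, p = levene_test([rng.normal(0, 1, 50), rng.normal(0, 10, 50)])
            rejections += p < 0.05
        assert rejections == 30

    def test_type_one_error_near_alpha_large_n(self):
        # the F reference for mean-centered Levene is asymptotic; it is
        # known to be liberal at n=6 (~0.10 here), so calibration is
        # asserted where the approximation holds
        reps, rej = 400, 0
        rng = np.random.default_rng(99)
        for _ in range(reps):
            groups = rng.normal(0, 1, size=(9, 50))
            _, p = levene_test(list(groups))
            rej += p < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) < 3.5 * se

    def test_liberal_at_study_sample_size(self):
        reps, rej = 500, 0
        rng = np.random.default_rng(7)
        for _ in range(reps):
            _, p = levene_test(list(rng.normal(0, 1, size=(9, 6))))
            rej += p < 0.05
        assert 0.05 < rej / reps < 0.18


class TestGamesHowell:
    def test_null_pairs_not_significant(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(5, 1, 6) for _ in range(3)]
        tab = games_howell(groups)
        assert (tab["p"] > 0.05).all()

    def test_shifted_group_flagged_only(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(0, 1, 8), rng.normal(0, 1, 8), rng.normal(10, 1, 8)]
        tab = games_howell(groups)
        involves_2 = (tab["group_i"] == 2) | (tab["group_j"] == 2)
        assert (tab.loc[involves_2, "p"] < 0.01).all()
        assert (tab.loc[~involves_2, "p"] > 0.05).all()

    def test_welch_df_matches_two_group_welch(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 6), rng.normal(0, 4, 9)
        tab = games_howell([a, b])
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert abs(tab["df"].iloc[0] - ref.df) < 1e-10

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        groups = [rng.normal(0, 1, 6), rng.normal(1, 3, 8), rng.normal(0.5, 0.5, 7)]
        mine = games_howell(groups)
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat(["a", "b", "c"], [6, 8, 7]),
            }
        )
        ref = pg.pairwise_gameshowell(data=df, dv="y", between="g")
        assert np.allclose(mine["mean_diff"].abs(), ref["diff"].abs(), atol=1e-10)
        assert np.allclose(mine["df"], ref["df"], atol=1e-8)
        assert np.allclose(mine["p"], ref["pval"], atol=1e-6)


class TestAnova:
    @staticmethod
    def _fixed_panel(seed=7, effect=0.0):
        rng = np.random.default_rng(seed)
        cells = {("UNTREATED", 0): rng.lognormal(3, 0.3, (6, 1))}
        for t in (1, 2, 3, 4):
            cells[("ST", t)] = rng.lognormal(3, 0.3, (6, 1))
            cells[("ST_HS", t)] = rng.lognormal(3 + effect, 0.3, (6, 1))
        return make_panel(cells, ["IL-6"])

    def test_brute_force_sums_of_squares_oracle(self):
        panel = self._fixed_panel()
        tab = anova_two_way(panel, "IL-6").table
        wide = panel.treated().wide()
        y = wide["IL-6"].to_numpy()
        grand = y.mean()
        proc = wide["procedure"].to_numpy()
        time = wide["time_h"].to_numpy()
        ss_a = sum(
            (y[proc == p_].size) * (y[proc == p_].mean() - grand) ** 2
            for p_ in ("ST", "ST_HS")
        )
        ss_b = sum(
            (y[time == t].size) * (y[time == t].mean() - grand) ** 2 for t in (1, 2, 3, 4)
        )
        ss_cells = sum(
            (y[(proc == p_) & (time == t)].size)
            * (y[(proc == p_) & (time == t)].mean() - grand) ** 2
            for p_ in ("ST", "ST_HS")
            for t in (1, 2, 3, 4)
        )
        ss_ab = ss_cells - ss_a - ss_b
        ss_e = sum(
            ((y[(proc == p_) & (time == t)] - y[(proc == p_) & (time == t)].mean()) ** 2).sum()
            for p_ in ("ST", "ST_HS")
            for t in (1, 2, 3, 4)
        )
        f_a = (ss_a / 1) / (ss_e / 40)
        f_b = (ss_b / 3) / (ss_e / 40)
        f_ab = (ss_ab / 3) / (ss_e / 40)
        assert abs(tab.loc["Procedure", "F"] - f_a) < 1e-8
        assert abs(tab.loc["Time", "F"] - f_b) < 1e-8
        assert abs(tab.loc["Procedure:Time", "F"] - f_ab) < 1e-8
        assert tab.loc["Residual", "df"] == 40

    def test_planted_procedure_effect(self):
        tab = anova_two_way(self._fixed_panel(seed=8, effect=1.0), "IL-6").table
        assert tab.loc["Procedure", "p"] < 1e-6
        assert tab.loc["Procedure:Time", "p"] > 0.001

    def test_unbalanced_design_rejected(self, study_panel):
        from dynacyt.panel import MediatorPanel

        df = study_panel.data
        drop = df[(df["procedure"] == "ST") & (df["time_h"] == 1)]["subject_id"].iloc[0]
        broken = MediatorPanel(df[df["subject_id"] != drop].copy())
        with pytest.raises(AnalysisError, match="balanced"):
            anova_two_way(broken, "IL-6")


class TestTrendFit:
    @staticmethod
    def _panel(seed, slope_st=0.0, slope_shs=0.0, quad=0.0, sigma=1.0):
        rng = np.random.default_rng(seed)
        cells = {("UNTREATED", 0): rng.normal(10, sigma, (6, 1)).clip(min=0)}
        for t in (1, 2, 3, 4):
            st_mu = 10 + slope_st * t + quad * t * t
            shs_mu = 10 + slope_shs * t + quad * t * t
            cells[("ST", t)] = rng.normal(st_mu, sigma, (6, 1)).clip(min=0)
            cells[("ST_HS", t)] = rng.normal(shs_mu, sigma, (6, 1)).clip(min=0)
        return make_panel(cells, ["IL-12.total"])

    def test_linear_trend_recovered_and_quadratic_dropped(self):
        fit = trend_model_fit(self._panel(10, slope_st=3.0, slope_shs=3.0), "IL-12.total")
        assert fit.reduced
        assert fit.params.loc["Time.L", "p"] < 1e-6

    def test_procedure_specific_slope_detected(self):
        hits = 0
        for seed in range(40):
            fit = trend_model_fit(
                self._panel(seed, slope_st=0.0, slope_shs=3.0), "IL-12.total", reduce=False
            )
            hits += fit.params.loc["Procedure:Time.L", "p"] < 0.05
        assert hits >= 38

    def test_null_keeps_nothing_significant_too_often(self):
        ps = []
        for seed in range(60):
            fit = trend_model_fit(self._panel(seed + 500), "IL-12.total", reduce=False)
            ps.append(fit.params.loc["Time.Q", "p"])
        # under the null the quadratic p-values are roughly uniform
        assert 0.25 < np.mean(ps) < 0.75
        assert np.mean(np.array(ps) < 0.05) < 0.15

    def test_orthogonal_contrasts(self):
        from dynacyt.univariate import _TIME_L, _TIME_Q

        L = np.array(list(_TIME_L.values()))
        Q = np.array(list(_TIME_Q.values()))
        assert abs(L @ Q) < 1e-12 and abs(L.sum()) < 1e-12 and abs(Q.sum()) < 1e-12

    def test_agrees_with_anova_on_procedure_direction(self, study_panel):
        tab = anova_two_way(study_panel, "MIG").table
        fit = trend_model_fit(study_panel, "MIG", reduce=False)
        wide = study_panel.treated().wide()
        diff = (
            wide.loc[wide["procedure"] == "ST_HS", "MIG"].mean()
            - wide.loc[wide["procedure"] == "ST", "MIG"].mean()
        )
        assert np.sign(fit.params.loc["Procedure", "coef"]) == np.sign(diff)
        assert tab.loc["Procedure", "F"] > 0


class TestCorrelationMatrix:
    @staticmethod
    def _latent_panel(seed, rho):
        rng = np.random.default_rng(seed)
        cells = {("UNTREATED", 0): rng.lognormal(3, 0.2, (6, 3))}
        cov = [[1.0, rho], [rho, 1.0]]
        for p in ("ST", "ST_HS"):
            for t in (1, 2, 3, 4):
                z = rng.multivariate_normal([3, 3], np.array(cov) * 0.04, size=6)
                third = rng.normal(3, 0.2, (6, 1))
                cells[(p, t)] = np.exp(np.hstack([z, third]))
        return make_panel(cells, ["IL-6", "KC", "MIG"])

    @pytest.mark.parametrize("rho,lo,hi", [(0.95, 0.9, 1.0), (-0.95, -1.0, -0.9)])
    def test_diagonal_and_planted_rho(self, rho, lo, hi):
        hits = 0
        for seed in range(20):
            panel = self._latent_panel(seed, rho)
            corr = correlation_matrix(panel, ["IL-6", "KC", "MIG"])
            assert np.allclose(np.diag(corr), 1.0)
            hits += lo <= corr.loc["IL-6", "KC"] <= hi
        assert hits >= 18

    def test_zero_variance_flagged_not_silently_zero(self, study_panel):
        from dynacyt.panel import MediatorPanel

        df = study_panel.data.copy()
        df.loc[df["mediator"] == "IL-5", "value"] = 7.0
        panel = MediatorPanel(df)
        with pytest.warns(UserWarning, match="IL-5"):
            corr = correlation_matrix(panel, ["IL-5", "IL-6"])
        assert np.isnan(corr.loc["IL-5", "IL-6"])


class TestBaselineGate:
    def test_alpha_zero_empty_and_monotone(self, study_panel):
        assert baseline_altered_set(study_panel, "ST", (2, 3), alpha=0.0).mediators == frozenset()
        small = baseline_altered_set(study_panel, "ST", (2, 3), alpha=0.01).mediators
        large = baseline_altered_set(study_panel, "ST", (2, 3), alpha=0.10).mediators
        assert small <= large

    def test_planted_shift_always_included(self):
        hits = 0
        for seed in range(20):
            cfg = SyntheticConfig(effects={("ST", 2, "IL-6"): 5.0, ("ST", 3, "IL-6"): 5.0})
            panel, _ = generate_panel(cfg, seed=seed)
            hits += "IL-6" in baseline_altered_set(panel, "ST", (2, 3)).mediators
        assert hits >= 19

    def test_window_zero_tests_one_hour_cell_only(self, study_panel):
        # manual 6-vs-6 pooled t on the 1-h cell must reproduce the gate
        alt = baseline_altered_set(study_panel, "ST", (0, 1), alpha=0.05).mediators
        manual = set()
        for m in study_panel.mediators:
            base = study_panel.cell_values("UNTREATED", 0, m)
            one = study_panel.cell_values("ST", 1, m)
            if pooled_t_test(base, one).p < 0.05:
                manual.add(m)
        assert alt == manual

    def test_bad_window_rejected(self, study_panel):
        with pytest.raises(AnalysisError, match="window"):
            baseline_altered_set(study_panel, "ST", (1, 3))


class TestPercentModulated:
    def test_planted_five_of_21(self):
        meds = ["IL-6", "KC", "MIG", "IP-10", "MCP-1"]
        effects = {("ST", t, m): 8.0 for t in (2, 3) for m in meds}
        cfg = SyntheticConfig(effects=effects, sigma=0.3)
        panel, _ = generate_panel(cfg, seed=3)
        pm = percent_modulated(panel, alpha=0.05)
        row = pm[(pm["procedure"] == "ST") & (pm["window"] == "2-3 h")].iloc[0]
        # 5 planted of 21 = 23.8%, plus at most a couple of false positives
        assert row["n_altered"] >= 5
        assert abs(row["percent"] - 100 * 5 / 21) <= 100 * 2 / 21

    def test_empty_altered_set_is_zero_percent(self, null_panel):
        pm = percent_modulated(null_panel, alpha=1e-9)
        assert (pm["percent"] == 0).all()
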