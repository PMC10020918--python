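import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pseudodxa.stats import (
    MODEL_PREDICTORS,
    ancova_compare,
    bivariate_fit,
    fit_model_ladder,
    group_compare,
    icc_3_1,
    normality_gate,
    sensitivity_exclusion,
    split_subgroups,
    vif_prune,
)
from pseudodxa.synthetic import CohortSpec, generate_cohort


class TestNormalityGate:
    def test_normal_sample_passes_untouched(self, rng):
        x = rng.normal(size=100)
        out, tag = normality_gate(x)
        assert tag == "identity"
        np.testing.assert_array_equal(out, x)

    def test_lognormal_body_weight_gets_log(self, rng):
        bw = np.exp(rng.normal(np.log(67), 0.5, size=120))
        out, tag = normality_gate(bw)
        assert tag.startswith("log")
        assert sps.shapiro(out).pvalue >= 0.05

    def test_squared_normal_pyd_gets_a_normalising_transform(self, rng):
        pyd = rng.normal(1.6, 0.5, size=120) ** 2
        out, tag = normality_gate(pyd)
        assert tag != "identity"
        assert sps.shapiro(out).pvalue >= 0.05

    def test_nonpositive_values_skip_log(self, rng):
        x = np.concatenate([[0.0], rng.exponential(size=80) ** 2])
        _, tag = normality_gate(x)
        assert "log" not in tag.split("+")[0] or "skipped" in tag


class TestBivariateFit:
    def test_perfect_line(self):
        x = np.arange(10.0)
        fit = bivariate_fit(x, 2 * x)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_r2_equals_squared_correlation(self, rng):
        x = rng.normal(size=50)
        y = 1.5 * x + rng.normal(size=50)
        fit = bivariate_fit(x, y)
        assert fit.r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12)

    def test_ci_coverage_near_nominal(self):
        """95% slope CI covers the truth at its nominal rate (200 reps)."""
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(200):
            x = rng.normal(size=50)
            y = 2.0 * x + rng.normal(scale=1.0, size=50)
            fit = bivariate_fit(x, y)
            hits += fit.slope_ci[0] <= 2.0 <= fit.slope_ci[1]
        assert 0.90 <= hits / 200 <= 0.99

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            bivariate_fit(np.ones(10), np.arange(10.0))


class TestAncova:
    def test_identical_groups_are_nonsignificant(self):
        x = np.tile(np.arange(10.0), 2)
        y = np.tile(2 * np.arange(10.0) + 1, 2)
        g = ["a"] * 10 + ["b"] * 10
        slope_p, intercept_p = ancova_compare(x, y, g)
        assert slope_p == pytest.approx(1.0)
        assert intercept_p == pytest.approx(1.0)

    def test_intercept_shift_detected_with_power(self):
        """Equal slopes, intercepts 5σ apart → intercept_p < 0.001 in ≥95%
        of seeded replicates."""
        rng = np.random.default_rng(4)
        detected = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(size=30)
            g = np.array(["a"] * 15 + ["b"] * 15)
            y = 1.2 * x + np.where(g == "b", 5.0, 0.0) + rng.normal(size=30)
            _, intercept_p = ancova_compare(x, y, g)
            detected += intercept_p < 0.001
        assert detected / reps >= 0.95

    def test_f_statistics_match_sum_of_squares_oracle(self):
        """Slope-homogeneity F on a 10-point dataset equals a from-scratch
        ANOVA decomposition to 1e-9 relative."""
        x = np.array([1, 2, 3, 4, 5, 1, 2, 3, 4, 5], dtype=float)
        y = np.array([2.1, 4.2, 5.9, 8.3, 9.8, 1.0, 3.5, 5.2, 7.9, 9.0])
        g = np.array(["a"] * 5 + ["b"] * 5)
        slope_p, intercept_p = ancova_compare(x, y, g)

        def _ssr(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return r @ r

        d = (g == "b").astype(float)
        one = np.ones_like(x)
        ssr_full = _ssr(np.column_stack([one, x, d, d * x]))
        ssr_common = _ssr(np.column_stack([one, x, d]))
        ssr_slope = _ssr(np.column_stack([one, x]))
        F_slope = (ssr_common - ssr_full) / 1 / (ssr_full / (10 - 4))
        F_int = (ssr_slope - ssr_common) / 1 / (ssr_common / (10 - 3))
        assert slope_p == pytest.approx(float(sps.f.sf(F_slope, 1, 6)), rel=1e-9)
        assert intercept_p == pytest.approx(float(sps.f.sf(F_int, 1, 7)), rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            ancova_compare(
                np.arange(5.0), np.arange(5.0), ["a", "a", "a", "b", "b"]
            )


class TestIcc:
    def test_identical_raters_give_unity(self):
        M = np.tile(np.arange(6.0)[:, None], (1, 3))
        res = icc_3_1(M)
        assert res.icc == pytest.approx(1.0)
        assert res.category == "excellent"

    def test_hand_matrix_matches_anova_oracle(self):
        """ICC on a 5×3 matrix equals the two-way-ANOVA mean squares formula
        computed from scratch, and pingouin's ICC3."""
        M = np.array(
            [
                [9.0, 10.0, 8.0],
                [6.0, 6.5, 7.0],
                [8.0, 7.5, 8.5],
                [7.0, 6.0, 6.5],
                [10.0, 9.5, 9.0],
            ]
        )
        res = icc_3_1(M)
        n, k = M.shape
        grand = M.mean()
        msr = k * ((M.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((M.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = (((M - grand) ** 2).sum() - msr * (n - 1) - msc * (k - 1)) / (
            (n - 1) * (k - 1)
        )
        expected = (msr - mse) / (msr + (k - 1) * mse)
        assert res.icc == pytest.approx(expected, rel=1e-9)
        pg = pytest.importorskip("pingouin")
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "score": M.ravel(),
            }
        )
        icc_pg = pg.intraclass_corr(
            data=df, targets="targets", raters="raters", ratings="score"
        )
        # consistency, single rater: labelled ICC3 or ICC(C,1) by version
        sel = icc_pg["Type"].isin(["ICC3", "ICC(C,1)"])
        ref = float(icc_pg.loc[sel, "ICC"].iloc[0])
        assert res.icc == pytest.approx(ref, rel=1e-9)

    def test_simulated_known_icc_recovered(self):
        """Rows with variance ratio tuned for a true ICC of 0.8 give an
        estimate whose CI covers 0.8."""
        rng = np.random.default_rng(8)
        sigma_r, sigma_e = 2.0, 1.0  # ICC = 4/(4+1) = 0.8
        row = rng.normal(0, sigma_r, size=(30, 1))
        M = row + rng.normal(0, sigma_e, size=(30, 4))
        res = icc_3_1(M)
        assert res.ci_low <= 0.8 <= res.ci_high
        assert res.icc == pytest.approx(0.8, abs=0.15)

    def test_constant_matrix_is_undefined(self):
        res = icc_3_1(np.ones((6, 3)))
        assert res.category == "undefined"
        assert np.isnan(res.icc)

    @pytest.mark.parametrize("shape", [(4, 3), (6, 1)])
    def test_undersized_matrix_rejected(self, shape):
        with pytest.raises(ValueError):
            icc_3_1(np.zeros(shape))


class TestSplitSubgroups:
    def _cohort(self, areas, ids=None):
        n = len(areas)
        return pd.DataFrame(
            {"id": ids or [f"S{i}" for i in range(n)], "area_cm2": areas}
        )

    def test_thirty_samples_split_fifteen_fifteen(self, rng):
        df = split_subgroups(self._cohort(rng.uniform(4.0, 5.3, 30)))
        assert df["subgroup"].value_counts().to_dict() == {"narrow": 15, "wide": 15}
        med = df.loc[df.subgroup == "narrow", "area_cm2"].max()
        assert (df.loc[df.subgroup == "wide", "area_cm2"] >= med).all()

    def test_odd_count_assigns_median_to_narrow(self):
        df = split_subgroups(self._cohort([1.0, 2.0, 3.0, 4.0, 5.0]))
        counts = df["subgroup"].value_counts()
        assert counts["narrow"] == 3 and counts["wide"] == 2

    def test_row_order_invariance(self, rng):
        base = self._cohort(rng.uniform(4, 5, 20))
        a = split_subgroups(base).sort_values("id")["subgroup"].tolist()
        b = (
            split_subgroups(base.sample(frac=1, random_state=1))
            .sort_values("id")["subgroup"]
            .tolist()
        )
        assert a == b

    def test_all_equal_areas_warns_and_splits_by_id(self):
        with pytest.warns(UserWarning, match="id order"):
            df = split_subgroups(self._cohort([4.5] * 6))
        assert df.loc[df.subgroup == "narrow", "id"].tolist() == ["S0", "S1", "S2"]


class TestVifPrune:
    def test_orthogonal_predictors_untouched(self):
        n = 32
        t = np.arange(n)
        X = pd.DataFrame(
            {
                "a": np.cos(2 * np.pi * t / n),
                "b": np.sin(2 * np.pi * t / n),
                "c": np.cos(4 * np.pi * t / n),
            }
        )
        retained, table = vif_prune(X)
        assert retained == ["a", "b", "c"]
        assert (table["vif"] < 1.01).all()

    def test_near_duplicate_dropped(self, rng):
        x1 = rng.normal(size=60)
        x2 = x1 + rng.normal(scale=0.01, size=60)
        x3 = rng.normal(size=60)
        retained, _ = vif_prune(pd.DataFrame({"x1": x1, "x2": x2, "x3": x3}))
        assert len(retained) == 2 and "x3" in retained

    def test_two_predictor_vif_matches_closed_form(self, rng):
        """For a predictor pair, VIF = 1/(1−r²) exactly."""
        x1 = rng.normal(size=60)
        x2 = 0.9 * x1 + rng.normal(scale=0.5, size=60)
        _, table = vif_prune(pd.DataFrame({"x1": x1, "x2": x2}), cap=np.inf)
        r2 = np.corrcoef(x1, x2)[0, 1] ** 2
        first = table[table.iteration == 0].set_index("predictor")["vif"]
        assert first["x1"] == pytest.approx(1 / (1 - r2), rel=1e-9)
        assert first["x2"] == pytest.approx(1 / (1 - r2), rel=1e-9)

    def test_vifs_match_auxiliary_regression_oracle(self, rng):
        X = pd.DataFrame(
            rng.normal(size=(40, 5)) @ (np.eye(5) + 0.4), columns=list("abcde")
        )
        _, table = vif_prune(X, cap=np.inf)
        import statsmodels.api as sm

        for c in X.columns:
            others = [o for o in X.columns if o != c]
            r2 = sm.OLS(X[c], sm.add_constant(X[others])).fit().rsquared
            got = float(table[table.predictor == c]["vif"].iloc[0])
            assert got == pytest.approx(1 / (1 - r2), rel=1e-9)

    def test_single_predictor_rejected(self):
        with pytest.raises(ValueError):
            vif_prune(pd.DataFrame({"a": np.arange(5.0)}))


class TestSensitivityExclusion:
    def _cohort(self, n=30):
        df = pd.DataFrame(
            {"id": [f"S{i:02d}" for i in range(n)], "area_cm2": np.linspace(4, 5, n)}
        )
        return split_subgroups(df)

    def test_zero_exclusion_is_identity(self):
        df = self._cohort()
        pd.testing.assert_frame_equal(sensitivity_exclusion(df, 0), df)

    def test_middle_four_leaves_13_13(self):
        out = sensitivity_exclusion(self._cohort(), 4)
        assert out["subgroup"].value_counts().to_dict() == {"narrow": 13, "wide": 13}

    def test_removed_ids_are_the_boundary_ranks(self):
        """With areas increasing in id order, removing the middle 4 drops
        exactly area-ranks 14–17 (0-based 13–16)."""
        df = self._cohort()
        out = sensitivity_exclusion(df, 4)
        removed = sorted(set(df["id"]) - set(out["id"]))
        assert removed == ["S13", "S14", "S15", "S16"]

    def test_commutes_with_row_permutation(self):
        df = self._cohort()
        a = sensitivity_exclusion(df, 8).sort_values("id")["id"].tolist()
        b = (
            sensitivity_exclusion(df.sample(frac=1, random_state=3), 8)
            .sort_values("id")["id"]
            .tolist()
        )
        assert a == b

    @pytest.mark.parametrize("m", [3, 40])
    def test_invalid_m_rejected(self, m):
        with pytest.raises(ValueError):
            sensitivity_exclusion(self._cohort(), m)


class TestGroupCompare:
    def _cohort(self, narrow_vals, wide_vals):
        n = len(narrow_vals) + len(wide_vals)
        return pd.DataFrame(
            {
                "id": [f"S{i}" for i in range(n)],
                "v": list(narrow_vals) + list(wide_vals),
                "subgroup": ["narrow"] * len(narrow_vals) + ["wide"] * len(wide_vals),
            }
        )

    def test_identical_groups_give_p_one(self):
        res = group_compare(self._cohort([1, 2, 3], [1, 2, 3]), "v")
        assert res["t_p"] == pytest.approx(1.0)

    def test_ten_sd_shift_is_overwhelming(self, rng):
        a = rng.normal(0, 1, 15)
        res = group_compare(self._cohort(a, a + 10), "v")
        assert res["t_p"] < 1e-6

    def test_means_and_sds_match_hand_computation(self):
        res = group_compare(self._cohort([1.0, 2.0, 3.0], [4.0, 6.0, 8.0]), "v")
        assert res["narrow_mean"] == pytest.approx(2.0)
        assert res["narrow_sd"] == pytest.approx(1.0)
        assert res["wide_mean"] == pytest.approx(6.0)
        assert res["wide_sd"] == pytest.approx(2.0)
        t = sps.ttest_ind([1.0, 2.0, 3.0], [4.0, 6.0, 8.0])
        assert res["t_p"] == pytest.approx(float(t.pvalue), rel=1e-12)


class TestModelLadder:
    def test_outcome_as_its_own_predictor_gives_perfect_fit(self, rng):
        n = 20
        y = rng.normal(3000, 800, n)
        df = pd.DataFrame(
            {
                "id": [f"S{i}" for i in range(n)],
                "age_yr": rng.uniform(40, 90, n),
                "body_weight_kg": rng.uniform(50, 100, n),
                "bmd_voxels_per_cm2": y,  # outcome smuggled in as predictor
                "max_load_n": y,
            }
        )
        res = fit_model_ladder(df, "all", models=(1,))[0]
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-9)
        assert res.std_betas["bmd_voxels_per_cm2"] == pytest.approx(1.0, abs=1e-9)

    def test_model1_parameter_recovery(self):
        """A cohort generated under model 1 with standardized effects
        (0.5, −0.3, 0.6) returns betas within ±0.1 at n = 200."""
        effects = {"age_yr": 0.5, "body_weight_kg": -0.3, "bmd_voxels_per_cm2": 0.6}
        df, truth = generate_cohort(
            CohortSpec(n=200, model_id=1, effects=effects, seed=17)
        )
        res = fit_model_ladder(df, "all", models=(1,))[0]
        keymap = {
            "age_yr": "age_yr",
            "body_weight_kg": "log_body_weight_kg",
            "bmd_voxels_per_cm2": "bmd_voxels_per_cm2",
        }
        for col, beta_true in truth["std_betas"].items():
            assert res.std_betas[keymap[col]] == pytest.approx(beta_true, abs=0.1)

    def test_standardized_betas_invariant_to_predictor_rescaling(self, rng):
        df, _ = generate_cohort(CohortSpec(n=60, model_id=1, seed=3))
        base = fit_model_ladder(df, "all", models=(1,))[0]
        df2 = df.copy()
        df2["age_yr"] = df2["age_yr"] * 12.0  # age in months
        scaled = fit_model_ladder(df2, "all", models=(1,))[0]
        assert scaled.std_betas["age_yr"] == pytest.approx(
            base.std_betas["age_yr"], abs=1e-10
        )

    def test_all_five_models_fit_on_generated_cohort(self):
        df, _ = generate_cohort(CohortSpec(n=40, model_id=5, effects={}, seed=9))
        results = fit_model_ladder(df, "all")
        assert [r.model_id for r in results] == [1, 2, 3, 4, 5]
        for r in results:
            assert np.isfinite(r.adj_r2) and r.adj_r2 <= 1.0
            assert set(r.p_values) == set(r.predictors)

    def test_per_variable_missingness_handled_listwise(self):
        """A specimen missing strength is dropped from the fit, mirroring a
        cohort where one sample lacks mechanical data."""
        df, _ = generate_cohort(CohortSpec(n=30, model_id=1, seed=21))
        df.loc[df.index[0], "max_load_n"] = np.nan
        res = fit_model_ladder(df, "narrow", models=(1,))
        assert res[0].n in (14, 15) and res[0].n == (
            (df["subgroup"] == "narrow") & df["max_load_n"].notna()
        ).sum()

    def test_too_few_rows_names_the_model(self):
        df, _ = generate_cohort(CohortSpec(n=30, model_id=1, seed=2))
        with pytest.raises(ValueError, match="model 5"):
            fit_model_ladder(df.head(8), "all", models=(5,))
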