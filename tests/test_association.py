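import math

import numpy as np
import pandas as pd
import pytest

from immunospat.association import (
    ScreenPlan,
    bh_adjust,
    correlation_cluster_map,
    cox_per_unit,
    group_comparisons,
    km_curves_by_group,
    logistic_per_unit,
    primary_met_contrast,
    reverse_km_median,
    run_association_screen,
    tertile_split,
)
from immunospat.synthetic import OutcomeModel, simulate_clinical


def clinical_frame(times, events, **extra):
    d = pd.DataFrame({"os_months": times, "death_event": events})
    for k, v in extra.items():
        d[k] = v
    return d


def efron_partial_loglik(beta, times, events, x):
    """Independent Efron partial likelihood for one covariate."""
    ll = 0.0
    for t in sorted(set(times[events == 1])):
        d_idx = np.where((times == t) & (events == 1))[0]
        r_idx = np.where(times >= t)[0]
        d = len(d_idx)
        sum_risk = np.exp(beta * x[r_idx]).sum()
        sum_tied = np.exp(beta * x[d_idx]).sum()
        ll += beta * x[d_idx].sum()
        for j in range(d):
            ll -= math.log(sum_risk - (j / d) * sum_tied)
    return ll


class TestCox:
    def toy(self):
        times = np.array([5.0, 8, 12, 16, 20, 30])
        events = np.array([1, 1, 0, 1, 0, 1])
        x = np.array([1.0, 0, 1, 0, 1, 0])
        return times, events, x

    def test_coefficient_matches_grid_search_oracle(self):
        times, events, x = self.toy()
        d = clinical_frame(times, events, x=x)
        res = cox_per_unit(d, "x")
        grid = np.arange(-3, 3, 1e-4)
        ll = [efron_partial_loglik(b, times, events, x) for b in grid]
        beta_hat = grid[int(np.argmax(ll))]
        assert math.log(res.estimate) == pytest.approx(beta_hat, abs=1e-4)

    def test_lr_p_matches_oracle_likelihoods(self):
        times, events, x = self.toy()
        d = clinical_frame(times, events, x=x)
        res = cox_per_unit(d, "x")
        beta = math.log(res.estimate)
        from scipy.stats import chi2
        lr = 2 * (efron_partial_loglik(beta, times, events, x)
                  - efron_partial_loglik(0.0, times, events, x))
        assert res.lr_p == pytest.approx(chi2.sf(lr, 1), rel=1e-3)

    def test_zero_events_rejected(self):
        d = clinical_frame([1.0, 2, 3], [0, 0, 0], x=[1.0, 2, 3])
        with pytest.raises(ValueError, match="zero events"):
            cox_per_unit(d, "x")

    def test_constant_variable_rejected(self):
        d = clinical_frame([1.0, 2, 3], [1, 1, 0], x=[2.0, 2, 2])
        with pytest.raises(ValueError, match="constant"):
            cox_per_unit(d, "x")

    def test_adjusted_fit_reports_covariates(self):
        rng = np.random.default_rng(0)
        n = 120
        x, z = rng.normal(size=n), rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / (0.05 * np.exp(0.4 * x + 0.5 * z)))
        d = clinical_frame(np.minimum(t, 60), (t < 60).astype(int), x=x, z=z)
        res = cox_per_unit(d, "x", covariates=("z",))
        assert res.covariates == ("z",)
        assert res.estimate > 1.0 and res.lr_p < 0.05


class TestLogistic:
    def table_2x2(self, a, b, c, d):
        """a = exposed responders, b = exposed non, c = unexposed
        responders, d = unexposed non."""
        y = [1] * a + [0] * b + [1] * c + [0] * d
        x = [1.0] * (a + b) + [0.0] * (c + d)
        return pd.DataFrame({"rcr": y, "x": x})

    def test_balanced_table_or_one(self):
        res = logistic_per_unit(self.table_2x2(10, 10, 10, 10), "x")
        assert res.estimate == pytest.approx(1.0, abs=1e-6)

    def test_cross_product_ratio(self):
        res = logistic_per_unit(self.table_2x2(20, 10, 10, 20), "x")
        assert res.estimate == pytest.approx(4.0, rel=1e-6)

    def test_single_class_rejected(self):
        d = pd.DataFrame({"rcr": [1, 1, 1], "x": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="single class"):
            logistic_per_unit(d, "x")

    def test_complete_separation_flagged(self):
        d = pd.DataFrame({"rcr": [0, 0, 0, 1, 1, 1],
                          "x": [1.0, 2, 3, 10, 11, 12]})
        with pytest.raises(RuntimeError, match="separation"):
            logistic_per_unit(d, "x")


class TestReverseKM:
    def test_all_alive_at_sixty_months(self):
        d = clinical_frame([60.0] * 5, [0] * 5)
        assert reverse_km_median(d) == 60.0

    def test_all_dead_not_reached(self):
        d = clinical_frame([10.0, 20, 30], [1, 1, 1])
        assert math.isinf(reverse_km_median(d))

    def test_hand_computed_eight_record_example(self):
        # censored at 4, 8, 12, 16; deaths at 2, 6, 10, 14.
        # Reversed product-limit: S(4) = 6/7, S(8) = 6/7 * 4/5 = 0.686,
        # S(12) = 0.686 * 2/3 = 0.457 < 0.5  =>  median 12.
        d = clinical_frame([2.0, 4, 6, 8, 10, 12, 14, 16],
                           [1, 0, 1, 0, 1, 0, 1, 0])
        assert reverse_km_median(d) == 12.0

    def test_identity_with_flipped_indicator_km(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(1)
        t = rng.exponential(20, 50)
        e = rng.integers(0, 2, 50)
        d = clinical_frame(t, e)
        km = KaplanMeierFitter().fit(t, 1 - e)
        assert reverse_km_median(d) == km.median_survival_time_


class TestBH:
    def test_step_up_worked_example(self):
        out = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_unchanged(self):
        assert np.allclose(bh_adjust([0.04] * 5), [0.04] * 5)

    def test_monotone_and_dominates_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=40)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert math.isnan(out[1]) and not math.isnan(out[0])


class TestTertiles:
    def test_exact_thirds(self):
        labels = tertile_split(list(range(1, 10)))
        assert labels.value_counts().tolist() == [3, 3, 3]

    def test_sizes_differ_by_at_most_one(self):
        labels = tertile_split(list(range(1, 11)))
        counts = labels.value_counts()
        assert counts.max() - counts.min() <= 1

    def test_all_identical_single_group(self):
        with pytest.warns(UserWarning):
            labels = tertile_split([5.0] * 6)
        assert (labels == "T1").all()

    def test_partition_of_non_missing(self):
        vals = [1.0, np.nan, 3, 8, 2, 9, 4]
        labels = tertile_split(vals)
        assert labels.notna().sum() == 6
        assert labels[1] is pd.NA or pd.isna(labels[1])

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            tertile_split([1.0, 2.0])


class TestKMCurves:
    def test_duplicated_group_logrank_near_one(self):
        d = clinical_frame([5.0, 10, 15, 20] * 2, [1, 0, 1, 0] * 2)
        labels = pd.Series(["g1"] * 4 + ["g2"] * 4)
        curves, p = km_curves_by_group(d, labels)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_extreme_separation_significant(self):
        d = clinical_frame([1.0] * 20 + [10.0] * 20, [1] * 40)
        labels = pd.Series(["early"] * 20 + ["late"] * 20)
        _, p = km_curves_by_group(d, labels)
        assert p < 0.01

    def test_curve_starts_at_one(self):
        d = clinical_frame([5.0, 8.0], [1, 1])
        curves, _ = km_curves_by_group(d, pd.Series(["g", "g"]))
        sf = curves["g"]
        assert sf.iloc[0, 0] == 1.0

    def test_single_group_no_test(self):
        d = clinical_frame([5.0, 8.0], [1, 1])
        curves, p = km_curves_by_group(d, pd.Series(["g", "g"]))
        assert math.isnan(p) and "g" in curves


class TestPrimaryMetContrast:
    def frame(self, prim, met, pair=True):
        n = max(len(prim), len(met))
        rows = []
        for i, v in enumerate(prim):
            rows.append({"sample_type": "primary", "f": v,
                         "pair_id": f"p{i}" if pair else None})
        for i, v in enumerate(met):
            rows.append({"sample_type": "metastasis", "f": v,
                         "pair_id": f"p{i}" if pair else None})
        return pd.DataFrame(rows)

    def test_identical_pairs(self):
        d = self.frame([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        res = primary_met_contrast(d, "f", paired=True)
        assert res["mean_difference"] == 0.0 and res["p"] == 1.0

    def test_constant_shift_eight_pairs_exact_p(self):
        prim = [float(i) for i in range(8)]
        met = [v + 10 for v in prim]
        res = primary_met_contrast(self.frame(prim, met), "f", paired=True)
        assert res["mean_difference"] == pytest.approx(10.0)
        assert res["p"] == pytest.approx(2 * 0.5**8)  # sign-test enumeration

    def test_unpaired_mode_reports_mwu(self):
        d = self.frame([1.0, 2, 3, 4, 5], [11.0, 12, 13, 14, 15], pair=False)
        res = primary_met_contrast(d, "f", paired=False)
        assert res["mean_difference"] == pytest.approx(10.0)
        assert res["p"] < 0.05

    def test_feature_missing_in_all_metastases(self):
        d = self.frame([1.0, 2, 3], [np.nan, np.nan, np.nan], pair=False)
        res = primary_met_contrast(d, "f", paired=False)
        assert math.isnan(res["p"]) and "metastases" in res["reason"]

    def test_no_pairs_rejected(self):
        d = self.frame([1.0], [2.0])
        d["pair_id"] = ["a", "b"]
        with pytest.raises(ValueError, match="pairs"):
            primary_met_contrast(d, "f", paired=True)


class TestCorrelationMap:
    def test_duplicate_feature_clusters_adjacent(self):
        rng = np.random.default_rng(0)
        d = pd.DataFrame({"a": rng.normal(size=30)})
        d["b"] = d["a"]
        d["c"] = rng.normal(size=30)
        rho, p, stars, order = correlation_cluster_map(d)
        assert rho.loc["a", "b"] == pytest.approx(1.0)
        ia, ib = order.index("a"), order.index("b")
        assert abs(ia - ib) == 1

    def test_negation_gives_minus_one(self):
        rng = np.random.default_rng(1)
        d = pd.DataFrame({"a": rng.normal(size=20)})
        d["b"] = -d["a"]
        rho, *_ = correlation_cluster_map(d)
        assert rho.loc["a", "b"] == pytest.approx(-1.0)

    def test_independent_features_mostly_uncorrelated(self):
        rng = np.random.default_rng(2)
        d = pd.DataFrame(rng.normal(size=(200, 8)),
                         columns=[f"f{i}" for i in range(8)])
        rho, *_ = correlation_cluster_map(d)
        off = rho.to_numpy()[~np.eye(8, dtype=bool)]
        assert (np.abs(off) < 0.2).mean() >= 0.95

    def test_sparse_feature_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        d = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10),
                          "sparse": [1.0, 2.0] + [np.nan] * 8})
        with pytest.warns(UserWarning, match="sparse"):
            rho, *_ = correlation_cluster_map(d)
        assert "sparse" not in rho.columns


class TestGroupComparisons:
    def test_two_groups_dispatch_mwu(self):
        name, _, p = group_comparisons([1.0, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert name == "mann-whitney"

    def test_three_groups_dispatch_kruskal(self):
        name, _, _ = group_comparisons(list(range(9)), ["a", "b", "c"] * 3)
        assert name == "kruskal-wallis"

    def test_identical_groups_p_near_one(self):
        vals = [1.0, 2, 3] * 2
        _, _, p = group_comparisons(vals, ["a"] * 3 + ["b"] * 3)
        assert p > 0.9

    def test_shifted_groups_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 30)
        b = rng.normal(3, 1, 30)
        _, _, p = group_comparisons(np.r_[a, b], ["a"] * 30 + ["b"] * 30)
        assert p < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_comparisons([1.0, 2.0], ["a", "a"])


class TestScreen:
    def cohort(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        scores = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "biomarker": rng.normal(size=n),
        })
        model = OutcomeModel(log_hazard_coefficients={"biomarker": 0.8},
                             logistic_coefficients={"biomarker": 0.5},
                             baseline_hazard_scale=0.03, seed=seed)
        records = simulate_clinical(scores, model)
        return scores, records

    def test_minimal_plan_gives_one_result(self):
        scores, records = self.cohort()
        plan = ScreenPlan(variables=["biomarker"], endpoints=["OS"],
                          subgroups=["all"])
        out = run_association_screen(scores, records, plan)
        assert len(out) == 1
        assert out["estimate"].iloc[0] > 1.0

    def test_bh_spans_full_family_and_tiers_assigned(self):
        scores, records = self.cohort()
        plan = ScreenPlan(variables=["biomarker"], endpoints=["OS", "rCR"],
                          subgroups=["all", "ER+", "ER-"],
                          covariate_sets={"unadjusted": (),
                                          "adjusted": ("er_positive",)})
        out = run_association_screen(scores, records, plan)
        assert len(out) == 2 * 3 * 2
        ok = out["lr_p"].notna()
        assert (out.loc[ok, "bh_adjusted_p"] >= out.loc[ok, "lr_p"] - 1e-12).all()
        assert set(out["tier"]) <= {"white", "light-gray", "gray", "na"}

    def test_all_censored_subgroup_flagged_not_estimable(self):
        scores, records = self.cohort(n=60)
        records["death_event"] = 0
        plan = ScreenPlan(variables=["biomarker"], endpoints=["OS"])
        out = run_association_screen(scores, records, plan)
        assert not out["estimable"].iloc[0]
        assert "zero events" in out["reason"].iloc[0]
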