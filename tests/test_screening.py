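import numpy as np
import pandas as pd
import pytest

from immunomark.screening import (
    cox_fit,
    fisher_exact,
    intersect_biomarkers,
    km_curve,
    mann_whitney,
    map_response,
    optimize_threshold,
    roc_auc,
    screen_biomarkers,
    select_pfs_biomarkers,
    select_response_biomarkers,
)

from conftest import random_survival
from oracles import gridsearch_cox_beta, pairwise_auc, product_limit


class TestMapResponse:
    @pytest.mark.parametrize("label,expected", [
        ("CR", "responder"), ("PR", "responder"), ("MPR", "responder"),
        ("SD", "non_responder"), ("PD", "non_responder"), ("non-MPR", "non_responder"),
    ])
    def test_mapping(self, label, expected):
        assert map_response(label) == expected

    def test_missing_values(self):
        assert map_response(None) == "missing"
        assert map_response(float("nan")) == "missing"

    def test_unknown_label_lists_accepted(self):
        with pytest.raises(ValueError, match="CR"):
            map_response("XYZ")


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 10, 11], [False, False, True, True]) == 1.0

    def test_all_equal_is_half(self):
        assert roc_auc([3, 3, 3, 3], [True, False, True, False]) == 0.5

    def test_three_of_four_pairwise_wins(self):
        assert roc_auc([3, 5, 1, 4], [True, True, False, False]) == 0.75

    def test_empty_class_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            roc_auc([1, 2], [True, True])

    def test_complement_identity(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 30))
            values = rng.choice([0.0, 0.5, 1.0, 2.0], size=n)
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                continue
            assert roc_auc(values, labels) + roc_auc(values, ~labels) == pytest.approx(1.0, abs=0)

    def test_matches_pairwise_enumeration(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 31))
            values = rng.choice(np.arange(6, dtype=float), size=n)
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                continue
            assert roc_auc(values, labels) == pytest.approx(
                pairwise_auc(values, labels), abs=1e-12
            )


class TestResponseTests:
    def test_identical_groups_mw_p_one(self):
        with pytest.warns(UserWarning, match="constant"):
            assert mann_whitney([1, 1, 1, 1], [True, True, False, False]) == 1.0

    def test_mw_detects_shift(self, rng):
        x = np.r_[rng.normal(0, 1, 30), rng.normal(3, 1, 30)]
        labels = np.r_[np.zeros(30), np.ones(30)].astype(bool)
        assert mann_whitney(x, labels) < 1e-6

    def test_fisher_five_zero_table(self):
        assert fisher_exact(5, 0, 0, 5) == pytest.approx(0.00794, abs=1e-5)
        assert fisher_exact(5, 0, 0, 5) == pytest.approx(2 / 252, abs=1e-12)

    def test_fisher_flat_table(self):
        assert fisher_exact(1, 1, 1, 1) == 1.0

    def test_fisher_zero_margin_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact(0, 0, 3, 4) == 1.0


class TestCox:
    def test_identical_groups_hr_one(self):
        t = np.r_[[1, 2, 3, 4, 5.0], [1, 2, 3, 4, 5.0]]
        e = np.ones(10, int)
        x = np.r_[np.zeros(5), np.ones(5)]
        res = cox_fit(t, e, x)
        assert res.hr[0] == pytest.approx(1.0, abs=1e-8)

    def test_six_subject_toy_vs_gridsearch(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 0, 1, 1, 1])
        x = np.array([1.0, 0, 1, 0, 1, 0])
        res = cox_fit(t, e, x)
        beta = gridsearch_cox_beta(t, e, x)
        assert res.hr[0] == pytest.approx(np.exp(beta), abs=1e-4)

    def test_time_scaling_invariance(self, rng):
        t, e = random_survival(rng, 40)
        x = rng.normal(size=40)
        a = cox_fit(t, e, x)
        b = cox_fit(10 * t, e, x)
        assert a.hr[0] == pytest.approx(b.hr[0], rel=1e-9)

    def test_label_swap_inverts_hr(self, rng):
        t, e = random_survival(rng, 50)
        x = rng.integers(0, 2, 50).astype(float)
        a = cox_fit(t, e, x)
        b = cox_fit(t, e, 1.0 - x)
        assert a.hr[0] * b.hr[0] == pytest.approx(1.0, abs=1e-8)

    def test_handles_ties_like_lifelines(self, rng):
        from lifelines import CoxPHFitter

        t = rng.integers(1, 8, size=60).astype(float)  # heavy ties
        e = rng.integers(0, 2, 60)
        e[0] = 1
        x = rng.normal(size=60)
        mine = cox_fit(t, e, x)
        cph = CoxPHFitter().fit(pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e")
        assert mine.coef[0] == pytest.approx(cph.params_["x"], abs=1e-6)
        assert mine.p[0] == pytest.approx(cph.summary["p"]["x"], abs=1e-6)

    def test_multivariate_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter

        t, e = random_survival(rng, 80)
        X = rng.normal(size=(80, 3))
        mine = cox_fit(t, e, X)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["t"], df["e"] = t, e
        cph = CoxPHFitter().fit(df, "t", "e")
        assert np.allclose(mine.coef, cph.params_.to_numpy(), atol=1e-6)

    def test_monotone_likelihood_flagged(self):
        # group 1 has no events at all -> coefficient runs away
        t = np.r_[np.arange(1, 11), np.arange(1, 11)].astype(float)
        e = np.r_[np.ones(10, int), np.zeros(10, int)]
        x = np.r_[np.zeros(10), np.ones(10)]
        res = cox_fit(t, e, x)
        assert res.flagged

    def test_no_events_errors(self):
        with pytest.raises(ValueError, match="event"):
            cox_fit([1, 2, 3], [0, 0, 0], [0.0, 1, 0])

    def test_constant_covariate_errors(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1, 2, 3], [1, 1, 0], [1.0, 1, 1])


class TestOptimizeThreshold:
    def test_constant_marker_not_ok(self, rng):
        t, e = random_survival(rng, 20)
        res = optimize_threshold(np.ones(20), t, e)
        assert not res.ok and res.threshold is None

    def test_group_size_constraint(self, rng):
        t, e = random_survival(rng, 10)
        values = rng.normal(size=10)
        res = optimize_threshold(values, t, e, min_frac=0.3)
        if res.ok:
            assert min(res.n_low, res.n_high) >= 3

    def test_time_tracking_marker_finds_protective_split(self, rng):
        # a marker strongly (not perfectly) tracking survival time: any
        # perfect copy makes the partial likelihood monotone, which is
        # flagged rather than reported as a split
        t = np.sort(rng.exponential(5, 20))
        e = np.ones(20, int)
        marker = 2.0 * t + rng.normal(0, 0.5, 20)
        res = optimize_threshold(marker, t, e)
        assert res.ok and res.hr < 1.0

    def test_matches_exhaustive_scan_oracle(self, rng):
        from oracles import exhaustive_threshold_scan

        for _ in range(10):
            n = int(rng.integers(15, 40))
            t, e = random_survival(rng, n)
            values = rng.normal(size=n)
            res = optimize_threshold(values, t, e)
            thr, metric = exhaustive_threshold_scan(values, t, e)
            if res.ok and thr is not None:
                assert res.threshold == pytest.approx(thr, abs=1e-12) or \
                    abs(np.log(res.hr)) == pytest.approx(metric, abs=1e-4)


class TestSelectionFilters:
    def make_results(self, rows):
        return pd.DataFrame(rows).set_index("id", drop=False)

    def test_pfs_filter_on_reported_tuples(self):
        res = self.make_results([
            {"id": "cd3g", "hr": 0.34, "hr_p": 0.0018},
            {"id": "pdl1_ihc", "hr": 0.66, "hr_p": 0.42},
            {"id": "edge", "hr": 0.30, "hr_p": 0.06},
            {"id": "risk", "hr": 3.1, "hr_p": 0.01},
        ])
        assert select_pfs_biomarkers(res) == ["cd3g", "risk"]

    def test_response_filter_on_reported_tuples(self):
        res = self.make_results([
            {"id": "gh_pathway", "auc": 0.72, "response_p": 0.01},
            {"id": "cd3g", "auc": 0.63, "response_p": 0.13},
            {"id": "highauc", "auc": 0.90, "response_p": 0.20},
        ])
        assert select_response_biomarkers(res) == ["gh_pathway"]

    def test_intersection_order_stable(self):
        assert intersect_biomarkers(["a", "b", "c"], ["c", "b", "d"]) == ["b", "c"]
        assert intersect_biomarkers(["a"], ["b"]) == []


class TestKM:
    def test_single_subject(self):
        curve = km_curve([3.0], [1])
        assert curve.at(2.9) == 1.0
        assert curve.at(3.0) == 0.0
        assert curve.median == 3.0

    def test_median_of_ten_events(self):
        curve = km_curve(np.arange(1, 11, dtype=float), np.ones(10, int))
        assert curve.median == 5.0

    def test_all_censored_flat_undefined_median(self):
        curve = km_curve([2.0, 4.0, 6.0], [0, 0, 0])
        assert np.isnan(curve.median)
        assert curve.at(6.0) == 1.0

    def test_matches_product_limit_oracle(self, rng):
        t, e = random_survival(rng, 25)
        t = np.round(t, 0) + 1  # force ties
        curve = km_curve(t, e)
        oracle = product_limit(t, e)
        for time, surv in oracle.items():
            assert curve.at(time) == pytest.approx(surv, abs=1e-12)


class TestScreenBiomarkers:
    def make_clinical(self, rng, n):
        t, e = random_survival(rng, n)
        return pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "histotype": rng.choice(["adenocarcinoma", "squamous"], n),
            "recist": rng.choice(["CR", "PR", "SD", "PD"], n, p=[0.1, 0.2, 0.3, 0.4]),
            "pfs_months": t,
            "event": e,
            "anti_pd1": 1, "anti_pdl1": 0, "anti_ctla4": 0,
        }).set_index("sample_id", drop=False)

    def test_output_schema_and_flags(self, rng):
        clinical = self.make_clinical(rng, 40)
        markers = pd.DataFrame(
            rng.normal(size=(3, 40)), index=["m1", "m2", "m3"], columns=clinical.index
        )
        markers.loc["m3"] = rng.integers(0, 2, 40)  # categorical
        res = screen_biomarkers(markers, clinical)
        for col in ["id", "kind", "hr", "hr_p", "threshold", "n_low", "n_high",
                    "auc", "response_p", "hr_p_bh", "response_p_bh",
                    "selected_pfs", "selected_response", "selected_both"]:
            assert col in res.columns
        assert res.loc["m3", "kind"] == "categorical"
        assert (res["selected_both"] == (res["selected_pfs"] & res["selected_response"])).all()

    def test_missing_recist_excluded_from_response_only(self, rng):
        clinical = self.make_clinical(rng, 30)
        clinical.loc[clinical.index[:10], "recist"] = np.nan
        markers = pd.DataFrame(
            rng.normal(size=(1, 30)), index=["m"], columns=clinical.index
        )
        res = screen_biomarkers(markers, clinical)
        # survival stats still computed on all 30 samples
        assert res.loc["m", "n_low"] + res.loc["m", "n_high"] == 30

    def test_auc_mw_consistency_with_u_statistic(self, rng):
        from scipy import stats as ss

        values = rng.choice(np.arange(8, dtype=float), size=30)
        labels = rng.integers(0, 2, 30).astype(bool)
        n1, n2 = labels.sum(), (~labels).sum()
        u = ss.mannwhitneyu(values[labels], values[~labels], alternative="two-sided").statistic
        assert roc_auc(values, labels) == pytest.approx(u / (n1 * n2), abs=1e-12)
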