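import numpy as np
import pandas as pd
import pytest

from immunomark.signature import (
    SignatureModel,
    apply_scaler,
    backward_eliminate,
    evaluate_signature,
    fit_logistic,
    minmax_scale,
    risk_score,
)

from conftest import random_survival
from oracles import gridsearch_logistic

# The five reference coefficients exercised by the risk-score checks.
REFERENCE_COEFFICIENTS = {
    "CD3G_expression": -1.79,
    "NCAM1_expression": -2.33,
    "adrenergic_signaling_pal": 1.22,
    "endothelins_pal": -3.95,
    "growth_hormone_signaling_pal": -7.18,
}


def reference_model():
    comps = list(REFERENCE_COEFFICIENTS)
    return SignatureModel(
        components=comps,
        scaler={c: (0.0, 1.0) for c in comps},
        coefficients=dict(REFERENCE_COEFFICIENTS),
        risk_threshold=0.0,
        orientation="lower_is_risk",
    )


class TestMinMax:
    def test_simple_row(self):
        scaled, scaler = minmax_scale(pd.DataFrame([[0.0, 5.0, 10.0]], index=["m"]))
        assert scaled.loc["m"].tolist() == [0.0, 0.5, 1.0]
        assert scaler.loc["m", "min"] == 0.0 and scaler.loc["m", "max"] == 10.0

    def test_stored_scaler_reproduces_training(self, rng):
        mat = pd.DataFrame(rng.normal(size=(4, 10)), index=list("abcd"))
        scaled, scaler = minmax_scale(mat)
        again = apply_scaler(mat, scaler)
        pd.testing.assert_frame_equal(scaled, again)

    def test_constant_row_names_biomarker(self):
        mat = pd.DataFrame([[1.0, 1.0], [0.0, 2.0]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            minmax_scale(mat)

    def test_out_of_range_passes_through_with_warning(self):
        train = pd.DataFrame([[0.0, 10.0]], index=["m"])
        _, scaler = minmax_scale(train)
        new = pd.DataFrame([[-5.0]], index=["m"])
        with pytest.warns(UserWarning, match="outside"):
            scaled = apply_scaler(new, scaler)
        assert scaled.iloc[0, 0] == pytest.approx(-0.5)

    def test_clip_flag(self):
        train = pd.DataFrame([[0.0, 10.0]], index=["m"])
        _, scaler = minmax_scale(train)
        scaled = apply_scaler(pd.DataFrame([[20.0]], index=["m"]), scaler, clip=True)
        assert scaled.iloc[0, 0] == 1.0


class TestLogistic:
    def test_null_feature_coefficient_near_zero(self, rng):
        X = rng.normal(size=(800, 1))
        y = rng.integers(0, 2, 800).astype(float)
        fit = fit_logistic(X, y)
        assert abs(fit.coef[0]) < 0.15

    def test_recovers_known_log_odds_vs_gridsearch(self, rng):
        x = rng.normal(size=120)
        p = 1 / (1 + np.exp(-(-0.5 + 1.3 * x)))
        y = (rng.uniform(size=120) < p).astype(float)
        fit = fit_logistic(x[:, None], y, ridge=0.0)
        b0, b1 = gridsearch_logistic(x, y)
        assert fit.intercept == pytest.approx(b0, abs=0.02)
        assert fit.coef[0] == pytest.approx(b1, abs=0.02)

    def test_label_flip_negates_coefficients(self, rng):
        X = rng.normal(size=(60, 2))
        y = rng.integers(0, 2, 60).astype(float)
        a = fit_logistic(X, y)
        b = fit_logistic(X, 1.0 - y)
        assert np.allclose(a.coef, -b.coef, atol=1e-6)

    def test_single_class_errors(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(rng.normal(size=(10, 1)), np.ones(10))

    def test_ridge_controls_separation(self):
        x = np.r_[np.zeros(5), np.ones(5)]
        y = x.copy()
        fit = fit_logistic(x[:, None], y, ridge=1e-4)
        assert np.isfinite(fit.coef[0])


class TestRiskScore:
    def test_zero_vector_scores_zero(self):
        model = reference_model()
        scaled = pd.DataFrame(0.0, index=model.components, columns=["s1"])
        assert risk_score(scaled, model)["s1"] == 0.0

    def test_unit_vectors_return_coefficients(self):
        model = reference_model()
        for comp, coef in REFERENCE_COEFFICIENTS.items():
            scaled = pd.DataFrame(0.0, index=model.components, columns=["s1"])
            scaled.loc[comp, "s1"] = 1.0
            assert risk_score(scaled, model)["s1"] == pytest.approx(coef, abs=1e-12)

    def test_all_ones_returns_coefficient_sum(self):
        model = reference_model()
        scaled = pd.DataFrame(1.0, index=model.components, columns=["s1"])
        assert risk_score(scaled, model)["s1"] == pytest.approx(-14.03, abs=1e-9)

    def test_missing_component_errors(self):
        model = reference_model()
        scaled = pd.DataFrame(0.0, index=model.components[:-1], columns=["s1"])
        with pytest.raises(KeyError, match="growth_hormone"):
            risk_score(scaled, model)

    def test_json_roundtrip_preserves_arithmetic(self, tmp_path):
        model = reference_model()
        model.to_json(tmp_path / "model.json")
        back = SignatureModel.from_json(tmp_path / "model.json")
        v1 = pd.DataFrame(
            [[0.2], [0.4], [0.6], [0.8], [1.0]], index=model.components, columns=["s"]
        )
        v2 = v1 * 0.5
        direct = risk_score(v1, model)["s"] - risk_score(v2, model)["s"]
        loaded = risk_score(v1, back)["s"] - risk_score(v2, back)["s"]
        assert direct == pytest.approx(loaded, abs=1e-12)

    def test_affine_in_each_component(self, rng):
        model = reference_model()
        base = pd.DataFrame(rng.uniform(size=(5, 1)), index=model.components, columns=["s"])
        for comp in model.components:
            bumped = base.copy()
            bumped.loc[comp] += 0.25
            delta = risk_score(bumped, model)["s"] - risk_score(base, model)["s"]
            assert delta == pytest.approx(0.25 * model.coefficients[comp], abs=1e-12)


def synthetic_signature_cohort(seed, n=120, n_markers=6, informative=3):
    """Markers with planted joint response/hazard effects for elimination tests."""
    rng = np.random.default_rng(seed)
    ids = [f"m{i}" for i in range(n_markers)]
    samples = [f"s{i}" for i in range(n)]
    values = rng.normal(size=(n_markers, n))
    effect = np.zeros(n_markers)
    effect[:informative] = -1.0
    log_h = np.log(0.1) + effect @ values
    t_event = rng.exponential(1.0, n) / np.exp(log_h)
    t_cens = rng.uniform(0, 30, n)
    pfs = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    lin = (-1.5 * effect) @ values  # protective markers also predict response
    p = 1 / (1 + np.exp(-(lin - 1.0)))
    resp = rng.uniform(size=n) < p
    clinical = pd.DataFrame({
        "sample_id": samples,
        "histotype": "adenocarcinoma",
        "recist": np.where(resp, "PR", "PD"),
        "pfs_months": pfs,
        "event": event,
        "anti_pd1": 1, "anti_pdl1": 0, "anti_ctla4": 0,
    }).set_index("sample_id", drop=False)
    markers = pd.DataFrame(values, index=ids, columns=samples)
    return markers, clinical


class TestBackwardElimination:
    def test_termination_with_two_candidates(self, rng):
        markers, clinical = synthetic_signature_cohort(0, n=80, n_markers=2, informative=2)
        model, trace = backward_eliminate(markers, clinical)
        assert len(model.components) == 2
        assert sum(s.accepted for s in trace) == 0

    def test_trace_bounded_by_input_size(self):
        markers, clinical = synthetic_signature_cohort(1, n=100, n_markers=8, informative=4)
        model, trace = backward_eliminate(markers, clinical)
        assert len(trace) <= 7
        assert len(model.components) + sum(s.accepted for s in trace) == 8

    def test_deterministic(self):
        markers, clinical = synthetic_signature_cohort(2, n=100, n_markers=5)
        m1, t1 = backward_eliminate(markers, clinical)
        m2, t2 = backward_eliminate(markers, clinical)
        assert m1.components == m2.components
        assert m1.coefficients == m2.coefficients
        assert [s.removed for s in t1] == [s.removed for s in t2]

    def test_model_is_serializable(self, tmp_path):
        markers, clinical = synthetic_signature_cohort(3, n=100, n_markers=5)
        model, _ = backward_eliminate(markers, clinical)
        model.to_json(tmp_path / "m.json")
        back = SignatureModel.from_json(tmp_path / "m.json")
        assert back.components == model.components


class TestEvaluate:
    def test_training_closure(self):
        markers, clinical = synthetic_signature_cohort(4, n=100, n_markers=5)
        model, trace = backward_eliminate(markers, clinical)
        report = evaluate_signature(model, markers, clinical)
        accepted_hrs = [s.hr for s in trace if s.accepted]
        final_hr = accepted_hrs[-1] if accepted_hrs else None
        if final_hr is not None:
            assert report["hr"] == pytest.approx(final_hr, rel=1e-9)
        assert "auc" in report

    def test_single_sample_scores_only(self):
        markers, clinical = synthetic_signature_cohort(5, n=100, n_markers=5)
        model, _ = backward_eliminate(markers, clinical)
        report = evaluate_signature(model, markers.iloc[:, :1], clinical.iloc[:1])
        assert len(report["scores"]) == 1
        assert "hr" not in report and "auc" not in report

    def test_missing_pfs_gives_auc_only(self):
        markers, clinical = synthetic_signature_cohort(6, n=100, n_markers=5)
        model, _ = backward_eliminate(markers, clinical)
        clin2 = clinical.copy()
        clin2["pfs_months"] = np.nan
        clin2["event"] = np.nan
        with pytest.warns(UserWarning):
            report = evaluate_signature(model, markers * 1.5, clin2)
        assert "auc" in report and "hr" not in report

    def test_validation_cohort_auc_close_to_training(self):
        # fresh draw from the same generative model: AUC within +-0.1 of
        # training over a handful of seeds (simulation consistency)
        markers, clinical = synthetic_signature_cohort(7, n=150, n_markers=5)
        model, _ = backward_eliminate(markers, clinical)
        train_auc = evaluate_signature(model, markers, clinical)["auc"]
        diffs = []
        for seed in range(100, 105):
            vmarkers, vclinical = synthetic_signature_cohort(seed, n=150, n_markers=5)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report = evaluate_signature(model, vmarkers, vclinical)
            diffs.append(abs(report["auc"] - train_auc))
        assert np.median(diffs) < 0.12
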