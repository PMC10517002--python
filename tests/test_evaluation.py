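"""Evaluation metrics, the feature GLM, and detector comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from ratseiz import (
    AnnotationTrack,
    SeizureEvent,
    ValidationError,
    compare_detectors,
    evaluate,
    evaluate_events,
    fit_segment_glm,
)

B, I = "BASELINE", "ICTAL"


def grid_labels(track, n):
    return [
        I if track.overlap(2.0 * i, 2.0 * i + 2.0) > 1.0 else B for i in range(n)
    ]


class TestEvaluate:
    def test_hand_counted_metrics(self):
        track = AnnotationTrack(((10.0, 20.0),))
        duration = 200.0  # 100 segments
        truth = grid_labels(track, 100)
        pred = list(truth)
        # introduce 3 errors on baseline segments
        flips = [0, 1, 2]
        for f in flips:
            pred[f] = I
        report = evaluate({"ch": pred}, [], track, duration)
        assert report.overall_accuracy == pytest.approx(0.97)
        assert report.ictal_segment_accuracy == pytest.approx(1.0)

    def test_fp_per_hour(self):
        track = AnnotationTrack()
        dets = [SeizureEvent(10.0 + 100 * k, 16.0 + 100 * k) for k in range(3)]
        n = int(7200 // 2)
        report = evaluate({"ch": [B] * n}, dets, track, 7200.0)
        assert report.fp_per_hour == pytest.approx(1.5)
        assert report.fp_fraction == pytest.approx(1.0)

    def test_sensitivity_fraction(self):
        refs = tuple((100.0 * k, 100.0 * k + 10.0) for k in range(20))
        track = AnnotationTrack(refs)
        dets = [SeizureEvent(on, off) for on, off in refs[:18]]
        report = evaluate_events(dets, track, 2000.0)
        assert report.seizure_sensitivity == pytest.approx(0.9)

    def test_invariant_to_detection_order(self):
        track = AnnotationTrack(((10.0, 20.0), (50.0, 60.0)))
        dets = [SeizureEvent(12.0, 16.0), SeizureEvent(52.0, 58.0), SeizureEvent(80.0, 86.0)]
        a = evaluate_events(dets, track, 200.0)
        b = evaluate_events(dets[::-1], track, 200.0)
        assert a.to_dict() == b.to_dict()

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            evaluate({"ch": [B] * 3}, [], AnnotationTrack(), 10.0)


def simulate_logistic(n, seed, beta_h=-40.0, beta_k=0.3, beta_ll=0.0, intercept=2.0):
    # entropy drawn in the low, ictal-like range so the steep entropy effect
    # leaves both classes populated
    rng = np.random.default_rng(seed)
    h = rng.uniform(0.02, 0.15, n)
    k = rng.gamma(6.0, 0.7, n)
    ll = rng.normal(40000.0, 8000.0, n)
    logit = intercept + beta_h * h + beta_k * k + beta_ll * ll
    y = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
    table = pd.DataFrame({"kurtosis": k, "entropy": h, "line_length": ll})
    labels = [I if v else B for v in y]
    return table, labels


class TestGLM:
    def test_parameter_recovery_on_simulated_segments(self):
        """Recover the generating coefficients; line length stays null."""
        table, labels = simulate_logistic(10_000, seed=12345)
        fit = fit_segment_glm(table, labels)
        assert fit.coef_entropy == pytest.approx(-40.0, rel=0.2)
        assert fit.coef_kurtosis == pytest.approx(0.3, rel=0.2)
        assert fit.pvalues["entropy"] < 0.01
        assert fit.pvalues["kurtosis"] < 0.01
        assert fit.pvalues["line_length"] > 0.01
        # LogWorth definition (-log10 p) checked on a term whose p-value
        # does not underflow to zero
        assert fit.logworth["line_length"] == pytest.approx(
            -math.log10(fit.pvalues["line_length"]), abs=1e-9
        )
        assert fit.logworth["entropy"] > 2.0

    def test_null_features_rarely_reach_high_logworth(self):
        table, _ = simulate_logistic(2000, seed=99)
        rng = np.random.default_rng(5)
        labels = [I if v else B for v in rng.random(2000) < 0.3]
        fit = fit_segment_glm(table, labels)
        assert max(
            fit.logworth[k] for k in ("kurtosis", "entropy", "line_length")
        ) < 3.0

    def test_matches_newton_irls_oracle_on_tiny_data(self):
        """Independent Newton iteration reproduces the fitted coefficients."""
        table, labels = simulate_logistic(400, seed=3, beta_h=-4.0, beta_k=0.2,
                                          beta_ll=0.0, intercept=1.0)
        # standardize line length so the oracle's Hessian is well conditioned
        table = table.assign(line_length=table["line_length"] / 1e4)
        fit = fit_segment_glm(table, labels)
        X = np.column_stack(
            [np.ones(len(table)), table["kurtosis"], table["entropy"], table["line_length"]]
        )
        y = np.array([1.0 if l == I else 0.0 for l in labels])
        beta = np.zeros(4)
        for _ in range(50):
            p = 1.0 / (1.0 + np.exp(-X @ beta))
            W = p * (1 - p)
            grad = X.T @ (y - p)
            hess = (X * W[:, None]).T @ X
            step = np.linalg.solve(hess, grad)
            beta = beta + step
            if np.max(np.abs(step)) < 1e-12:
                break
        got = [fit.intercept, fit.coef_kurtosis, fit.coef_entropy, fit.coef_linelength]
        np.testing.assert_allclose(got, beta, atol=1e-6)

    def test_single_class_rejected(self):
        table, _ = simulate_logistic(50, seed=1)
        with pytest.raises(ValidationError):
            fit_segment_glm(table, [I] * 50)

    def test_constant_feature_dropped_with_warning(self):
        table, labels = simulate_logistic(500, seed=2, beta_h=-4.0)
        table = table.assign(line_length=1.0)
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_segment_glm(table, labels)
        assert math.isnan(fit.coef_linelength)
        assert fit.dropped == ("line_length",)


class TestCompare:
    def test_identical_reports_have_zero_differences(self):
        track = AnnotationTrack(((10.0, 20.0),))
        r = evaluate_events([SeizureEvent(11.0, 15.0)], track, 100.0)
        table = compare_detectors(r, r)
        assert np.allclose(table["difference"], 0.0)

    def test_sensitivity_difference(self):
        refs = tuple((100.0 * k, 100.0 * k + 10.0) for k in range(10))
        track = AnnotationTrack(refs)
        a = evaluate_events([SeizureEvent(on, off) for on, off in refs[:9]], track, 2000.0)
        b = evaluate_events([SeizureEvent(on, off) for on, off in refs[:4]], track, 2000.0)
        table = compare_detectors(a, b).set_index("metric")
        assert table.loc["seizure_sensitivity", "difference"] == pytest.approx(0.5)

    def test_mismatched_references_rejected(self):
        a = evaluate_events([], AnnotationTrack(((10.0, 20.0),)), 100.0)
        b = evaluate_events([], AnnotationTrack(((10.0, 30.0),)), 100.0)
        with pytest.raises(ValidationError):
            compare_detectors(a, b)
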