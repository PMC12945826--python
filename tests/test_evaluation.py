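"""Tests for the evaluation protocol: metrics, AUC, latency sweep, baselines."""

import numpy as np
import pytest

from respmotion.evaluation import (
    accuracy_from_confusion,
    aggregate_residuals,
    confusion_matrix,
    dump_residuals,
    latency_sweep,
    mae,
    precision_recall_f1,
    psnr,
    reference_predictor,
    rmse,
    roc_auc_ovr,
)
from respmotion.preprocess import WindowSpec, make_windows
from respmotion.siggen import MotionLabel, RespiratorySignal


class TestPrecisionRecallF1:
    def test_direct_arithmetic(self):
        cm = np.zeros((4, 4), dtype=int)
        cm[0, 0] = 9   # TP
        cm[1, 0] = 1   # FP for class 0
        cm[0, 1] = 1   # FN for class 0
        p, r, f1, _ = precision_recall_f1(cm)
        assert p[0] == pytest.approx(0.9)
        assert r[0] == pytest.approx(0.9)
        assert f1[0] == pytest.approx(0.9)

    def test_diagonal_matrix_is_perfect(self):
        cm = np.diag([5, 3, 2, 7])
        p, r, f1, deg = precision_recall_f1(cm)
        assert np.all(p == 1.0) and np.all(r == 1.0) and np.all(f1 == 1.0)
        assert not deg.any()

    def test_zero_over_zero_flagged(self):
        cm = np.zeros((4, 4), dtype=int)
        cm[0, 1] = 5   # class 0: TP=0, FN=5; class 1: FP=5
        p, r, f1, deg = precision_recall_f1(cm)
        assert p[0] == 0.0 and r[0] == 0.0 and f1[0] == 0.0
        assert deg[0]

    def test_rejects_negative_counts(self):
        cm = np.zeros((4, 4), dtype=int)
        cm[0, 0] = -1
        with pytest.raises(ValueError):
            precision_recall_f1(cm)

    def test_accuracy_is_trace_over_total(self):
        rng = np.random.default_rng(0)
        cm = rng.integers(0, 20, (4, 4))
        assert accuracy_from_confusion(cm) == pytest.approx(
            np.trace(cm) / cm.sum()
        )

    def test_f1_harmonic_mean_identity(self):
        rng = np.random.default_rng(1)
        cm = rng.integers(1, 30, (4, 4))
        p, r, f1, _ = precision_recall_f1(cm)
        np.testing.assert_allclose(f1, 2 * p * r / (p + r), atol=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        aucs = roc_auc_ovr(scores, labels, n_classes=2)
        assert aucs == [1.0, 1.0]

    def test_constant_scores_give_half(self):
        labels = np.array([0, 1, 0, 1, 2, 3])
        scores = np.full((6, 4), 0.25)
        aucs = roc_auc_ovr(scores, labels)
        assert all(a == pytest.approx(0.5) for a in aucs)

    def test_single_class_reported_missing(self):
        labels = np.zeros(5, dtype=int)
        scores = np.random.default_rng(0).random((5, 4))
        aucs = roc_auc_ovr(scores, labels)
        assert aucs[1] is None and aucs[0] is None  # no negatives for class 0

    def test_matches_all_pairs_counting_oracle(self):
        rng = np.random.default_rng(9)
        n = 50
        labels = rng.integers(0, 4, n)
        scores = rng.random((n, 4))
        aucs = roc_auc_ovr(scores, labels)
        for c in range(4):
            pos = np.flatnonzero(labels == c)
            neg = np.flatnonzero(labels != c)
            wins = 0.0
            for i in pos:
                for j in neg:
                    if scores[i, c] > scores[j, c]:
                        wins += 1.0
                    elif scores[i, c] == scores[j, c]:
                        wins += 0.5
            oracle = wins / (len(pos) * len(neg))
            assert abs(aucs[c] - oracle) < 1e-12


class TestRmseMaePsnr:
    def test_identical_arrays_zero(self):
        x = np.arange(10.0)
        assert rmse(x, x) == 0.0 and mae(x, x) == 0.0

    def test_unit_error(self):
        assert rmse([0, 0], [1, 1]) == pytest.approx(1.0)
        assert mae([0, 0], [1, 1]) == pytest.approx(1.0)

    def test_matches_elementwise_loop_oracle(self):
        rng = np.random.default_rng(4)
        a, b = rng.random(40), rng.random(40)
        sq = sum((x - y) ** 2 for x, y in zip(a, b)) / len(a)
        ab = sum(abs(x - y) for x, y in zip(a, b)) / len(a)
        assert abs(rmse(a, b) - np.sqrt(sq)) < 1e-12
        assert abs(mae(a, b) - ab) < 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse(np.zeros(3), np.zeros(4))

    def test_psnr_closed_form(self):
        ref = np.zeros(100)
        test = np.full(100, 0.1)           # MSE = 0.01, max 1 -> 20 dB
        assert psnr(ref, test, 1.0).db == pytest.approx(20.0)

    def test_psnr_identical_flagged_infinite(self):
        x = np.arange(5.0)
        res = psnr(x, x, 10.0)
        assert res.infinite and np.isinf(res.db)

    def test_psnr_full_scale_error_zero_db(self):
        ref = np.zeros(10)
        test = np.full(10, 255.0)
        assert psnr(ref, test, 255.0).db == pytest.approx(0.0)


def _sine_dataset(omega=2 * np.pi / 4.0, fs=20.0, n=2400):
    """Noise-free unit-amplitude sine windowed into supervised examples."""
    t = np.arange(n) / fs
    x = np.sin(omega * t)
    samples = np.repeat(x[:, None], 3, axis=1)
    sig = RespiratorySignal("P0S0", samples, fs, n / fs, clean_samples=samples.copy())
    label = MotionLabel.from_amplitudes((2.0, 2.0, 2.0))
    return make_windows(sig, label, WindowSpec(stride=7)), omega, fs


class TestLatencySweepAndBaselines:
    def test_persistence_on_sine_matches_closed_form(self):
        ds, omega, fs = _sine_dataset()
        report = latency_sweep(reference_predictor("persistence"), ds)
        # the sine normalizes to 0.5 + 0.5 sin(.); for a unit sine the
        # persistence error RMS over uniform phase is sqrt(1 - cos(omega h dt)),
        # so the normalized amplitude scales it by 0.5
        for j, h in enumerate(ds.horizons):
            expected = 0.5 * np.sqrt(1.0 - np.cos(omega * h / fs))
            assert abs(report.rmse_mean_axes_per_horizon[j] - expected) < 1e-3

    def test_persistence_zero_error_on_constant(self):
        pred = reference_predictor("persistence")
        w = np.full((5, 20, 3), 0.7)
        out = pred(w, (1, 3))
        assert np.all(out == 0.7)

    def test_linear_extrapolation_exact_on_line(self):
        pred = reference_predictor("linear_extrapolation")
        t = np.arange(20.0)
        w = np.repeat((0.01 * t)[None, :, None], 3, axis=2)
        out = pred(w, (1, 5))
        expected_h1 = 0.01 * 20
        assert out[0, 0, 0] == pytest.approx(expected_h1)
        assert out[0, 0, 1] == pytest.approx(0.01 * 24)

    def test_unknown_predictor_rejected(self):
        with pytest.raises(ValueError):
            reference_predictor("oracle")

    def test_report_recomputable_from_residuals(self, tmp_path):
        ds, _, _ = _sine_dataset()
        report, residuals = latency_sweep(
            reference_predictor("persistence"), ds, return_residuals=True
        )
        agg = aggregate_residuals(residuals)
        np.testing.assert_allclose(
            agg["rmse_per_axis_per_horizon"],
            report.rmse_per_axis_per_horizon, atol=1e-12,
        )
        np.testing.assert_allclose(
            agg["rmse_mean_axes_per_horizon"],
            report.rmse_mean_axes_per_horizon, atol=1e-12,
        )
        # and from a CSV dump round trip
        import pandas as pd

        path = tmp_path / "residuals.csv"
        dump_residuals(residuals, ds.record_ids, ds.window_starts, path)
        df = pd.read_csv(path)
        re_rmse = np.sqrt(
            df.groupby(["axis", "horizon_index"])["residual"]
            .apply(lambda s: np.mean(s**2))
            .to_numpy()
        ).reshape(3, len(ds.horizons))
        np.testing.assert_allclose(re_rmse, report.rmse_per_axis_per_horizon,
                                   atol=1e-9)

    def test_empty_test_set_rejected(self):
        ds, _, _ = _sine_dataset()
        empty = ds.subset(np.array([], dtype=int))
        with pytest.raises(ValueError):
            latency_sweep(reference_predictor("persistence"), empty)

    def test_report_json_round_trip(self):
        ds, _, _ = _sine_dataset()
        report = latency_sweep(reference_predictor("persistence"), ds)
        from respmotion.evaluation import EvaluationReport

        rt = EvaluationReport.from_json(report.to_json())
        np.testing.assert_allclose(rt.rmse_per_axis_per_horizon,
                                   report.rmse_per_axis_per_horizon)
        assert rt.latency_bins == report.latency_bins


class TestConfusionMatrix:
    def test_counts_and_invariants(self):
        y_true = [0, 0, 1, 2, 3, 3]
        y_pred = [0, 1, 1, 2, 3, 2]
        cm = confusion_matrix(y_true, y_pred)
        assert cm.sum() == 6
        assert cm[0, 0] == 1 and cm[0, 1] == 1 and cm[3, 2] == 1
        # row sum equals TP + FN for every class
        for c in range(4):
            tp = cm[c, c]
            fn = cm[c].sum() - tp
            assert tp + fn == cm[c].sum()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 5], [0, 1])
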