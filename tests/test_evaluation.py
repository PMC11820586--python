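"""Metrics, QRS detection and peak matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import optimal_matching_count
from fecgnet.evaluation import (
    DetectionResult,
    MetricsReport,
    aggregate,
    detection_jaccard,
    detection_scores,
    evaluate_record,
    extract_record,
    match_peaks,
    pan_tompkins,
    signal_metrics,
)
from fecgnet.preprocess import bandpass_3_100, resample_to_250
from fecgnet.synthgen import ScenarioSpec, make_scenario_record


class TestSignalMetrics:
    def test_perfect_prediction(self, rng):
        y = rng.normal(size=100)
        mse, mae, snr = signal_metrics(y, y)
        assert mse == 0.0 and mae == 0.0 and np.isinf(snr)

    def test_half_amplitude_gives_6db(self, rng):
        y = rng.normal(size=1000)
        _, _, snr = signal_metrics(y, y / 2)
        assert snr == pytest.approx(10 * np.log10(4), abs=1e-9)

    def test_hand_computed_case(self):
        mse, mae, snr = signal_metrics([1.0, -1.0], [0.0, 0.0])
        assert (mse, mae, snr) == (1.0, 1.0, 0.0)

    def test_all_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            signal_metrics(np.zeros(10), np.ones(10))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            signal_metrics(np.zeros(10), np.zeros(11))

    def test_snr_monotone_in_noise_power(self, rng):
        y = rng.normal(size=2000)
        snrs = [signal_metrics(y, y + s * rng.normal(size=2000))[2]
                for s in (0.1, 0.3, 1.0, 3.0)]
        assert all(a > b for a, b in zip(snrs, snrs[1:]))


class TestPanTompkins:
    def test_clean_fetal_detection(self, clean_fetal_record):
        rec = clean_fetal_record
        det = pan_tompkins(rec.signals[0], rec.fs, "fetal")
        res = match_peaks(det, rec.rpeaks_fetal, rec.fs)
        se, ppv, _ = detection_scores(res)
        assert se >= 99.0 and ppv >= 99.0

    def test_clean_maternal_beat_count(self, clean_maternal_record):
        rec = clean_maternal_record
        det = pan_tompkins(rec.signals[0], rec.fs, "maternal")
        assert abs(det.size - 80) <= 1

    def test_all_zero_signal_gives_no_peaks(self):
        assert pan_tompkins(np.zeros(2500), 250.0, "fetal").size == 0

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="2 s"):
            pan_tompkins(np.zeros(100), 250.0, "fetal")

    def test_unknown_profile_rejected(self):
        with pytest.raises(ValueError, match="profile"):
            pan_tompkins(np.zeros(2500), 250.0, "adult")


class TestMatchPeaks:
    def test_exact_match(self):
        truth = np.array([100, 300, 500])
        res = match_peaks(truth, truth, 250.0)
        assert (res.tp, res.fp, res.fn) == (3, 0, 0)

    def test_within_tolerance_counts(self):
        # 10 ms at 250 Hz = 2.5 samples
        res = match_peaks([102], [100], 250.0)
        assert res.tp == 1

    def test_two_predictions_one_truth(self):
        res = match_peaks([98, 103], [100], 250.0)
        assert (res.tp, res.fp, res.fn) == (1, 1, 0)
        assert res.matches == [(98, 100)]  # closer one wins

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            match_peaks([300, 100], [100], 250.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_counts_conserved_and_greedy_is_optimal(self, seed):
        """TP+FN = |truth|, TP+FP = |pred|; greedy matches the exhaustive
        optimum when true beats are separated by at least twice the
        tolerance (the refractory period guarantees this physiologically)."""
        rng = np.random.default_rng(seed)
        fs, tol_s = 250.0, 0.03125
        n_t = rng.integers(0, 8)
        gaps = rng.integers(int(2 * tol_s * fs) + 1, 200, size=n_t)
        truth = np.cumsum(gaps) + 50 if n_t else np.empty(0, int)
        n_p = rng.integers(0, 8)
        pred = np.sort(rng.integers(0, 1500, size=n_p))
        res = match_peaks(pred, truth, fs, tol_s)
        assert res.tp + res.fn == len(truth)
        assert res.tp + res.fp == len(pred)
        assert res.tp == optimal_matching_count(pred, truth, tol_s * fs)
        for p, t in res.matches:
            assert abs(p - t) <= tol_s * fs


class TestDetectionScores:
    def test_perfect_scores(self):
        se, ppv, f1 = detection_scores(DetectionResult(100, 0, 0))
        assert (se, ppv, f1) == (100.0, 100.0, 100.0)

    def test_harmonic_mean_vs_literal_overlap(self):
        res = DetectionResult(tp=90, fp=10, fn=10)
        se, ppv, f1 = detection_scores(res)
        assert (se, ppv, f1) == (90.0, 90.0, 90.0)
        assert detection_jaccard(res) == pytest.approx(81.82, abs=0.005)

    def test_empty_denominators_rejected(self):
        with pytest.raises(ValueError):
            detection_scores(DetectionResult(0, 5, 0))
        with pytest.raises(ValueError):
            detection_scores(DetectionResult(0, 0, 5))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(tp=st.integers(1, 500), fp=st.integers(0, 200),
           fn=st.integers(0, 200))
    def test_f1_between_se_and_ppv_and_dominates_jaccard(self, tp, fp, fn):
        res = DetectionResult(tp, fp, fn)
        se, ppv, f1 = detection_scores(res)
        assert min(se, ppv) - 1e-9 <= f1 <= max(se, ppv) + 1e-9
        assert detection_jaccard(res) <= f1 + 1e-9


class _IdentityModel:
    """Pass-through stand-in: predicts the mixture for both branches."""

    def predict(self, segments):
        segs = np.asarray(segments)
        return segs.copy(), segs.copy()


class TestEvaluateRecord:
    def test_full_report_on_synthetic_record(self, mixture_record):
        rep = evaluate_record(mixture_record, _IdentityModel())
        assert rep.mse is not None and rep.snr_db is not None
        assert rep.n_true_beats > 0

    def test_annotations_only_record(self, mixture_record):
        from dataclasses import replace
        rec = replace(mixture_record,
                      signals=mixture_record.signals[:1].copy(),
                      channel_roles=["abdominal_mixture"])
        rep = evaluate_record(rec, _IdentityModel())
        assert rep.mse is None and rep.snr_db is None
        assert rep.se_pct is not None

    def test_no_truth_no_annotations_rejected(self, rng):
        from fecgnet.signal_io import Record
        rec = Record(rng.normal(size=(1, 5000)), 250.0, ["abdominal_mixture"])
        with pytest.raises(ValueError, match="neither"):
            evaluate_record(rec, _IdentityModel())

    def test_identity_model_recovers_intrinsic_snr(self, noise_free_record):
        """Extraction SNR of the pass-through model equals the mixture's own
        fetal SNR computed directly on the conditioned channels."""
        from dataclasses import replace
        rec = noise_free_record
        rep = evaluate_record(rec, _IdentityModel())
        proc = replace(rec, signals=np.stack(
            [bandpass_3_100(ch, rec.fs) for ch in rec.signals]))
        proc = resample_to_250(proc)
        _, _, snr_direct = signal_metrics(proc.channel("fetal_truth"),
                                          proc.channel("abdominal_mixture"))
        assert rep.snr_db == pytest.approx(snr_direct, abs=0.2)

    def test_extract_record_output_lengths(self, mixture_record):
        out = extract_record(mixture_record, _IdentityModel())
        assert out.channel("fecg_pred").size == mixture_record.n_samples
        assert out.fs == 250.0


class TestAggregate:
    def test_published_style_mean_rows(self):
        reports = [MetricsReport(mse=m, snr_db=s) for m, s in
                   zip([0.019, 0.024, 0.031, 0.025, 0.027],
                       [9.08, 7.17, 7.94, 8.41, 7.53])]
        agg = aggregate(reports)
        assert round(agg["mse"], 3) == 0.025
        assert round(agg["snr_db"], 2) == 8.03

    def test_single_report_zero_std(self):
        agg = aggregate([MetricsReport(mse=0.5, se_pct=90.0, ppv_pct=80.0,
                                       f1_pct=84.7)])
        assert agg["mse"] == 0.5
        assert agg["mse_std"] == 0.0

    def test_pooled_sums_counts_before_scoring(self):
        reports = [MetricsReport(tp=50, fp=0, fn=50),
                   MetricsReport(tp=100, fp=0, fn=0)]
        agg = aggregate(reports, mode="pooled")
        assert agg["se_pct"] == pytest.approx(75.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])
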