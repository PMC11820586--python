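"""Reference experiments at desk scale.

These functions wire the whole pipeline together — synthesize a dataset,
train a 1/8-width network for a few epochs on one CPU, and score extraction
and fetal QRS detection on held-out records.  They exist so the package's
headline behaviour (how much the network cleans up the fetal component, and
how well Pan–Tompkins recovers fetal beats afterwards) can be reproduced
with one call.
"""

from __future__ import annotations

import tempfile
from dataclasses import replace

import numpy as np

from .evaluation import (
    aggregate,
    detection_scores,
    evaluate_record,
    match_peaks,
    pan_tompkins,
    signal_metrics,
)
from .preprocess import bandpass_3_100, resample_to_250
from .r2wnet import AttentionR2WNet
from .synthgen import (
    FETAL_MORPHOLOGY,
    ScenarioSpec,
    make_dataset,
    make_scenario_record,
    synth_single_ecg,
)
from .training import TrainConfig, desk_network_config, train

__all__ = ["desk_extraction_experiment", "pan_tompkins_sanity",
           "input_fetal_snr"]


def input_fetal_snr(record) -> float:
    """Fetal SNR of the conditioned abdominal mixture itself (dB)."""
    proc = replace(record, signals=np.stack(
        [bandpass_3_100(ch, record.fs) for ch in record.signals]))
    proc = resample_to_250(proc)
    _, _, snr = signal_metrics(proc.channel("fetal_truth"),
                               proc.channel("abdominal_mixture"))
    return snr


def desk_extraction_experiment(train_seed: int, data_seed: int = 11,
                               n_train_records: int = 22,
                               n_eval_records: int = 5,
                               epochs: int = 10,
                               duration_s: float = 60.0,
                               work_dir=None) -> dict:
    """Train the desk-scale network on C0/6 dB mixtures and score it.

    Returns mean held-out metrics: input and output fetal SNR (dB), the
    improvement, detection SE/PPV/F1 (%), and extraction MSE/MAE, plus the
    problem sizes used.
    """
    work_dir = work_dir or tempfile.mkdtemp(prefix="fecgnet_desk_")
    spec = ScenarioSpec(scenario="C0", noise_snr_db=6.0, seed=data_seed)
    manifest = make_dataset(n_train_records, [spec], work_dir,
                            duration_s=duration_s)
    model = AttentionR2WNet(desk_network_config(), seed=train_seed)
    cfg = TrainConfig.desk(epochs=epochs, seed=train_seed)
    model, history = train(model, manifest, cfg)

    reports, snr_in = [], []
    for k in range(n_eval_records):
        rec = make_scenario_record(
            replace(spec, seed=900_000 + 37 * data_seed + k), duration_s, 250)
        snr_in.append(input_fetal_snr(rec))
        reports.append(evaluate_record(rec, model))
    agg = aggregate(reports)
    out = {
        "snr_in_db": float(np.mean(snr_in)),
        "snr_out_db": agg["snr_db"],
        "snr_improvement_db": agg["snr_db"] - float(np.mean(snr_in)),
        "se_pct": agg["se_pct"],
        "ppv_pct": agg["ppv_pct"],
        "f1_pct": agg["f1_pct"],
        "mse": agg["mse"],
        "mae": agg["mae"],
        "final_train_loss": history.train_loss[-1],
        "n_eval_records": n_eval_records,
        "n_train_records": n_train_records,
        "epochs": epochs,
    }
    return out


def pan_tompkins_sanity(seed: int = 5, hr_bpm: float = 140.0,
                        duration_s: float = 60.0) -> dict:
    """Recall/precision of the QRS detector on a clean synthetic fetal ECG."""
    rec = synth_single_ecg(hr_bpm, duration_s, 250, FETAL_MORPHOLOGY,
                           rr_jitter_pct=3.0, seed=seed)
    detected = pan_tompkins(rec.signals[0], rec.fs, profile="fetal")
    res = match_peaks(detected, rec.rpeaks_fetal, rec.fs)
    se, ppv, f1 = detection_scores(res)
    return {"recall_pct": se, "precision_pct": ppv, "f1_pct": f1,
            "n_beats": int(rec.rpeaks_fetal.size)}
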