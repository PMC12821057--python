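"""End-to-end helpers: cohort -> model-ready dataset -> cross-validated runs.

These functions wire the modules together the way the experiments use them:
band-pass filter each record, detect R peaks, cut the middle synchronized
beat, attach landmarks (simulator ground truth when available), and bundle
beats + scalars + targets into a :class:`~elvmass.train_eval.ModelDataset`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_cohort import CohortRow, EcgRecord
from .model import ModelSpec
from .preprocess import (DEFAULT_BEAT_WINDOW, annotate_landmarks,
                         bandpass_filter, detect_r_peaks,
                         extract_single_beat, SignalQualityError)
from .synth import SyntheticCohort
from .train_eval import (EvalReport, FoldSplit, ModelDataset, TrainConfig,
                         evaluate, lvh_metrics, make_folds, predict_dataset,
                         train_fold)


def scalar_frame(rows: list[CohortRow]) -> pd.DataFrame:
    """Model scalar features from cohort rows (sex coded male=1/female=0)."""
    data = {
        "age": [r.age for r in rows],
        "sex_male": [1.0 if r.sex == "male" else 0.0 for r in rows],
        "height": [r.height for r in rows],
        "weight": [r.weight for r in rows],
        "qrs_duration": [r.qrs_duration for r in rows],
        "p_axis": [r.p_axis for r in rows],
        "r_axis": [r.r_axis for r in rows],
        "t_axis": [r.t_axis for r in rows],
    }
    return pd.DataFrame(data)


def beats_from_records(records: list[EcgRecord],
                       fiducials: list | None = None,
                       window: tuple[float, float] = DEFAULT_BEAT_WINDOW,
                       band: tuple[float, float] = (0.5, 40.0)):
    """Filter, detect (or take true) R peaks, and cut the middle beat.

    Returns ``(beats, landmarks, kept)``: an (n x 12 x W) array, a per-beat
    landmark dict list (r_index plus segment boundaries, window-relative),
    and the indices of records that produced a usable beat.
    """
    beats, landmarks, kept = [], [], []
    for i, rec in enumerate(records):
        filtered = bandpass_filter(rec, *band)
        try:
            if fiducials is not None:
                peaks = np.asarray(fiducials[i]["r_peaks"], dtype=int)
            else:
                peaks = detect_r_peaks(filtered)
            seg = extract_single_beat(filtered, peaks, window=window)
        except SignalQualityError:
            continue
        if fiducials is not None:
            # translate the chosen beat's true landmarks into the window
            w_start = seg.r_record_index - seg.r_index
            truth = None
            for b in fiducials[i]["beats"]:
                if b["r_peak"] == seg.r_record_index:
                    cand = {k: b[k] - w_start for k in
                            ("p_onset", "qrs_onset", "qrs_offset", "t_offset")}
                    if cand["p_onset"] >= 0 and cand["t_offset"] < seg.width:
                        truth = cand
                    break
            seg = annotate_landmarks(seg, truth=truth)
        else:
            seg = annotate_landmarks(seg)
        lm = dict(seg.landmarks)
        lm["r_index"] = seg.r_index
        beats.append(seg.waveform)
        landmarks.append(lm)
        kept.append(i)
    if not beats:
        raise SignalQualityError("no usable beats in any record")
    return np.stack(beats), landmarks, np.array(kept, dtype=int)


def dataset_from_cohort(cohort: SyntheticCohort,
                        use_true_fiducials: bool = True,
                        window: tuple[float, float] = DEFAULT_BEAT_WINDOW
                        ) -> ModelDataset:
    """Preprocess a synthetic cohort into a model-ready dataset."""
    fid = cohort.fiducials if use_true_fiducials else None
    beats, landmarks, kept = beats_from_records(cohort.records, fid,
                                                window=window)
    rows = [cohort.rows[i] for i in kept]
    return ModelDataset(
        beats=beats, scalars=scalar_frame(rows),
        lvm=np.array([r.lvm_truth for r in rows]),
        sex=np.array([r.sex for r in rows]),
        fs=cohort.records[0].fs, ids=kept, landmarks=landmarks)


def mean_predictor_baseline(dataset: ModelDataset, split: FoldSplit) -> dict:
    """Predict-the-training-mean baseline, cross-validated like the model."""
    maes, mapes = [], []
    for fold in split.folds:
        mean = float(dataset.lvm[fold["train"]].mean())
        preds = np.full(len(fold["test"]), mean)
        mae, mape = evaluate(preds, dataset.lvm[fold["test"]])
        maes.append(mae)
        mapes.append(mape)
    return {"mae": float(np.mean(maes)), "mape": float(np.mean(mapes)),
            "per_fold_mae": maes, "per_fold_mape": mapes}


def cross_validate(spec: ModelSpec, dataset: ModelDataset, split: FoldSplit,
                   config: TrainConfig | None = None,
                   folds: list[int] | None = None):
    """Train/evaluate over folds; returns ``(report, models, predictions)``.

    ``predictions`` maps fold id -> (test indices, predicted LVM).
    """
    config = config or TrainConfig()
    folds = list(range(split.k)) if folds is None else list(folds)
    maes, mapes, models, preds_by_fold = [], [], {}, {}
    all_preds, all_truth, all_idx = [], [], []
    for f in folds:
        model, _ = train_fold(spec, dataset, split, f, config)
        test_idx = split.folds[f]["test"]
        if spec.sex_scope != "all":
            test_idx = test_idx[dataset.sex[test_idx] == spec.sex_scope]
        preds = predict_dataset(model, dataset, test_idx)
        mae, mape = evaluate(preds, dataset.lvm[test_idx])
        maes.append(mae)
        mapes.append(mape)
        models[f] = model
        preds_by_fold[f] = (test_idx, preds)
        all_preds.append(preds)
        all_truth.append(dataset.lvm[test_idx])
        all_idx.append(test_idx)
    idx = np.concatenate(all_idx)
    preds = np.concatenate(all_preds)
    lvh = lvh_metrics(preds, np.concatenate(all_truth),
                      dataset.scalars["height"].to_numpy()[idx],
                      dataset.scalars["weight"].to_numpy()[idx],
                      dataset.sex[idx])
    report = EvalReport.from_folds(maes, mapes, lvh, n_test=len(idx),
                                   sex_scope=spec.sex_scope)
    return report, models, preds_by_fold
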