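"""Cross-validation splitting, training loop, LVM metrics, LVH classification.

The five-fold split is *sorted systematic*: indices are ordered by the target
LVM and every 5th sample lands in the same fold, so all folds see the same
LVM distribution.  The validation set is carved out of each training portion
by the same rule (every 10th of the LVM-sorted training samples).  Model
selection keeps the epoch with the lowest validation MAE.

LVH is defined on indexed LVM (grams per m^2 of body surface area) with
sex-specific thresholds: > 72 g/m^2 for men, > 55 g/m^2 for women (strict
inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import _nn
from .io_cohort import CohortError
from .model import (LvmRegressor, ModelSpec, build_model, mae_loss,
                    mae_loss_grad)

LVH_THRESHOLDS = {"male": 72.0, "female": 55.0}  # g/m^2


# ---------------------------------------------------------------------------
# Fold splitting

@dataclass
class FoldSplit:
    k: int
    fold_of: np.ndarray                 # index -> fold id
    folds: list                         # per fold: dict(train, val, test)

    def __post_init__(self):
        n = len(self.fold_of)
        for f in self.folds:
            parts = [f["train"], f["val"], f["test"]]
            cat = np.concatenate(parts)
            if len(np.unique(cat)) != n or len(cat) != n:
                raise CohortError("train/val/test must partition all indices")


def make_folds(lvm: np.ndarray, k: int = 5, val_every: int = 10) -> FoldSplit:
    """Sorted systematic k-fold split on the target LVM.

    Sort by LVM ascending (stable on ties); the sample at sorted position j
    goes to fold ``j % k``.  For each test fold, every ``val_every``-th
    sample (sorted positions 9, 19, ...) of the remaining training portion
    becomes validation; the rest train.
    """
    lvm = np.asarray(lvm, dtype=float)
    n = len(lvm)
    if n < k:
        raise CohortError(f"need at least k={k} samples, got {n}")
    if not np.all(np.isfinite(lvm)):
        raise CohortError("LVM values must be finite")
    order = np.argsort(lvm, kind="stable")
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % k
    folds = []
    for f in range(k):
        test = order[fold_of[order] == f]
        train_sorted = order[fold_of[order] != f]  # still LVM-sorted
        val = train_sorted[val_every - 1::val_every]
        train = np.setdiff1d(train_sorted, val, assume_unique=True)
        folds.append({"train": np.sort(train), "val": np.sort(val),
                      "test": np.sort(test)})
    return FoldSplit(k=k, fold_of=fold_of, folds=folds)


# ---------------------------------------------------------------------------
# Dataset container and training

@dataclass
class ModelDataset:
    """Model-ready arrays for one cohort: synchronized beats plus scalars."""

    beats: np.ndarray            # n x 12 x W
    scalars: pd.DataFrame        # columns: DEMOGRAPHIC + ECG_PARAM features
    lvm: np.ndarray              # n, grams
    sex: np.ndarray              # n, "male"/"female"
    fs: float
    ids: np.ndarray | None = None
    landmarks: list | None = None  # per-beat landmark dicts (for saliency)

    def __post_init__(self):
        n = self.beats.shape[0]
        if not (len(self.scalars) == len(self.lvm) == len(self.sex) == n):
            raise CohortError("dataset arrays must align")
        if self.ids is None:
            self.ids = np.arange(n)

    @property
    def n(self) -> int:
        return self.beats.shape[0]

    @property
    def width(self) -> int:
        return self.beats.shape[2]


@dataclass
class TrainConfig:
    epochs: int = 40
    batch_size: int = 64
    lr: float = 1e-3
    patience: int = 10
    seed: int = 0


def _scalar_matrix(dataset: ModelDataset, spec: ModelSpec, branch: str,
                   idx: np.ndarray) -> np.ndarray:
    cols = list(spec.branch_features(branch))
    return dataset.scalars.iloc[idx][cols].to_numpy(dtype=float)


def _model_inputs(dataset: ModelDataset, spec: ModelSpec, idx: np.ndarray):
    grouping = spec.grouping
    beats = dataset.beats[idx]
    groups = [beats[:, gi, :] for gi in grouping.indices()]
    scalars = {br: _scalar_matrix(dataset, spec, br, idx)
               for br in spec.branch_names}
    return groups, scalars


def _eval_mae(model: LvmRegressor, dataset: ModelDataset, idx: np.ndarray,
              batch: int = 256) -> float:
    preds = predict_dataset(model, dataset, idx, batch=batch)
    return mae_loss(preds, dataset.lvm[idx])


def predict_dataset(model: LvmRegressor, dataset: ModelDataset,
                    idx: np.ndarray, batch: int = 256) -> np.ndarray:
    out = []
    for s in range(0, len(idx), batch):
        sub = idx[s:s + batch]
        groups, scalars = _model_inputs(dataset, model.spec, sub)
        out.append(model.forward(groups, scalars, train=False))
    return np.concatenate(out)


def apply_sex_scope(idx: np.ndarray, sex: np.ndarray, scope: str) -> np.ndarray:
    if scope == "all":
        return idx
    return idx[sex[idx] == scope]


def train_fold(spec: ModelSpec, dataset: ModelDataset, split: FoldSplit,
               fold_id: int, config: TrainConfig | None = None):
    """Train on one fold; returns ``(model, history)``.

    The checkpoint returned is the one with minimum validation MAE; training
    stops early after ``patience`` consecutive non-improving epochs.  Fully
    seeded: identical config and seed reproduce identical histories.
    """
    config = config or TrainConfig()
    fold = split.folds[fold_id]
    train_idx = apply_sex_scope(fold["train"], dataset.sex, spec.sex_scope)
    val_idx = apply_sex_scope(fold["val"], dataset.sex, spec.sex_scope)
    test_idx = apply_sex_scope(fold["test"], dataset.sex, spec.sex_scope)
    if min(len(train_idx), len(val_idx), len(test_idx)) == 0:
        raise CohortError(
            f"empty partition after sex_scope={spec.sex_scope!r}: "
            f"train={len(train_idx)}, val={len(val_idx)}, test={len(test_idx)}")

    model = build_model(spec, dataset.width, seed=config.seed)
    fit_scalars = {br: _scalar_matrix(dataset, spec, br, train_idx)
                   for br in spec.branch_names}
    model.fit_standardizers(fit_scalars)

    opt = _nn.Adam(model.params(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    history = {"train_mae": [], "val_mae": []}
    best_val, best_state, best_epoch = np.inf, None, -1
    bad_epochs = 0
    for epoch in range(config.epochs):
        perm = rng.permutation(len(train_idx))
        epoch_losses = []
        for s in range(0, len(perm), config.batch_size):
            sub = train_idx[perm[s:s + config.batch_size]]
            groups, scalars = _model_inputs(dataset, spec, sub)
            preds = model.forward(groups, scalars, train=True)
            truth = dataset.lvm[sub]
            epoch_losses.append(mae_loss(preds, truth))
            opt.zero_grad()
            model.backward(mae_loss_grad(preds, truth))
            opt.step()
        val_mae = _eval_mae(model, dataset, val_idx)
        history["train_mae"].append(float(np.mean(epoch_losses)))
        history["val_mae"].append(val_mae)
        if val_mae < best_val:
            best_val, best_epoch = val_mae, epoch
            best_state = [p.value.copy() for p in model.params()]
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.patience:
                break
    if best_state is not None:
        for p, v in zip(model.params(), best_state):
            p.value[...] = v
    history["best_epoch"] = best_epoch
    history["fold_sizes"] = {"train": len(train_idx), "val": len(val_idx),
                             "test": len(test_idx)}
    return model, history


# ---------------------------------------------------------------------------
# Metrics

def evaluate(preds: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """(MAE in grams, MAPE in percent).  Truth must be positive for MAPE."""
    preds = np.asarray(preds, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if preds.shape != truth.shape or preds.size == 0:
        raise CohortError("preds and truth must be equal-length, non-empty")
    if np.any(truth <= 0):
        raise CohortError("MAPE undefined for non-positive truth")
    mae = float(np.mean(np.abs(preds - truth)))
    mape = float(100.0 * np.mean(np.abs(preds - truth) / truth))
    return mae, mape


def bsa(height_cm, weight_kg, formula: str = "mosteller"):
    h = np.asarray(height_cm, dtype=float)
    w = np.asarray(weight_kg, dtype=float)
    if np.any(h <= 0) or np.any(w <= 0):
        raise CohortError("height and weight must be positive")
    if formula == "mosteller":
        out = np.sqrt(h * w / 3600.0)
    elif formula == "dubois":
        out = 0.007184 * h ** 0.725 * w ** 0.425
    else:
        raise CohortError(f"unknown BSA formula {formula!r}")
    return float(out) if np.isscalar(height_cm) else out


def indexed_lvm(lvm, height_cm, weight_kg, formula: str = "mosteller"):
    """LVM / body surface area, g/m^2 (Mosteller BSA by default)."""
    lvm = np.asarray(lvm, dtype=float)
    out = lvm / bsa(height_cm, weight_kg, formula)
    return float(out) if out.ndim == 0 else out


def classify_lvh(indexed, sex):
    """Strict sex-specific thresholds: > 72 g/m^2 (men), > 55 g/m^2 (women)."""
    if isinstance(sex, str):
        if sex not in LVH_THRESHOLDS:
            raise CohortError(f"sex must be male or female, got {sex!r}")
        return bool(np.asarray(indexed) > LVH_THRESHOLDS[sex])
    sex = np.asarray(sex)
    bad = set(np.unique(sex)) - set(LVH_THRESHOLDS)
    if bad:
        raise CohortError(f"sex must be male or female, got {sorted(bad)}")
    thr = np.where(sex == "male", LVH_THRESHOLDS["male"],
                   LVH_THRESHOLDS["female"])
    return np.asarray(indexed, dtype=float) > thr


def c_statistic(scores: np.ndarray, labels: np.ndarray):
    """Rank-based AUROC; ties count 0.5.  Returns None for one-class labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)  # midranks handle ties as 0.5
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def lvh_metrics(pred_lvm, truth_lvm, height_cm, weight_kg, sex,
                formula: str = "mosteller") -> dict:
    """LVH classification block: hard-label metrics from predicted LVM plus
    a rank-based c-statistic using predicted indexed LVM as the score."""
    pred_idx = indexed_lvm(pred_lvm, height_cm, weight_kg, formula)
    truth_idx = indexed_lvm(truth_lvm, height_cm, weight_kg, formula)
    pred_lab = classify_lvh(pred_idx, sex)
    truth_lab = classify_lvh(truth_idx, sex)
    tp = int(np.sum(pred_lab & truth_lab))
    tn = int(np.sum(~pred_lab & ~truth_lab))
    fp = int(np.sum(pred_lab & ~truth_lab))
    fn = int(np.sum(~pred_lab & truth_lab))
    n = tp + tn + fp + fn
    out = {
        "accuracy": (tp + tn) / n if n else float("nan"),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "ppv": tp / (tp + fp) if tp + fp else float("nan"),
        "confusion": {"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    }
    prec, rec = out["ppv"], out["sensitivity"]
    out["f1"] = (2 * prec * rec / (prec + rec)
                 if np.isfinite(prec) and np.isfinite(rec) and prec + rec > 0
                 else float("nan"))
    c = c_statistic(pred_idx, truth_lab)
    if c is None:
        out["c_statistic"] = None
        out["c_statistic_reason"] = "single-class truth"
    else:
        out["c_statistic"] = c
    return out


def recalibrate_echo_lvm(echo_lvm, coefficients: tuple[float, float]):
    """Linear echo -> CT recalibration: slope * LVM + intercept.

    Coefficients must come from configuration (a published echo-to-CT
    regression); a non-positive slope is rejected.
    """
    slope, intercept = coefficients
    if slope <= 0:
        raise CohortError("recalibration slope must be positive")
    out = slope * np.asarray(echo_lvm, dtype=float) + intercept
    return float(out) if np.isscalar(echo_lvm) else out


# ---------------------------------------------------------------------------
# Reporting

@dataclass
class EvalReport:
    mae: float
    mape: float
    per_fold_mae: list = field(default_factory=list)
    per_fold_mape: list = field(default_factory=list)
    mae_sd: float = float("nan")
    mape_sd: float = float("nan")
    lvh: dict = field(default_factory=dict)
    n_test: int = 0
    sex_scope: str = "all"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_folds(cls, fold_maes, fold_mapes, lvh: dict, n_test: int,
                   sex_scope: str = "all") -> "EvalReport":
        fm, fp = np.asarray(fold_maes), np.asarray(fold_mapes)
        return cls(mae=float(fm.mean()), mape=float(fp.mean()),
                   per_fold_mae=[float(x) for x in fm],
                   per_fold_mape=[float(x) for x in fp],
                   mae_sd=float(fm.std(ddof=1)) if len(fm) > 1 else float("nan"),
                   mape_sd=float(fp.std(ddof=1)) if len(fp) > 1 else float("nan"),
                   lvh=lvh, n_test=n_test, sex_scope=sex_scope)
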