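"""Gradient saliency and ECG-segment importance tables.

Saliency for one beat is the absolute gradient of the predicted LVM with
respect to every input waveform sample, |d(yhat)/d(x[lead, t])|; gradients
with respect to scalar inputs are deliberately excluded — the table
attributes importance to the ECG alone.  Each map's mass is distributed over
non-overlapping beat segments (PR, QRS, ST-T, TP) crossed with the limb /
precordial lead split, normalized to 100% per map, then averaged over maps —
so every importance table sums to 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_cohort import CohortError
from .model import LvmRegressor
from .preprocess import BeatSegment
from .train_eval import ModelDataset, _model_inputs

SEGMENT_NAMES = ("PR", "QRS", "STT", "TP")
SALIENCY_LEAD_GROUPS = ("limb", "precordial")  # leads 0-5 / 6-11


@dataclass
class SaliencyMap:
    values: np.ndarray            # 12 x W, |gradient|, >= 0
    segment_masks: np.ndarray     # W, values in SEGMENT_NAMES
    lead_group_of: np.ndarray = field(
        default_factory=lambda: np.array(
            ["limb"] * 6 + ["precordial"] * 6))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != 12:
            raise CohortError("saliency values must be 12 x W")
        if np.any(self.values < 0):
            raise CohortError("saliency values must be non-negative")
        self.segment_masks = np.asarray(self.segment_masks)
        if self.segment_masks.shape != (self.values.shape[1],):
            raise CohortError("segment_masks must label every sample")
        bad = set(np.unique(self.segment_masks)) - set(SEGMENT_NAMES)
        if bad:
            raise CohortError(f"unknown segment labels {sorted(bad)}")


@dataclass
class SegmentImportanceTable:
    """Percent importance per (segment x lead group); cells sum to 100."""

    percentages: pd.DataFrame     # index SEGMENT_NAMES, columns lead groups
    stratum: str = "all"
    n_samples: int = 0

    def __post_init__(self):
        total = float(self.percentages.to_numpy().sum())
        if abs(total - 100.0) > 1e-6:
            raise CohortError(f"importance table sums to {total}, not 100")

    @property
    def totals(self) -> pd.Series:
        """Per-lead-group totals (the table's bottom row)."""
        return self.percentages.sum(axis=0)


def saliency_map(model: LvmRegressor, group_waveforms: list[np.ndarray],
                 scalars: dict | None = None,
                 segment_masks: np.ndarray | None = None) -> SaliencyMap:
    """Absolute input gradient of the prediction for a single beat.

    ``group_waveforms`` holds one (1, n_leads, W) array per lead group of the
    model's grouping; the returned 12 x W map is reassembled into canonical
    lead order.
    """
    for g in group_waveforms:
        if g.shape[0] != 1:
            raise CohortError("saliency_map expects a single-sample batch")
    model.forward(group_waveforms, scalars, train=False)
    grads = model.backward(np.ones(1))
    W = group_waveforms[0].shape[2]
    values = np.zeros((12, W))
    for gi, g in zip(model.spec.grouping.indices(), grads):
        values[gi] = np.abs(g[0])
    if segment_masks is None:
        segment_masks = np.array(["TP"] * W)
    return SaliencyMap(values=values, segment_masks=segment_masks)


def build_segment_masks(segment: BeatSegment) -> np.ndarray:
    """Per-sample labels: PR = [p_onset, qrs_onset), QRS = [qrs_onset,
    qrs_offset), STT = [qrs_offset, t_offset), TP = the remainder."""
    if segment.landmarks is None:
        raise CohortError("segment has no landmarks; annotate first")
    lm = segment.landmarks
    p, qo, qe, te = (lm["p_onset"], lm["qrs_onset"],
                     lm["qrs_offset"], lm["t_offset"])
    if not p <= qo <= qe <= te:
        raise CohortError(f"landmark ordering violated: {lm}")
    W = segment.width
    masks = np.array(["TP"] * W, dtype=object)
    masks[p:qo] = "PR"
    masks[qo:qe] = "QRS"
    masks[qe:te] = "STT"
    return masks.astype(str)


def _cell_sums(m: SaliencyMap) -> np.ndarray:
    """4 x 2 sums of saliency over (segment x lead group)."""
    out = np.zeros((len(SEGMENT_NAMES), len(SALIENCY_LEAD_GROUPS)))
    for i, seg in enumerate(SEGMENT_NAMES):
        cols = m.segment_masks == seg
        if not cols.any():
            continue
        sub = m.values[:, cols]
        for j, grp in enumerate(SALIENCY_LEAD_GROUPS):
            out[i, j] = sub[m.lead_group_of == grp].sum()
    return out


def segment_importance(maps: list[SaliencyMap], stratum: str = "all"
                       ) -> SegmentImportanceTable:
    """Per-map normalization to 100% over the 8 (segment x group) cells,
    then averaging across maps.  All-zero maps are excluded with a warning
    (their normalization is undefined)."""
    tables = []
    for k, m in enumerate(maps):
        cells = _cell_sums(m)
        total = cells.sum()
        if total <= 0:
            warnings.warn(f"saliency map {k} is all-zero; excluded")
            continue
        tables.append(100.0 * cells / total)
    if not tables:
        raise CohortError("no usable (non-zero) saliency maps")
    mean = np.mean(tables, axis=0)
    df = pd.DataFrame(mean, index=list(SEGMENT_NAMES),
                      columns=list(SALIENCY_LEAD_GROUPS))
    return SegmentImportanceTable(percentages=df, stratum=stratum,
                                  n_samples=len(tables))


def stratify_by_lvm(lvm: np.ndarray, m: int = 5,
                    bounds: tuple[float, float] | None = None,
                    seed: int = 0) -> dict[str, np.ndarray]:
    """Draw ``m`` sample indices from each of the low/middle/high LVM strata
    (tertiles by default; explicit ``bounds = (b1, b2)`` override)."""
    lvm = np.asarray(lvm, dtype=float)
    if len(lvm) < 3 * m:
        raise CohortError(f"need >= {3 * m} rows, got {len(lvm)}")
    if bounds is None:
        b1, b2 = np.quantile(lvm, [1 / 3, 2 / 3])
    else:
        b1, b2 = bounds
    strata = {"low": np.flatnonzero(lvm <= b1),
              "middle": np.flatnonzero((lvm > b1) & (lvm <= b2)),
              "high": np.flatnonzero(lvm > b2)}
    rng = np.random.default_rng(seed)
    out = {}
    for name, idx in strata.items():
        if len(idx) < m:
            raise CohortError(
                f"stratum {name!r} has {len(idx)} rows, need {m}")
        out[name] = np.sort(rng.choice(idx, size=m, replace=False))
    return out


def dataset_saliency_tables(model: LvmRegressor, dataset: ModelDataset,
                            m: int = 5, seed: int = 0,
                            bounds: tuple[float, float] | None = None
                            ) -> dict[str, SegmentImportanceTable]:
    """Importance tables for low/middle/high LVM strata of a dataset.

    Requires per-beat landmarks on the dataset (to build segment masks).
    """
    if dataset.landmarks is None:
        raise CohortError("dataset has no landmarks")
    strata = stratify_by_lvm(dataset.lvm, m=m, bounds=bounds, seed=seed)
    tables = {}
    for name, idx in strata.items():
        maps = []
        for i in idx:
            groups, scalars = _model_inputs(dataset, model.spec,
                                            np.array([i]))
            seg = BeatSegment(waveform=dataset.beats[i], fs=dataset.fs,
                              r_index=dataset.landmarks[i]["r_index"],
                              landmarks={k: dataset.landmarks[i][k]
                                         for k in ("p_onset", "qrs_onset",
                                                   "qrs_offset", "t_offset")})
            masks = build_segment_masks(seg)
            maps.append(saliency_map(model, groups, scalars,
                                     segment_masks=masks))
        tables[name] = segment_importance(maps, stratum=name)
    return tables


def importance_tables_to_frame(tables: dict[str, SegmentImportanceTable]
                               ) -> pd.DataFrame:
    """Wide table: rows = segments (+Total), columns = stratum x lead group."""
    pieces = {}
    for name, t in tables.items():
        df = t.percentages.copy()
        df.loc["Total"] = t.totals
        for grp in df.columns:
            pieces[(name, grp)] = df[grp]
    return pd.DataFrame(pieces)
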