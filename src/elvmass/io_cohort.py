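"""Waveform and cohort-table I/O, record matching, exclusions, imputation.

The native on-disk formats are a cohort CSV (one row per patient/record pair,
ISO-8601 timestamps) and waveforms as either a single HDF5 container (one
dataset per record with fs / lead_names / acquired_at attributes) or a
directory of per-record CSV files.  All unit conversions happen at this
boundary: waveforms are millivolts, height cm, weight kg, QRS duration ms,
axes degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

LEAD_NAMES = ("I", "II", "III", "aVR", "aVL", "aVF",
              "V1", "V2", "V3", "V4", "V5", "V6")

SEXES = ("male", "female", "unknown")
RHYTHM_FLAGS = ("bbb", "paced", "afib")

NUMERIC_COLUMNS = ("age", "height", "weight", "qrs_duration",
                   "p_axis", "r_axis", "t_axis")


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class EcgRecord:
    """A 12-lead waveform in canonical lead order, millivolts."""

    record_id: str
    waveform: np.ndarray  # 12 x L, mV
    fs: float = 500.0
    lead_names: tuple = LEAD_NAMES
    acquired_at: str | None = None

    def __post_init__(self):
        wf = np.asarray(self.waveform, dtype=float)
        object.__setattr__(self, "waveform", wf)
        if wf.ndim != 2 or wf.shape[0] != 12:
            raise CohortError(
                f"record {self.record_id}: waveform must be 12 x L, "
                f"got {wf.shape}")
        if tuple(self.lead_names) != LEAD_NAMES:
            raise CohortError(
                f"record {self.record_id}: leads must be in canonical order "
                f"{LEAD_NAMES}")
        if np.isnan(wf).any():
            raise CohortError(f"record {self.record_id}: NaN samples")
        if self.fs <= 0:
            raise CohortError(f"record {self.record_id}: fs must be positive")

    @property
    def duration(self) -> float:
        return self.waveform.shape[1] / self.fs


@dataclass(frozen=True)
class CohortRow:
    """One patient's scalar features and ground truth."""

    patient_id: str
    record_id: str
    age: float | None = None
    sex: str = "unknown"
    height: float | None = None
    weight: float | None = None
    qrs_duration: float | None = None
    p_axis: float | None = None
    r_axis: float | None = None
    t_axis: float | None = None
    lvm_truth: float | None = None
    lvm_source: str = "ct"
    ct_time: str | None = None
    ecg_time: str | None = None
    rhythm_flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.sex not in SEXES:
            raise CohortError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.lvm_truth is not None and not self.lvm_truth > 0:
            raise CohortError(f"lvm_truth must be > 0, got {self.lvm_truth}")
        bad = set(self.rhythm_flags) - set(RHYTHM_FLAGS)
        if bad:
            raise CohortError(f"unknown rhythm flags {sorted(bad)}")


def _reorder_leads(waveform: np.ndarray, names: list[str],
                   record_id: str) -> np.ndarray:
    names = [str(n) for n in names]
    missing = [n for n in LEAD_NAMES if n not in names]
    if missing:
        raise CohortError(f"record {record_id}: missing lead(s) {missing}")
    unknown = [n for n in names if n not in LEAD_NAMES]
    if unknown:
        raise CohortError(f"record {record_id}: unknown lead(s) {unknown}")
    return np.stack([waveform[names.index(n)] for n in LEAD_NAMES])


# ---------------------------------------------------------------------------
# Waveform containers

def save_waveforms(records: list[EcgRecord], path, format: str = "hdf5"):
    path = Path(path)
    if format == "hdf5":
        import h5py

        with h5py.File(path, "w") as f:
            for rec in records:
                ds = f.create_dataset(rec.record_id, data=rec.waveform)
                ds.attrs["fs"] = rec.fs
                ds.attrs["lead_names"] = list(rec.lead_names)
                ds.attrs["acquired_at"] = rec.acquired_at or ""
    elif format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        for rec in records:
            fp = path / f"{rec.record_id}.csv"
            with open(fp, "w") as f:
                f.write(f"# fs={rec.fs}\n# acquired_at={rec.acquired_at or ''}\n")
                pd.DataFrame(rec.waveform.T, columns=list(rec.lead_names)
                             ).to_csv(f, index=False, float_format="%.17g")
    else:
        raise CohortError(f"unknown waveform format {format!r}")


def _load_hdf5(path) -> list[EcgRecord]:
    import h5py

    records = []
    with h5py.File(path, "r") as f:
        for rid in sorted(f.keys()):
            ds = f[rid]
            if "fs" not in ds.attrs:
                raise CohortError(f"record {rid}: missing fs attribute")
            names = [n.decode() if isinstance(n, bytes) else str(n)
                     for n in ds.attrs["lead_names"]]
            wf = np.asarray(ds[...], dtype=float)
            if wf.shape[0] != len(names):
                raise CohortError(f"record {rid}: lead count mismatch")
            gain = float(ds.attrs.get("gain", 1.0))  # units per mV
            acquired = str(ds.attrs.get("acquired_at", "")) or None
            records.append(EcgRecord(
                record_id=rid, waveform=_reorder_leads(wf / gain, names, rid),
                fs=float(ds.attrs["fs"]), acquired_at=acquired))
    return records


def _load_csv_dir(path) -> list[EcgRecord]:
    records = []
    for fp in sorted(Path(path).glob("*.csv")):
        rid = fp.stem
        meta = {}
        with open(fp) as f:
            pos = f.tell()
            line = f.readline()
            while line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                meta[k.strip()] = v.strip()
                pos = f.tell()
                line = f.readline()
            f.seek(pos)
            df = pd.read_csv(f, float_precision="round_trip")
        if "fs" not in meta:
            raise CohortError(f"record {rid}: missing fs header")
        gain = float(meta.get("gain", 1.0))
        wf = df.to_numpy(dtype=float).T / gain
        records.append(EcgRecord(
            record_id=rid,
            waveform=_reorder_leads(wf, list(df.columns), rid),
            fs=float(meta["fs"]), acquired_at=meta.get("acquired_at") or None))
    return records


def load_waveforms(path, format: str = "hdf5") -> list[EcgRecord]:
    """Load 12-lead records; leads are reordered to canonical order and
    divided by any declared gain (units per mV)."""
    if format == "hdf5":
        return _load_hdf5(path)
    if format == "csv":
        return _load_csv_dir(path)
    raise CohortError(f"unknown waveform format {format!r}")


# ---------------------------------------------------------------------------
# Cohort table

def rows_to_frame(rows: list[CohortRow]) -> pd.DataFrame:
    recs = []
    for r in rows:
        d = r.__dict__.copy()
        d["rhythm_flags"] = "|".join(sorted(r.rhythm_flags))
        recs.append(d)
    return pd.DataFrame(recs)


def frame_to_rows(df: pd.DataFrame) -> list[CohortRow]:
    rows = []
    for rec in df.to_dict("records"):
        flags = rec.get("rhythm_flags", "")
        if isinstance(flags, float) and np.isnan(flags):
            flags = ""
        rec["rhythm_flags"] = frozenset(f for f in str(flags).split("|") if f)
        for k, v in list(rec.items()):
            if isinstance(v, float) and np.isnan(v):
                rec[k] = None
        rows.append(CohortRow(**{k: rec.get(k) for k in
                                 CohortRow.__dataclass_fields__}))
    return rows


def write_cohort_csv(rows: list[CohortRow], path):
    rows_to_frame(rows).to_csv(path, index=False)


def read_cohort_csv(path) -> list[CohortRow]:
    return frame_to_rows(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Matching and exclusion rules

def match_ecg_to_lvm(rows: list[CohortRow], window_days: int = 183):
    """Keep at most one ECG per LVM measurement.

    Rows whose ECG falls more than ``window_days`` from the CT are dropped
    ("window"); among the remainder, one ECG per patient is kept (closest to
    the CT in time; tie broken by the earlier ECG) and the rest are logged as
    "redundant".  Rows lacking either timestamp are dropped as "unmatchable".
    """
    log = []
    candidates: dict[str, list] = {}
    for r in rows:
        if r.ct_time is None or r.ecg_time is None:
            log.append((r.patient_id, r.record_id, "unmatchable"))
            continue
        delta = abs((pd.Timestamp(r.ecg_time) - pd.Timestamp(r.ct_time))
                    / pd.Timedelta(days=1))
        if delta > window_days:
            log.append((r.patient_id, r.record_id, "window"))
            continue
        candidates.setdefault(r.patient_id, []).append((delta, r))
    kept = []
    for pid, cands in candidates.items():
        cands.sort(key=lambda c: (c[0], pd.Timestamp(c[1].ecg_time)))
        kept.append(cands[0][1])
        for _, r in cands[1:]:
            log.append((pid, r.record_id, "redundant"))
    kept.sort(key=lambda r: r.patient_id)
    return kept, pd.DataFrame(log, columns=["patient_id", "record_id", "reason"])


def apply_rhythm_exclusions(rows: list[CohortRow]):
    """Drop rows with any rhythm flag (BBB, paced, AF) or unknown sex."""
    kept, log = [], []
    for r in rows:
        if r.rhythm_flags:
            log.append((r.patient_id, r.record_id,
                        "|".join(sorted(r.rhythm_flags))))
        elif r.sex == "unknown":
            log.append((r.patient_id, r.record_id, "unknown sex"))
        else:
            kept.append(r)
    return kept, pd.DataFrame(log, columns=["patient_id", "record_id", "reason"])


def impute_scalars(rows: list[CohortRow],
                   train_index: list[int] | None = None,
                   medians: dict | None = None):
    """Replace missing numeric scalars by column medians.

    Medians are computed on ``train_index`` rows only (all rows when None) so
    that statistics fitted on a training partition can be reused for held-out
    rows without leakage; precomputed ``medians`` override both.  Returns
    ``(rows, report, medians)`` where the report lists column, median used and
    number imputed.
    """
    df = rows_to_frame(rows)
    train_df = df.iloc[list(train_index)] if train_index is not None else df
    med = dict(medians) if medians is not None else {}
    report = []
    out = list(rows)
    for col in NUMERIC_COLUMNS:
        if col not in med:
            vals = train_df[col].dropna()
            if vals.empty:
                raise CohortError(f"column {col!r} has no observed values "
                                  "to impute from")
            med[col] = float(vals.median())
        missing = [i for i, r in enumerate(out) if getattr(r, col) is None]
        for i in missing:
            out[i] = replace(out[i], **{col: med[col]})
        if missing:
            report.append((col, med[col], len(missing)))
    report_df = pd.DataFrame(report, columns=["column", "median", "n_imputed"])
    return out, report_df, med


MYOCARDIUM_DENSITY_G_PER_ML = 1.05


def lvm_from_volume(volume_ml):
    """LV mass (g) from myocardial volume (mL) at density 1.05 g/mL."""
    v = np.asarray(volume_ml, dtype=float)
    if np.any(v < 0):
        raise CohortError("volume must be non-negative")
    out = v * MYOCARDIUM_DENSITY_G_PER_ML
    return float(out) if np.isscalar(volume_ml) else out
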