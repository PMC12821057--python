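"""Signal conditioning and the three model-input representations.

A record can enter the regressor as (i) the full-length waveform, (ii) a
random-length crop synchronized over the 12 leads, or (iii) the middle single
heartbeat, synchronized over the 12 leads — the representation the estimator
uses by default.  Lead grouping splits the 12 leads into per-encoder groups
by electrical plane (limb vs precordial) or coronary territory.

All sample windows are half-open ``[start, end)`` with 0-based indexing, and
every representation slices the *same* sample range from all 12 leads.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .io_cohort import LEAD_NAMES, CohortError, EcgRecord

DEFAULT_BEAT_WINDOW = (-0.25, 0.45)  # s around the R peak; holds P, QRS, T

#: Fixed-offset fallback landmarks (s relative to the R peak), used when
#: rule-based delineation fails on a noisy beat.
FALLBACK_LANDMARKS = {"p_onset": -0.200, "qrs_onset": -0.050,
                      "qrs_offset": 0.050, "t_offset": 0.400}

LANDMARK_ORDER = ("p_onset", "qrs_onset", "qrs_offset", "t_offset")


class SignalQualityError(ValueError):
    pass


@dataclass
class BeatSegment:
    """A synchronized single-beat window over all 12 leads."""

    waveform: np.ndarray  # 12 x W, mV
    fs: float
    r_index: int          # sample offset of the R peak within the window
    landmarks: dict | None = None
    source_record_id: str = ""
    delineation_failed: bool = False
    r_record_index: int | None = None  # R-peak sample in record coordinates

    def __post_init__(self):
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.waveform.ndim != 2 or self.waveform.shape[0] != 12:
            raise CohortError("BeatSegment waveform must be 12 x W")
        W = self.waveform.shape[1]
        if not 0 <= self.r_index < W:
            raise CohortError("r_index outside the window")
        if self.landmarks is not None:
            lm = self.landmarks
            vals = [lm[k] for k in LANDMARK_ORDER]
            if not all(0 <= v < W for v in vals):
                raise CohortError("landmarks outside the window")
            ordered = (lm["p_onset"] <= lm["qrs_onset"] < self.r_index
                       < lm["qrs_offset"] < lm["t_offset"])
            if not ordered:
                raise CohortError(
                    f"landmarks must satisfy p_onset <= qrs_onset < r_index "
                    f"< qrs_offset < t_offset, got {lm} (r={self.r_index})")

    @property
    def width(self) -> int:
        return self.waveform.shape[1]


ELECTRICAL_GROUPS = (("limb", ("I", "II", "III", "aVR", "aVL", "aVF")),
                     ("precordial", ("V1", "V2", "V3", "V4", "V5", "V6")))
ANATOMICAL_GROUPS = (("LAD", ("V1", "V2", "V3", "V4")),
                     ("LCx", ("I", "aVL", "V5", "V6")),
                     ("RCA", ("II", "III", "aVF")),
                     ("LM", ("aVR",)))


@dataclass(frozen=True)
class LeadGrouping:
    """An ordered partition of the 12 leads into encoder groups."""

    name: str
    groups: tuple = ()

    def __post_init__(self):
        all_leads = [l for _, leads in self.groups for l in leads]
        if sorted(all_leads) != sorted(LEAD_NAMES):
            raise CohortError(
                f"grouping {self.name!r} must partition the 12 leads; "
                f"covers {sorted(all_leads)}")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def indices(self) -> list[np.ndarray]:
        return [np.array([LEAD_NAMES.index(l) for l in leads])
                for _, leads in self.groups]


def lead_grouping(name: str) -> LeadGrouping:
    """Build one of the named groupings: none, electrical, anatomical."""
    if name == "none":
        return LeadGrouping("none", (("all", LEAD_NAMES),))
    if name == "electrical":
        return LeadGrouping("electrical", ELECTRICAL_GROUPS)
    if name == "anatomical":
        return LeadGrouping("anatomical", ANATOMICAL_GROUPS)
    raise CohortError(f"unknown grouping {name!r} "
                      "(expected none, electrical or anatomical)")


def bandpass_filter(record: EcgRecord, low: float = 0.5,
                    high: float = 40.0, order: int = 3) -> EcgRecord:
    """Zero-phase Butterworth band-pass, removing baseline wander and
    high-frequency noise while preserving the ST-T band."""
    if not 0 < low < high < record.fs / 2:
        raise CohortError(
            f"band ({low}, {high}) Hz invalid for fs={record.fs}")
    sos = sps.butter(order, [low, high], btype="bandpass",
                     fs=record.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, record.waveform, axis=1)
    return replace(record, waveform=filtered)


def _reference_lead(record: EcgRecord) -> int:
    ii = LEAD_NAMES.index("II")
    if np.std(record.waveform[ii]) > 1e-6:
        return ii
    v5 = LEAD_NAMES.index("V5")
    if np.std(record.waveform[v5]) > 1e-6:
        return v5
    raise SignalQualityError(
        f"record {record.record_id}: reference leads II and V5 are flat")


def detect_r_peaks(record: EcgRecord, refractory_s: float = 0.2) -> np.ndarray:
    """Pan-Tompkins-style R-peak detection on lead II (V5 fallback).

    Band-pass 5-15 Hz, differentiate, square, 150-ms moving integration,
    peak picking with a 200-ms refractory period, then refinement to the
    local extremum of the band-passed reference lead.
    """
    fs = record.fs
    if record.duration < 2.0:
        raise SignalQualityError(
            f"record {record.record_id}: need >= 2 s, got {record.duration} s")
    ref = _reference_lead(record)
    x = record.waveform[ref]
    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    energy = np.convolve(np.gradient(bp) ** 2,
                         np.ones(int(round(0.150 * fs))) / (0.150 * fs),
                         mode="same")
    height = 0.2 * np.max(energy)
    locs, _ = sps.find_peaks(energy, height=height,
                             distance=int(round(refractory_s * fs)))
    if len(locs) == 0:
        raise SignalQualityError(
            f"record {record.record_id}: no R peaks found")
    # refine each detection to the extremum of the band-passed lead
    half = int(round(0.1 * fs))
    peaks = []
    for loc in locs:
        lo, hi = max(0, loc - half), min(len(x), loc + half + 1)
        peaks.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    peaks = np.unique(peaks)
    # re-enforce the refractory period after refinement
    out = [int(peaks[0])]
    for p in peaks[1:]:
        if p - out[-1] >= refractory_s * fs:
            out.append(int(p))
    return np.array(out, dtype=int)


def extract_single_beat(record: EcgRecord, peaks: np.ndarray,
                        window: tuple[float, float] = DEFAULT_BEAT_WINDOW
                        ) -> BeatSegment:
    """Slice the middle eligible heartbeat, synchronized over 12 leads.

    Eligible peaks are those whose full window lies inside the record; the
    middle one (index ``n_eligible // 2``, 0-based) is chosen.
    """
    fs, L = record.fs, record.waveform.shape[1]
    w0, w1 = window
    W = int(round((w1 - w0) * fs))
    off = int(round(w0 * fs))
    eligible = [p for p in np.sort(np.asarray(peaks))
                if p + off >= 0 and p + off + W <= L]
    if not eligible:
        raise SignalQualityError(
            f"record {record.record_id}: no peak with a full "
            f"({w0}, {w1}) s window")
    peak = eligible[len(eligible) // 2]
    start = peak + off
    return BeatSegment(waveform=record.waveform[:, start:start + W],
                       fs=fs, r_index=peak - start,
                       source_record_id=record.record_id,
                       r_record_index=int(peak))


def random_length_crop(record: EcgRecord, min_s: float, max_s: float,
                       rng: np.random.Generator) -> EcgRecord:
    """Crop a random-length segment, the same sample range on all 12 leads."""
    dur, fs = record.duration, record.fs
    if not min_s <= max_s:
        raise CohortError("min_s must be <= max_s")
    if max_s > dur:
        raise CohortError(f"max_s {max_s} exceeds record duration {dur}")
    length = int(round(rng.uniform(min_s, max_s) * fs))
    length = min(max(length, 1), record.waveform.shape[1])
    start = int(rng.integers(0, record.waveform.shape[1] - length + 1))
    return replace(record, waveform=record.waveform[:, start:start + length])


def group_leads(data, grouping: LeadGrouping) -> list[np.ndarray]:
    """Split a 12-lead matrix (or EcgRecord/BeatSegment) into per-group
    matrices, leads in each group's declared order, time axis untouched."""
    wf = data.waveform if hasattr(data, "waveform") else np.asarray(data)
    if wf.ndim != 2 or wf.shape[0] != 12:
        raise CohortError("group_leads expects a 12 x T matrix")
    return [wf[idx] for idx in grouping.indices()]


# ---------------------------------------------------------------------------
# Landmark delineation

def _threshold_crossing(x: np.ndarray, peak: int, thr: float, fs: float,
                        direction: int) -> int | None:
    """March from ``peak`` in ``direction`` until |x| stays below ``thr``
    for >= 10 ms; returns the first sub-threshold sample."""
    sustain = max(1, int(round(0.010 * fs)))
    n = len(x)
    run, idx = 0, None
    i = peak
    while 0 <= i < n:
        if abs(x[i]) < thr:
            if run == 0:
                idx = i
            run += 1
            if run >= sustain:
                return idx
        else:
            run, idx = 0, None
        i += direction
    return idx


def _delineate(segment: BeatSegment) -> dict:
    """Slope-threshold delineation on lead II.

    Boundaries are located where |dx/dt| stays below 2% of the local wave's
    peak slope for >= 10 ms; slope thresholds are insensitive to any residual
    baseline offset the band-pass filter leaves behind.
    """
    fs = segment.fs
    ii = LEAD_NAMES.index("II")
    x = segment.waveform[ii]
    r = segment.r_index
    W = segment.width
    base = np.median(x)
    if abs(x[r] - base) < 1e-6:
        raise SignalQualityError("flat reference lead at R")
    d = np.gradient(x) * fs  # mV/s
    # QRS bounds: 2% of the peak slope inside the +-80 ms QRS region
    q_lo, q_hi = max(0, r - int(0.080 * fs)), min(W, r + int(0.080 * fs))
    thr_qrs = 0.02 * np.max(np.abs(d[q_lo:q_hi]))
    qrs_onset = _threshold_crossing(d, r, thr_qrs, fs, -1)
    qrs_offset = _threshold_crossing(d, r, thr_qrs, fs, +1)
    if qrs_onset is None or qrs_offset is None:
        raise SignalQualityError("QRS bounds not found")
    # P wave: largest positive deflection in [-280, -80] ms before R
    p_lo, p_hi = max(0, r - int(0.280 * fs)), max(0, r - int(0.080 * fs))
    if p_hi - p_lo < 3:
        raise SignalQualityError("no room for P search")
    p_peak = p_lo + int(np.argmax(x[p_lo:p_hi]))
    if x[p_peak] - base < 0.02:
        raise SignalQualityError("P wave too small")
    thr_p = 0.02 * np.max(np.abs(d[p_lo:p_hi]))
    p_onset = _threshold_crossing(d, p_peak, thr_p, fs, -1)
    # T wave: largest |deflection| in [+120, +420] ms after R
    t_lo, t_hi = min(W, r + int(0.120 * fs)), min(W, r + int(0.420 * fs))
    if t_hi - t_lo < 3:
        raise SignalQualityError("no room for T search")
    t_peak = t_lo + int(np.argmax(np.abs(x[t_lo:t_hi] - base)))
    if abs(x[t_peak] - base) < 0.02:
        raise SignalQualityError("T wave too small")
    thr_t = 0.02 * np.max(np.abs(d[t_lo:t_hi]))
    t_offset = _threshold_crossing(d, t_peak, thr_t, fs, +1)
    if p_onset is None or t_offset is None:
        raise SignalQualityError("wave boundary not found")
    t_offset = min(t_offset, W - 1)
    lm = {"p_onset": p_onset, "qrs_onset": qrs_onset,
          "qrs_offset": qrs_offset, "t_offset": t_offset}
    if not (lm["p_onset"] <= lm["qrs_onset"] < r < lm["qrs_offset"]
            < lm["t_offset"]):
        raise SignalQualityError(f"landmark ordering violated: {lm}")
    return lm


def fallback_landmarks(r_index: int, fs: float, width: int) -> dict:
    lm = {k: r_index + int(round(v * fs))
          for k, v in FALLBACK_LANDMARKS.items()}
    lm = {k: int(np.clip(v, 0, width - 1)) for k, v in lm.items()}
    return lm


def annotate_landmarks(segment: BeatSegment,
                       truth: dict | None = None) -> BeatSegment:
    """Locate p_onset / qrs_onset / qrs_offset / t_offset on lead II.

    Simulator ground truth, when supplied, overrides detection.  If the
    rule-based delineation fails the segment is flagged and fixed-offset
    fallback landmarks are attached, so downstream segment partitions stay
    deterministic.
    """
    if truth is not None:
        lm = {k: int(truth[k]) for k in LANDMARK_ORDER}
        return replace(segment, landmarks=lm, delineation_failed=False)
    try:
        lm = _delineate(segment)
        failed = False
    except SignalQualityError:
        lm = fallback_landmarks(segment.r_index, segment.fs, segment.width)
        failed = True
    return replace(segment, landmarks=lm, delineation_failed=failed)
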