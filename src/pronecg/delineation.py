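"""Beat detection, fiducial delineation and per-wave amplitude measurement.

Each cardiac cycle is carved into the three modelling windows used by the
segment-wise conversion models: the P-R interval, the QRS complex and the
ST-T segment.  R peaks are found with a Pan-Tompkins-style energy detector;
QRS onset/offset use a slope-magnitude criterion, the T offset a tangent
rule on the low-pass filtered repolarisation wave.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .errors import EdgeBeat
from .records import ECGRecord

# Detector constants (seconds unless noted)
REFRACTORY_S = 0.200
PR_FALLBACK_S = 0.120      # PR window length when no P wave is found
PRE_R_CONTEXT_S = 0.300
POST_R_CONTEXT_S = 0.450
P_FLAT_THRESH_MV = 0.05
ST_MEASURE_OFFSET_S = 0.060  # ST level at J + 60 ms


@dataclass(frozen=True)
class BeatFiducials:
    """Fiducial sample indices (0-based) of one cardiac cycle."""

    p_onset: int
    qrs_onset: int
    r_peak: int
    qrs_offset: int
    t_offset: int
    p_present: bool = True

    def __post_init__(self) -> None:
        seq = (self.p_onset, self.qrs_onset, self.r_peak,
               self.qrs_offset, self.t_offset)
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise ValueError(f"fiducials must be strictly increasing: {seq}")


class SegmentKind(str, enum.Enum):
    PR = "PR"
    QRS = "QRS"
    STT = "STT"


@dataclass(frozen=True)
class SegmentWindow:
    """Half-open sample window [start, end) of one modelling segment."""

    kind: SegmentKind
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("window start must precede end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class WaveAmplitudes:
    """Per-wave amplitudes in mV, referenced to the P-R baseline."""

    p_pos: float
    p_neg: float
    q: float
    r: float
    s: float
    st_level: float
    t_pos: float
    t_neg: float

    def __post_init__(self) -> None:
        if not (self.p_pos >= 0 >= self.p_neg and self.t_pos >= 0 >= self.t_neg
                and self.r >= 0 and self.q <= 0 and self.s <= 0):
            raise ValueError("wave amplitude sign conventions violated")


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 2) -> np.ndarray:
    nyq = fs / 2.0
    hi = min(hi, 0.99 * nyq)
    b, a = butter(order, [lo / nyq, hi / nyq], btype="band")
    return filtfilt(b, a, x)


def _lowpass(x: np.ndarray, fs: float, hi: float, order: int = 3) -> np.ndarray:
    nyq = fs / 2.0
    b, a = butter(order, min(hi, 0.99 * nyq) / nyq, btype="low")
    return filtfilt(b, a, x)


def detect_r_peaks(signal: np.ndarray, fs: float) -> np.ndarray:
    """Locate R peaks on one lead.

    Band-pass (5-25 Hz), squared-derivative energy envelope, adaptive
    threshold at 40% of the largest candidate, 200 ms refractory period.
    Returns strictly increasing sample indices; may be empty.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size < fs:
        raise ValueError("need at least 1 s of signal")
    if np.ptp(signal) < 1e-9:
        return np.array([], dtype=int)
    filt = _bandpass(signal, fs, 5.0, 25.0)
    energy = np.gradient(filt) ** 2
    win = max(1, int(round(0.150 * fs)))
    env = np.sqrt(np.convolve(energy, np.ones(win) / win, mode="same"))
    dist = max(1, int(round(REFRACTORY_S * fs)))
    cand, props = find_peaks(env, distance=dist, height=1e-9)
    if cand.size == 0:
        return np.array([], dtype=int)
    thr = 0.4 * props["peak_heights"].max()
    kept = cand[props["peak_heights"] >= thr]
    # snap each detection to the local extremum of the raw signal
    half = int(round(0.05 * fs))
    peaks = []
    for c in kept:
        lo, hi = max(0, c - half), min(signal.size, c + half + 1)
        peaks.append(lo + int(np.argmax(np.abs(signal[lo:hi] - np.median(signal)))))
    peaks = np.array(sorted(set(peaks)), dtype=int)
    # enforce refractory after snapping
    out: list[int] = []
    for p in peaks:
        if not out or p - out[-1] >= dist:
            out.append(int(p))
    return np.array(out, dtype=int)


def _activity_bound(act: np.ndarray, fs: float, r: int, direction: int,
                    span_s: float, thresh: float) -> int:
    """Walk from R until the activity signal stays below ``thresh``.

    The 30 ms quiet-run requirement bridges the low-activity gaps between
    QRS deflections while stopping at the isoelectric segments that
    separate the QRS from the P and T waves.  Returns the window edge when
    no sustained quiet run exists (very wide complexes).
    """
    lo = max(0, r - int(round(span_s * fs)))
    hi = min(act.size, r + int(round(span_s * fs)) + 1)
    run_needed = max(1, int(round(0.030 * fs)))
    i, run = r, 0
    while True:
        i += direction
        if not (lo <= i < hi):
            return lo if direction < 0 else hi - 1
        if act[i] < thresh:
            run += 1
            if run >= run_needed:
                return i + run if direction < 0 else i - run
        else:
            run = 0


def delineate(rec: ECGRecord, r_index: int, lead: str | None = None) -> BeatFiducials:
    """Delineate the beat anchored at ``r_index``.

    Fiducials are found on lead II (falling back to V2, then the first
    available lead) and shared by all leads of the record: a beat has one
    time base.  Raises :class:`EdgeBeat` when the beat lacks 300 ms of
    context before or 450 ms after the R peak.
    """
    fs = rec.fs
    pre = int(round(PRE_R_CONTEXT_S * fs))
    post = int(round(POST_R_CONTEXT_S * fs))
    if r_index < pre or r_index + post >= rec.n_samples:
        raise EdgeBeat(f"R at {r_index} lacks {PRE_R_CONTEXT_S:.0e}/{POST_R_CONTEXT_S} s context")
    if lead is None:
        lead = "II" if rec.has_lead("II") else ("V2" if rec.has_lead("V2") else rec.lead_names[0])
    raw = rec.lead(lead)
    smooth = _lowpass(raw, fs, 60.0)
    win_lo = max(0, r_index - pre)
    win_hi = min(rec.n_samples, r_index + post)
    # baseline from the diastolic stretch before the P wave
    b_lo = max(0, r_index - int(round(0.290 * fs)))
    b_hi = max(b_lo + 1, r_index - int(round(0.220 * fs)))
    baseline_est = float(np.median(smooth[b_lo:b_hi]))
    x = smooth - baseline_est

    # QRS bounds: slope activity falls below 2% of the local maximum slope
    # (slope, unlike amplitude, ignores ST-segment deviation)
    slope_act = np.abs(np.gradient(smooth))
    ref = float(np.max(slope_act[max(0, r_index - int(0.14 * fs)):
                                 r_index + int(0.14 * fs)]))
    thresh = max(0.02 * ref, 1e-6)
    qrs_on = _activity_bound(slope_act, fs, r_index, -1, 0.140, thresh)
    qrs_off = _activity_bound(slope_act, fs, r_index, +1, 0.130, thresh)
    qrs_on = min(qrs_on, r_index - 1)
    qrs_off = max(qrs_off, r_index + 1)

    # T offset: tangent rule — intersect the steepest post-peak slope of the
    # low-pass filtered T wave with the baseline
    t_search_end = win_hi
    stt = _lowpass(raw, fs, 15.0) - baseline_est
    t_start = qrs_off + int(round(0.06 * fs))
    seg = stt[t_start:t_search_end]
    if seg.size < 3:
        t_off = t_search_end - 1
    else:
        t_peak = t_start + int(np.argmax(np.abs(seg)))
        tail = stt[t_peak:t_search_end]
        if tail.size < 3:
            t_off = t_search_end - 1
        else:
            d = np.gradient(tail)
            sign = 1.0 if stt[t_peak] >= 0 else -1.0
            k = int(np.argmin(sign * d))  # steepest return toward baseline
            slope = d[k]
            if abs(slope) < 1e-9:
                t_off = t_search_end - 1
            else:
                cross = k + (0.0 - tail[k]) / slope
                t_off = t_peak + int(round(np.clip(cross, k + 1, tail.size - 1)))
    t_off = int(np.clip(t_off, qrs_off + 2, rec.n_samples - 1))

    # P wave: search [R - 300 ms, QRS onset)
    p_lo = win_lo
    p_hi = qrs_on - int(round(0.01 * fs))
    p_present, p_on = False, 0
    if p_hi - p_lo > 4:
        dev = np.abs(x[p_lo:p_hi])
        if dev.max() >= P_FLAT_THRESH_MV:
            p_peak = int(np.argmax(dev))
            thr = max(0.08 * dev[p_peak], 0.01)
            i = p_peak
            while i > 0 and dev[i] > thr:
                i -= 1
            p_on = p_lo + i
            p_present = True
    if not p_present or p_on >= qrs_on:
        p_on = qrs_on - int(round(PR_FALLBACK_S * fs))
        p_present = False
    p_on = max(0, p_on)

    return BeatFiducials(int(p_on), int(qrs_on), int(r_index),
                         int(qrs_off), int(t_off), p_present)


def segment_windows(fid: BeatFiducials, fs: float = 500.0) -> tuple[SegmentWindow, SegmentWindow, SegmentWindow]:
    """The three modelling windows of one beat: PR, QRS and ST-T.

    When no P wave was found the PR window falls back to a fixed 120 ms
    span immediately before the QRS onset.
    """
    if fid.p_present:
        pr_start = fid.p_onset
    else:
        pr_start = max(0, fid.qrs_onset - int(round(PR_FALLBACK_S * fs)))
    return (
        SegmentWindow(SegmentKind.PR, pr_start, fid.qrs_onset),
        SegmentWindow(SegmentKind.QRS, fid.qrs_onset, fid.qrs_offset),
        SegmentWindow(SegmentKind.STT, fid.qrs_offset, fid.t_offset),
    )


def measure_amplitudes(rec: ECGRecord, lead: str, fid: BeatFiducials) -> WaveAmplitudes:
    """Measure per-wave amplitudes of one beat on one lead.

    The baseline is the mean over the P-R window; P and T waves report the
    bidirectional maximum (largest positive and negative excursions); the
    ST level is read at J + 60 ms.
    """
    sig = rec.lead(lead)
    fs = rec.fs
    pr, qrs, stt = segment_windows(fid, fs)
    baseline = float(np.mean(sig[pr.start:pr.end]))
    x = sig - baseline

    if fid.p_present:
        pwin = x[pr.start:pr.end]
        p_pos = max(0.0, float(pwin.max()))
        p_neg = min(0.0, float(pwin.min()))
    else:
        p_pos = p_neg = 0.0

    qwin = x[qrs.start:qrs.end]
    r_rel = int(np.argmax(qwin))
    r = max(0.0, float(qwin[r_rel]))
    q = min(0.0, float(qwin[:r_rel].min())) if r_rel > 0 else 0.0
    s = min(0.0, float(qwin[r_rel + 1:].min())) if r_rel + 1 < qwin.size else 0.0

    st_idx = min(rec.n_samples - 1, fid.qrs_offset + int(round(ST_MEASURE_OFFSET_S * fs)))
    st_level = float(x[st_idx])

    twin = x[stt.start:stt.end]
    t_pos = max(0.0, float(twin.max()))
    t_neg = min(0.0, float(twin.min()))

    return WaveAmplitudes(p_pos, p_neg, q, r, s, st_level, t_pos, t_neg)


def delineate_record(rec: ECGRecord, lead: str | None = None) -> list[BeatFiducials]:
    """Detect and delineate every beat with full context in a record."""
    if lead is None:
        lead = "II" if rec.has_lead("II") else ("V2" if rec.has_lead("V2") else rec.lead_names[0])
    fids = []
    for r in detect_r_peaks(rec.lead(lead), rec.fs):
        try:
            fids.append(delineate(rec, int(r), lead=lead))
        except EdgeBeat:
            continue
    return fids


def export_delineation(rec: ECGRecord, fids: list[BeatFiducials]):
    """Tabulate fiducials and per-lead amplitudes as a DataFrame (CSV-ready)."""
    import pandas as pd

    rows = []
    for i, fid in enumerate(fids):
        row: dict[str, object] = {
            "subject_id": rec.subject_id, "beat": i,
            "p_onset": fid.p_onset, "qrs_onset": fid.qrs_onset,
            "r_peak": fid.r_peak, "qrs_offset": fid.qrs_offset,
            "t_offset": fid.t_offset, "p_present": fid.p_present,
        }
        for lead in rec.lead_names:
            amp = measure_amplitudes(rec, lead, fid)
            for f in ("p_pos", "p_neg", "q", "r", "s", "st_level", "t_pos", "t_neg"):
                row[f"{lead}_{f}"] = getattr(amp, f)
        rows.append(row)
    return pd.DataFrame(rows)
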