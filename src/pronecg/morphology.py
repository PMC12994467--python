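"""Waveform morphology descriptors and descriptor-level similarity.

Descriptors follow conventional ECG nomenclature: P and T waves are
upright / inverted / biphasic / flat; the QRS complex is written as an
ordered polarity string (e.g. ``qRs``, ``QS``, ``RsR'``) in which letter
case encodes relative deflection size and a prime marks a repeated
polarity; the ST segment is elevated / depressed / isoelectric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .delineation import WaveAmplitudes
from .errors import EmptyQRS, LengthMismatch

FLAT_THRESH_MV = 0.05          # 0.5 mm at standard gain
MAJOR_LOBE_FRACTION = 0.5      # lobes above this fraction of the largest are upper-case
ST_ELEVATED_MV = 0.10
ST_DEPRESSED_MV = -0.05

PRIME = "′"  # ′


@dataclass(frozen=True)
class MorphologyDescriptor:
    """Categorical waveform descriptors for one lead of one record."""

    lead: str
    p_class: str      # upright / inverted / biphasic / flat / absent
    qrs_pattern: str  # e.g. "qRs", "QS", "RsR′"
    st_class: str     # elevated / depressed / isoelectric
    t_class: str      # upright / inverted / biphasic / flat


def classify_wave(samples: np.ndarray, flat_thresh: float = FLAT_THRESH_MV) -> str:
    """Classify a baseline-referenced wave window.

    flat if no excursion reaches ``flat_thresh``; biphasic when both
    polarities do; otherwise upright/inverted by the dominant polarity.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty wave window")
    hi, lo = float(x.max()), float(x.min())
    pos, neg = hi >= flat_thresh, -lo >= flat_thresh
    if pos and neg:
        return "biphasic"
    if not pos and not neg:
        return "flat"
    return "upright" if pos else "inverted"


def _lobes(x: np.ndarray, flat_thresh: float) -> list[float]:
    """Signed peak of each zero-crossing-separated lobe above threshold."""
    sign = np.sign(x)
    sign[sign == 0] = 1
    peaks: list[float] = []
    start = 0
    for i in range(1, x.size + 1):
        if i == x.size or sign[i] != sign[start]:
            seg = x[start:i]
            peak = seg[np.argmax(np.abs(seg))]
            if abs(peak) >= flat_thresh:
                # merge consecutive same-sign lobes split by grazing zeros
                if peaks and np.sign(peaks[-1]) == np.sign(peak):
                    peaks[-1] = max(peaks[-1], peak, key=abs)
                else:
                    peaks.append(float(peak))
            start = i
    return peaks


def classify_qrs(samples: np.ndarray, flat_thresh: float = FLAT_THRESH_MV) -> str:
    """Name the QRS pattern of a baseline-referenced window.

    Deflections are zero-crossing-separated lobes exceeding the flat
    threshold.  Initial negatives are Q/q, positives R/r (a second
    positive gains a prime), post-R negatives S/s.  A lobe is upper-case
    when its |peak| exceeds half the largest lobe's.  A single
    all-negative deflection is the ``QS`` pattern.
    """
    x = np.asarray(samples, dtype=float)
    peaks = _lobes(x, flat_thresh)
    if not peaks:
        raise EmptyQRS("no deflection exceeds the flat threshold")
    if all(p < 0 for p in peaks) and len(peaks) == 1:
        return "QS"
    largest = max(abs(p) for p in peaks)
    letters: list[str] = []
    seen_positive = 0
    seen_post_r_negative = 0
    for p in peaks:
        major = abs(p) > MAJOR_LOBE_FRACTION * largest
        if p > 0:
            letter = "R" if major else "r"
            if seen_positive >= 1:
                letter += PRIME
            seen_positive += 1
        elif seen_positive == 0:
            letter = "Q" if major else "q"
        else:
            letter = "S" if major else "s"
            if seen_post_r_negative >= 1:
                letter += PRIME
            seen_post_r_negative += 1
        letters.append(letter)
    return "".join(letters)


def classify_st(st_level: float) -> str:
    if st_level >= ST_ELEVATED_MV:
        return "elevated"
    if st_level <= ST_DEPRESSED_MV:
        return "depressed"
    return "isoelectric"


def describe_lead(rec, lead: str, fid) -> MorphologyDescriptor:
    """Full descriptor for one lead of one delineated beat."""
    from .delineation import segment_windows

    sig = rec.lead(lead)
    pr, qrs, stt = segment_windows(fid, rec.fs)
    baseline = float(np.mean(sig[pr.start:pr.end]))
    x = sig - baseline
    if fid.p_present:
        p_class = classify_wave(x[pr.start:pr.end])
    else:
        p_class = "absent"
    try:
        qrs_pattern = classify_qrs(x[qrs.start:qrs.end])
    except EmptyQRS:
        qrs_pattern = "flat"
    st_idx = min(rec.n_samples - 1, fid.qrs_offset + int(round(0.060 * rec.fs)))
    st_class = classify_st(float(x[st_idx]))
    # T window: skip the early ST plateau so the T wave dominates
    t_start = min(stt.end - 1, stt.start + int(round(0.08 * rec.fs)))
    t_class = classify_wave(x[t_start:stt.end])
    return MorphologyDescriptor(lead, p_class, qrs_pattern, st_class, t_class)


def descriptor_match(a: MorphologyDescriptor, b: MorphologyDescriptor) -> bool:
    """Complete match: all four descriptor fields equal."""
    return (a.p_class == b.p_class and a.qrs_pattern == b.qrs_pattern
            and a.st_class == b.st_class and a.t_class == b.t_class)


def morphology_similarity(A, B, by: str | None = None):
    """Proportion of index-aligned descriptor pairs in full agreement.

    ``A`` and ``B`` are aligned sequences of MorphologyDescriptor.  With
    ``by='lead'`` a per-lead breakdown dict is returned; with
    ``by='field'`` a per-descriptor-kind breakdown.
    """
    A, B = list(A), list(B)
    if len(A) != len(B):
        raise LengthMismatch(f"descriptor sets differ in length: {len(A)} vs {len(B)}")
    if not A:
        raise LengthMismatch("empty descriptor sets")
    if by is None:
        return sum(descriptor_match(a, b) for a, b in zip(A, B)) / len(A)
    if by == "lead":
        out: dict[str, list[bool]] = {}
        for a, b in zip(A, B):
            out.setdefault(a.lead, []).append(descriptor_match(a, b))
        return {lead: sum(v) / len(v) for lead, v in out.items()}
    if by == "field":
        fields = ("p_class", "qrs_pattern", "st_class", "t_class")
        return {f: sum(getattr(a, f) == getattr(b, f) for a, b in zip(A, B)) / len(A)
                for f in fields}
    raise ValueError(f"unknown aggregation {by!r}")
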