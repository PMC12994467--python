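"""Readers and writers for ECG/VCG records and covariate tables.

Two dialects are supported:

``csv``
    One column per lead with a header row of lead names, preceded by a
    metadata comment line ``# fs=<Hz> units=<mV|uV> posture=<supine|prone>``.
    Self-describing, diff-friendly, the preferred fixture format.

``wfdb``
    A minimal WFDB-compatible pair (``.hea`` header + format-16 ``.dat``,
    little-endian int16 with a per-signal gain in ADC units per millivolt).
    Implemented in-package; covers the single-segment, single-.dat layout
    used by this toolkit.

Amplitudes are normalised to millivolts on read.
"""

from __future__ import annotations

import os
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .errors import FormatError, MissingLead
from .records import LEAD_NAMES, ECGRecord, Posture, SubjectCovariates, VCGRecord

_VCG_LEADS = ("X", "Y", "Z")


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _parse_meta_line(line: str) -> dict[str, str]:
    if not line.startswith("#"):
        raise FormatError("CSV dialect requires a '# fs=... units=...' metadata line")
    meta: dict[str, str] = {}
    for token in line.lstrip("#").split():
        if "=" in token:
            key, val = token.split("=", 1)
            meta[key] = val
    if "fs" not in meta:
        raise FormatError("metadata line lacks fs=<Hz>")
    return meta


def _read_table_csv(path: Path, required: tuple[str, ...]):
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    meta = _parse_meta_line(lines[0])
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: {exc}") from exc
    for name in required:
        if name not in df.columns:
            raise MissingLead(f"{path}: required lead column {name!r} is missing")
    scale = 0.001 if meta.get("units", "mV") == "uV" else 1.0
    data = {name: df[name].to_numpy(dtype=float) * scale for name in required}
    if any(not np.all(np.isfinite(v)) for v in data.values()):
        raise FormatError(f"{path}: non-finite amplitude values")
    return meta, data


def _write_table_csv(path: Path, meta: str, columns: dict[str, np.ndarray]) -> None:
    df = pd.DataFrame(columns)
    with open(path, "w") as fh:
        fh.write(meta + "\n")
        df.to_csv(fh, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Minimal WFDB (format 16)
# ---------------------------------------------------------------------------

_WFDB_GAIN = 4000.0  # ADC units per millivolt; 0.25 uV resolution


def _read_wfdb(path: Path) -> tuple[float, dict[str, np.ndarray], str]:
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"header file {hea} not found")
    lines = [
        ln.strip() for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    comments = [
        ln.lstrip("# ").strip() for ln in hea.read_text().splitlines()
        if ln.startswith("#")
    ]
    head = lines[0].split()
    try:
        nsig, fs, nsamp = int(head[1]), float(head[2]), int(head[3])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{hea}: malformed record line") from exc
    names, gains, datfile = [], [], None
    for ln in lines[1 : 1 + nsig]:
        parts = ln.split()
        datfile = parts[0]
        fmt = parts[1]
        if fmt != "16":
            raise FormatError(f"{hea}: only format 16 supported, got {fmt}")
        gains.append(float(parts[2].split("/")[0].split("(")[0]))
        names.append(parts[-1])
    raw = np.fromfile(path.parent / datfile, dtype="<i2")
    if raw.size != nsig * nsamp:
        raise FormatError(f"{datfile}: expected {nsig * nsamp} samples, found {raw.size}")
    raw = raw.reshape(nsamp, nsig).T.astype(float)
    data = {name: raw[i] / gains[i] for i, name in enumerate(names)}
    posture = ""
    for c in comments:
        if c.startswith("posture"):
            posture = c.split("=", 1)[-1].strip()
    return fs, data, posture


def _write_wfdb(path: Path, fs: float, columns: dict[str, np.ndarray],
                posture: str = "") -> None:
    hea = path.with_suffix(".hea")
    dat = path.with_suffix(".dat").name
    names = list(columns)
    nsamp = len(next(iter(columns.values())))
    lines = [f"{path.stem} {len(names)} {fs:g} {nsamp}"]
    for name in names:
        lines.append(f"{dat} 16 {_WFDB_GAIN:g}/mV 16 0 0 0 0 {name}")
    if posture:
        lines.append(f"# posture={posture}")
    hea.write_text("\n".join(lines) + "\n")
    arr = np.vstack([columns[n] for n in names]) * _WFDB_GAIN
    arr = np.clip(np.round(arr), -32768, 32767).astype("<i2")
    arr.T.tofile(path.with_suffix(".dat"))


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_ecg(path: str | os.PathLike, dialect: str = "csv") -> ECGRecord:
    """Read a 12-lead ECG record, normalising units to millivolts.

    Lead order is canonicalised to I, II, III, aVR, aVL, aVF, V1–V6.
    """
    path = Path(path)
    if dialect == "csv":
        meta, data = _read_table_csv(path, LEAD_NAMES)
        posture = meta.get("posture", "supine")
        fs = float(meta["fs"])
    elif dialect == "wfdb":
        fs, data, posture = _read_wfdb(path)
        missing = [n for n in LEAD_NAMES if n not in data]
        if missing:
            raise MissingLead(f"{path}: required lead column {missing[0]!r} is missing")
        posture = posture or "supine"
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    return ECGRecord.from_lead_dict(
        {n: data[n] for n in LEAD_NAMES}, fs=fs,
        posture=Posture(posture), subject_id=path.stem,
    )


def write_ecg(rec: ECGRecord, path: str | os.PathLike, dialect: str = "csv") -> None:
    path = Path(path)
    columns = {n: rec.lead(n) for n in rec.lead_names}
    if dialect == "csv":
        meta = f"# fs={rec.fs:g} units=mV posture={rec.posture.value}"
        _write_table_csv(path, meta, columns)
    elif dialect == "wfdb":
        _write_wfdb(path, rec.fs, columns, posture=rec.posture.value)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")


def read_vcg(path: str | os.PathLike, dialect: str = "csv") -> VCGRecord:
    """Read a 3-lead orthogonal VCG record (columns X, Y, Z)."""
    path = Path(path)
    if dialect == "csv":
        meta, data = _read_table_csv(path, _VCG_LEADS)
        fs = float(meta["fs"])
    elif dialect == "wfdb":
        fs, data, _ = _read_wfdb(path)
        missing = [n for n in _VCG_LEADS if n not in data]
        if missing:
            raise MissingLead(f"{path}: required lead column {missing[0]!r} is missing")
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    xyz = np.vstack([data[n] for n in _VCG_LEADS])
    return VCGRecord(xyz, fs=fs, subject_id=path.stem)


def write_vcg(vcg: VCGRecord, path: str | os.PathLike, dialect: str = "csv") -> None:
    path = Path(path)
    columns = dict(zip(_VCG_LEADS, vcg.xyz))
    if dialect == "csv":
        _write_table_csv(path, f"# fs={vcg.fs:g} units=mV", columns)
    elif dialect == "wfdb":
        _write_wfdb(path, vcg.fs, columns)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")


def read_covariates(path: str | os.PathLike) -> dict[str, SubjectCovariates]:
    """Read a covariate table (CSV keyed by subject_id) into a dict."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    for col in ("subject_id",) + SubjectCovariates.FIELDS:
        if col not in df.columns:
            raise FormatError(f"covariate table lacks column {col!r}")
    return {
        row["subject_id"]: SubjectCovariates(
            male=int(row["male"]), age=float(row["age"]),
            height=float(row["height"]), weight=float(row["weight"]),
            chest=float(row["chest"]), waist=float(row["waist"]),
        )
        for _, row in df.iterrows()
    }


def write_covariates(cov: dict[str, SubjectCovariates], path: str | os.PathLike) -> None:
    rows = [{"subject_id": sid, **{f: getattr(c, f) for f in SubjectCovariates.FIELDS}}
            for sid, c in cov.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def resample(rec: ECGRecord, fs_target: float) -> ECGRecord:
    """Band-limited resampling of all leads to ``fs_target`` Hz.

    Uses polyphase filtering with the rational approximation of the rate
    ratio; a no-op when the target rate equals the record's rate.
    """
    if fs_target <= 0:
        raise ValueError("fs_target must be positive")
    if fs_target == rec.fs:
        return rec
    frac = Fraction(fs_target / rec.fs).limit_denominator(1000)
    sig = resample_poly(rec.signals, frac.numerator, frac.denominator, axis=1)
    return ECGRecord(sig, rec.lead_names, fs_target, rec.posture, rec.subject_id)
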