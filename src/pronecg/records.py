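"""Core signal and covariate containers.

All amplitudes are stored in millivolts on a common 500 Hz-style time base.
An :class:`ECGRecord` holds the 12 conventional leads in canonical order;
a :class:`VCGRecord` holds the three orthogonal (Frank) leads X, Y, Z.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import MissingLead

#: Canonical 12-lead ordering used everywhere in the toolkit.
LEAD_NAMES: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

LIMB_LEADS: tuple[str, ...] = LEAD_NAMES[:6]
PRECORDIAL_LEADS: tuple[str, ...] = LEAD_NAMES[6:]

#: The eight electrically independent leads; III/aVR/aVL/aVF derive from I, II.
INDEPENDENT_LEADS: tuple[str, ...] = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")


class Posture(str, enum.Enum):
    SUPINE = "supine"
    PRONE = "prone"


class DiagnosisLabel(str, enum.Enum):
    """Closed diagnosis enumeration of the cohort class mix."""

    NORMAL = "Normal"
    ST_ELEVATION = "ST_elevation"
    OLD_MI = "Old_MI"
    ST_DEPRESSION = "ST_depression"
    CLBBB = "CLBBB"
    CRBBB_RBBB = "CRBBB_RBBB"
    LAH = "LAH"


@dataclass
class ECGRecord:
    """A multichannel 12-lead ECG in millivolts.

    Parameters
    ----------
    signals : (n_leads, n_samples) float array, millivolts.
    lead_names : lead labels matching the rows of ``signals``.
    fs : sampling rate in Hz.
    posture : recording posture (supine or prone).
    subject_id : opaque identifier.
    """

    signals: np.ndarray
    lead_names: tuple[str, ...] = LEAD_NAMES
    fs: float = 500.0
    posture: Posture = Posture.SUPINE
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.lead_names = tuple(self.lead_names)
        self.posture = Posture(self.posture)
        if self.signals.ndim != 2 or self.signals.shape[0] != len(self.lead_names):
            raise ValueError("signals must be (n_leads, n_samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("amplitudes must be finite")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def is_complete(self) -> bool:
        return set(self.lead_names) == set(LEAD_NAMES)

    def lead(self, name: str) -> np.ndarray:
        try:
            return self.signals[self.lead_names.index(name)]
        except ValueError:
            raise MissingLead(f"lead {name!r} not present in record") from None

    def has_lead(self, name: str) -> bool:
        return name in self.lead_names

    def with_lead(self, name: str, samples: np.ndarray) -> "ECGRecord":
        """Return a copy with one lead replaced."""
        sig = self.signals.copy()
        sig[self.lead_names.index(name)] = samples
        return replace(self, signals=sig)

    @classmethod
    def from_lead_dict(
        cls,
        leads: Mapping[str, np.ndarray],
        fs: float,
        posture: Posture | str = Posture.SUPINE,
        subject_id: str = "",
    ) -> "ECGRecord":
        """Build a record from a lead-name → samples mapping, canonically ordered."""
        names = tuple(n for n in LEAD_NAMES if n in leads)
        extra = set(leads) - set(LEAD_NAMES)
        if extra:
            raise MissingLead(f"unknown lead names: {sorted(extra)}")
        sig = np.vstack([np.asarray(leads[n], dtype=float) for n in names])
        return cls(sig, names, fs, Posture(posture), subject_id)


@dataclass
class VCGRecord:
    """Orthogonal-lead vectorcardiogram (X, Y, Z) in millivolts."""

    xyz: np.ndarray  # (3, n_samples)
    fs: float = 500.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[0] != 3:
            raise ValueError("xyz must be (3, n_samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("values must be finite")

    @property
    def X(self) -> np.ndarray:
        return self.xyz[0]

    @property
    def Y(self) -> np.ndarray:
        return self.xyz[1]

    @property
    def Z(self) -> np.ndarray:
        return self.xyz[2]

    @property
    def n_samples(self) -> int:
        return self.xyz.shape[1]


@dataclass(frozen=True)
class SubjectCovariates:
    """Anthropometric covariates recorded for every participant."""

    male: int
    age: float
    height: float
    weight: float
    chest: float
    waist: float

    FIELDS = ("male", "age", "height", "weight", "chest", "waist")

    def __post_init__(self) -> None:
        if self.male not in (0, 1):
            raise ValueError("male must be 0 or 1")
        if self.age < 0:
            raise ValueError("age must be non-negative")
        for name in ("height", "weight", "chest", "waist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def as_array(self, fields: tuple[str, ...] = FIELDS) -> np.ndarray:
        return np.array([float(getattr(self, f)) for f in fields])
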