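"""Fixed VCG-to-ECG transform matrices (Dower, Uijen) and their projection.

A transform matrix stores one (X, Y, Z) weight row per electrically
independent lead (I, II, V1-V6); the four derived limb leads are computed
from I and II by the Einthoven/Goldberger identities and never stored:

    III = II - I,  aVR = -(I + II)/2,  aVL = I - II/2,  aVF = II - I/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import INDEPENDENT_LEADS, LEAD_NAMES, ECGRecord, Posture, VCGRecord


@dataclass(frozen=True)
class TransformMatrix:
    """Per-lead (X, Y, Z) projection weights for the 8 independent leads."""

    name: str
    rows: dict[str, tuple[float, float, float]]
    citation: str = ""

    def __post_init__(self) -> None:
        missing = set(INDEPENDENT_LEADS) - set(self.rows)
        if missing:
            raise ValueError(f"transform {self.name} lacks rows for {sorted(missing)}")

    def row(self, lead: str) -> np.ndarray:
        return np.asarray(self.rows[lead], dtype=float)

    def full_rows(self) -> dict[str, np.ndarray]:
        """Rows for all 12 leads, deriving the limb-augmented leads from I, II."""
        r = {lead: self.row(lead) for lead in INDEPENDENT_LEADS}
        r["III"] = r["II"] - r["I"]
        r["aVR"] = -(r["I"] + r["II"]) / 2.0
        r["aVL"] = r["I"] - r["II"] / 2.0
        r["aVF"] = r["II"] - r["I"] / 2.0
        return r


#: Classic Dower VCG→ECG matrix (Frank leads to the 8 independent leads).
DOWER = TransformMatrix(
    name="Dower",
    rows={
        "I":  (0.632, -0.235, 0.059),
        "II": (0.235, 1.066, -0.132),
        "V1": (-0.515, 0.157, -0.917),
        "V2": (0.044, 0.164, -1.387),
        "V3": (0.882, 0.098, -1.277),
        "V4": (1.213, 0.127, -0.601),
        "V5": (1.125, 0.127, -0.086),
        "V6": (0.831, 0.076, 0.230),
    },
    citation="Dower GE et al., synthesis of the 12-lead ECG from Frank leads "
             "(tabulation after Edenbrandt & Pahlm, J Electrocardiol 1988).",
)

#: Regression-style VCG→ECG matrix in the spirit of Uijen & van Oosterom.
#: SYNTHETIC STAND-IN: the exact published entries were not available when
#: this fixture was assembled; these values are a plausible regression-
#: flavoured variant of the dipole geometry and are clearly labelled so.
#: Replace via TransformMatrix(...) in config for production use.
UIJEN = TransformMatrix(
    name="Uijen",
    rows={
        "I":  (0.701, -0.201, 0.036),
        "II": (0.292, 0.987, -0.090),
        "V1": (-0.461, 0.104, -0.860),
        "V2": (-0.013, 0.191, -1.293),
        "V3": (0.796, 0.161, -1.191),
        "V4": (1.280, 0.091, -0.554),
        "V5": (1.181, 0.104, -0.040),
        "V6": (0.851, 0.091, 0.241),
    },
    citation="Synthetic stand-in for the Uijen regression VCG→ECG transform "
             "(original coefficients unavailable; see package docs).",
)

MATRICES: dict[str, TransformMatrix] = {"dower": DOWER, "uijen": UIJEN}


def vcg_to_ecg(vcg: VCGRecord, matrix: TransformMatrix,
               subject_id: str | None = None) -> ECGRecord:
    """Project an orthogonal VCG to a 12-lead ECG through ``matrix``.

    Linear: superposition holds to numerical precision, and the limb-lead
    identities hold exactly on every output by construction.
    """
    rows = matrix.full_rows()
    sig = np.vstack([rows[lead] @ vcg.xyz for lead in LEAD_NAMES])
    return ECGRecord(sig, LEAD_NAMES, vcg.fs, Posture.SUPINE,
                     subject_id if subject_id is not None else vcg.subject_id)
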