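"""Approach 1: direct per-lead linear regression on inversely paired leads.

In the prone electrode geometry the anterior standard leads pick up the
dipole from roughly opposite directions: standard V1 pairs inversely with
prone V4, V2 with prone V2, and V4 with prone V1.  Each of the three
target leads is regressed on its prone counterpart plus age and sex,
pooled over all time points of the healthy subjects' beats.  V3 and V5
are then derived geometrically as midpoints:

    V3 = (V2 + V4) / 2      V5 = (V4 + V6) / 2

V6 and the limb leads pass through from the prone record unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientData, LengthMismatch, ModelNotFitted
from .records import DiagnosisLabel, ECGRecord, Posture, SubjectCovariates

#: standard target lead -> inversely correlated prone source lead
INVERSE_PAIRS: dict[str, str] = {"V1": "V4", "V2": "V2", "V4": "V1"}

#: covariates entering Approach 1 (the demographic pair)
COVARIATE_FIELDS: tuple[str, ...] = ("male", "age")


def derive_midpoint_lead(lead_a: np.ndarray, lead_b: np.ndarray) -> np.ndarray:
    """Elementwise mean of two equal-length amplitude series."""
    a = np.asarray(lead_a, dtype=float)
    b = np.asarray(lead_b, dtype=float)
    if a.shape != b.shape:
        raise LengthMismatch(f"series lengths differ: {a.shape} vs {b.shape}")
    return (a + b) / 2.0


@dataclass
class DirectLeadModel:
    """Per-target-lead OLS coefficients with goodness-of-fit metadata."""

    predictors: dict[str, list[str]] = field(default_factory=dict)
    coef: dict[str, np.ndarray] = field(default_factory=dict)
    intercept: dict[str, float] = field(default_factory=dict)
    r2: dict[str, float] = field(default_factory=dict)
    n: int = 0

    @property
    def fitted(self) -> bool:
        return set(self.coef) == set(INVERSE_PAIRS)

    def to_json(self) -> str:
        return json.dumps({
            "schema": "pronecg.direct_lead_model.v1",
            "n": self.n,
            "leads": {
                lead: {
                    "predictors": self.predictors[lead],
                    "coef": list(map(float, self.coef[lead])),
                    "intercept": self.intercept[lead],
                    "r2": self.r2[lead],
                }
                for lead in self.coef
            },
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DirectLeadModel":
        doc = json.loads(text)
        m = cls(n=doc["n"])
        for lead, entry in doc["leads"].items():
            m.predictors[lead] = list(entry["predictors"])
            m.coef[lead] = np.asarray(entry["coef"], dtype=float)
            m.intercept[lead] = float(entry["intercept"])
            m.r2[lead] = float(entry["r2"])
        return m


def _pooled_design(pairs, restrict):
    """Stack (prone-lead value, covariates) rows across subjects and samples."""
    cols: dict[str, list[np.ndarray]] = {t: [] for t in INVERSE_PAIRS}
    ys: dict[str, list[np.ndarray]] = {t: [] for t in INVERSE_PAIRS}
    for prone, supine, cov, label in pairs:
        if restrict is not None and label not in restrict:
            continue
        cov_vals = cov.as_array(COVARIATE_FIELDS)
        n = prone.n_samples
        for target, source in INVERSE_PAIRS.items():
            x = np.column_stack([
                prone.lead(source),
                np.tile(cov_vals, (n, 1)),
            ])
            cols[target].append(x)
            ys[target].append(supine.lead(target))
    return cols, ys


def fit_direct(
    pairs,
    restrict: set[DiagnosisLabel] | None = frozenset({DiagnosisLabel.NORMAL}),
) -> DirectLeadModel:
    """Fit the three direct-lead regressions.

    Parameters
    ----------
    pairs : iterable of (prone ECGRecord, supine ECGRecord, SubjectCovariates,
        DiagnosisLabel) tuples; signals are pooled over all time points.
    restrict : diagnosis classes to keep (default: healthy subjects only,
        the development rule); ``None`` keeps everyone.
    """
    cols, ys = _pooled_design(list(pairs), restrict)
    model = DirectLeadModel()
    for target in INVERSE_PAIRS:
        if not cols[target]:
            raise InsufficientData("no eligible subjects after restriction")
        X = np.vstack(cols[target])
        y = np.concatenate(ys[target])
        if X.shape[0] < X.shape[1] + 2:
            raise InsufficientData(
                f"{X.shape[0]} samples for {X.shape[1]} predictors on {target}")
        A = np.column_stack([np.ones(len(X)), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        yhat = A @ beta
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        model.predictors[target] = [f"prone_{INVERSE_PAIRS[target]}"] + list(COVARIATE_FIELDS)
        model.intercept[target] = float(beta[0])
        model.coef[target] = beta[1:]
        model.r2[target] = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        model.n = max(model.n, len(y))
    return model


def convert_direct(model: DirectLeadModel, prone: ECGRecord,
                   cov: SubjectCovariates) -> ECGRecord:
    """Convert a complete prone record to a standard-posture estimate.

    V1, V2, V4 come from the fitted regressions; V3 and V5 are midpoints of
    their converted neighbours (V5 uses the passed-through prone V6); V6 and
    all limb leads pass through unchanged.
    """
    if not model.fitted:
        raise ModelNotFitted("fit_direct must be called before conversion")
    if not prone.is_complete:
        raise ValueError("conversion requires a complete 12-lead prone record")
    cov_vals = cov.as_array(COVARIATE_FIELDS)
    out = {lead: prone.lead(lead).copy() for lead in prone.lead_names}
    for target, source in INVERSE_PAIRS.items():
        x = prone.lead(source)
        beta = model.coef[target]
        out[target] = (model.intercept[target] + beta[0] * x
                       + float(beta[1:] @ cov_vals))
    out["V3"] = derive_midpoint_lead(out["V2"], out["V4"])
    out["V5"] = derive_midpoint_lead(out["V4"], out["V6"])
    rec = ECGRecord.from_lead_dict(out, fs=prone.fs, posture=Posture.SUPINE,
                                   subject_id=prone.subject_id)
    return rec
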