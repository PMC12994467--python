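"""Approach 2: prone ECG -> VCG regression, then VCG -> standard ECG.

The orthogonal leads X, Y, Z are regressed on the 12 prone leads plus four
covariates (Male, Age, Height, Weight) by ordinary least squares, pooled
over all time points.  The predicted VCG is then projected to the
standard 12-lead ECG with a fixed transform matrix; the per-lead matrix
selection rule uses the Uijen transform for V1, V2, V4, V5 (and V6) and
the Dower transform for V3, with limb leads taken from the Uijen
projection.

Note on collinearity: on a noise-free cohort every prone lead is an exact
projection of the same 3-D dipole, so the 12 prone-lead columns have rank
3 and the pooled design is rank deficient.  The fit then returns the
minimum-norm least-squares solution and issues a RankDeficientWarning;
predictions (and hence R^2) are unaffected.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientData, ModelNotFitted, RankDeficientWarning, SchemaMismatch
from .records import ECGRecord, LEAD_NAMES, SubjectCovariates, VCGRecord
from .transforms import DOWER, MATRICES, UIJEN, TransformMatrix, vcg_to_ecg

#: predictor schema, ordered as the coefficient table rows
PREDICTOR_NAMES: tuple[str, ...] = tuple(f"Lead {n}" for n in LEAD_NAMES) + (
    "Male", "Age", "Height", "Weight")

COVARIATE_FIELDS: tuple[str, ...] = ("male", "age", "height", "weight")

TARGETS: tuple[str, ...] = ("X", "Y", "Z")

#: the per-lead transform selection rule (Dower preferred for V3 only)
DEFAULT_MATRIX_RULE: dict[str, str] = {
    "V1": "uijen", "V2": "uijen", "V3": "dower",
    "V4": "uijen", "V5": "uijen", "V6": "uijen",
}


@dataclass
class VCGRegressionModel:
    """16-predictor x 3-target OLS coefficient matrix with intercepts."""

    B: np.ndarray | None = None          # (16, 3)
    intercept: np.ndarray | None = None  # (3,)
    r2: dict[str, float] = field(default_factory=dict)
    n: int = 0
    predictor_names: tuple[str, ...] = PREDICTOR_NAMES
    scale_note: str = ""

    @property
    def fitted(self) -> bool:
        return self.B is not None

    def coefficient(self, predictor: str, target: str) -> float:
        if not self.fitted:
            raise ModelNotFitted("model has no coefficients")
        return float(self.B[self.predictor_names.index(predictor),
                            TARGETS.index(target)])

    def to_json(self) -> str:
        if not self.fitted:
            raise ModelNotFitted("cannot serialise an unfitted model")
        return json.dumps({
            "schema": "pronecg.vcg_regression_model.v1",
            "predictors": list(self.predictor_names),
            "targets": list(TARGETS),
            "B": self.B.tolist(),
            "intercept": self.intercept.tolist(),
            "r2": self.r2,
            "n": self.n,
            "scale_note": self.scale_note,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "VCGRegressionModel":
        doc = json.loads(text)
        return cls(B=np.asarray(doc["B"], dtype=float),
                   intercept=np.asarray(doc["intercept"], dtype=float),
                   r2=dict(doc["r2"]), n=int(doc["n"]),
                   predictor_names=tuple(doc["predictors"]),
                   scale_note=doc.get("scale_note", ""))


def published_cohort_model() -> VCGRegressionModel:
    """The packaged cohort coefficient table as a read-only model.

    Flagged ``scale-unknown``: the source table does not state predictor
    standardisation or intercepts, so this fixture documents the published
    map but is excluded from amplitude-accuracy claims.  Fit a fresh model
    with :func:`fit_prone_to_vcg` for validated conversions.
    """
    from importlib import resources

    text = (resources.files("pronecg") / "data" / "cohort_vcg_coefficients.json").read_text()
    return VCGRegressionModel.from_json(text)


def _design_matrix(prone: ECGRecord, cov: SubjectCovariates) -> np.ndarray:
    n = prone.n_samples
    leads = np.column_stack([prone.lead(name) for name in LEAD_NAMES])
    covs = np.tile(cov.as_array(COVARIATE_FIELDS), (n, 1))
    return np.column_stack([leads, covs])


def fit_prone_to_vcg(cohort) -> VCGRegressionModel:
    """Fit X, Y, Z on the pooled (prone leads + covariates) design.

    Parameters
    ----------
    cohort : iterable of (prone ECGRecord, VCGRecord, SubjectCovariates)
        triples with time-aligned prone and VCG series.
    """
    Xs, Ys = [], []
    for prone, vcg, cov in cohort:
        if prone.n_samples != vcg.n_samples:
            raise SchemaMismatch("prone record and VCG must share a time base")
        Xs.append(_design_matrix(prone, cov))
        Ys.append(vcg.xyz.T)
    if not Xs:
        raise InsufficientData("empty cohort")
    X = np.vstack(Xs)
    Y = np.vstack(Ys)
    n_pred = X.shape[1]
    if X.shape[0] < n_pred + 2:
        raise InsufficientData(f"{X.shape[0]} samples for {n_pred} predictors")
    A = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        warnings.warn(
            f"design rank {rank} < {A.shape[1]}; returning minimum-norm solution",
            RankDeficientWarning, stacklevel=2)
    beta, *_ = np.linalg.lstsq(A, Y, rcond=None)
    model = VCGRegressionModel(B=beta[1:], intercept=beta[0], n=len(X))
    resid = Y - A @ beta
    for j, target in enumerate(TARGETS):
        ss_res = float(np.sum(resid[:, j] ** 2))
        ss_tot = float(np.sum((Y[:, j] - Y[:, j].mean()) ** 2))
        model.r2[target] = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return model


def apply_prone_to_vcg(model: VCGRegressionModel, prone: ECGRecord,
                       cov: SubjectCovariates) -> VCGRecord:
    """Predict the orthogonal VCG from a complete prone record."""
    if not model.fitted:
        raise ModelNotFitted("fit_prone_to_vcg must run first")
    if model.predictor_names != PREDICTOR_NAMES:
        raise SchemaMismatch("model predictor schema does not match")
    if not prone.is_complete:
        raise SchemaMismatch("complete 12-lead prone record required")
    X = _design_matrix(prone, cov)
    xyz = (X @ model.B + model.intercept).T
    return VCGRecord(xyz, fs=prone.fs, subject_id=prone.subject_id)


def convert_approach2(model: VCGRegressionModel, prone: ECGRecord,
                      cov: SubjectCovariates,
                      matrix_rule: dict[str, str] | str | None = None) -> ECGRecord:
    """Full Approach-2 conversion with the per-lead matrix selection rule.

    ``matrix_rule`` may be a per-precordial-lead mapping to matrix names, or
    the shorthand strings ``"dower"`` / ``"uijen"`` / ``"hybrid"`` (default:
    the hybrid selection, Dower for V3 and Uijen elsewhere).
    """
    if matrix_rule is None or matrix_rule == "hybrid":
        rule = dict(DEFAULT_MATRIX_RULE)
    elif isinstance(matrix_rule, str):
        if matrix_rule not in MATRICES:
            raise ValueError(f"unknown matrix rule {matrix_rule!r}")
        rule = {lead: matrix_rule for lead in DEFAULT_MATRIX_RULE}
    else:
        rule = {**DEFAULT_MATRIX_RULE, **matrix_rule}

    vcg = apply_prone_to_vcg(model, prone, cov)
    base = vcg_to_ecg(vcg, UIJEN, subject_id=prone.subject_id)
    projections = {name: vcg_to_ecg(vcg, m, subject_id=prone.subject_id)
                   for name, m in MATRICES.items()}
    out = base
    for lead, name in rule.items():
        out = out.with_lead(lead, projections[name].lead(lead))
    return out
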