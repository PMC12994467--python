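"""Approach 3: per-lead, per-segment tree-ensemble regression.

Every (beat, normalised time point) contributes one row: the 12 prone-lead
amplitudes at that time point plus six subject covariates (18 features)
predict the matched standard-lead amplitude.  Separate models are fitted
for each target lead V1-V5 and each modelling segment (P-R, QRS, ST-T),
with participant-level train/test splitting and grouped five-fold
cross-validation so no subject's cycles ever appear on both sides.

Hyperparameters default to the study values: random forest with
ntree=500, mtry=6; gradient boosting with eta=0.1, max_depth=2,
gamma=0.001, colsample_bytree=0.4 (nrounds configurable, default 500).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GroupKFold

from .delineation import BeatFiducials, SegmentKind, segment_windows
from .errors import (
    EmptySlot,
    LeakageError,
    MissingCovariate,
    ModelNotFitted,
    TooManyFolds,
    UndelineatedBeat,
)
from .records import LEAD_NAMES, ECGRecord, Posture, SubjectCovariates

TARGET_LEADS: tuple[str, ...] = ("V1", "V2", "V3", "V4", "V5")

FEATURE_NAMES: tuple[str, ...] = tuple(f"prone_{n}" for n in LEAD_NAMES) + (
    "male", "age", "height", "weight", "chest", "waist")

#: fixed per-segment normalised lengths (samples at the 500 Hz reference rate)
SEGMENT_LENGTHS: dict[SegmentKind, int] = {
    SegmentKind.PR: 50, SegmentKind.QRS: 60, SegmentKind.STT: 200,
}

RF_DEFAULTS: dict[str, float] = {"ntree": 500, "mtry": 6}
XGB_DEFAULTS: dict[str, float] = {
    "eta": 0.1, "max_depth": 2, "gamma": 0.001,
    "colsample_bytree": 0.4, "nrounds": 500,
}

CROSSFADE_S = 0.010  # boundary blending window


def _resample_window(x: np.ndarray, length: int) -> np.ndarray:
    """Piecewise-linear time normalisation of a window to a fixed length."""
    if x.size == length:
        return np.asarray(x, dtype=float)
    src = np.linspace(0.0, 1.0, x.size)
    dst = np.linspace(0.0, 1.0, length)
    return np.interp(dst, src, x)


def build_feature_table(
    prone: ECGRecord,
    prone_fid: BeatFiducials,
    standard: ECGRecord,
    standard_fid: BeatFiducials,
    cov: SubjectCovariates,
    segment: SegmentKind,
    subject_id: str | None = None,
) -> pd.DataFrame:
    """Feature/target rows for one paired beat and one segment.

    Both beats' segment windows are time-normalised to the fixed segment
    length so that rows align prone features with standard targets.
    Columns: the 18 features, ``target_V1`` .. ``target_V5`` and ``group``.
    """
    if cov is None:
        raise MissingCovariate("subject covariates are required")
    if prone_fid is None or standard_fid is None:
        raise UndelineatedBeat("both beats must be delineated")
    length = SEGMENT_LENGTHS[segment]
    windows_p = {w.kind: w for w in segment_windows(prone_fid, prone.fs)}
    windows_s = {w.kind: w for w in segment_windows(standard_fid, standard.fs)}
    wp, ws = windows_p[segment], windows_s[segment]

    data: dict[str, np.ndarray] = {}
    for lead in LEAD_NAMES:
        data[f"prone_{lead}"] = _resample_window(
            prone.lead(lead)[wp.start:wp.end], length)
    for name in SubjectCovariates.FIELDS:
        data[name] = np.full(length, float(getattr(cov, name)))
    for lead in TARGET_LEADS:
        data[f"target_{lead}"] = _resample_window(
            standard.lead(lead)[ws.start:ws.end], length)
    df = pd.DataFrame(data)
    df["group"] = subject_id if subject_id is not None else prone.subject_id
    return df


def cohort_feature_tables(cohort, segments=tuple(SegmentKind)) -> dict[SegmentKind, pd.DataFrame]:
    """Pool per-beat feature tables over a simulated cohort.

    Prone beat *i* is paired with the subject's representative standard
    beat (the median-index beat), reflecting that the two recordings are
    sequential rather than simultaneous.
    """
    pooled: dict[SegmentKind, list[pd.DataFrame]] = {s: [] for s in segments}
    for subj in cohort:
        fids = subj.fiducials
        rep = fids[len(fids) // 2]
        for fid in fids:
            for seg in segments:
                pooled[seg].append(build_feature_table(
                    subj.prone, fid, subj.supine, rep, subj.covariates, seg,
                    subject_id=subj.subject_id))
    return {s: pd.concat(v, ignore_index=True) for s, v in pooled.items()}


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def participant_split(subject_ids, ratio: float, seed: int) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive participant-level split; train = round(ratio*n)."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    ids = sorted(subject_ids)
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    n_train = int(round(ratio * len(ids)))
    train, test = sorted(ids[:n_train]), sorted(ids[n_train:])
    assert_no_leakage(train, test)
    return train, test


def assert_no_leakage(train, test) -> None:
    """Public leakage guard: raises if any subject sits on both sides."""
    overlap = set(train) & set(test)
    if overlap:
        raise LeakageError(f"subjects in both partitions: {sorted(overlap)}")


# ---------------------------------------------------------------------------
# Model bundle
# ---------------------------------------------------------------------------

def _make_estimator(algo: str, params: dict, seed: int):
    if algo == "random_forest":
        p = {**RF_DEFAULTS, **(params or {})}
        return RandomForestRegressor(
            n_estimators=int(p["ntree"]), max_features=int(p["mtry"]),
            random_state=seed, n_jobs=1), p
    if algo == "gradient_boosted_trees":
        from xgboost import XGBRegressor

        p = {**XGB_DEFAULTS, **(params or {})}
        return XGBRegressor(
            learning_rate=float(p["eta"]), max_depth=int(p["max_depth"]),
            gamma=float(p["gamma"]), colsample_bytree=float(p["colsample_bytree"]),
            n_estimators=int(p["nrounds"]), random_state=seed,
            n_jobs=1, verbosity=0), p
    raise ValueError(f"unknown algorithm {algo!r}")


@dataclass
class SegmentModelBundle:
    """One fitted regressor per (target lead, segment)."""

    algorithm: str
    params: dict
    seed: int
    models: dict = dc_field(default_factory=dict)  # (lead, SegmentKind) -> estimator
    feature_names: tuple[str, ...] = FEATURE_NAMES

    @property
    def fitted(self) -> bool:
        return all((lead, seg) in self.models
                   for lead in TARGET_LEADS for seg in SegmentKind)

    def predict(self, lead: str, segment: SegmentKind, X: np.ndarray) -> np.ndarray:
        key = (lead, segment)
        if key not in self.models:
            raise ModelNotFitted(f"no model for {key}")
        return self.models[key].predict(X)


def train_segment_models(
    tables: dict[SegmentKind, pd.DataFrame],
    algo: str = "random_forest",
    params: dict | None = None,
    seed: int = 0,
    train_subjects=None,
    leads: tuple[str, ...] = TARGET_LEADS,
    segments: tuple[SegmentKind, ...] = tuple(SegmentKind),
) -> SegmentModelBundle:
    """Fit one model per (lead, segment) on the training subjects' rows."""
    _, resolved = _make_estimator(algo, params or {}, seed)
    bundle = SegmentModelBundle(algorithm=algo, params=resolved, seed=seed)
    for seg in segments:
        df = tables[seg]
        if train_subjects is not None:
            df = df[df["group"].isin(set(train_subjects))]
        if df.empty:
            raise EmptySlot(f"no training rows for segment {seg.value}")
        X = df[list(FEATURE_NAMES)].to_numpy()
        for lead in leads:
            est, _ = _make_estimator(algo, params or {}, seed)
            est.fit(X, df[f"target_{lead}"].to_numpy())
            bundle.models[(lead, seg)] = est
    return bundle


def crossvalidate(
    tables: dict[SegmentKind, pd.DataFrame],
    algo: str = "random_forest",
    params: dict | None = None,
    k: int = 5,
    seed: int = 0,
    leads: tuple[str, ...] = TARGET_LEADS,
    segments: tuple[SegmentKind, ...] = tuple(SegmentKind),
) -> pd.DataFrame:
    """Grouped k-fold CV; returns per-fold rows plus mean/sd summary rows.

    Folds partition subjects (no subject in two folds).  Columns: lead,
    segment, fold ('mean'/'sd' for the summary), rmse, mae, r2.
    """
    any_df = tables[segments[0]]
    n_subjects = any_df["group"].nunique()
    if k > n_subjects:
        raise TooManyFolds(f"{k} folds for {n_subjects} subjects")
    rows = []
    for seg in segments:
        df = tables[seg]
        X = df[list(FEATURE_NAMES)].to_numpy()
        groups = df["group"].to_numpy()
        splitter = GroupKFold(n_splits=k)
        for lead in leads:
            y = df[f"target_{lead}"].to_numpy()
            per_fold = []
            for fold, (tr, te) in enumerate(splitter.split(X, y, groups)):
                if set(groups[tr]) & set(groups[te]):
                    raise LeakageError("grouped CV produced overlapping folds")
                est, _ = _make_estimator(algo, params or {}, seed)
                est.fit(X[tr], y[tr])
                pred = est.predict(X[te])
                resid = y[te] - pred
                rmse = float(np.sqrt(np.mean(resid**2)))
                mae = float(np.mean(np.abs(resid)))
                sst = float(np.sum((y[te] - y[te].mean()) ** 2))
                r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else float("nan")
                per_fold.append((rmse, mae, r2))
                rows.append({"lead": lead, "segment": seg.value, "fold": str(fold),
                             "rmse": rmse, "mae": mae, "r2": r2})
            arr = np.array(per_fold)
            for stat, vals in (("mean", arr.mean(axis=0)), ("sd", arr.std(axis=0, ddof=1))):
                rows.append({"lead": lead, "segment": seg.value, "fold": stat,
                             "rmse": vals[0], "mae": vals[1], "r2": vals[2]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Beat reconstruction
# ---------------------------------------------------------------------------

def predict_full_beat(
    bundle: SegmentModelBundle,
    prone: ECGRecord,
    fid: BeatFiducials,
    cov: SubjectCovariates,
) -> dict[str, np.ndarray]:
    """Reconstruct one converted beat on the record's native time base.

    Per-segment predictions are mapped back from normalised time to the
    beat's windows and joined with a 10 ms decaying cross-fade at segment
    boundaries; samples outside [p_onset, t_offset) stay at baseline 0.
    Returns a lead -> full-length array dict for leads V1-V5.
    """
    if not bundle.fitted:
        raise ModelNotFitted("bundle has unfitted (lead, segment) slots")
    fs = prone.fs
    windows = segment_windows(fid, fs)
    cov_vals = np.array([float(getattr(cov, f)) for f in SubjectCovariates.FIELDS])
    out: dict[str, np.ndarray] = {}
    fade = max(1, int(round(CROSSFADE_S * fs)))
    for lead in TARGET_LEADS:
        y = np.zeros(prone.n_samples)
        prev_edge = 0.0
        for w in windows:
            length = SEGMENT_LENGTHS[w.kind]
            feats = np.column_stack(
                [_resample_window(prone.lead(name)[w.start:w.end], length)
                 for name in LEAD_NAMES]
                + [np.full(length, v) for v in cov_vals])
            pred_norm = bundle.predict(lead, w.kind, feats)
            pred = _resample_window(pred_norm, w.length)
            y[w.start:w.end] = pred
            # decaying correction into this segment removes the step at its onset
            n = min(fade, w.length)
            delta = prev_edge - pred[0]
            y[w.start:w.start + n] += delta * (1.0 - np.arange(n) / n)
            prev_edge = y[w.end - 1]
        out[lead] = y
    return out


def convert_approach3(
    bundle: SegmentModelBundle,
    prone: ECGRecord,
    fids: list[BeatFiducials],
    cov: SubjectCovariates,
) -> ECGRecord:
    """Convert a whole prone record beat by beat.

    Leads V1-V5 are model outputs; V6 and the limb leads pass through.
    """
    leads = {name: prone.lead(name).copy() for name in prone.lead_names}
    acc = {lead: np.zeros(prone.n_samples) for lead in TARGET_LEADS}
    for fid in fids:
        beat = predict_full_beat(bundle, prone, fid, cov)
        for lead in TARGET_LEADS:
            acc[lead] += beat[lead]
    for lead in TARGET_LEADS:
        leads[lead] = acc[lead]
    return ECGRecord.from_lead_dict(leads, fs=prone.fs, posture=Posture.SUPINE,
                                    subject_id=prone.subject_id)


def feature_importance(bundle: SegmentModelBundle) -> pd.DataFrame:
    """Native impurity/gain importances, ranked per (lead, segment)."""
    if not bundle.models:
        raise ModelNotFitted("bundle has no fitted models")
    rows = []
    for (lead, seg), est in bundle.models.items():
        imp = np.asarray(est.feature_importances_, dtype=float)
        order = np.argsort(-imp, kind="stable")
        for rank, idx in enumerate(order):
            rows.append({"lead": lead, "segment": seg.value,
                         "feature": bundle.feature_names[idx],
                         "importance": float(imp[idx]), "rank": rank})
    return pd.DataFrame(rows)
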