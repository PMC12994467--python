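"""Reproduction protocols: noise-free synthetic refits of the three approaches.

Each function regenerates its inputs from scratch at the study scale
(70 subjects, 590 prone cycles, 500 Hz) and runs one conversion approach
end to end, returning the goodness-of-fit summary.  These are the
protocols behind ``scripts/acceptance.py`` and the acceptance test suite.
"""

from __future__ import annotations

import warnings

import numpy as np

from .approach1 import fit_direct, convert_direct
from .approach2 import COVARIATE_FIELDS, fit_prone_to_vcg
from .approach3 import (
    FEATURE_NAMES,
    cohort_feature_tables,
    participant_split,
    train_segment_models,
)
from .delineation import SegmentKind
from .errors import RankDeficientWarning
from .evaluation import regression_metrics
from .records import LEAD_NAMES, VCGRecord
from .synthetic import SyntheticCohortConfig, simulate_cohort

STUDY_N_SUBJECTS = 70
STUDY_TOTAL_BEATS = 590


def _study_cohort(seed: int, n_subjects: int = STUDY_N_SUBJECTS,
                  total_beats: int = STUDY_TOTAL_BEATS):
    cfg = SyntheticCohortConfig(n_subjects=n_subjects, total_beats=total_beats,
                                noise_sd=0.0, seed=seed)
    return simulate_cohort(cfg)


def vcg_regression_refit_r2(seed: int, n_subjects: int = STUDY_N_SUBJECTS,
                            total_beats: int = STUDY_TOTAL_BEATS) -> dict[str, float]:
    """Refit the prone-ECG→VCG regression on a known linear map.

    The orthogonal targets X, Y, Z are generated exactly from the 12 prone
    leads plus Male/Age/Height/Weight through a fixed random 16x3
    coefficient matrix; the refit's per-target R² is returned.  On
    noise-free cohorts the pooled design is rank deficient (every lead is
    a projection of the same dipole), so the minimum-norm solution is
    used; predictions, and hence R², are exact.
    """
    cohort = _study_cohort(seed)
    rng = np.random.default_rng(seed + 1)
    B = rng.normal(0.0, 0.5, size=(16, 3))
    triples = []
    for s in cohort:
        X = np.column_stack([
            np.column_stack([s.prone.lead(n) for n in LEAD_NAMES]),
            np.tile(s.covariates.as_array(COVARIATE_FIELDS),
                    (s.prone.n_samples, 1)),
        ])
        triples.append((s.prone, VCGRecord((X @ B).T, fs=s.prone.fs), s.covariates))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RankDeficientWarning)
        model = fit_prone_to_vcg(triples)
    return {k: float(v) for k, v in model.r2.items()}


def direct_conversion_r2(seed: int, n_subjects: int = STUDY_N_SUBJECTS,
                         total_beats: int = STUDY_TOTAL_BEATS) -> dict[str, float]:
    """Fit the direct inverse-lead model on healthy subjects, convert all.

    Returns pooled R² of converted vs true standard signals for the three
    regression-derived leads.  The default prone field encodes the
    inverse V1/V4 pairing, so the noise-free refit is exact.
    """
    cohort = _study_cohort(seed)
    pairs = [(s.prone, s.supine, s.covariates, s.label) for s in cohort]
    model = fit_direct(pairs)  # healthy-labelled subjects only
    pooled_y = {lead: [] for lead in ("V1", "V2", "V4")}
    pooled_p = {lead: [] for lead in ("V1", "V2", "V4")}
    for s in cohort:
        conv = convert_direct(model, s.prone, s.covariates)
        for lead in pooled_y:
            pooled_y[lead].append(s.supine.lead(lead))
            pooled_p[lead].append(conv.lead(lead))
    return {
        lead: float(regression_metrics(np.concatenate(pooled_y[lead]),
                                       np.concatenate(pooled_p[lead])).r2)
        for lead in pooled_y
    }


def heldout_qrs_r2(algo: str, seed: int, lead: str = "V1",
                   n_subjects: int = STUDY_N_SUBJECTS,
                   total_beats: int = STUDY_TOTAL_BEATS,
                   nrounds: int = 1000) -> tuple[float, int]:
    """Held-out-subject R² of one QRS segment model under the 8:2 split.

    Trains with the study hyperparameters (forest: ntree=500, mtry=6;
    boosting: eta=0.1, max_depth=2, gamma=0.001, colsample_bytree=0.4)
    on the training subjects' QRS rows and scores the held-out subjects.
    Returns (r2, number of held-out rows).
    """
    cohort = _study_cohort(seed)
    tables = cohort_feature_tables(cohort, segments=(SegmentKind.QRS,))
    train_ids, test_ids = participant_split(cohort.subject_ids(), 0.8, seed=seed)
    params = {"nrounds": nrounds} if algo == "gradient_boosted_trees" else None
    bundle = train_segment_models(tables, algo, params, seed=seed,
                                  train_subjects=train_ids, leads=(lead,),
                                  segments=(SegmentKind.QRS,))
    df = tables[SegmentKind.QRS]
    test = df[df["group"].isin(set(test_ids))]
    X = test[list(FEATURE_NAMES)].to_numpy()
    y = test[f"target_{lead}"].to_numpy()
    pred = bundle.predict(lead, SegmentKind.QRS, X)
    return float(regression_metrics(y, pred).r2), len(y)


def split_sizes(n_subjects: int = STUDY_N_SUBJECTS, ratio: float = 0.8,
                seed: int = 0) -> tuple[int, int]:
    """Train/test subject counts of the participant-level split."""
    ids = [f"S{i + 1:03d}" for i in range(n_subjects)]
    train, test = participant_split(ids, ratio, seed)
    return len(train), len(test)
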