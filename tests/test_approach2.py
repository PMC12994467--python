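"""Prone-to-VCG regression and fixed-matrix VCG-to-ECG projection."""

import numpy as np
import pytest

from pronecg import (
    DOWER,
    LEAD_NAMES,
    UIJEN,
    apply_prone_to_vcg,
    convert_approach2,
    fit_prone_to_vcg,
    published_cohort_model,
    regression_metrics,
    vcg_to_ecg,
)
from pronecg.approach2 import (
    COVARIATE_FIELDS,
    PREDICTOR_NAMES,
    VCGRegressionModel,
)
from pronecg.errors import (
    InsufficientData,
    ModelNotFitted,
    RankDeficientWarning,
    SchemaMismatch,
)
from pronecg.records import ECGRecord, Posture, SubjectCovariates, VCGRecord
from pronecg.synthetic import LeadFieldMatrix
from pronecg.transforms import TransformMatrix

COV = SubjectCovariates(male=1, age=55.0, height=172.0, weight=68.0,
                        chest=91.0, waist=86.0)


def _prone(signals):
    return ECGRecord(signals, LEAD_NAMES, 500.0, Posture.PRONE, "P")


def _full_rank_cohort(rng, B, n_subjects=8, n=300):
    """Random full-rank prone designs whose VCG follows a known 16x3 map."""
    cohort = []
    for i in range(n_subjects):
        cov = SubjectCovariates(male=i % 2, age=float(rng.integers(20, 80)),
                                height=float(rng.uniform(150, 190)),
                                weight=float(rng.uniform(50, 100)),
                                chest=88.0, waist=84.0)
        prone = _prone(rng.normal(0, 0.5, size=(12, n)))
        X = np.column_stack([prone.signals.T,
                             np.tile(cov.as_array(COVARIATE_FIELDS), (n, 1))])
        cohort.append((prone, VCGRecord((X @ B).T), cov))
    return cohort


class TestFitProneToVcg:
    def test_exact_recovery_of_known_map(self, rng):
        B = rng.normal(0, 0.5, size=(16, 3))
        model = fit_prone_to_vcg(_full_rank_cohort(rng, B))
        assert np.max(np.abs(model.B - B)) < 1e-6
        for target in ("X", "Y", "Z"):
            assert model.r2[target] == pytest.approx(1.0, abs=1e-9)

    def test_published_fixture_coefficient(self):
        model = published_cohort_model()
        assert model.coefficient("Lead II", "X") == 1.123
        assert "scale-unknown" in model.scale_note
        assert model.r2 == {"X": 0.968, "Y": 0.968, "Z": 0.845}

    def test_rank_deficient_warns_and_still_predicts(self, rng):
        B = rng.normal(size=(16, 3))
        cohort = []
        # duplicated predictor column in every record, targets consistent
        for prone, _, cov in _full_rank_cohort(rng, B):
            prone.signals[1] = prone.signals[0]
            X = np.column_stack([prone.signals.T,
                                 np.tile(cov.as_array(COVARIATE_FIELDS),
                                         (prone.n_samples, 1))])
            cohort.append((prone, VCGRecord((X @ B).T), cov))
        with pytest.warns(RankDeficientWarning):
            model = fit_prone_to_vcg(cohort)
        for target in ("X", "Y", "Z"):
            assert model.r2[target] == pytest.approx(1.0, abs=1e-9)

    def test_insufficient_data(self, rng):
        cohort = _full_rank_cohort(rng, rng.normal(size=(16, 3)), n_subjects=1, n=5)
        with pytest.raises(InsufficientData):
            fit_prone_to_vcg(cohort)

    def test_misaligned_series_rejected(self, rng):
        prone = _prone(rng.normal(size=(12, 100)))
        with pytest.raises(SchemaMismatch):
            fit_prone_to_vcg([(prone, VCGRecord(np.zeros((3, 50))), COV)])

    def test_serialisation_round_trip(self, rng):
        model = fit_prone_to_vcg(_full_rank_cohort(rng, rng.normal(size=(16, 3))))
        back = VCGRegressionModel.from_json(model.to_json())
        assert np.allclose(back.B, model.B)
        assert back.predictor_names == PREDICTOR_NAMES


class TestApplyProneToVcg:
    def test_single_lead_selection_identity(self, rng):
        B = np.zeros((16, 3))
        B[0, 0] = 1.0  # X = prone lead I
        model = VCGRegressionModel(B=B, intercept=np.zeros(3))
        prone = _prone(rng.normal(size=(12, 200)))
        vcg = apply_prone_to_vcg(model, prone, COV)
        assert np.allclose(vcg.X, prone.lead("I"))

    def test_linearity_in_prone_signal(self, rng):
        B = rng.normal(size=(16, 3))
        B[12:] = 0.0  # zero covariate terms
        model = VCGRegressionModel(B=B, intercept=np.zeros(3))
        prone = _prone(rng.normal(size=(12, 150)))
        doubled = _prone(2 * prone.signals)
        v1 = apply_prone_to_vcg(model, prone, COV)
        v2 = apply_prone_to_vcg(model, doubled, COV)
        assert np.allclose(v2.xyz, 2 * v1.xyz)

    def test_fit_then_apply_recovers_generator_vcg(self, clean_cohort):
        model = fit_prone_to_vcg(
            [(s.prone, s.vcg, s.covariates) for s in clean_cohort])
        for s in clean_cohort.subjects[:3]:
            pred = apply_prone_to_vcg(model, s.prone, s.covariates)
            for i, target in enumerate(("X", "Y", "Z")):
                r2 = regression_metrics(s.vcg.xyz[i], pred.xyz[i]).r2
                assert r2 >= 0.999

    def test_unfitted_raises(self, rng):
        with pytest.raises(ModelNotFitted):
            apply_prone_to_vcg(VCGRegressionModel(),
                               _prone(np.zeros((12, 10))), COV)


class TestVcgToEcg:
    def test_zero_vcg_gives_zero_ecg(self):
        out = vcg_to_ecg(VCGRecord(np.zeros((3, 100))), DOWER)
        assert np.all(out.signals == 0.0)

    def test_unit_impulse_reads_matrix_weights(self):
        xyz = np.zeros((3, 10))
        xyz[0, 4] = 1.0  # X impulse
        out = vcg_to_ecg(VCGRecord(xyz), DOWER)
        full = DOWER.full_rows()
        for lead in LEAD_NAMES:
            assert out.lead(lead)[4] == pytest.approx(full[lead][0])

    def test_superposition(self, rng):
        u = VCGRecord(rng.normal(size=(3, 80)))
        v = VCGRecord(rng.normal(size=(3, 80)))
        combo = VCGRecord(2.0 * u.xyz + 3.0 * v.xyz)
        lhs = vcg_to_ecg(combo, UIJEN).signals
        rhs = 2.0 * vcg_to_ecg(u, UIJEN).signals + 3.0 * vcg_to_ecg(v, UIJEN).signals
        assert np.max(np.abs(lhs - rhs)) < 1e-12

    def test_limb_lead_identities(self, rng):
        out = vcg_to_ecg(VCGRecord(rng.normal(size=(3, 200))), DOWER)
        i, ii = out.lead("I"), out.lead("II")
        assert np.allclose(out.lead("III"), ii - i, atol=1e-12)
        assert np.allclose(out.lead("aVR"), -(i + ii) / 2, atol=1e-12)
        assert np.allclose(out.lead("aVL"), i - ii / 2, atol=1e-12)
        assert np.allclose(out.lead("aVF"), ii - i / 2, atol=1e-12)

    def test_matrix_requires_all_independent_leads(self):
        with pytest.raises(ValueError):
            TransformMatrix(name="partial", rows={"I": (1, 0, 0)})


class TestConvertApproach2:
    def test_selection_rule_uses_dower_for_v3(self, clean_cohort):
        model = fit_prone_to_vcg(
            [(s.prone, s.vcg, s.covariates) for s in clean_cohort])
        s = clean_cohort.subjects[0]
        out = convert_approach2(model, s.prone, s.covariates)
        vcg = apply_prone_to_vcg(model, s.prone, s.covariates)
        assert np.allclose(out.lead("V3"), vcg_to_ecg(vcg, DOWER).lead("V3"))
        assert np.allclose(out.lead("V4"), vcg_to_ecg(vcg, UIJEN).lead("V4"))

    def test_all_dower_override_changes_only_differing_leads(self, clean_cohort):
        model = fit_prone_to_vcg(
            [(s.prone, s.vcg, s.covariates) for s in clean_cohort])
        s = clean_cohort.subjects[0]
        hybrid = convert_approach2(model, s.prone, s.covariates)
        dower = convert_approach2(model, s.prone, s.covariates, "dower")
        assert np.allclose(hybrid.lead("V3"), dower.lead("V3"))
        assert not np.allclose(hybrid.lead("V1"), dower.lead("V1"))

    def test_end_to_end_composite_field_recovery(self):
        # when the supine field equals the Uijen/Dower composite the whole
        # chain prone -> VCG -> matrices reproduces the supine record
        from pronecg import SyntheticCohortConfig, simulate_cohort

        comp = LeadFieldMatrix.from_selection({"V3": DOWER}, default=UIJEN,
                                              posture=Posture.SUPINE)
        cfg = SyntheticCohortConfig(n_subjects=6, total_beats=50, noise_sd=0.0,
                                    seed=21, supine_field=comp)
        co = simulate_cohort(cfg)
        model = fit_prone_to_vcg([(s.prone, s.vcg, s.covariates) for s in co])
        for s in co:
            out = convert_approach2(model, s.prone, s.covariates)
            for lead in LEAD_NAMES:
                assert regression_metrics(s.supine.lead(lead),
                                          out.lead(lead)).r2 >= 0.99
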