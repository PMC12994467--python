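"""R detection, fiducial delineation, segment windows and wave amplitudes."""

import numpy as np
import pytest

from pronecg import (
    BeatFiducials,
    DiagnosisLabel,
    ECGRecord,
    LEAD_NAMES,
    SegmentKind,
    delineate,
    detect_r_peaks,
    measure_amplitudes,
    segment_windows,
)
from pronecg.delineation import delineate_record, export_delineation
from pronecg.errors import EdgeBeat

FS = 500.0


def _gaussian_train(amplitudes, centers_s, fs=FS, dur_s=10.0, sigma_s=0.012):
    t = np.arange(int(dur_s * fs)) / fs
    sig = np.zeros_like(t)
    for a, c in zip(amplitudes, centers_s):
        sig += a * np.exp(-((t - c) ** 2) / (2 * sigma_s**2))
    return sig


def _beat_record(waves, fs=FS, dur_s=2.0):
    """One-lead synthetic beat copied to all 12 leads."""
    t = np.arange(int(dur_s * fs)) / fs
    sig = np.zeros_like(t)
    for a, c, s in waves:
        sig += a * np.exp(-((t - c) ** 2) / (2 * s**2))
    return ECGRecord(np.tile(sig, (12, 1)), LEAD_NAMES, fs)


class TestDetectRPeaks:
    def test_all_zero_gives_no_beats(self):
        assert detect_r_peaks(np.zeros(5000), FS).size == 0

    def test_train_of_ten_beats_within_10ms(self):
        centers = [0.5 + i for i in range(10)]
        sig = _gaussian_train([1.0] * 10, centers)
        peaks = detect_r_peaks(sig, FS)
        assert peaks.size == 10
        assert np.max(np.abs(peaks / FS - centers)) <= 0.010

    def test_halved_beat_still_detected(self):
        amps = [1.0] * 10
        amps[4] = 0.5
        sig = _gaussian_train(amps, [0.5 + i for i in range(10)])
        assert detect_r_peaks(sig, FS).size == 10

    def test_refractory_spacing(self):
        sig = _gaussian_train([1.0] * 10, [0.5 + i for i in range(10)])
        peaks = detect_r_peaks(sig, FS)
        assert np.all(np.diff(peaks) >= 0.2 * FS)

    def test_perfect_sensitivity_and_ppv_on_cohort(self, clean_cohort):
        # noise-free trains of >= 5 beats: every true beat found, none invented
        for s in clean_cohort.subjects[:5]:
            truth = np.array([f.r_peak for f in s.fiducials])
            det = detect_r_peaks(s.supine.lead("II"), s.supine.fs)
            assert det.size == truth.size
            assert np.max(np.abs(det - truth)) <= 0.010 * FS


class TestDelineate:
    def test_fiducials_within_20ms_of_generator_truth(self, clean_cohort):
        for s in clean_cohort.subjects:
            if s.label is not DiagnosisLabel.NORMAL:
                continue
            for truth in s.fiducials[1:4]:
                det = delineate(s.supine, truth.r_peak)
                for name in ("p_onset", "qrs_onset", "r_peak", "qrs_offset", "t_offset"):
                    err_ms = abs(getattr(det, name) - getattr(truth, name)) / FS * 1000
                    assert err_ms <= 20, (s.subject_id, name, err_ms)

    def test_ordering_invariant_all_classes(self, clean_cohort):
        for s in clean_cohort.subjects:
            for truth in s.fiducials[1:3]:
                det = delineate(s.supine, truth.r_peak)  # constructor checks ordering
                assert det.p_onset < det.qrs_onset < det.r_peak
                assert det.r_peak < det.qrs_offset < det.t_offset

    def test_absent_p_wave_detected(self):
        rec = _beat_record([(1.0, 1.0, 0.010), (0.3, 1.25, 0.04)])  # QRS + T, no P
        fid = delineate(rec, int(1.0 * FS))
        assert not fid.p_present

    def test_edge_beat_raises(self):
        rec = _beat_record([(1.0, 0.05, 0.010)])
        with pytest.raises(EdgeBeat):
            delineate(rec, int(0.05 * FS))

    def test_delineate_record_skips_edge_beats(self, clean_cohort):
        s = clean_cohort.subjects[0]
        fids = delineate_record(s.supine)
        assert len(fids) >= s.n_beats - 1


class TestSegmentWindows:
    def test_windows_follow_definition(self):
        fid = BeatFiducials(100, 200, 230, 260, 460)
        pr, qrs, stt = segment_windows(fid, FS)
        assert (pr.start, pr.end) == (100, 200)
        assert (qrs.start, qrs.end) == (200, 260)
        assert (stt.start, stt.end) == (260, 460)

    def test_windows_tile_without_gaps(self, clean_cohort):
        for s in clean_cohort.subjects[:4]:
            for fid in s.fiducials:
                pr, qrs, stt = segment_windows(fid, FS)
                assert pr.end == qrs.start and qrs.end == stt.start
                assert pr.kind is SegmentKind.PR and stt.kind is SegmentKind.STT

    def test_absent_p_fallback_span(self):
        fid = BeatFiducials(100, 200, 230, 260, 460, p_present=False)
        pr, _, _ = segment_windows(fid, FS)
        assert pr.start == 200 - int(0.12 * FS)


class TestMeasureAmplitudes:
    def _rs_beat(self, r=1.0, s=-0.3, dc=0.0, scale=1.0):
        # R/S/T beat on a true zero baseline (no P wave)
        rec = _beat_record([(r, 1.0, 0.010), (s, 1.035, 0.009), (0.3, 1.3, 0.05)])
        return ECGRecord(rec.signals * scale + dc, LEAD_NAMES, FS)

    def test_r_and_s_amplitudes(self):
        rec = self._rs_beat()
        fid = delineate(rec, int(1.0 * FS))
        amp = measure_amplitudes(rec, "II", fid)
        assert amp.r == pytest.approx(1.0, abs=0.02)
        assert amp.s == pytest.approx(-0.3, abs=0.02)

    def test_dc_offset_invariance(self):
        fid = delineate(self._rs_beat(), int(1.0 * FS))
        a0 = measure_amplitudes(self._rs_beat(), "II", fid)
        a1 = measure_amplitudes(self._rs_beat(dc=0.5), "II", fid)
        for f in ("p_pos", "q", "r", "s", "st_level", "t_pos", "t_neg"):
            assert getattr(a0, f) == pytest.approx(getattr(a1, f), abs=1e-9)

    def test_scaling_equivariance(self):
        fid = delineate(self._rs_beat(), int(1.0 * FS))
        a1 = measure_amplitudes(self._rs_beat(), "II", fid)
        a2 = measure_amplitudes(self._rs_beat(scale=2.0), "II", fid)
        for f in ("p_pos", "r", "s", "t_pos"):
            assert getattr(a2, f) == pytest.approx(2 * getattr(a1, f), rel=1e-6, abs=1e-9)

    def test_biphasic_t_bidirectional_maxima(self):
        # fiducials chosen so the ST-T window spans both T lobes
        rec = _beat_record([(1.0, 1.0, 0.010), (0.2, 1.25, 0.03), (-0.1, 1.38, 0.03)])
        fid = BeatFiducials(p_onset=400, qrs_onset=470, r_peak=500,
                            qrs_offset=530, t_offset=760, p_present=False)
        amp = measure_amplitudes(rec, "II", fid)
        assert amp.t_pos == pytest.approx(0.2, abs=0.03)
        assert amp.t_neg == pytest.approx(-0.1, abs=0.03)

    def test_export_table_shape(self, clean_cohort):
        s = clean_cohort.subjects[0]
        df = export_delineation(s.supine, list(s.fiducials[1:4]))
        assert len(df) == 3
        assert "V3_r" in df.columns and "II_st_level" in df.columns
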