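"""Filtering, R-peak detection, beat extraction, grouping, delineation."""

import numpy as np
import pytest

import elvmass as em
from elvmass.io_cohort import CohortError, EcgRecord
from elvmass.preprocess import (SignalQualityError, annotate_landmarks,
                                extract_single_beat, fallback_landmarks,
                                lead_grouping)


def sine_record(freq, fs=500.0, dur=10.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    wf = np.tile(amp * np.sin(2 * np.pi * freq * t), (12, 1))
    return EcgRecord(record_id=f"sine{freq}", waveform=wf, fs=fs)


class TestBandpass:
    def test_dc_rejection(self):
        rec = EcgRecord(record_id="dc", waveform=np.ones((12, 5000)))
        out = em.bandpass_filter(rec)
        # ignore the filter transient at the edges
        assert np.max(np.abs(out.waveform[:, 1000:-1000])) < 0.01

    def test_passband_gain_near_unity(self):
        out = em.bandpass_filter(sine_record(10.0))
        mid = out.waveform[0, 2000:3000]
        assert np.max(np.abs(mid)) == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuation(self):
        out = em.bandpass_filter(sine_record(100.0))
        mid = out.waveform[0, 2000:3000]
        assert np.max(np.abs(mid)) < 0.1

    def test_invalid_band_rejected(self):
        rec = sine_record(10.0)
        with pytest.raises(CohortError):
            em.bandpass_filter(rec, low=40.0, high=0.5)
        with pytest.raises(CohortError):
            em.bandpass_filter(rec, low=0.5, high=300.0)

    def test_linearity(self):
        rec = sine_record(7.0)
        a = em.bandpass_filter(rec).waveform
        scaled = EcgRecord(record_id="s", waveform=3.5 * rec.waveform, fs=500)
        b = em.bandpass_filter(scaled).waveform
        np.testing.assert_allclose(b, 3.5 * a, rtol=1e-9, atol=1e-12)


class TestRPeaks:
    def test_detects_true_peaks(self, noiseless_cohort):
        for rec, fid in zip(noiseless_cohort.records,
                            noiseless_cohort.fiducials):
            filtered = em.bandpass_filter(rec)
            peaks = em.detect_r_peaks(filtered)
            truth = fid["r_peaks"]
            assert len(peaks) == len(truth)
            assert np.max(np.abs(peaks - truth)) <= 0.010 * rec.fs  # 10 ms

    def test_flat_record_rejected(self):
        rec = EcgRecord(record_id="flat", waveform=np.zeros((12, 5000)))
        with pytest.raises(SignalQualityError):
            em.detect_r_peaks(rec)

    def test_beat_count_matches_heart_rate_range(self):
        # 10-s records at 55-95 bpm hold 8-15 beats given the tiling phase
        effect = em.EffectModel(amp_variation_sd=0.0)
        c = em.synthesize_cohort(3, effect, seed=8)
        for rec, fid in zip(c.records, c.fiducials):
            filtered = em.bandpass_filter(rec)
            peaks = em.detect_r_peaks(filtered)
            # 10 s at 55-95 bpm, tiling phase: between 8 and 15 beats
            assert 8 <= len(peaks) <= 15
            assert len(peaks) == len(fid["r_peaks"])

    def test_refractory_enforced(self, tiny_cohort):
        rec = em.bandpass_filter(tiny_cohort.records[0])
        peaks = em.detect_r_peaks(rec)
        assert np.all(np.diff(peaks) >= 0.2 * rec.fs)


class TestSingleBeat:
    def test_middle_peak_chosen(self):
        rec = EcgRecord(record_id="m", waveform=np.zeros((12, 5000)))
        peaks = np.array([500, 1500, 2500, 3500, 4500])
        seg = extract_single_beat(rec, peaks)
        assert seg.r_record_index == 2500  # peak #2 of 5 (0-based)

    def test_single_eligible_peak(self):
        rec = EcgRecord(record_id="s", waveform=np.zeros((12, 5000)))
        seg = extract_single_beat(rec, np.array([2000]))
        assert seg.r_record_index == 2000

    def test_window_geometry(self):
        rec = EcgRecord(record_id="g", waveform=np.zeros((12, 5000)))
        seg = extract_single_beat(rec, np.array([2000]))
        assert seg.width == 350 and seg.r_index == 125

    def test_edge_peaks_ineligible(self):
        rec = EcgRecord(record_id="e", waveform=np.zeros((12, 1000)))
        # window -0.25..0.45 s needs 125 before / 225 after
        seg = extract_single_beat(rec, np.array([50, 500, 990]))
        assert seg.r_record_index == 500

    def test_no_eligible_peak_rejected(self):
        rec = EcgRecord(record_id="n", waveform=np.zeros((12, 300)))
        with pytest.raises(SignalQualityError):
            extract_single_beat(rec, np.array([10]))

    def test_synchrony_same_slice_on_all_leads(self):
        # index-valued dummy signal: every lead = sample index
        wf = np.tile(np.arange(5000.0), (12, 1))
        rec = EcgRecord(record_id="sync", waveform=wf, fs=500)
        seg = extract_single_beat(rec, np.array([2000]))
        expect = np.arange(2000 - 125, 2000 + 225)
        for lead in range(12):
            np.testing.assert_array_equal(seg.waveform[lead], expect)


class TestRandomCrop:
    def test_identity_crop(self, rng):
        rec = EcgRecord(record_id="i", waveform=np.zeros((12, 5000)))
        out = em.random_length_crop(rec, 10.0, 10.0, rng)
        assert out.waveform.shape == (12, 5000)

    def test_seeded_determinism(self):
        rec = EcgRecord(record_id="d",
                        waveform=np.random.default_rng(1).normal(
                            size=(12, 5000)))
        a = em.random_length_crop(rec, 2, 5, np.random.default_rng(7))
        b = em.random_length_crop(rec, 2, 5, np.random.default_rng(7))
        np.testing.assert_array_equal(a.waveform, b.waveform)

    def test_lengths_within_bounds(self, rng):
        rec = EcgRecord(record_id="b", waveform=np.zeros((12, 5000)))
        for _ in range(200):
            out = em.random_length_crop(rec, 2.0, 5.0, rng)
            assert 2.0 <= out.waveform.shape[1] / 500 <= 5.0 + 1e-9

    def test_crop_synchrony(self, rng):
        wf = np.tile(np.arange(5000.0), (12, 1))
        rec = EcgRecord(record_id="cs", waveform=wf, fs=500)
        out = em.random_length_crop(rec, 2, 5, rng)
        for lead in range(1, 12):
            np.testing.assert_array_equal(out.waveform[lead],
                                          out.waveform[0])

    def test_too_long_crop_rejected(self, rng):
        rec = EcgRecord(record_id="t", waveform=np.zeros((12, 1000)))
        with pytest.raises(CohortError):
            em.random_length_crop(rec, 2.0, 20.0, rng)


class TestGrouping:
    def test_electrical_two_groups_of_six(self):
        g = lead_grouping("electrical")
        mats = em.group_leads(np.arange(12)[:, None] * np.ones((12, 10)), g)
        assert [m.shape[0] for m in mats] == [6, 6]
        np.testing.assert_array_equal(mats[0][:, 0], np.arange(6))
        np.testing.assert_array_equal(mats[1][:, 0], np.arange(6, 12))

    def test_anatomical_group_sizes(self):
        g = lead_grouping("anatomical")
        mats = em.group_leads(np.zeros((12, 10)), g)
        assert [m.shape[0] for m in mats] == [4, 4, 3, 1]
        assert dict(g.groups)["LM"] == ("aVR",)

    def test_none_grouping_is_identity(self):
        wf = np.random.default_rng(0).normal(size=(12, 20))
        mats = em.group_leads(wf, lead_grouping("none"))
        assert len(mats) == 1
        np.testing.assert_array_equal(mats[0], wf)

    def test_grouping_is_a_partition(self):
        # concatenating group outputs and re-sorting recovers all 12 leads
        wf = np.arange(12)[:, None] * np.ones((12, 5))
        for name in ("none", "electrical", "anatomical"):
            mats = em.group_leads(wf, lead_grouping(name))
            leads = np.concatenate([m[:, 0] for m in mats])
            assert sorted(leads) == list(range(12))

    def test_unknown_grouping_rejected(self):
        with pytest.raises(CohortError):
            lead_grouping("sagittal")


class TestLandmarks:
    def test_truth_override_passthrough(self, tiny_cohort):
        ds = em.dataset_from_cohort(tiny_cohort, use_true_fiducials=True)
        # landmarks equal simulator truth exactly (translated to the window)
        for lm, fid in zip(ds.landmarks, tiny_cohort.fiducials):
            # window start = chosen beat's r_peak - r_index
            matched = any(
                all(b[k] - (b["r_peak"] - lm["r_index"]) == lm[k]
                    for k in ("p_onset", "qrs_onset", "qrs_offset",
                              "t_offset"))
                for b in fid["beats"])
            assert matched

    def test_detection_close_to_truth_on_noiseless_beats(self,
                                                         noiseless_cohort):
        detected = em.dataset_from_cohort(noiseless_cohort,
                                          use_true_fiducials=False)
        truth = em.dataset_from_cohort(noiseless_cohort,
                                       use_true_fiducials=True)
        fs = truth.fs
        for d, t in zip(detected.landmarks, truth.landmarks):
            for k in ("p_onset", "qrs_onset", "qrs_offset", "t_offset"):
                assert abs(d[k] - t[k]) <= 0.020 * fs, k  # within 20 ms

    def test_fallback_on_garbage_segment(self):
        from elvmass.preprocess import BeatSegment

        rng = np.random.default_rng(0)
        seg = BeatSegment(waveform=0.001 * rng.normal(size=(12, 350)),
                          fs=500, r_index=125)
        out = annotate_landmarks(seg)
        assert out.delineation_failed
        assert out.landmarks == fallback_landmarks(125, 500, 350)

    def test_beat_window_covers_p_qrs_t(self, noiseless_cohort):
        # >= 99% of noiseless records yield a window holding all landmarks
        ds = em.dataset_from_cohort(noiseless_cohort, use_true_fiducials=True)
        assert len(ds.ids) == len(noiseless_cohort.records)
        for lm in ds.landmarks:
            assert 0 <= lm["p_onset"] < lm["qrs_onset"] < lm["r_index"]
            assert lm["r_index"] < lm["qrs_offset"] < lm["t_offset"] < 350
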