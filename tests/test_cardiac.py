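"""Cardiac chain: trimming, artifact flagging, segmentation, HRV metrics."""

import numpy as np
import pytest

from cardioconn.cardiac import (
    BeatRecord,
    PPGSignal,
    Segment,
    aggregate_profile,
    ar_band_power,
    ar_psd,
    detect_beats,
    flag_artifacts,
    process_beats,
    segment_metrics,
    segment_series,
    trim_stabilization,
)
from cardioconn.simulate import AutonomicSimConfig, generate_beats


def record_from_ibis(ibis_ms, t0=0.0):
    times = t0 + np.concatenate(([0.0], np.cumsum(ibis_ms) / 1000.0))
    return BeatRecord(beat_times_s=times)


class TestBeatRecord:
    def test_interval_definition(self):
        rec = BeatRecord(beat_times_s=np.array([0.0, 0.8, 1.61, 2.4]))
        np.testing.assert_allclose(rec.ibis_ms, [800.0, 810.0, 790.0])

    def test_rejects_non_increasing(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            BeatRecord(beat_times_s=np.array([0.0, 0.8, 0.8]))

    def test_flag_length_contract(self):
        with pytest.raises(ValueError, match="per interval"):
            BeatRecord(
                beat_times_s=np.array([0.0, 0.8, 1.6]),
                artifact_flags=np.array([True]),
            )


class TestTrim:
    def test_600s_record_leaves_540s(self, constant_beats):
        trimmed = trim_stabilization(constant_beats, trim_s=60.0)
        assert trimmed.beat_times_s[0] >= 60.0
        assert trimmed.duration_s == pytest.approx(540.0, abs=2.0)

    def test_zero_trim_is_identity(self, constant_beats):
        out = trim_stabilization(constant_beats, trim_s=0.0)
        np.testing.assert_array_equal(out.beat_times_s, constant_beats.beat_times_s)

    def test_boundary_beat_retained(self):
        rec = BeatRecord(beat_times_s=np.array([59.0, 60.0, 61.0, 62.0]))
        out = trim_stabilization(rec, trim_s=60.0)
        assert out.beat_times_s[0] == 60.0

    def test_short_record_errors(self):
        rec = BeatRecord(beat_times_s=np.array([0.0, 10.0, 20.0]))
        with pytest.raises(ValueError, match="shorter"):
            trim_stabilization(rec, trim_s=60.0)


class TestArtifactFlagging:
    def test_constant_series_clean(self):
        rec = record_from_ibis(np.full(100, 800.0))
        assert flag_artifacts(rec).artifact_flags.sum() == 0

    def test_halved_interval_flagged(self):
        ibis = np.full(100, 800.0)
        ibis[50] = 400.0
        rec = record_from_ibis(ibis)
        flags = flag_artifacts(rec).artifact_flags
        assert flags[50]
        assert flags.sum() == 1

    def test_injected_artifact_sensitivity(self):
        """>= 95% of injected halvings/doublings flagged at defaults."""
        found = total = 0
        for seed in range(5):
            cfg = AutonomicSimConfig(artifact_rate=2.0, seed=seed)
            sim = generate_beats(cfg)
            flags = flag_artifacts(sim.record).artifact_flags
            total += sim.artifact_indices.size
            found += int(flags[sim.artifact_indices].sum())
        assert total >= 10
        assert found / total >= 0.95

    def test_zero_thresholds_flag_everything(self):
        """Degenerate limit: with both thresholds at zero every interval
        deviating at all from the running median is flagged."""
        rng = np.random.default_rng(0)
        rec = record_from_ibis(800.0 + rng.normal(0, 10, 200))
        flags = flag_artifacts(rec, rel_thr=0.0, abs_thr_ms=0.0).artifact_flags
        # only intervals that happen to equal their own running median escape
        assert flags.mean() > 0.9


class TestSegmentation:
    def test_clean_540s_gives_nine_60s_segments(self, constant_beats):
        trimmed = trim_stabilization(flag_artifacts(constant_beats))
        segs = segment_series(flag_artifacts(trimmed))
        assert len(segs) == 9
        for s in segs:
            assert s.duration_s == pytest.approx(60.0, abs=0.8)

    def test_short_span_gives_no_segment(self):
        rec = record_from_ibis(np.full(48, 800.0))  # 38.4 s
        assert segment_series(rec) == []

    def test_buffer_excludes_two_intervals_each_side(self):
        ibis = np.full(200, 800.0)
        rec = record_from_ibis(ibis)
        flags = np.zeros(200, dtype=bool)
        flags[100] = True
        rec = BeatRecord(beat_times_s=rec.beat_times_s, artifact_flags=flags)
        segs = segment_series(rec, min_s=10.0, max_s=200.0)
        covered = set()
        for s in segs:
            covered.update(range(s.start, s.end))
        assert covered.isdisjoint(range(98, 103))
        assert {97, 103} <= covered

    def test_segments_disjoint_and_within_bounds(self, rng):
        ibis = 800.0 + rng.normal(0, 30, 600)
        flags = rng.random(600) < 0.02
        rec = record_from_ibis(ibis)
        rec = BeatRecord(beat_times_s=rec.beat_times_s, artifact_flags=flags)
        segs = segment_series(rec)
        seen = set()
        for s in segs:
            assert 40.0 <= s.duration_s <= 60.0
            idx = set(range(s.start, s.end))
            assert seen.isdisjoint(idx)
            seen.update(idx)
            assert not flags[s.start : s.end].any()


class TestSegmentMetrics:
    def test_constant_series(self):
        rec = record_from_ibis(np.full(30, 800.0))
        m = segment_metrics(rec, Segment(0, 30, 24.0))
        assert m.rmssd_ms == pytest.approx(0.0, abs=1e-9)
        assert m.sdnn_ms == pytest.approx(0.0, abs=1e-9)
        assert m.mean_hr_bpm == pytest.approx(75.0)

    def test_hand_computed_rmssd_sdnn(self):
        """RMSSD and SDNN from their printed definitions on a 4-interval
        series, padded to the minimum segment length with a repeat."""
        base = [800.0, 810.0, 790.0, 800.0]
        m_vals = np.array(base)
        rmssd = np.sqrt(((m_vals[1:] - m_vals[:-1]) ** 2).mean())
        sdnn = np.std(m_vals, ddof=1)
        assert rmssd == pytest.approx(np.sqrt((100 + 400 + 100) / 3))
        assert sdnn == pytest.approx(np.sqrt(200 / 3))
        # same numbers through the implementation on a tiled version
        ibis = np.tile(base, 5)
        rec = record_from_ibis(ibis)
        m = segment_metrics(rec, Segment(0, 20, float(np.sum(ibis) / 1000)))
        brute_rmssd = np.sqrt(np.mean(np.diff(ibis) ** 2))
        brute_sdnn = np.std(ibis, ddof=1)
        assert m.rmssd_ms == pytest.approx(brute_rmssd, rel=1e-12)
        assert m.sdnn_ms == pytest.approx(brute_sdnn, rel=1e-12)

    def test_brute_force_oracle_all_metrics(self, rng):
        """Every time-domain metric equals a from-scratch recomputation."""
        ibis = 800.0 + rng.normal(0, 40, 60)
        rec = record_from_ibis(ibis)
        seg = Segment(5, 55, float(ibis[5:55].sum() / 1000))
        m = segment_metrics(rec, seg)
        sub = ibis[5:55]
        assert m.mean_ibi_ms == pytest.approx(sub.mean(), rel=1e-9)
        assert m.mean_hr_bpm == pytest.approx(np.mean(60000.0 / sub), rel=1e-9)
        assert m.rmssd_ms == pytest.approx(
            np.sqrt(np.mean(np.diff(sub) ** 2)), rel=1e-9
        )
        assert m.sdnn_ms == pytest.approx(np.std(sub, ddof=1), rel=1e-9)

    def test_hf_power_of_planted_sinusoid(self, modulated_beats):
        """A 30 ms modulation at 0.25 Hz carries ~a^2/2 = 450 ms^2 in-band."""
        trimmed = trim_stabilization(modulated_beats)
        segs = segment_series(flag_artifacts(trimmed))
        m = segment_metrics(flag_artifacts(trimmed), segs[0])
        assert m.hf_power_ms2 == pytest.approx(450.0, rel=0.15)
        assert m.hf_peak_hz == pytest.approx(0.25, abs=0.02)

    def test_too_short_segment_errors(self):
        rec = record_from_ibis(np.full(20, 800.0))
        with pytest.raises(ValueError, match="at least 16"):
            segment_metrics(rec, Segment(0, 10, 8.0))

    def test_hr_jensen_inequality(self, rng):
        """Mean instantaneous HR exceeds the interval-mean HR whenever the
        IBIs are not constant (convexity of 1/x)."""
        for _ in range(5):
            ibis = 800.0 + rng.normal(0, 50, 40)
            rec = record_from_ibis(ibis)
            m = segment_metrics(rec, Segment(0, 40, float(ibis.sum() / 1000)))
            assert m.mean_hr_bpm > 60000.0 / m.mean_ibi_ms

    def test_time_shift_invariance(self, rng):
        ibis = 800.0 + rng.normal(0, 30, 40)
        seg = Segment(0, 40, float(ibis.sum() / 1000))
        m0 = segment_metrics(record_from_ibis(ibis, t0=0.0), seg)
        m1 = segment_metrics(record_from_ibis(ibis, t0=1000.0), seg)
        assert m0.rmssd_ms == pytest.approx(m1.rmssd_ms, rel=1e-12)
        assert m0.sdnn_ms == pytest.approx(m1.sdnn_ms, rel=1e-12)

    def test_sdnn_permutation_invariant_rmssd_not(self, rng):
        ibis = 800.0 + rng.normal(0, 30, 40)
        perm = rng.permutation(ibis)
        seg = Segment(0, 40, float(ibis.sum() / 1000))
        m0 = segment_metrics(record_from_ibis(ibis), seg)
        m1 = segment_metrics(record_from_ibis(perm), seg)
        assert m0.sdnn_ms == pytest.approx(m1.sdnn_ms, rel=1e-12)
        assert abs(m0.rmssd_ms - m1.rmssd_ms) > 1e-6


class TestArSpectrum:
    def test_white_noise_parseval(self, rng):
        x = rng.standard_normal(1000)
        f, psd = ar_psd(x, order=16, fs=4.0)
        assert np.trapezoid(psd, f) == pytest.approx(x.var(), rel=0.10)
        assert (psd >= 0).all()

    def test_sinusoid_peak_location(self, rng):
        t = np.arange(2000) / 4.0
        x = 5 * np.sin(2 * np.pi * 0.3 * t) + 0.01 * rng.standard_normal(2000)
        f, psd = ar_psd(x, order=16, fs=4.0)
        assert abs(f[np.argmax(psd)] - 0.3) <= f[1] - f[0] + 1e-9

    def test_constant_input_zero_density(self):
        with pytest.warns(UserWarning, match="constant"):
            f, psd = ar_psd(np.full(200, 5.0), order=16, fs=4.0)
        assert (psd == 0).all()

    def test_band_power_of_pure_sinusoid(self, rng):
        t = np.arange(2400) / 4.0
        x = 10 * np.sin(2 * np.pi * 0.3 * t) + 0.01 * rng.standard_normal(2400)
        power, peak = ar_band_power(x, (0.15, 0.40), order=16, fs=4.0)
        assert power == pytest.approx(50.0, rel=0.05)
        assert peak == pytest.approx(0.3, abs=0.01)

    def test_too_short_series_errors(self):
        with pytest.raises(ValueError, match="too short"):
            ar_psd(np.zeros(60), order=16)


class TestAggregation:
    def _metrics(self, **kw):
        from cardioconn.cardiac import SegmentMetrics

        base = dict(
            mean_ibi_ms=800.0,
            mean_hr_bpm=75.0,
            rmssd_ms=10.0,
            sdnn_ms=12.0,
            hf_power_ms2=100.0,
            hf_peak_hz=0.25,
            duration_s=60.0,
        )
        base.update(kw)
        return SegmentMetrics(**base)

    def test_unweighted_mean(self):
        prof = aggregate_profile([self._metrics(rmssd_ms=10.0), self._metrics(rmssd_ms=20.0)])
        assert prof.rmssd_ms == pytest.approx(15.0)

    def test_single_segment_identity(self):
        m = self._metrics()
        prof = aggregate_profile([m])
        assert prof.rmssd_ms == m.rmssd_ms
        assert prof.qc.n_segments == 1

    def test_log_of_mean_hf(self):
        prof = aggregate_profile([self._metrics(hf_power_ms2=float(np.exp(6.0)))])
        assert prof.ln_hf_power == pytest.approx(6.0)

    def test_zero_segments_marked_unusable(self):
        prof = aggregate_profile([])
        assert not prof.usable
        assert prof.qc.n_segments == 0
        assert np.isnan(prof.rmssd_ms)

    def test_peak_plausibility_power_weighted(self):
        segs = [
            self._metrics(hf_peak_hz=0.30, hf_power_ms2=1000.0),
            self._metrics(hf_peak_hz=0.95, hf_power_ms2=1.0),
        ]
        assert aggregate_profile(segs).qc.hf_peak_plausible


class TestRecovery:
    def test_rmssd_monotone_in_planted_hf_amplitude(self):
        rmssds = []
        for amp in (10.0, 20.0, 30.0, 40.0):
            cfg = AutonomicSimConfig(
                hf_amp_ms=amp, lf_amp_ms=0, noise_sd_ms=0, artifact_rate=0, seed=7
            )
            prof = process_beats(generate_beats(cfg).record)
            rmssds.append(prof.rmssd_ms)
        assert all(a < b for a, b in zip(rmssds, rmssds[1:]))


class TestBeatDetection:
    @staticmethod
    def _ppg(beat_times, fs=64.0, duration=60.0, noise_sd=0.0, rng=None):
        t = np.arange(int(duration * fs)) / fs
        sig = np.zeros_like(t)
        for bt in beat_times:
            sig += np.exp(-((t - bt) ** 2) / (2 * 0.03**2))
        if noise_sd:
            sig += noise_sd * rng.standard_normal(t.size)
        return PPGSignal(samples=sig, sampling_rate_hz=fs)

    def test_rate_recovered_on_clean_pulse_train(self):
        beats = np.arange(0.5, 59.5, 0.8)  # 75 bpm
        rec = detect_beats(self._ppg(beats))
        rate = 60.0 / np.mean(rec.ibis_ms / 1000.0)
        assert rate == pytest.approx(75.0, abs=1.0)

    def test_flat_signal_errors(self):
        with pytest.raises(ValueError, match="no beats|flat"):
            detect_beats(PPGSignal(samples=np.ones(64 * 20), sampling_rate_hz=64.0))

    def test_noisy_detection_matches_ground_truth(self, rng):
        beats = np.arange(0.5, 59.5, 0.8)
        ppg = self._ppg(beats, noise_sd=0.1, rng=rng)  # pulse amp 1, SNR ~10
        rec = detect_beats(ppg)
        matched = sum(
            np.min(np.abs(rec.beat_times_s - bt)) <= 0.05 for bt in beats[1:-1]
        )
        assert matched / (beats.size - 2) >= 0.99


def test_process_beats_full_chain(modulated_beats):
    prof = process_beats(modulated_beats)
    assert prof.usable
    assert prof.qc.n_segments == 9
    assert prof.hf_power_ms2 == pytest.approx(450.0, rel=0.15)
    assert prof.qc.hf_peak_plausible
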