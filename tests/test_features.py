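import numpy as np
import pandas as pd
import pytest

from ppg2bp.errors import DomainError, FiducialError
from ppg2bp.features import (detect_fiducials,
                             extract_feature_table, second_derivative,
                             zscore_apply, zscore_fit)
from ppg2bp.quality import Beat, segment_beats


class TestSecondDerivative:
    fs = 125.0

    def test_quadratic_exact(self):
        t = np.arange(100) / self.fs
        sd = second_derivative(t**2, self.fs)
        assert np.abs(sd[5:-5] - 2.0).max() < 1e-6

    def test_linear_ramp_zero(self):
        t = np.arange(100) / self.fs
        sd = second_derivative(3.0 * t + 1.0, self.fs)
        assert np.abs(sd[5:-5]).max() < 1e-9

    @pytest.mark.parametrize("f", [1.0, 3.0, 5.0])
    def test_sinusoid_closed_form(self, f):
        t = np.arange(1000) / self.fs
        x = np.sin(2 * np.pi * f * t)
        sd = second_derivative(x, self.fs)
        expected = -((2 * np.pi * f) ** 2) * x
        rel = np.abs(sd[20:-20] - expected[20:-20]).max() / (2 * np.pi * f) ** 2
        assert rel < 0.02

    def test_short_beat_rejected(self):
        with pytest.raises(DomainError):
            second_derivative(np.zeros(5), self.fs)


def _matched_beats(rec, gt):
    beats = segment_beats(rec)
    by_foot = {int(r.foot_sample): r for r in gt.itertuples()}
    return [(b, by_foot[b.start_sample]) for b in beats
            if b.start_sample in by_foot]


class TestFiducials:
    def test_clean_peaks_within_one_sample_of_truth(self, clean_recording):
        rec, gt = clean_recording
        fs = rec.sampling_rate
        n_checked = 0
        for b, g in _matched_beats(rec, gt):
            fid = detect_fiducials(b, fs)
            assert abs(b.start_sample + round(fid.sys_t * fs)
                       - g.systolic_peak_sample) <= 1
            if not fid.dia_from_e:
                assert abs(b.start_sample + round(fid.dia_t * fs)
                           - g.diastolic_peak_sample) <= 1
                n_checked += 1
        assert n_checked > 50

    def test_exercise_morphology_takes_e_wave_fallback(self, clean_recording):
        rec, gt = clean_recording
        flags = [detect_fiducials(b, rec.sampling_rate).dia_from_e
                 for b, _ in _matched_beats(rec, gt) if b.phase == "exercise"]
        assert len(flags) > 20 and all(flags)

    def test_rest_morphology_uses_direct_diastolic_peak(self, clean_recording):
        rec, gt = clean_recording
        flags = [detect_fiducials(b, rec.sampling_rate).dia_from_e
                 for b, _ in _matched_beats(rec, gt) if b.phase == "rest"]
        assert len(flags) > 50 and not any(flags)

    def test_time_reversed_beat_fails(self, clean_recording):
        rec, gt = clean_recording
        b, _ = _matched_beats(rec, gt)[5]
        rev = Beat(b.start_sample, b.end_sample, b.samples[::-1].copy(), b.phase)
        with pytest.raises(FiducialError):
            detect_fiducials(rev, rec.sampling_rate)

    def test_sdppg_wave_signs_and_ordering(self, clean_recording):
        rec, gt = clean_recording
        for b, _ in _matched_beats(rec, gt)[::13]:
            fid = detect_fiducials(b, rec.sampling_rate)
            assert fid.wave_amp[0] > 0 and fid.wave_amp[1] < 0
            assert np.all(np.diff(fid.wave_t) > 0)


class TestFeatureExtraction:
    def test_clean_failure_rate_below_two_percent(self, clean_recording):
        rec, _ = clean_recording
        beats = segment_beats(rec)
        for b in beats:
            b.verdict = "accepted"
        tbl = extract_feature_table(rec, beats)
        assert len(tbl) >= 0.98 * len(beats)

    def test_definitional_identities(self, clean_recording):
        rec, _ = clean_recording
        beats = segment_beats(rec)
        for b in beats:
            b.verdict = "accepted"
        tbl = extract_feature_table(rec, beats)
        np.testing.assert_allclose(
            tbl.f07_augmentation_index,
            tbl.f02_diastolic_peak / tbl.f01_systolic_peak, rtol=1e-12)
        # telescoping wave intervals: the four gaps sum to t_e - t_a
        span = (tbl.f14_tb_a + tbl.f15_tb_c + tbl.f16_tc_d
                + tbl.f17_td_e).to_numpy()
        for row in tbl.iloc[::11].itertuples():
            fid = detect_fiducials(beats[row.beat_id], rec.sampling_rate)
            expect = fid.wave_t[4] - fid.wave_t[0]
            assert span[row.Index] == pytest.approx(expect, abs=1e-12)
        assert (tbl.f06_pulse_interval.between(0.3, 2.0)).all()
        assert (tbl.f03_t1 < tbl.f06_pulse_interval).all()

    def test_latent_parameters_recovered(self, clean_recording):
        """f1/f3/f4 track the generator's A1, t1 and dT on clean beats."""
        from ppg2bp.synth import WaveformParams
        rec, gt = clean_recording
        p = WaveformParams()
        beats = segment_beats(rec)
        for b in beats:
            b.verdict = "accepted"
        tbl = extract_feature_table(rec, beats)
        ann = {int(r.foot_sample): r for r in gt.itertuples()}
        n_checked = 0
        for row in tbl.itertuples():
            b = beats[row.beat_id]
            g = ann.get(b.start_sample)
            if g is None:
                continue
            fid = detect_fiducials(b, rec.sampling_rate)
            if fid.dia_from_e:  # merged reflected wave: dT not measurable
                continue
            a1 = p.k_a * (g.sbp - g.dbp)
            assert row.f01_systolic_peak == pytest.approx(a1, rel=0.10)
            assert abs(row.f03_t1 - p.t1) <= 1.5 / rec.sampling_rate
            dt_true = p.dt0 - p.k_t * (g.sbp - p.sbp_baseline)
            assert abs(row.f04_delta_t - dt_true) <= 1.5 / rec.sampling_rate
            n_checked += 1
        assert n_checked > 50

    def test_scale_equivariance(self, clean_recording):
        rec, gt = clean_recording
        b, _ = _matched_beats(rec, gt)[3]
        fs = rec.sampling_rate
        f1 = detect_fiducials(b, fs)
        scaled = Beat(b.start_sample, b.end_sample, 3.0 * b.samples, b.phase)
        f2 = detect_fiducials(scaled, fs)
        assert f2.sys_t == f1.sys_t and f2.dia_t == f1.dia_t
        assert f2.sys_amp == pytest.approx(3.0 * f1.sys_amp, rel=1e-9)
        assert f2.dia_amp == pytest.approx(3.0 * f1.dia_amp, rel=1e-9)
        np.testing.assert_allclose(f2.wave_amp / f2.wave_amp[0],
                                   f1.wave_amp / f1.wave_amp[0], rtol=1e-9)
        np.testing.assert_allclose(f2.wave_t, f1.wave_t)

    def test_delta_t_decreases_with_sbp(self, clean_recording):
        """Across beats with a measurable reflected wave, the reflected-wave
        delay falls as SBP rises (by construction of the latent map)."""
        from scipy.stats import spearmanr
        rec, _ = clean_recording
        beats = segment_beats(rec)
        for b in beats:
            b.verdict = "accepted"
        tbl = extract_feature_table(rec, beats)
        direct = [not detect_fiducials(beats[i], rec.sampling_rate).dia_from_e
                  for i in tbl.beat_id]
        sub = tbl[np.asarray(direct)]
        rho = spearmanr(sub.f04_delta_t, sub.sbp_ref).statistic
        assert rho < -0.8


class TestZScore:
    def test_self_normalization(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(2.0, 3.0, size=(200, 4)),
                          columns=list("abcd"))
        stats = zscore_fit(df)
        z = zscore_apply(df, stats)
        assert np.abs(z.mean(axis=0)).max() < 1e-12
        assert np.abs(z.std(axis=0, ddof=1) - 1).max() < 1e-12

    def test_constant_feature_flagged_and_dropped(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            stats = zscore_fit(df)
        z = zscore_apply(df, stats)
        assert list(z.columns) == ["a"]

    def test_single_row_rejected(self):
        with pytest.raises(DomainError):
            zscore_fit(pd.DataFrame({"a": [1.0]}))

    def test_train_stats_generalize(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(0, 1, size=(2000, 3)), columns=list("xyz"))
        stats = zscore_fit(df.iloc[:1000])
        z = zscore_apply(df.iloc[1000:], stats)
        assert np.abs(z.mean(axis=0)).max() < 0.1

    def test_schema_mismatch_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        stats = zscore_fit(df)
        with pytest.raises(DomainError):
            zscore_apply(df.rename(columns={"a": "b"}), stats)
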