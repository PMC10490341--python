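import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from ppg2bp.errors import DegenerateBeatError, DomainError, TrainingError
from ppg2bp.quality import (Beat, QualityModel, bandpass, classify_beats,
                            compute_ssqi, rejection_rate, segment_beats,
                            train_quality_model)


class TestBandpass:
    fs = 125.0

    def _amp(self, f):
        t = np.arange(0, 60, 1 / self.fs)
        y = bandpass(np.sin(2 * np.pi * f * t), self.fs)
        mid = slice(len(y) // 4, 3 * len(y) // 4)
        return float(np.abs(y[mid]).max())

    def test_stopband_attenuation_below_passband(self):
        assert self._amp(0.05) < 10 ** (-20 / 20)  # >= 20 dB down

    def test_passband_preserved(self):
        assert self._amp(2.0) == pytest.approx(1.0, rel=0.05)

    def test_zeros_in_zeros_out(self):
        out = bandpass(np.zeros(1000), self.fs)
        assert np.allclose(out, 0.0)

    def test_invalid_band_rejected(self):
        with pytest.raises(DomainError):
            bandpass(np.zeros(1000), self.fs, 8.0, 0.5)

    def test_too_short_signal_rejected(self):
        with pytest.raises(DomainError):
            bandpass(np.zeros(10), self.fs)


class TestSSQI:
    def test_symmetric_samples_give_zero(self):
        assert compute_ssqi([-1.0, 0.0, 1.0]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_asymmetric_case(self):
        # mean 1/3, population sd sqrt(2/9) -> third moment 1/sqrt(2)
        assert compute_ssqi([0.0, 0.0, 1.0]) == pytest.approx(0.70711, abs=1e-4)

    def test_negation_antisymmetry(self):
        x = np.random.default_rng(0).gamma(2.0, size=100)
        assert compute_ssqi(-x) == pytest.approx(-compute_ssqi(x), rel=1e-12)

    def test_matches_third_standardized_moment_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            x = rng.normal(size=rng.integers(3, 200))
            ref = float(sstats.skew(x, bias=True))
            assert compute_ssqi(x) == pytest.approx(ref, rel=1e-12, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=50),
           st.floats(0.1, 10), st.floats(-50, 50))
    def test_affine_invariance(self, xs, a, b):
        x = np.asarray(xs)
        if np.std(x) < 1e-6:
            return
        s = compute_ssqi(x)
        assert compute_ssqi(a * x + b) == pytest.approx(s, rel=1e-6, abs=1e-9)
        assert compute_ssqi(-a * x + b) == pytest.approx(-s, rel=1e-6, abs=1e-9)

    def test_constant_beat_degenerate(self):
        with pytest.raises(DegenerateBeatError):
            compute_ssqi(np.ones(50))


class TestSegmentation:
    def test_clean_rest_beats_recovered_with_exact_feet(self, clean_recording):
        rec, gt = clean_recording
        beats = segment_beats(rec)
        rest_gt = gt[gt.phase == "rest"]
        rest_beats = [b for b in beats if b.phase == "rest"]
        # ~60 bpm for 120 s -> one complete beat fewer than gt feet, +/- 1
        assert abs(len(rest_beats) - (len(rest_gt) - 1)) <= 1
        feet_gt = rest_gt.foot_sample.to_numpy()
        for b in rest_beats:
            assert np.abs(feet_gt - b.start_sample).min() <= 1

    def test_constant_signal_gives_empty_list(self):
        from ppg2bp.io import Phase, Recording
        rec = Recording(125.0, np.ones(5000), [Phase("rest", 0, 5000)])
        assert segment_beats(rec) == []

    def test_deterministic(self, noisy_recording):
        rec, _ = noisy_recording
        a = segment_beats(rec)
        b = segment_beats(rec)
        assert [(x.start_sample, x.end_sample) for x in a] == \
               [(y.start_sample, y.end_sample) for y in b]


def _skewed_beat(skew_sign, n=60, phase="rest"):
    x = np.linspace(0, 1, n)
    samples = np.exp(-((x - 0.25) ** 2) / 0.01)  # right-skewed pulse
    if skew_sign < 0:
        samples = -samples
    return Beat(0, n, samples, phase)


class TestClassification:
    def test_threshold_semantics(self):
        beats = [_skewed_beat(+1), _skewed_beat(-1)]
        ann = classify_beats(beats, QualityModel(threshold=0.0))
        assert list(ann.verdict) == ["accepted", "rejected"]
        assert ann.ssqi[0] > 0.0 > ann.ssqi[1]

    def test_minus_infinity_threshold_accepts_all_nondegenerate(self):
        beats = [_skewed_beat(+1), _skewed_beat(-1),
                 Beat(0, 50, np.ones(50), "rest")]
        ann = classify_beats(beats, QualityModel(threshold=-np.inf))
        assert list(ann.verdict) == ["accepted", "accepted", "rejected"]

    def test_partition_conservation(self, noisy_recording):
        rec, _ = noisy_recording
        beats = segment_beats(rec)
        ann = classify_beats(beats, QualityModel())
        assert (ann.verdict == "accepted").sum() + \
               (ann.verdict == "rejected").sum() == len(beats)

    def test_untrained_svm_rejected(self):
        with pytest.raises(TrainingError):
            classify_beats([_skewed_beat(1)], QualityModel(mode="svm"))

    def test_threshold_classifier_matches_artifact_flags(self, noisy_recording):
        from .conftest import match_beats_to_truth
        rec, gt = noisy_recording
        beats = segment_beats(rec)
        ann = classify_beats(beats, QualityModel())
        is_art = match_beats_to_truth(ann, gt)
        rejected = (ann.verdict == "rejected").to_numpy()
        sens = (rejected & is_art).sum() / is_art.sum()
        spec = (~rejected & ~is_art).sum() / (~is_art).sum()
        assert sens >= 0.8 and spec >= 0.8


class TestSVMTraining:
    def _toy(self, n_per=20, seed=0):
        rng = np.random.default_rng(seed)
        beats, labels = [], []
        for i in range(n_per):
            beats.append(_skewed_beat(+1))
            labels.append(True)
            beats.append(_skewed_beat(-1))
            labels.append(False)
        return beats, np.asarray(labels)

    def test_separable_set_perfect_training_accuracy(self):
        beats, labels = self._toy()
        model = train_quality_model(beats, labels)
        ann = classify_beats(beats, model)
        acc = ((ann.verdict == "accepted").to_numpy() == labels).mean()
        assert acc == 1.0

    def test_shuffled_labels_chance_accuracy(self):
        rng = np.random.default_rng(3)
        beats = []
        for _ in range(200):
            b = _skewed_beat(+1 if rng.random() < 0.5 else -1)
            b.samples = b.samples + rng.normal(0, 0.05, len(b.samples))
            beats.append(b)
        labels = rng.random(200) < 0.5  # labels independent of the beats
        model = train_quality_model(beats[:100], labels[:100])
        ann = classify_beats(beats[100:], model)
        acc = ((ann.verdict == "accepted").to_numpy() == labels[100:]).mean()
        assert abs(acc - 0.5) <= 0.10

    def test_refit_deterministic(self):
        beats, labels = self._toy()
        m1 = train_quality_model(beats, labels, seed=1)
        m2 = train_quality_model(beats, labels, seed=1)
        np.testing.assert_array_equal(m1.svm_weights, m2.svm_weights)
        assert m1.svm_bias == m2.svm_bias

    def test_single_class_rejected(self):
        beats, _ = self._toy()
        with pytest.raises(TrainingError):
            train_quality_model(beats, np.ones(len(beats), dtype=bool))


class TestRejectionRate:
    @pytest.mark.parametrize("before,after,expected", [
        (14290, 10878, 23.88),
        (21174, 6566, 68.99),
        (17193, 14419, 16.13),
        (100, 100, 0.00),
    ])
    def test_rates(self, before, after, expected):
        assert rejection_rate(before, after) == expected

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            rejection_rate(0, 0)
        with pytest.raises(DomainError):
            rejection_rate(10, 11)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(1, 10_000), st.data())
    def test_bounds_and_monotonicity(self, before, data):
        a1 = data.draw(st.integers(0, before))
        a2 = data.draw(st.integers(a1, before))
        r1, r2 = rejection_rate(before, a1), rejection_rate(before, a2)
        assert 0 <= r2 <= r1 <= 100
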