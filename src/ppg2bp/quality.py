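"""Beat segmentation and skewness-based signal-quality rejection.

Clean PPG pulses are strongly right-skewed (steep upstroke, long diastolic
tail), whereas motion-corrupted segments are symmetric or left-skewed, so the
third standardized moment of the samples in a beat (the skewness signal
quality index, SSQI) separates acceptable beats from unfit ones.  Two
rejection strategies are provided: a fixed SSQI threshold (default 0, i.e.
keep positively skewed beats) and a linear SVM over three per-beat statistics,
because a single fixed threshold is not optimal when the SSQI distribution
shifts between phases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.svm import LinearSVC

from .errors import DegenerateBeatError, DomainError, TrainingError
from .io import ANNOTATION_COLUMNS, Recording

logger = logging.getLogger(__name__)

MIN_BEAT_S = 0.3
MAX_BEAT_S = 2.0


@dataclass
class Beat:
    """One pulse cycle: a half-open sample span of the raw PPG."""

    start_sample: int
    end_sample: int
    samples: np.ndarray
    phase: str
    ssqi: float | None = None
    verdict: str | None = None

    @property
    def n(self) -> int:
        return self.end_sample - self.start_sample


@dataclass
class QualityModel:
    """Beat-quality classifier: fixed SSQI threshold or trained linear SVM.

    In svm mode the decision is linear over (ssqi, beat length in s,
    peak-to-peak amplitude normalized by the recording's median beat
    amplitude); weights/bias act on standardized statistics.
    """

    mode: str = "threshold"
    threshold: float = 0.0
    svm_weights: np.ndarray | None = None
    svm_bias: float | None = None
    stat_mean: np.ndarray | None = None
    stat_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("threshold", "svm"):
            raise DomainError(f"unknown quality mode {self.mode!r}")

    @property
    def is_trained(self) -> bool:
        return self.svm_weights is not None


def bandpass(
    x: np.ndarray, fs: float, low_hz: float = 0.5, high_hz: float = 8.0
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (order 2, forward-backward)."""
    if not (0 < low_hz < high_hz < fs / 2):
        raise DomainError(
            f"band edges must satisfy 0 < {low_hz} < {high_hz} < fs/2 = {fs / 2}"
        )
    x = np.asarray(x, dtype=float)
    sos = sps.butter(2, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    if len(x) <= 15:  # 3x the effective filter order of the cascaded sections
        raise DomainError(f"signal too short to filter ({len(x)} samples)")
    return sps.sosfiltfilt(sos, x)


def compute_ssqi(samples: np.ndarray) -> float:
    """Skewness signal quality index: third standardized moment, 1/N moments.

    SSQI = (1/N) sum_i ((x_i - mean) / sd)^3 with the population (1/N)
    standard deviation.  Raises DegenerateBeatError when sd = 0.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        raise DomainError(f"need at least 3 samples, got {x.size}")
    mu = x.mean()
    sd = np.sqrt(np.mean((x - mu) ** 2))
    if sd == 0:
        raise DegenerateBeatError("constant beat: sigma = 0, SSQI undefined")
    return float(np.mean(((x - mu) / sd) ** 3))


def segment_beats(
    rec: Recording, low_hz: float = 0.5, high_hz: float = 8.0
) -> list[Beat]:
    """Segment the PPG into beats spanning [foot_i, foot_{i+1}).

    Feet are the local minima preceding each systolic upstroke: upstrokes are
    picked on the first difference of the band-passed signal (adaptive height
    threshold, minimum peak distance 0.3 s), the foot is the preceding
    band-passed minimum, refined to the raw-signal minimum within +/-5
    samples.  Beats outside [0.3, 2.0] s or outside any phase are dropped.
    """
    fs = rec.sampling_rate
    raw = rec.ppg
    filt = bandpass(raw, fs, low_hz, high_hz)
    if np.ptp(filt) <= 1e-12 * max(1.0, float(np.abs(raw).max())):
        logger.warning("flat signal after filtering; empty segmentation")
        return []
    d = np.diff(filt)
    pos = d[d > 0]
    if pos.size == 0:
        logger.warning("no upstrokes found; returning empty segmentation")
        return []
    height = 0.25 * np.percentile(pos, 98)
    peaks, _ = sps.find_peaks(d, height=height, distance=max(1, int(0.3 * fs)))
    if peaks.size == 0:
        logger.warning("no upstroke peaks above threshold; empty segmentation")
        return []
    back = max(1, int(0.25 * fs))
    feet = []
    for u in peaks:
        lo = max(0, u - back)
        cand = lo + int(np.argmin(filt[lo : u + 1]))
        rlo = max(0, cand - 5)
        rhi = min(len(raw), cand + 6)
        foot = rlo + int(np.argmin(raw[rlo:rhi]))
        if not feet or foot - feet[-1] >= int(MIN_BEAT_S * fs):
            feet.append(foot)
    beats: list[Beat] = []
    for a, b in zip(feet[:-1], feet[1:]):
        if not (MIN_BEAT_S * fs <= b - a <= MAX_BEAT_S * fs):
            continue
        phase = rec.phase_of(a)
        if phase is None:
            continue
        beats.append(Beat(a, b, raw[a:b].copy(), phase))
    return beats


def _beat_stats(beats: list[Beat]) -> np.ndarray:
    """Per-beat statistics (ssqi, length s, normalized peak-to-peak amplitude)
    for the SVM quality model; amplitude normalized by the recording's median
    beat peak-to-peak so the classifier is gain-invariant."""
    p2p = np.array([np.ptp(b.samples) for b in beats], dtype=float)
    med = np.median(p2p[p2p > 0]) if np.any(p2p > 0) else 1.0
    stats = np.empty((len(beats), 3))
    for i, b in enumerate(beats):
        try:
            ssqi = compute_ssqi(b.samples)
        except DegenerateBeatError:
            ssqi = np.nan
        stats[i] = (ssqi, b.n, p2p[i] / med)
    return stats


def classify_beats(beats: list[Beat], model: QualityModel) -> pd.DataFrame:
    """Assign accepted/rejected verdicts; returns the beat-annotation table.

    Degenerate beats (sigma = 0) are always rejected.  Threshold mode accepts
    ssqi >= threshold; svm mode applies the trained linear decision.
    """
    if model.mode == "svm" and not model.is_trained:
        raise TrainingError("svm quality model is untrained")
    stats = _beat_stats(beats)
    rows = []
    for i, b in enumerate(beats):
        ssqi = stats[i, 0]
        if np.isnan(ssqi):
            b.ssqi, b.verdict = np.nan, "rejected"
        else:
            b.ssqi = float(ssqi)
            if model.mode == "threshold":
                ok = ssqi >= model.threshold
            else:
                z = (stats[i] - model.stat_mean) / model.stat_scale
                ok = float(z @ model.svm_weights + model.svm_bias) >= 0
            b.verdict = "accepted" if ok else "rejected"
        rows.append(
            {
                "beat_id": i,
                "start_sample": b.start_sample,
                "end_sample": b.end_sample,
                "ssqi": b.ssqi,
                "verdict": b.verdict,
                "phase": b.phase,
            }
        )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def train_quality_model(
    beats: list[Beat], labels: np.ndarray, seed: int = 0
) -> QualityModel:
    """Fit the linear max-margin classifier on per-beat quality statistics.

    ``labels``: boolean, True = acceptable.  Requires >= 10 beats per class.
    Deterministic given data order and seed.
    """
    labels = np.asarray(labels, dtype=bool)
    if len(labels) != len(beats):
        raise TrainingError("labels and beats length mismatch")
    if len(np.unique(labels)) < 2:
        raise TrainingError("need both acceptable and unfit beats to train")
    if min(labels.sum(), (~labels).sum()) < 10:
        raise TrainingError("need at least 10 beats per class")
    stats = _beat_stats(beats)
    keep = ~np.isnan(stats).any(axis=1)
    stats, labels = stats[keep], labels[keep]
    mean = stats.mean(axis=0)
    scale = stats.std(axis=0)
    scale[scale == 0] = 1.0
    z = (stats - mean) / scale
    clf = LinearSVC(C=1.0, random_state=seed, max_iter=10000)
    clf.fit(z, labels.astype(int))
    return QualityModel(
        mode="svm",
        svm_weights=clf.coef_.ravel().copy(),
        svm_bias=float(clf.intercept_[0]),
        stat_mean=mean,
        stat_scale=scale,
    )


def rejection_rate(n_before: int, n_after: int) -> float:
    """Percentage of beats rejected, reported to 2 decimals."""
    if n_before <= 0:
        raise DomainError("n_before must be positive")
    if not (0 <= n_after <= n_before):
        raise DomainError("need 0 <= n_after <= n_before")
    return round(100.0 * (1.0 - n_after / n_before), 2)
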