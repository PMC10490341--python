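"""Fiducial detection and the 17 per-beat pulse/SDPPG features.

Per accepted beat, the pulse fiducials are the systolic peak, the dicrotic
minimum and the reflected (diastolic) peak; the second derivative of the PPG
(SDPPG) contributes the alternating a-b-c-d-e waves of early systole.  The 17
features are the foot-referenced peak amplitudes and times, the pulse
interval, the augmentation index (diastolic/systolic amplitude ratio), the
raw a-wave amplitude, the b/a..e/a amplitude ratios, and the a-e wave timing
intervals.  Feature matrices are z-score normalized with training-set
statistics only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import DomainError, FiducialError
from .io import FEATURE_COLUMNS
from .quality import Beat

logger = logging.getLogger(__name__)

#: minimum prominence of an acceptable diastolic local maximum, as a fraction
#: of the systolic amplitude; below this the reflected wave is considered
#: merged (exercise morphology) and the e-wave fallback is used
DIA_PROMINENCE_FRAC = 0.05


@dataclass
class Fiducials:
    """Beat-relative fiducial times (s) and amplitudes (foot-referenced for
    the pulse, raw SDPPG values for waves a-e)."""

    sys_t: float
    sys_amp: float
    dia_t: float
    dia_amp: float
    dia_from_e: bool
    wave_t: np.ndarray  # times of a, b, c, d, e
    wave_amp: np.ndarray  # SDPPG values at those times


def second_derivative(samples: np.ndarray, fs: float) -> np.ndarray:
    """SDPPG via Savitzky-Golay differentiation (9-sample window at 125 Hz,
    scaled with fs; polynomial order 4 so pulse-band sinusoids differentiate
    to better than 1%).  Exact for polynomials up to the fit order."""
    x = np.asarray(samples, dtype=float)
    win = int(round(9 * fs / 125.0))
    win = max(7, win + (win % 2 == 0))  # odd, > polyorder
    if x.size < max(9, win):
        raise DomainError(f"beat too short for SDPPG ({x.size} samples)")
    return sps.savgol_filter(x, window_length=win, polyorder=4, deriv=2,
                             delta=1.0 / fs)


def _alternating_waves(sd: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """First five alternating SDPPG extrema (a=max, b=min, c=max, d=min,
    e=max) after the foot, each the first extremum of the required kind after
    the previous one."""
    maxima, _ = sps.find_peaks(sd)
    minima, _ = sps.find_peaks(-sd)
    idx = []
    pools = (maxima, minima, maxima, minima, maxima)
    prev = 0
    for pool in pools:
        nxt = pool[pool > prev]
        if nxt.size == 0:
            raise FiducialError(
                f"only {len(idx)} of 5 alternating SDPPG extrema found"
            )
        prev = int(nxt[0])
        idx.append(prev)
    idx = np.asarray(idx)
    return idx / fs, sd[idx]


def detect_fiducials(beat: Beat | np.ndarray, fs: float) -> Fiducials:
    """Locate pulse and SDPPG fiducials within one accepted beat.

    The systolic peak is the global maximum; the diastolic peak is the most
    prominent local maximum after the dicrotic minimum.  When the reflected
    wave is merged into the systolic decay (attenuated second peak during
    exercise) no qualifying local maximum exists and the e-wave time of the
    SDPPG is used as the diastolic surrogate (``dia_from_e`` flag set).
    """
    x = np.asarray(beat.samples if isinstance(beat, Beat) else beat, dtype=float)
    foot_val = x[0]
    sys_i = int(np.argmax(x))
    sys_t = sys_i / fs
    sys_amp = float(x[sys_i] - foot_val)
    if sys_i == 0 or sys_amp <= 0:
        raise FiducialError("no systolic upstroke: beat maximum at the foot")

    sd = second_derivative(x, fs)
    wave_t, wave_amp = _alternating_waves(sd, fs)
    if wave_amp[0] <= 0:
        raise FiducialError("a-wave amplitude not positive")
    if wave_amp[1] >= 0:
        raise FiducialError("b-wave amplitude not negative")

    dia_i = None
    seg = x[sys_i:]
    if seg.size >= 3:
        notches, _ = sps.find_peaks(-seg)
        if notches.size:
            tail_start = sys_i + int(notches[0])
            tail = x[tail_start:]
            peaks, props = sps.find_peaks(
                tail, prominence=DIA_PROMINENCE_FRAC * sys_amp
            )
            if peaks.size:
                best = peaks[np.argmax(tail[peaks])]
                dia_i = tail_start + int(best)
    if dia_i is not None:
        dia_t = dia_i / fs
        dia_amp = float(x[dia_i] - foot_val)
        dia_from_e = False
    else:
        dia_t = float(wave_t[4])  # e wave marks the dicrotic region
        j = min(len(x) - 1, int(round(dia_t * fs)))
        dia_amp = float(x[j] - foot_val)
        dia_from_e = True
    if not (0 < sys_t < dia_t < len(x) / fs):
        raise FiducialError(
            f"fiducial ordering violated: sys_t={sys_t:.3f}, dia_t={dia_t:.3f}"
        )
    return Fiducials(sys_t, sys_amp, dia_t, dia_amp, dia_from_e, wave_t, wave_amp)


def extract_features(
    beat: Beat, fid: Fiducials, fs: float, sbp_ref: float, dbp_ref: float
) -> dict:
    """The 17-feature row for one beat (plus reference BP).

    Pulse amplitudes are measured relative to the foot value; SDPPG wave
    amplitudes b-e are normalized by the a wave; all times are beat-relative
    seconds.
    """
    a, b, c, d, e = fid.wave_amp
    ta, tb, tc, td, te = fid.wave_t
    f6 = beat.n / fs
    row = {
        "f01_systolic_peak": fid.sys_amp,
        "f02_diastolic_peak": fid.dia_amp,
        "f03_t1": fid.sys_t,
        "f04_delta_t": fid.dia_t - fid.sys_t,
        "f05_dia_peak_time": fid.dia_t,
        "f06_pulse_interval": f6,
        "f07_augmentation_index": fid.dia_amp / fid.sys_amp,
        "f08_a_amp": a,
        "f09_b_a": b / a,
        "f10_c_a": c / a,
        "f11_d_a": d / a,
        "f12_e_a": e / a,
        "f13_ta": ta,
        "f14_tb_a": tb - ta,
        "f15_tb_c": tc - tb,
        "f16_tc_d": td - tc,
        "f17_td_e": te - td,
    }
    if not (0.3 <= f6 <= 2.0) or not (row["f03_t1"] < f6) or not (ta < f6):
        raise FiducialError("feature invariants violated for beat")
    row["sbp_ref"] = sbp_ref
    row["dbp_ref"] = dbp_ref
    return row


def extract_feature_table(rec, beats: list[Beat]) -> pd.DataFrame:
    """Run fiducial detection + feature extraction over accepted beats.

    Reference BP per beat is the median of the step-function reference
    channels over the beat span.  Beats whose fiducials fail are excluded
    with a logged reason.  Returns the canonical feature-table frame.
    """
    rows = []
    n_failed = 0
    for i, b in enumerate(beats):
        if b.verdict != "accepted":
            continue
        try:
            fid = detect_fiducials(b, rec.sampling_rate)
            sbp = float(np.median(rec.sbp_ref[b.start_sample : b.end_sample])) \
                if rec.sbp_ref is not None else np.nan
            dbp = float(np.median(rec.dbp_ref[b.start_sample : b.end_sample])) \
                if rec.dbp_ref is not None else np.nan
            row = extract_features(b, fid, rec.sampling_rate, sbp, dbp)
        except (FiducialError, DomainError) as exc:
            n_failed += 1
            logger.debug("beat %d excluded: %s", i, exc)
            continue
        rows.append({"beat_id": i, "phase": b.phase, **row})
    if n_failed:
        logger.info("fiducial/feature failure on %d beats", n_failed)
    cols = ["beat_id", "phase", *FEATURE_COLUMNS, "sbp_ref", "dbp_ref"]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class NormalizationStats:
    """Per-feature training-set mean/SD for z-score normalization."""

    feature_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    n: int

    @property
    def constant_mask(self) -> np.ndarray:
        return self.sd == 0


def zscore_fit(matrix: pd.DataFrame) -> NormalizationStats:
    """Fit per-feature mean and sample SD (ddof=1) on the training matrix.

    Constant features (SD = 0) are flagged and excluded by
    :func:`zscore_apply` with a warning.
    """
    if len(matrix) < 2:
        raise DomainError("need at least 2 rows to fit normalization stats")
    mean = matrix.mean(axis=0).to_numpy()
    sd = matrix.std(axis=0, ddof=1).to_numpy()
    if np.any(sd == 0):
        bad = [c for c, s in zip(matrix.columns, sd) if s == 0]
        warnings.warn(f"constant features flagged for exclusion: {bad}",
                      stacklevel=2)
    return NormalizationStats(list(matrix.columns), mean, sd, len(matrix))


def zscore_apply(matrix: pd.DataFrame, stats: NormalizationStats) -> pd.DataFrame:
    """(y - M)/SD with training-set statistics; constant features dropped."""
    if list(matrix.columns) != stats.feature_names:
        raise DomainError("feature schema does not match normalization stats")
    keep = ~stats.constant_mask
    names = [n for n, k in zip(stats.feature_names, keep) if k]
    z = (matrix.to_numpy()[:, keep] - stats.mean[keep]) / stats.sd[keep]
    return pd.DataFrame(z, columns=names, index=matrix.index)
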