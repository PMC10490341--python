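import numpy as np
import pytest

from ppg2bp.synth import ProtocolConfig, WaveformParams, synthesize_recording


@pytest.fixture(scope="session")
def clean_recording():
    """Artifact-free recording (2-min phases) with per-beat ground truth."""
    cfg = ProtocolConfig(phase_durations_s=(120.0, 120.0, 120.0), seed=1)
    params = WaveformParams(p_artifact=(0.0, 0.0, 0.0))
    return synthesize_recording(cfg, params)


@pytest.fixture(scope="session")
def noisy_recording():
    """Recording with default artifact probabilities (5-min phases)."""
    cfg = ProtocolConfig(phase_durations_s=(300.0, 300.0, 300.0), seed=0)
    return synthesize_recording(cfg, WaveformParams())


def naive_rrelieff(X, y, k=10, sigma=50.0):
    """Brute-force O(n^2) regression-Relief reference (loop form).

    Independent of the package's vectorized scorer: explicit per-pair
    distances, explicit rank-decay accumulation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, f = X.shape
    yr = np.ptp(y)
    xr = np.ptp(X, axis=0)
    xr = np.where(xr == 0, 1.0, xr)
    ranks = np.arange(1, k + 1)
    rw = np.exp(-((ranks / sigma) ** 2))
    rw = rw / rw.sum()
    ndc = 0.0
    ndf = np.zeros(f)
    ndcdf = np.zeros(f)
    for i in range(n):
        pairs = [(float(np.abs(X[j] - X[i]).sum()), j) for j in range(n) if j != i]
        pairs.sort(key=lambda p: (p[0], p[1]))
        for r, (_, j) in enumerate(pairs[:k]):
            dy = abs(y[j] - y[i]) / yr
            ndc += rw[r] * dy
            for c in range(f):
                dx = abs(X[j, c] - X[i, c]) / xr[c]
                ndf[c] += rw[r] * dx
                ndcdf[c] += rw[r] * dy * dx
    return ndcdf / ndc - (ndf - ndcdf) / (n - ndc)


def match_beats_to_truth(annotations, ground_truth):
    """Label each detected beat artifact/clean by overlap with ground-truth
    beats (a detected beat is an artifact if it overlaps any flagged beat)."""
    import bisect

    feet = ground_truth["foot_sample"].to_numpy()
    flags = ground_truth["artifact_flag"].to_numpy()
    out = []
    for _, r in annotations.iterrows():
        i0 = max(0, bisect.bisect_right(feet, r["start_sample"]) - 1)
        i1 = bisect.bisect_left(feet, r["end_sample"])
        out.append(bool(flags[i0:i1].any()))
    return np.asarray(out)
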