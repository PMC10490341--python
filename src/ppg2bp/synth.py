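"""Protocol-faithful synthetic PPG + blood-pressure generator.

Emulates a 3 x 20-min rest / ergometer-exercise / recovery protocol: heart
rate relaxes toward the Karvonen target during exercise, systolic pressure
rises by ~40 mmHg while diastolic pressure stays near its baseline, and each
beat is rendered as two log-normal-shaped pulses (systolic + reflected
diastolic) whose second peak is strongly attenuated during exercise.  Motion
artifacts (baseline wander plus negative-going spike transients, the typical
signature of probe motion) corrupt beats with a per-phase probability that is
highest during exercise.

The latent -> waveform map is fixed and invertible on clean beats:

* systolic amplitude      A1 = k_a * (SBP - DBP)
* reflection arrival      dT = dT0 - k_t * (SBP - SBP_baseline)
* reflection index        RI = A2 / A1, phase-dependent (rest/recovery vs
  exercise), realising the attenuated second peak

so a downstream regressor provably has signal to learn.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .io import Phase, Recording

PHASE_ORDER = ("rest", "exercise", "recovery")


def karvonen_target_hr(age: float, resting_hr: float, intensity: float) -> float:
    """Karvonen target heart rate: (maxHR - restHR) * intensity + restHR.

    Maximum heart rate is the conventional 220 - age (bpm).
    """
    if not (0 < intensity <= 1):
        raise DomainError(f"intensity must be in (0, 1], got {intensity}")
    if not (10 <= age <= 100):
        raise DomainError(f"age must be in [10, 100] years, got {age}")
    if resting_hr <= 0:
        raise DomainError("resting_hr must be positive")
    max_hr = 220.0 - age
    return (max_hr - resting_hr) * intensity + resting_hr


@dataclass
class ProtocolConfig:
    """Protocol-level parameters of one synthetic session."""

    phase_durations_s: tuple[float, float, float] = (1200.0, 1200.0, 1200.0)
    age: float = 20.0
    resting_hr: float = 60.0
    intensity: float = 0.7
    seed: int = 0
    sampling_rate: float = 125.0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.phase_durations_s):
            raise DomainError("phase durations must be positive")
        if not (0 < self.intensity <= 1):
            raise DomainError("intensity must be in (0, 1]")
        if not (10 <= self.age <= 100):
            raise DomainError("age must be in [10, 100]")
        if self.sampling_rate <= 0:
            raise DomainError("sampling_rate must be positive")


@dataclass
class WaveformParams:
    """Latent-trajectory and waveform/artifact parameters.

    BP units mmHg, times s, amplitudes arbitrary units.  ``k_a`` converts
    pulse pressure to systolic pulse amplitude; ``k_t`` moves the reflected
    wave earlier as SBP rises; ``ri_*`` set the diastolic/systolic amplitude
    ratio per phase.
    """

    sbp_baseline: float = 115.0
    sbp_delta_exercise: float = 40.0
    dbp_baseline: float = 72.0
    dbp_drift_amp: float = 3.0
    dbp_drift_period_s: float = 600.0
    tau_hr_s: float = 60.0
    tau_sbp_s: float = 60.0
    bp_noise_sd: float = 2.0
    hr_noise_sd: float = 1.5
    k_a: float = 0.02
    dt0: float = 0.24
    k_t: float = 0.0012
    ri_rest: float = 0.45
    ri_exercise: float = 0.15
    t1: float = 0.13
    sys_width: float = 0.25
    dia_width: float = 0.30
    mid_frac: float = 0.25
    mid_delay: float = 0.09
    mid_width: float = 0.14
    p_artifact: tuple[float, float, float] = (0.25, 0.70, 0.17)
    ppg_noise_sd: float = 0.0

    def reflection_index(self, phase: str) -> float:
        return self.ri_exercise if phase == "exercise" else self.ri_rest


GROUND_TRUTH_COLUMNS = [
    "beat_id",
    "phase",
    "sbp",
    "dbp",
    "hr",
    "foot_sample",
    "systolic_peak_sample",
    "diastolic_peak_sample",
    "reflection_index",
    "artifact_flag",
]


def _phase_streams(seed: int, tag: str) -> dict[str, np.random.Generator]:
    """One child generator per phase so earlier phases are unaffected when a
    later phase's duration changes."""
    tag_key = zlib.crc32(tag.encode()) % (2**31)  # stable across processes
    root = np.random.SeedSequence([seed, tag_key])
    children = root.spawn(len(PHASE_ORDER))
    return {ph: np.random.default_rng(ss) for ph, ss in zip(PHASE_ORDER, children)}


def simulate_trajectories(
    cfg: ProtocolConfig, params: WaveformParams | None = None
) -> pd.DataFrame:
    """Per-beat heart-rate and blood-pressure trajectories over the protocol.

    HR relaxes (first order, time constant ``tau_hr_s``) from the resting rate
    toward the Karvonen target during exercise and back during recovery.  SBP
    relaxes from its baseline toward baseline + ``sbp_delta_exercise`` and
    back; DBP is baseline plus a slow sinusoidal drift.  Additive Gaussian
    beat-to-beat noise is drawn from per-phase seeded sub-streams.

    Returns a frame with one row per beat: t_foot_s, phase, hr, sbp, dbp.
    """
    params = params or WaveformParams()
    target_hr = karvonen_target_hr(cfg.age, cfg.resting_hr, cfg.intensity)
    d_rest, d_ex, d_rec = cfg.phase_durations_s
    rngs = _phase_streams(cfg.seed, "trajectory")

    # closed-form relaxation anchors at the phase transitions (noise-free)
    hr_ex_end = target_hr + (cfg.resting_hr - target_hr) * np.exp(-d_ex / params.tau_hr_s)
    sbp_top = params.sbp_baseline + params.sbp_delta_exercise
    sbp_ex_end = sbp_top + (params.sbp_baseline - sbp_top) * np.exp(-d_ex / params.tau_sbp_s)

    def latent(t: float) -> tuple[str, float, float, float]:
        if t < d_rest:
            return "rest", cfg.resting_hr, params.sbp_baseline, params.dbp_baseline
        if t < d_rest + d_ex:
            u = t - d_rest
            hr = target_hr + (cfg.resting_hr - target_hr) * np.exp(-u / params.tau_hr_s)
            sbp = sbp_top + (params.sbp_baseline - sbp_top) * np.exp(-u / params.tau_sbp_s)
            return "exercise", hr, sbp, params.dbp_baseline
        u = t - d_rest - d_ex
        hr = cfg.resting_hr + (hr_ex_end - cfg.resting_hr) * np.exp(-u / params.tau_hr_s)
        sbp = params.sbp_baseline + (sbp_ex_end - params.sbp_baseline) * np.exp(
            -u / params.tau_sbp_s
        )
        return "recovery", hr, sbp, params.dbp_baseline

    total = d_rest + d_ex + d_rec
    rows = []
    t = 0.0
    beat_id = 0
    while True:
        phase, hr0, sbp0, dbp0 = latent(t)
        rng = rngs[phase]
        dbp0 = dbp0 + params.dbp_drift_amp * np.sin(
            2 * np.pi * t / params.dbp_drift_period_s
        )
        hr = max(30.0, hr0 + rng.normal(0.0, params.hr_noise_sd))
        sbp = sbp0 + rng.normal(0.0, params.bp_noise_sd)
        dbp = dbp0 + rng.normal(0.0, params.bp_noise_sd)
        dbp = min(dbp, sbp - 10.0)  # keep pulse pressure physiological
        duration = 60.0 / hr
        if t + duration > total:
            break
        rows.append(
            {
                "beat_id": beat_id,
                "t_foot_s": t,
                "phase": phase,
                "hr": hr,
                "sbp": sbp,
                "dbp": dbp,
            }
        )
        t += duration
        beat_id += 1
    return pd.DataFrame(rows)


def _lognormal_bump(t: np.ndarray, t_peak: float, width: float) -> np.ndarray:
    """Unit-amplitude log-normal-shaped pulse peaking exactly at ``t_peak``.

    Gaussian in ln(t): rises steeply after the foot, decays with a long tail —
    the usual single-pulse PPG morphology surrogate.
    """
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = np.exp(-(np.log(t[pos] / t_peak) ** 2) / (2.0 * width**2))
    return out


def render_clean_beat(
    n_samples: int, fs: float, a1: float, ri: float, dt: float, params: WaveformParams
) -> np.ndarray:
    """Render one clean beat: systolic pulse + mid-systolic shoulder +
    attenuated reflected (diastolic) pulse.

    The shoulder (a small early reflection merged into the systolic decay)
    carries no latent information but gives the second derivative its
    conventional five-wave a-e systolic microstructure.
    """
    if dt < 0.05:
        raise DomainError(
            f"reflected-wave delay dT = {dt:.4f} s < 0.05 s: degenerate morphology"
        )
    t = np.arange(n_samples) / fs
    wave = a1 * _lognormal_bump(t, params.t1, params.sys_width)
    wave += params.mid_frac * a1 * _lognormal_bump(
        t, params.t1 + params.mid_delay, params.mid_width
    )
    wave += ri * a1 * _lognormal_bump(t, params.t1 + dt, params.dia_width)
    return wave


def _clean_beat_fiducials(wave: np.ndarray, dt: float, fs: float) -> tuple[int, int]:
    """(systolic, diastolic) peak sample offsets of a clean rendered beat.

    The diastolic peak is the local maximum after the dicrotic minimum that
    follows the systolic peak; if the reflected pulse is truncated or merged
    past recognition the nominal reflected-peak sample is used.
    """
    sys_i = int(np.argmax(wave))
    nominal = min(len(wave) - 1, sys_i + max(1, int(round(dt * fs))))
    seg = wave[sys_i:]
    if len(seg) < 3:
        return sys_i, nominal
    d = np.diff(seg)
    mins = np.nonzero((d[:-1] < 0) & (d[1:] >= 0))[0] + 1
    if mins.size == 0:
        return sys_i, nominal
    notch = int(mins[0])
    tail = seg[notch:]
    if len(tail) < 3:
        return sys_i, nominal
    dt_tail = np.diff(tail)
    maxs = np.nonzero((dt_tail[:-1] > 0) & (dt_tail[1:] <= 0))[0] + 1
    if maxs.size == 0:
        return sys_i, nominal
    dia_i = sys_i + notch + int(maxs[np.argmax(tail[maxs])])
    return sys_i, dia_i


def _corrupt(
    wave: np.ndarray, fs: float, a1: float, rng: np.random.Generator
) -> np.ndarray:
    """Add motion artifact: large baseline wander + negative spike transients."""
    t = np.arange(len(wave)) / fs
    amp = a1 * rng.uniform(1.0, 1.8)
    f = rng.uniform(0.1, 0.5)
    phi = rng.uniform(0, 2 * np.pi)
    out = wave + amp * np.sin(2 * np.pi * f * t + phi)
    for _ in range(rng.integers(1, 4)):
        pos = rng.uniform(0.0, t[-1] if len(t) > 1 else 0.0)
        spike_amp = -a1 * rng.uniform(0.8, 1.8)
        out += spike_amp * np.exp(-((t - pos) ** 2) / (2 * 0.02**2))
    return out


def synthesize_recording(
    cfg: ProtocolConfig, params: WaveformParams | None = None
) -> tuple[Recording, pd.DataFrame]:
    """Synthesize a full protocol recording with per-beat ground truth.

    Returns the Recording (PPG + per-sample step-function reference BP) and a
    ground-truth table (one row per beat, :data:`GROUND_TRUTH_COLUMNS`).
    """
    params = params or WaveformParams()
    fs = cfg.sampling_rate
    traj = simulate_trajectories(cfg, params)
    art_rngs = _phase_streams(cfg.seed, "artifact")
    noise_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 911]))

    d_rest, d_ex, d_rec = cfg.phase_durations_s
    bounds = np.cumsum([0.0, d_rest, d_ex, d_rec])
    n_total = int(round(bounds[-1] * fs))
    ppg = np.zeros(n_total)
    sbp_ch = np.full(n_total, params.sbp_baseline)
    dbp_ch = np.full(n_total, params.dbp_baseline)

    foot_samples = np.round(traj["t_foot_s"].to_numpy() * fs).astype(int)
    gt_rows = []
    for i, row in traj.iterrows():
        start = foot_samples[i]
        end = foot_samples[i + 1] if i + 1 < len(traj) else min(
            n_total, start + int(round(60.0 / row["hr"] * fs))
        )
        end = min(end, n_total)
        n_b = end - start
        if n_b <= 0:
            continue
        ri = params.reflection_index(row["phase"])
        a1 = params.k_a * (row["sbp"] - row["dbp"])
        dt = params.dt0 - params.k_t * (row["sbp"] - params.sbp_baseline)
        wave = render_clean_beat(n_b, fs, a1, ri, dt, params)
        sys_off, dia_off = _clean_beat_fiducials(wave, dt, fs)
        flagged = bool(art_rngs[row["phase"]].random() < params.p_artifact[
            PHASE_ORDER.index(row["phase"])
        ])
        if flagged:
            wave = _corrupt(wave, fs, a1, art_rngs[row["phase"]])
        ppg[start:end] = wave
        sbp_ch[start:end] = row["sbp"]
        dbp_ch[start:end] = row["dbp"]
        gt_rows.append(
            {
                "beat_id": int(row["beat_id"]),
                "phase": row["phase"],
                "sbp": row["sbp"],
                "dbp": row["dbp"],
                "hr": row["hr"],
                "foot_sample": int(start),
                "systolic_peak_sample": int(start + sys_off),
                "diastolic_peak_sample": int(start + dia_off),
                "reflection_index": ri,
                "artifact_flag": flagged,
            }
        )
    if params.ppg_noise_sd > 0:
        ppg += noise_rng.normal(0.0, params.ppg_noise_sd, size=n_total)

    phases = [
        Phase(label, int(round(bounds[k] * fs)), int(round(bounds[k + 1] * fs)))
        for k, label in enumerate(PHASE_ORDER)
    ]
    rec = Recording(
        sampling_rate=fs,
        ppg=ppg,
        sbp_ref=sbp_ch,
        dbp_ref=dbp_ch,
        phases=phases,
        subject_meta={"age_years": cfg.age, "resting_hr_bpm": cfg.resting_hr,
                      "intensity": cfg.intensity, "seed": cfg.seed},
    )
    return rec, pd.DataFrame(gt_rows, columns=GROUND_TRUTH_COLUMNS)
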