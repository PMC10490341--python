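"""Reading and writing recordings, beat annotations and feature tables.

A recording lives in a two-file pair: a comma-delimited data file with one
header line (columns ``time_s, ppg[, sbp_ref, dbp_ref]``) and a JSON sidecar
(``<stem>.json``) holding the sampling rate, the ordered phase intervals and
free-form subject metadata.  All sample intervals are 0-based and half-open.

Feature tables and beat-annotation tables are plain CSV with fixed, documented
headers so that fixtures stay diffable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

PHASE_LABELS = ("rest", "exercise", "recovery")

#: Canonical feature-table column order (17 pulse/SDPPG features + metadata).
FEATURE_COLUMNS = [
    "f01_systolic_peak",
    "f02_diastolic_peak",
    "f03_t1",
    "f04_delta_t",
    "f05_dia_peak_time",
    "f06_pulse_interval",
    "f07_augmentation_index",
    "f08_a_amp",
    "f09_b_a",
    "f10_c_a",
    "f11_d_a",
    "f12_e_a",
    "f13_ta",
    "f14_tb_a",
    "f15_tb_c",
    "f16_tc_d",
    "f17_td_e",
]

FEATURE_TABLE_HEADER = ["beat_id", "phase", *FEATURE_COLUMNS, "sbp_ref", "dbp_ref"]

ANNOTATION_COLUMNS = ["beat_id", "start_sample", "end_sample", "ssqi", "verdict", "phase"]


@dataclass(frozen=True)
class Phase:
    """A labelled half-open sample interval [start_sample, end_sample)."""

    label: str
    start_sample: int
    end_sample: int


@dataclass
class Recording:
    """A uniformly sampled multichannel recording.

    Channels: the PPG (arbitrary units) and optional per-sample reference
    blood pressures (mmHg, step functions of the beat-to-beat reference).
    """

    sampling_rate: float
    ppg: np.ndarray
    phases: list[Phase]
    sbp_ref: np.ndarray | None = None
    dbp_ref: np.ndarray | None = None
    subject_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppg = np.asarray(self.ppg, dtype=float)
        if self.sbp_ref is not None:
            self.sbp_ref = np.asarray(self.sbp_ref, dtype=float)
        if self.dbp_ref is not None:
            self.dbp_ref = np.asarray(self.dbp_ref, dtype=float)
        self.validate()

    @property
    def n_samples(self) -> int:
        return int(self.ppg.shape[0])

    def validate(self) -> None:
        if not np.isfinite(self.sampling_rate) or self.sampling_rate <= 0:
            raise FormatError("sampling_rate must be positive")
        n = self.n_samples
        for name in ("sbp_ref", "dbp_ref"):
            ch = getattr(self, name)
            if ch is not None and ch.shape[0] != n:
                raise FormatError(
                    f"channel {name} has length {ch.shape[0]}, expected {n}"
                )
        prev_end = 0
        for ph in self.phases:
            if ph.label not in PHASE_LABELS:
                raise FormatError(f"unknown phase label {ph.label!r}")
            if not (0 <= ph.start_sample < ph.end_sample <= n):
                raise FormatError(
                    f"phase {ph.label} interval [{ph.start_sample}, {ph.end_sample}) "
                    f"outside [0, {n})"
                )
            if ph.start_sample < prev_end:
                raise FormatError(f"phase {ph.label} overlaps the preceding phase")
            prev_end = ph.end_sample

    def phase_of(self, sample: int) -> str | None:
        """Phase label containing ``sample``, or None outside all phases."""
        for ph in self.phases:
            if ph.start_sample <= sample < ph.end_sample:
                return ph.label
        return None


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_recording(path: str | Path) -> Recording:
    """Read a recording from a data file + JSON sidecar pair.

    The time column must be a uniform grid consistent with the sidecar's
    sampling rate to within 1e-6 s.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not path.exists():
        raise FormatError(f"data file not found: {path}")
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar: {sidecar}")
    meta = json.loads(sidecar.read_text())
    try:
        fs = float(meta["sampling_rate_hz"])
        phase_spec = meta["phases"]
    except KeyError as exc:
        raise FormatError(f"sidecar missing required key {exc}") from exc
    phases = [
        Phase(str(p["label"]), int(p["start_sample"]), int(p["end_sample"]))
        for p in phase_spec
    ]
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns or "ppg" not in df.columns:
        raise FormatError("data file must have columns time_s and ppg")
    t = df["time_s"].to_numpy(dtype=float)
    expected = np.arange(len(t)) / fs
    dev = np.abs(t - expected)
    bad = np.nonzero(dev > 1e-6)[0]
    if bad.size:
        i = int(bad[0])
        raise FormatError(
            f"time column is not a uniform {fs} Hz grid: first offending index "
            f"{i} (time {t[i]:.9f} s, expected {expected[i]:.9f} s)"
        )
    return Recording(
        sampling_rate=fs,
        ppg=df["ppg"].to_numpy(dtype=float),
        sbp_ref=df["sbp_ref"].to_numpy(dtype=float) if "sbp_ref" in df else None,
        dbp_ref=df["dbp_ref"].to_numpy(dtype=float) if "dbp_ref" in df else None,
        phases=phases,
        subject_meta=dict(meta.get("subject_meta", {})),
    )


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write ``rec`` so that :func:`read_recording` inverts it exactly.

    Channel values are written with shortest-round-trip float formatting, so
    the round trip is bit-exact.  Absent reference channels are omitted from
    the data file and recorded as absent in the sidecar.
    """
    path = Path(path)
    cols: dict[str, np.ndarray] = {
        "time_s": np.arange(rec.n_samples) / rec.sampling_rate,
        "ppg": rec.ppg,
    }
    if rec.sbp_ref is not None:
        cols["sbp_ref"] = rec.sbp_ref
    if rec.dbp_ref is not None:
        cols["dbp_ref"] = rec.dbp_ref
    # %.17g is round-trip exact for float64, so read_recording inverts bit-wise
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    meta = {
        "sampling_rate_hz": rec.sampling_rate,
        "phases": [
            {"label": p.label, "start_sample": p.start_sample, "end_sample": p.end_sample}
            for p in rec.phases
        ],
        "channels": sorted(set(cols) - {"time_s"}),
        "subject_meta": rec.subject_meta,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def write_feature_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table (one row per accepted beat) as CSV.

    ``rows`` must carry exactly the canonical schema; an empty frame yields a
    header-only file.
    """
    if list(rows.columns) != FEATURE_TABLE_HEADER:
        missing = set(FEATURE_TABLE_HEADER) - set(rows.columns)
        extra = set(rows.columns) - set(FEATURE_TABLE_HEADER)
        raise FormatError(
            f"feature table schema mismatch (missing {sorted(missing)}, "
            f"extra {sorted(extra)}, or wrong order)"
        )
    rows.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != FEATURE_TABLE_HEADER:
        raise FormatError(f"unexpected feature table header in {path}")
    return df


def write_annotations(table: pd.DataFrame, path: str | Path) -> None:
    if list(table.columns) != ANNOTATION_COLUMNS:
        raise FormatError("annotation table schema mismatch")
    table.to_csv(path, index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != ANNOTATION_COLUMNS:
        raise FormatError(f"unexpected annotation header in {path}")
    return df
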