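"""End-to-end orchestration: synth -> quality -> features -> select -> train
-> evaluate, with a validated config, presets, artifact writing and an audit
log of per-stage counts."""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from . import __version__, io
from .errors import TrainingError
from .evaluation import phase_report
from .features import extract_feature_table, zscore_apply, zscore_fit
from .model import (ModelConfig, build_windows, phase_mean_baseline,
                    predict, split_dataset, train)
from .quality import QualityModel, classify_beats, segment_beats
from .selection import rrelieff, select_nonnegative
from .synth import ProtocolConfig, WaveformParams, synthesize_recording

logger = logging.getLogger(__name__)

PHASES = ("rest", "exercise", "recovery")
TARGETS = {"sbp": "sbp_ref", "dbp": "dbp_ref"}


class SynthSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    subjects: int = 2
    phase_durations_s: tuple[float, float, float] = (1200.0, 1200.0, 1200.0)
    age: float = 20.0
    resting_hr: float = 60.0
    intensity: float = 0.7
    sampling_rate: float = 125.0


class QualitySection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: Literal["threshold", "svm"] = "threshold"
    threshold: float = 0.0
    low_hz: float = 0.5
    high_hz: float = 8.0


class SelectionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_neighbors: int = 10
    sigma_decay: float = 50.0


class ModelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    bilstm_units: int = 100
    lstm_units: tuple[int, int, int] = (200, 400, 800)
    batch_size: int = 256
    epochs: int = 850
    learning_rate: float = 0.004
    window_len: int = 10
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    scale: float = 1.0

    @model_validator(mode="after")
    def _check(self):
        if any(f <= 0 for f in self.split) or abs(sum(self.split) - 1) > 1e-9:
            raise ValueError("split fractions must be positive and sum to 1")
        return self


class PipelineConfig(BaseModel):
    """Validated end-to-end configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    preset: Literal["paper", "ci"] = "ci"
    seed: int = 0
    synth: SynthSection = SynthSection()
    quality: QualitySection = QualitySection()
    selection: SelectionSection = SelectionSection()
    model: ModelSection = ModelSection()

    @classmethod
    def from_preset(cls, preset: str, seed: int = 0, **overrides) -> "PipelineConfig":
        if preset == "paper":
            base = {"synth": {"subjects": 17}, "model": {"scale": 1.0}}
        elif preset == "ci":
            # desk-scale: 2 subjects, 10-min phases, quarter-size network
            base = {
                "synth": {"subjects": 2, "phase_durations_s": (600.0, 600.0, 600.0)},
                "model": {"scale": 0.25},
            }
        else:
            raise ValueError(f"unknown preset {preset!r}")
        base.update(overrides)
        return cls(preset=preset, seed=seed, **base)


def _model_cfg(cfg: PipelineConfig, seed: int) -> ModelConfig:
    m = cfg.model
    return ModelConfig(
        bilstm_units=m.bilstm_units, lstm_units=m.lstm_units,
        batch_size=m.batch_size, epochs=m.epochs,
        learning_rate=m.learning_rate, window_len=m.window_len,
        split=m.split, seed=seed, scale=m.scale,
    )


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path,
                 targets: tuple[str, ...] = ("sbp", "dbp")) -> dict:
    """Execute every stage on freshly synthesized recordings.

    Writes all intermediate artifacts (recordings, annotations, feature
    tables, selection scores, training curves, report, manifest) under
    ``out_dir`` and returns the report dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    audit: dict = {"stages": {}}

    # --- synth + quality + features per subject ---------------------------
    frames = []
    ann_frames = []
    qmodel = QualityModel(mode=cfg.quality.mode, threshold=cfg.quality.threshold)
    for s in range(cfg.synth.subjects):
        pcfg = ProtocolConfig(
            phase_durations_s=cfg.synth.phase_durations_s, age=cfg.synth.age,
            resting_hr=cfg.synth.resting_hr, intensity=cfg.synth.intensity,
            seed=(cfg.seed * 1000 + s) % (2**31), sampling_rate=cfg.synth.sampling_rate,
        )
        rec, gt = synthesize_recording(pcfg, WaveformParams())
        io.write_recording(rec, out / f"subject{s:02d}.csv")
        gt.to_csv(out / f"subject{s:02d}_ground_truth.csv", index=False)
        beats = segment_beats(rec, cfg.quality.low_hz, cfg.quality.high_hz)
        ann = classify_beats(beats, qmodel)
        ann.insert(0, "subject", s)
        ann_frames.append(ann)
        feats = extract_feature_table(rec, beats)
        feats.insert(0, "subject", s)
        frames.append(feats)
    annotations = pd.concat(ann_frames, ignore_index=True)
    io.write_annotations(annotations.drop(columns="subject"),
                         out / "annotations.csv")
    features_all = pd.concat(frames, ignore_index=True)
    features_all.to_csv(out / "features.csv", index=False)
    audit["stages"]["quality"] = {
        "beats_in": int(len(annotations)),
        "accepted": int((annotations["verdict"] == "accepted").sum()),
        "rejected": int((annotations["verdict"] == "rejected").sum()),
    }
    audit["stages"]["features"] = {"rows": int(len(features_all))}

    # --- per phase / target: normalize, select, window, train, evaluate ---
    results: dict = {}
    scores_out: dict = {}
    for phase in PHASES:
        sub = features_all[features_all["phase"] == phase]
        for target in targets:
            key = (phase, target)
            tcol = TARGETS[target]
            if len(sub) < 4 * cfg.model.window_len:
                logger.warning("phase %s: too few feature rows (%d)", phase, len(sub))
                results[key] = None
                continue
            # chronological train portion (per subject) defines normalization
            # and selection statistics: no leakage into test/eval
            train_rows = sub.groupby("subject", group_keys=False).apply(
                lambda g: g.iloc[: int(cfg.model.split[0] * len(g))],
                include_groups=False,
            )
            Xtr = train_rows[io.FEATURE_COLUMNS]
            stats = zscore_fit(Xtr)
            ztr = zscore_apply(Xtr, stats)  # drops constant features
            scored_names = list(ztr.columns)
            scores = rrelieff(
                ztr.to_numpy(), train_rows[tcol].to_numpy(),
                k=cfg.selection.k_neighbors, sigma=cfg.selection.sigma_decay,
                feature_names=scored_names, target=target, phase=phase,
            )
            mask = select_nonnegative(scores)
            kept = [n for n, m in zip(scored_names, mask) if m]
            scores_out[f"{phase}/{target}"] = {
                "weights": dict(zip(scored_names, map(float, scores.weights))),
                "kept": kept,
            }
            z = zscore_apply(sub[io.FEATURE_COLUMNS], stats)[kept]
            tbl = pd.concat(
                [sub[["subject", "beat_id", "phase", tcol]].reset_index(drop=True),
                 z.reset_index(drop=True)], axis=1)
            mcfg = _model_cfg(cfg, cfg.seed)
            ds = build_windows(tbl, tcol, mcfg, feature_cols=kept,
                               group_cols=("subject", "phase"))
            if len(ds) < 20:
                logger.warning("phase %s/%s: only %d windows; skipping model",
                               phase, target, len(ds))
                results[key] = None
                continue
            try:
                tr, te, ev = split_dataset(ds, mcfg)
                trained = train(tr, te, mcfg)
            except TrainingError as exc:
                logger.warning("phase %s/%s training failed: %s", phase, target, exc)
                results[key] = None
                continue
            trained.curves.to_csv(out / f"curves_{phase}_{target}.csv", index=False)
            pred = predict(trained, ev)
            results[key] = (pred, ev.y)
            baseline = phase_mean_baseline(tr)
            audit["stages"][f"model/{phase}/{target}"] = {
                "windows": int(len(ds)), "train": int(len(tr)),
                "test": int(len(te)), "eval": int(len(ev)),
                "best_epoch": int(trained.best_epoch),
                "baseline_mae": float(np.mean(np.abs(baseline - ev.y))),
                "eval_mae": float(np.mean(np.abs(pred - ev.y))),
                "normalization_fit_rows": int(stats.n),
            }

    (out / "scores.json").write_text(json.dumps(scores_out, indent=1))
    report = phase_report(results, annotations)
    report["audit"] = audit
    (out / "report.json").write_text(json.dumps(report, indent=1))

    cfg_json = cfg.model_dump_json()
    manifest = {
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return report
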