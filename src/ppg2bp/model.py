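"""Beat-sequence windowing and the recurrent blood-pressure regressor.

Feature rows from accepted beats are grouped into sliding windows of
consecutive beats (a rejected or feature-failed beat breaks the run), the
window's target is the reference pressure of its final beat, and the window
stream is split chronologically 70/15/15 into train/test/eval.  The model is
a bidirectional LSTM followed by three LSTM layers and a linear regression
head, trained with MSE/Adam; the test split is monitored every epoch and the
best-test-loss parameters are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, TrainingError
from .nn import Adam, SequenceRegressor

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """Training configuration.  ``scale`` < 1 uniformly shrinks hidden-unit
    counts and the epoch budget for desk-scale runs (paper-exact settings at
    scale 1.0)."""

    bilstm_units: int = 100
    lstm_units: tuple[int, int, int] = (200, 400, 800)
    batch_size: int = 256
    epochs: int = 850
    learning_rate: float = 0.004
    window_len: int = 10
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    scale: float = 1.0
    shuffled_split: bool = False

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise DomainError(f"split fractions must sum to 1, got {self.split}")
        if any(s <= 0 for s in self.split):
            raise DomainError("every split fraction must be positive")
        if self.window_len < 1:
            raise DomainError("window_len must be >= 1")
        if not (0 < self.scale <= 1):
            raise DomainError("scale must be in (0, 1]")

    @property
    def scaled_bilstm_units(self) -> int:
        return max(1, round(self.bilstm_units * self.scale))

    @property
    def scaled_lstm_units(self) -> tuple[int, ...]:
        return tuple(max(1, round(u * self.scale)) for u in self.lstm_units)

    @property
    def scaled_epochs(self) -> int:
        return max(1, round(self.epochs * self.scale))


@dataclass
class SequenceDataset:
    """Windows (n, window_len, n_features), targets (n,) in mmHg, and
    provenance (first/last beat_id, run id, phase) per window."""

    X: np.ndarray
    y: np.ndarray
    meta: pd.DataFrame
    feature_names: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx: np.ndarray) -> "SequenceDataset":
        return SequenceDataset(self.X[idx], self.y[idx],
                               self.meta.iloc[idx].reset_index(drop=True),
                               self.feature_names)


def build_windows(
    feature_rows: pd.DataFrame,
    target_col: str,
    cfg: ModelConfig,
    feature_cols: list[str] | None = None,
    group_cols: tuple[str, ...] = ("phase",),
) -> SequenceDataset:
    """Sliding windows of consecutive accepted beats (stride 1).

    ``feature_rows`` must contain ``beat_id`` (consecutive integers within a
    run; a missing id is a gap that breaks the run), the feature columns and
    the target column.  Windows never span a gap or a group boundary.
    """
    if feature_cols is None:
        feature_cols = [c for c in feature_rows.columns
                        if c.startswith("f") and c[1:3].isdigit()]
    w = cfg.window_len
    Xs, ys, meta = [], [], []
    run_id = 0
    for keys, grp in feature_rows.groupby(list(group_cols), sort=False):
        grp = grp.sort_values("beat_id")
        ids = grp["beat_id"].to_numpy()
        breaks = np.nonzero(np.diff(ids) != 1)[0] + 1
        for run in np.split(np.arange(len(grp)), breaks):
            run_id += 1
            if len(run) < w:
                continue
            F = grp.iloc[run][feature_cols].to_numpy(dtype=float)
            t = grp.iloc[run][target_col].to_numpy(dtype=float)
            rids = ids[run]
            for s in range(len(run) - w + 1):
                Xs.append(F[s : s + w])
                ys.append(t[s + w - 1])
                meta.append(
                    {"first_beat": int(rids[s]), "last_beat": int(rids[s + w - 1]),
                     "run": run_id,
                     "group": keys if isinstance(keys, str) else "/".join(map(str, keys))}
                )
    if not Xs:
        logger.warning("no runs of %d consecutive accepted beats; empty dataset", w)
        return SequenceDataset(np.empty((0, w, len(feature_cols))), np.empty(0),
                               pd.DataFrame(columns=["first_beat", "last_beat",
                                                     "run", "group"]),
                               list(feature_cols))
    return SequenceDataset(np.stack(Xs), np.asarray(ys),
                           pd.DataFrame(meta), list(feature_cols))


def split_dataset(
    ds: SequenceDataset, cfg: ModelConfig
) -> tuple[SequenceDataset, SequenceDataset, SequenceDataset]:
    """Chronological 70/15/15 split of the window stream.

    Windows sharing source beats with an earlier partition (same run,
    overlapping beat span) are dropped from the later partition, so no beat
    leaks across the boundary.  ``shuffled_split`` gives a seeded random
    alternative.
    """
    n = len(ds)
    if n == 0:
        raise TrainingError("cannot split an empty dataset")
    f_train, f_test, _ = cfg.split
    if cfg.shuffled_split:
        rng = np.random.default_rng(cfg.seed)
        order = rng.permutation(n)
        i1, i2 = int(round(f_train * n)), int(round((f_train + f_test) * n))
        parts = (order[:i1], order[i1:i2], order[i2:])
        out = tuple(ds.subset(np.sort(p)) for p in parts)
    else:
        i1, i2 = int(round(f_train * n)), int(round((f_train + f_test) * n))
        idx = np.arange(n)
        train, test, ev = idx[:i1], idx[i1:i2], idx[i2:]
        test = _drop_overlap(ds, test, train)
        ev = _drop_overlap(ds, ev, np.concatenate([train, idx[i1:i2]]))
        out = (ds.subset(train), ds.subset(test), ds.subset(ev))
    if any(len(p) == 0 for p in out):
        raise TrainingError(
            f"a split partition is empty (sizes {[len(p) for p in out]})"
        )
    return out


def _drop_overlap(ds: SequenceDataset, part: np.ndarray,
                  earlier: np.ndarray) -> np.ndarray:
    if len(part) == 0 or len(earlier) == 0:
        return part
    last_by_run = ds.meta.iloc[earlier].groupby("run")["last_beat"].max()
    keep = []
    for i in part:
        row = ds.meta.iloc[i]
        bound = last_by_run.get(row["run"])
        if bound is None or row["first_beat"] > bound:
            keep.append(i)
    return np.asarray(keep, dtype=int)


@dataclass
class TrainedModel:
    net: SequenceRegressor
    config: ModelConfig
    feature_names: list[str]
    curves: pd.DataFrame
    best_epoch: int
    y_center: float = 0.0
    y_scale: float = 1.0


def train(
    train_ds: SequenceDataset, test_ds: SequenceDataset, cfg: ModelConfig
) -> TrainedModel:
    """Train the recurrent regressor; retain best-test-loss parameters.

    Targets are standardized with training-set statistics (the regression
    head learns in unit-variance space; predictions are mapped back to
    mmHg), so the fixed learning rate behaves identically across phases with
    very different pressure ranges.  Loss curves are reported in mmHg^2.
    """
    if train_ds.feature_names != test_ds.feature_names:
        raise TrainingError("train/test feature schema mismatch")
    if len(train_ds) == 0 or len(test_ds) == 0:
        raise TrainingError("empty training or test dataset")
    y_center = float(np.mean(train_ds.y))
    y_scale = float(np.std(train_ds.y))
    if y_scale == 0:
        y_scale = 1.0
    ytr = (train_ds.y - y_center) / y_scale
    yte = (test_ds.y - y_center) / y_scale
    net = SequenceRegressor(
        in_dim=train_ds.X.shape[2],
        bilstm_units=cfg.scaled_bilstm_units,
        lstm_units=cfg.scaled_lstm_units,
        seed=cfg.seed,
    )
    opt = Adam(net.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    best_state, best_loss, best_epoch = net.get_state(), np.inf, -1
    rows = []
    n = len(train_ds)
    for epoch in range(cfg.scaled_epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, cfg.batch_size):
            b = order[s : s + cfg.batch_size]
            losses.append(net.train_batch(train_ds.X[b], ytr[b], opt))
        test_pred = net.predict(test_ds.X)
        test_loss = float(np.mean((test_pred - yte) ** 2))
        rows.append({"epoch": epoch,
                     "train_mse": float(np.mean(losses)) * y_scale**2,
                     "test_mse": test_loss * y_scale**2})
        if test_loss < best_loss:
            best_loss, best_epoch = test_loss, epoch
            best_state = net.get_state()
    net.set_state(best_state)
    logger.info("training done: best test MSE %.4f mmHg^2 at epoch %d",
                best_loss * y_scale**2, best_epoch)
    return TrainedModel(net, cfg, list(train_ds.feature_names),
                        pd.DataFrame(rows), best_epoch, y_center, y_scale)


def predict(model: TrainedModel, ds: SequenceDataset) -> np.ndarray:
    """Per-window BP estimates (mmHg), order-preserving."""
    if len(ds) == 0:
        return np.empty(0)
    if ds.feature_names != model.feature_names:
        raise TrainingError("dataset schema does not match the trained model")
    return model.net.predict(ds.X) * model.y_scale + model.y_center


def phase_mean_baseline(train_ds: SequenceDataset) -> float:
    """Constant predictor: mean training target (the no-information baseline)."""
    if len(train_ds) == 0:
        raise TrainingError("empty training dataset")
    return float(np.mean(train_ds.y))
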