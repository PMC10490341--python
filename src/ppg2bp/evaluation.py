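"""Error metrics, Bland-Altman agreement, the ISO accuracy criterion, and
physiological utilities.

Per phase and target the report carries MAE, signed mean error (ME), RMSE,
the sample SD of the errors, and the variance-explained score
R = 1 - MSE_model / MSE_standard (a coefficient-of-determination-style score,
not a Pearson correlation; named ``r_score``).  The accuracy verdict follows
the automated-sphygmomanometer requirement |ME| <= 5 mmHg and SD <= 8 mmHg
(bounds inclusive).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass

import numpy as np

from .errors import DomainError
from .quality import rejection_rate

logger = logging.getLogger(__name__)


@dataclass
class ErrorReport:
    mae: float
    me: float
    rmse: float
    sd: float
    r_score: float
    n: int
    phase: str | None = None
    target: str | None = None


@dataclass
class BlandAltman:
    mean_diff: float
    loa_low: float
    loa_high: float
    within_fraction: float
    n: int


def error_report(
    pred: np.ndarray, truth: np.ndarray,
    phase: str | None = None, target: str | None = None,
) -> ErrorReport:
    """MAE / ME / RMSE / error-SD / variance-explained score.

    ``r_score`` is NaN (with a warning) when the truth is constant.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise DomainError(f"length mismatch: {pred.shape} vs {truth.shape}")
    if pred.size < 2:
        raise DomainError("need at least 2 samples")
    err = pred - truth
    mse_std = float(np.mean((truth - truth.mean()) ** 2))
    if mse_std == 0:
        warnings.warn("constant ground truth: r_score undefined", stacklevel=2)
        r = float("nan")
    else:
        r = 1.0 - float(np.mean(err**2)) / mse_std
    return ErrorReport(
        mae=float(np.mean(np.abs(err))),
        me=float(np.mean(err)),
        rmse=float(np.sqrt(np.mean(err**2))),
        sd=float(np.std(err, ddof=1)),
        r_score=r,
        n=int(pred.size),
        phase=phase,
        target=target,
    )


def bland_altman(ref: np.ndarray, est: np.ndarray) -> BlandAltman:
    """Mean difference and 95% limits of agreement (mean +/- 1.96 sample SD)."""
    ref = np.asarray(ref, dtype=float)
    est = np.asarray(est, dtype=float)
    if ref.shape != est.shape:
        raise DomainError("length mismatch")
    if ref.size < 2:
        raise DomainError("need at least 2 pairs")
    d = est - ref
    m = float(d.mean())
    s = float(np.std(d, ddof=1))
    lo, hi = m - 1.96 * s, m + 1.96 * s
    within = float(np.mean((d >= lo) & (d <= hi)))
    return BlandAltman(m, lo, hi, within, int(d.size))


def iso_check(me: float, sd: float) -> bool:
    """Accuracy verdict: |mean error| <= 5 mmHg and error SD <= 8 mmHg."""
    if sd < 0:
        raise DomainError("sd must be non-negative")
    return abs(me) <= 5.0 and sd <= 8.0


@dataclass
class VesselParams:
    """Arterial geometry for the elasticity estimate: end-diastolic radius
    r0 (mm), wall thickness h0 (mm), pulse pressure dp (mmHg), per-cycle
    thickness variation dh (mm)."""

    r0: float
    h0: float
    dp: float
    dh: float

    def __post_init__(self) -> None:
        if min(self.r0, self.h0, self.dp) <= 0 or self.dh < 0:
            raise DomainError("vessel parameters must be positive")
        if self.dh >= self.h0:
            raise DomainError("dh must be smaller than h0")


def elasticity(p: VesselParams) -> float:
    """Arterial wall elasticity E = (3/8)(1 + 2 r0/h0) dp / (dh/h0), mmHg.

    Assumes an incompressible, isotropic wall with no axial strain; lower E
    during exercise explains the attenuated reflected (second) PPG peak.
    """
    if p.dh == 0:
        raise DomainError("dh = 0: elasticity undefined")
    return (3.0 / 8.0) * (1.0 + 2.0 * p.r0 / p.h0) * p.dp / (p.dh / p.h0)


def phase_report(
    results: dict,
    annotations=None,
) -> dict:
    """Machine-readable per-phase report.

    ``results`` maps (phase, target) -> (pred, truth) arrays; ``annotations``
    is the beat-annotation table (for the rejection summary).  Phases without
    a trained model yield a partial report with a warning.
    """
    report: dict = {"errors": {}, "rejection": {}}
    for (phase, target), payload in results.items():
        key = f"{phase}/{target}"
        if payload is None:
            logger.warning("no model/predictions for %s; partial report", key)
            report["errors"][key] = None
            continue
        pred, truth = payload
        if len(pred) < 2:
            logger.warning("fewer than 2 evaluation pairs for %s; partial "
                           "report", key)
            report["errors"][key] = None
            continue
        er = error_report(pred, truth, phase=phase, target=target)
        ba = bland_altman(truth, pred)
        report["errors"][key] = {
            **asdict(er),
            "bland_altman": asdict(ba),
            "iso_pass": iso_check(er.me, er.sd),
        }
    if annotations is not None and len(annotations):
        for phase, grp in annotations.groupby("phase", sort=False):
            before = int(len(grp))
            after = int((grp["verdict"] == "accepted").sum())
            report["rejection"][phase] = {
                "before": before,
                "after": after,
                "rate_pct": rejection_rate(before, after),
            }
    return report
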