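"""Model comparison metrics, Bland-Altman agreement and diagnostic accuracy."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateTarget, LengthMismatch, MissingClass


@dataclass(frozen=True)
class MetricsReport:
    """RMSE / MAE / R-squared over n paired samples."""

    rmse: float
    mae: float
    r2: float
    n: int


@dataclass(frozen=True)
class BlandAltmanReport:
    """Bias and 1.96-sd limits of agreement of paired differences (a - b)."""

    bias: float
    loa_low: float
    loa_high: float
    sd: float
    n: int


@dataclass(frozen=True)
class DiagnosticReport:
    """One-vs-rest diagnostic metrics with percentile-bootstrap CIs."""

    positive_class: str
    sensitivity: float
    specificity: float
    auc: float
    f1: float
    n: int
    ci: dict = field(default_factory=dict)  # metric -> (low, high)


def regression_metrics(y: np.ndarray, yhat: np.ndarray) -> MetricsReport:
    """RMSE, MAE and R² = 1 - SSres/SStot for paired series."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise LengthMismatch(f"lengths differ: {y.shape} vs {yhat.shape}")
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    resid = y - yhat
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateTarget("constant observed series: R² undefined")
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return MetricsReport(rmse, mae, r2, y.size)


def bland_altman(a: np.ndarray, b: np.ndarray) -> BlandAltmanReport:
    """Agreement of paired measurements; differences d = a - b.

    Sign convention: ``a`` is the model-converted value, ``b`` the
    measured original, so positive bias means over-prediction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise LengthMismatch(f"lengths differ: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanReport(bias, bias - 1.96 * sd, bias + 1.96 * sd, sd, d.size)


def _binary_counts(truth: np.ndarray, pred: np.ndarray):
    tp = int(np.sum(truth & pred))
    tn = int(np.sum(~truth & ~pred))
    fp = int(np.sum(~truth & pred))
    fn = int(np.sum(truth & ~pred))
    return tp, tn, fp, fn


def _point_metrics(truth: np.ndarray, pred_bin: np.ndarray,
                   scores: np.ndarray | None) -> dict[str, float]:
    tp, tn, fp, fn = _binary_counts(truth, pred_bin)
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
    if scores is not None and len(np.unique(truth)) == 2:
        from sklearn.metrics import roc_auc_score

        auc = float(roc_auc_score(truth.astype(int), scores))
    else:
        # hard labels: trapezoid through (0,0), (1-spec, sens), (1,1)
        auc = (sens + spec) / 2.0
    return {"sensitivity": sens, "specificity": spec, "auc": auc, "f1": f1}


def diagnostic_metrics(
    truth,
    predicted,
    positive_class,
    scores: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    subjects=None,
) -> DiagnosticReport:
    """One-vs-rest diagnostic performance for one diagnosis class.

    ``predicted`` holds hard labels; pass per-record ``scores`` for a
    rank-based AUC instead of the single-threshold trapezoid.  Confidence
    intervals are percentile bootstrap over subjects (``subjects`` groups
    records; default: each record is its own subject).
    """
    truth = np.asarray([getattr(t, "value", t) for t in truth])
    predicted = np.asarray([getattr(p, "value", p) for p in predicted])
    if truth.shape != predicted.shape:
        raise LengthMismatch("truth and predicted lengths differ")
    pos = getattr(positive_class, "value", positive_class)
    t_bin = truth == pos
    if not t_bin.any():
        raise MissingClass(f"positive class {pos!r} absent from truth")
    p_bin = predicted == pos
    point = _point_metrics(t_bin, p_bin, scores)

    subjects = np.asarray(subjects if subjects is not None else np.arange(truth.size))
    uniq = np.unique(subjects)
    rng = np.random.default_rng(seed)
    boot: dict[str, list[float]] = {m: [] for m in point}
    for _ in range(n_boot):
        take = rng.choice(uniq, size=uniq.size, replace=True)
        idx = np.concatenate([np.flatnonzero(subjects == s) for s in take])
        tb, pb = t_bin[idx], p_bin[idx]
        if not tb.any() or tb.all():
            continue
        sc = scores[idx] if scores is not None else None
        for m, v in _point_metrics(tb, pb, sc).items():
            if np.isfinite(v):
                boot[m].append(v)
    ci = {m: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
          if v else (float("nan"), float("nan"))
          for m, v in boot.items()}
    return DiagnosticReport(
        positive_class=str(pos), sensitivity=point["sensitivity"],
        specificity=point["specificity"], auc=point["auc"], f1=point["f1"],
        n=truth.size, ci=ci)
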