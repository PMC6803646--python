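"""Single-marker diagnostic evaluation.

Each candidate probe's normalized expression is used as the sole feature of
a univariate logistic regression separating cancer from control. Two
complementary evaluations are produced, mirroring common small-cohort
biomarker practice:

* **Repeated-split**: the cohort is split 2:1 into training and validation
  (stratified per class, training size round(2n/3) per class), the model is
  fitted on training and AUC / accuracy / sensitivity / specificity are
  measured on validation; the split is repeated (default 500 times) and
  each metric is summarized by its mean and the 95% normal-theory
  confidence interval of the mean.
* **Whole-cohort**: the model is fitted on all samples and resubstitution
  metrics are reported, with an exact (Clopper-Pearson) binomial 95%
  confidence interval on the accuracy.

Logistic fitting is maximum likelihood by Newton/IRLS. With strongly
separating markers on 34 samples, perfect separation is common: it is
detected (diverging slope or fitted probabilities at 0/1) and flagged, and
the coefficients from the last stable iteration are returned — score
*orderings*, hence AUC and thresholded predictions, are unaffected by the
unbounded rescaling that separation induces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = ["LogisticFit", "MetricSet", "MarkerEvaluation", "ClassifierError",
           "fit_logistic", "predict_labels", "predict_proba", "compute_auc",
           "confusion_metrics", "repeated_split_eval", "whole_cohort_eval",
           "clopper_pearson", "evaluate_marker", "rank_markers"]

_MAX_ITER = 50
_TOL = 1e-8
_SEPARATION_SLOPE = 15.0   # |beta1 * sd(x)| beyond this flags separation
_SEPARATION_PROB = 1e-10


class ClassifierError(ValueError):
    pass


@dataclass(frozen=True)
class LogisticFit:
    beta0: float
    beta1: float
    converged: bool
    separated: bool
    n_iter: int


@dataclass(frozen=True)
class MetricSet:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float


@dataclass(frozen=True)
class MarkerEvaluation:
    probe_id: str
    split_summary: dict[str, tuple[float, float, float]]  # metric -> (mean, lo, hi)
    whole_cohort: MetricSet
    accuracy_ci: tuple[float, float]
    n_repeats: int
    train_fraction: float = 2.0 / 3.0
    fit: LogisticFit | None = field(default=None, compare=False)


def _validate_xy(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ClassifierError("x and y must be 1-d arrays of equal length")
    if not np.all(np.isfinite(x)):
        raise ClassifierError("feature contains non-finite values")
    classes = np.unique(y)
    if set(classes) - {0, 1} or len(classes) < 2:
        raise ClassifierError("y must contain both classes, coded 0/1")
    return x, y.astype(float)


def fit_logistic(x, y) -> LogisticFit:
    """Univariate logistic MLE (intercept + slope) by Newton iterations.

    Converges when the largest coefficient change drops below 1e-8 (max 50
    iterations). Separation is declared when |beta1|*sd(x) exceeds 15 or a
    working probability reaches 0/1 to within 1e-10; the last stable
    coefficients are then returned with ``separated=True``.
    """
    x, y = _validate_xy(x, y)
    sd_x = float(np.std(x))
    if sd_x == 0:
        raise ClassifierError("constant feature")
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    last_stable = beta.copy()
    for it in range(1, _MAX_ITER + 1):
        mu = expit(X @ beta)
        if np.any(mu < _SEPARATION_PROB) or np.any(mu > 1 - _SEPARATION_PROB) \
                or abs(beta[1]) * sd_x > _SEPARATION_SLOPE:
            return LogisticFit(float(beta[0]), float(beta[1]),
                               converged=False, separated=True, n_iter=it)
        last_stable = beta.copy()
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        XtWX = X.T @ (X * w[:, None])
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError:
            return LogisticFit(float(last_stable[0]), float(last_stable[1]),
                               converged=False, separated=True, n_iter=it)
        beta = beta + step
        if np.max(np.abs(step)) < _TOL:
            sep = abs(beta[1]) * sd_x > _SEPARATION_SLOPE
            return LogisticFit(float(beta[0]), float(beta[1]),
                               converged=True, separated=bool(sep), n_iter=it)
    return LogisticFit(float(beta[0]), float(beta[1]),
                       converged=False, separated=False, n_iter=_MAX_ITER)


def predict_proba(fit: LogisticFit, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return expit(fit.beta0 + fit.beta1 * x)


def predict_labels(fit: LogisticFit, x, cutoff: float = 0.5) -> np.ndarray:
    """Predicted cancer iff fitted probability >= cutoff (ties positive)."""
    return (predict_proba(fit, x) >= cutoff).astype(int)


def compute_auc(scores, y) -> float:
    """Mann-Whitney AUC with the half-tie convention.

    Equals the trapezoidal area under the empirical ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ClassifierError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def confusion_metrics(y_true, y_pred, scores=None) -> MetricSet:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    n = tp + fp + tn + fn
    auc = compute_auc(scores, y_true) if scores is not None else np.nan
    return MetricSet(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / n,
        sensitivity=tp / (tp + fn) if tp + fn else np.nan,
        specificity=tn / (tn + fp) if tn + fp else np.nan,
        auc=auc,
    )


def clopper_pearson(successes: int, n: int,
                    alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval via Beta quantiles."""
    if not (0 <= successes <= n) or n < 1:
        raise ClassifierError(f"invalid counts: {successes}/{n}")
    x = successes
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


def _stratified_split(y: np.ndarray, train_fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for cls in (0, 1):
        members = np.flatnonzero(y == cls)
        n_train = int(round(train_fraction * len(members)))
        perm = rng.permutation(members)
        train_idx.append(perm[:n_train])
        val_idx.append(perm[n_train:])
    return np.concatenate(train_idx), np.concatenate(val_idx)


def repeated_split_eval(x, y, n_repeats: int = 500,
                        train_fraction: float = 2.0 / 3.0,
                        seed: int = 0, cutoff: float = 0.5,
                        ) -> dict[str, tuple[float, float, float]]:
    """Stratified repeated 2:1 split evaluation.

    Returns, per metric (auc, accuracy, sensitivity, specificity), the mean
    over repeats and the 95% confidence interval of the mean
    (mean +/- 1.96 sd/sqrt(n_repeats)). Deterministic given *seed*.
    """
    x, y = _validate_xy(x, y)
    for cls in (0, 1):
        if (y == cls).sum() < 3:
            raise ClassifierError(
                "each class needs >= 3 samples for a 2:1 stratified split")
    rng = np.random.default_rng(seed)
    records = {m: np.empty(n_repeats)
               for m in ("auc", "accuracy", "sensitivity", "specificity")}
    for r in range(n_repeats):
        tr, va = _stratified_split(y, train_fraction, rng)
        fit = fit_logistic(x[tr], y[tr])
        proba = predict_proba(fit, x[va])
        pred = (proba >= cutoff).astype(int)
        m = confusion_metrics(y[va], pred, scores=proba)
        records["auc"][r] = m.auc
        records["accuracy"][r] = m.accuracy
        records["sensitivity"][r] = m.sensitivity
        records["specificity"][r] = m.specificity
    out = {}
    for name, vals in records.items():
        mean = float(vals.mean())
        half = 1.96 * float(vals.std(ddof=1)) / np.sqrt(n_repeats)
        out[name] = (mean, mean - half, mean + half)
    return out


def whole_cohort_eval(x, y, alpha: float = 0.05, cutoff: float = 0.5,
                      ) -> tuple[MetricSet, tuple[float, float], LogisticFit]:
    """Fit on all samples; resubstitution metrics plus exact accuracy CI."""
    x, y = _validate_xy(x, y)
    fit = fit_logistic(x, y)
    proba = predict_proba(fit, x)
    pred = (proba >= cutoff).astype(int)
    metrics = confusion_metrics(y, pred, scores=proba)
    ci = clopper_pearson(metrics.tp + metrics.tn, len(y), alpha)
    return metrics, ci, fit


def evaluate_marker(probe_id: str, x, y, n_repeats: int = 500,
                    seed: int = 0) -> MarkerEvaluation:
    """Run both evaluations for one candidate marker."""
    summary = repeated_split_eval(x, y, n_repeats=n_repeats, seed=seed)
    metrics, ci, fit = whole_cohort_eval(x, y)
    return MarkerEvaluation(probe_id=probe_id, split_summary=summary,
                            whole_cohort=metrics, accuracy_ci=ci,
                            n_repeats=n_repeats, fit=fit)


def rank_markers(evaluations: list[MarkerEvaluation]) -> list[MarkerEvaluation]:
    """Sort by whole-cohort accuracy desc, then AUC desc, then probe ID."""
    if not evaluations:
        raise ClassifierError("no marker evaluations to rank")
    return sorted(evaluations,
                  key=lambda e: (-e.whole_cohort.accuracy,
                                 -e.whole_cohort.auc, e.probe_id))


def evaluations_to_frame(evaluations: list[MarkerEvaluation]) -> pd.DataFrame:
    """Flatten evaluations into a report table (one row per marker)."""
    rows = []
    for ev in evaluations:
        row = {"probe": ev.probe_id}
        for metric, (mean, lo, hi) in ev.split_summary.items():
            row[f"split_{metric}"] = mean
            row[f"split_{metric}_ci_low"] = lo
            row[f"split_{metric}_ci_high"] = hi
        wc = ev.whole_cohort
        row.update({
            "cohort_auc": wc.auc, "cohort_accuracy": wc.accuracy,
            "cohort_accuracy_ci_low": ev.accuracy_ci[0],
            "cohort_accuracy_ci_high": ev.accuracy_ci[1],
            "cohort_sensitivity": wc.sensitivity,
            "cohort_specificity": wc.specificity,
            "tp": wc.tp, "fp": wc.fp, "tn": wc.tn, "fn": wc.fn,
            "n_repeats": ev.n_repeats,
        })
        rows.append(row)
    return pd.DataFrame(rows)
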