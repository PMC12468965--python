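"""Clinical-style evaluation: macro metrics, grouped splits, curves, CIs.

Metrics follow the standard confusion-matrix definitions

    se  = tp / (fn + tp)            (sensitivity / recall)
    sp  = tn / (fp + tn)            (specificity)
    pre = tp / (fp + tp)            (precision)
    f   = 2 tp / (2 tp + fn + fp)   (F-score)
    acc = (tn + tp) / (tn + tp + fn + fp)

macro-averaged as the unweighted mean over classes, each class taken in
turn as positive.  Splits are *patient-grouped*: all slices of one
patient stay on one side of the holdout split and inside one
cross-validation fold, stratified by the patient's class label, so no
patient leaks across evaluation subsets.  Curve machinery covers ROC
(trapezoidal AUC), precision-recall, equal-width calibration bins,
decision-curve net benefit, and seeded percentile-bootstrap confidence
intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import average_precision_score, precision_recall_curve
from sklearn.metrics import roc_curve

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self):
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other):
        return ConfusionMatrix(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass
class SplitPlan:
    mode: str                      # holdout | kfold
    seed: int
    train_ids: list = field(default_factory=list)
    test_ids: list = field(default_factory=list)
    folds: list = field(default_factory=list)   # [(train_ids, test_ids)]


@dataclass
class MetricReport:
    per_class: dict = field(default_factory=dict)
    macro: dict = field(default_factory=dict)
    auc: float | None = None
    average_precision: float | None = None
    curves: dict = field(default_factory=dict)
    confidence_intervals: dict = field(default_factory=dict)
    confusion: dict = field(default_factory=dict)
    per_fold: list = field(default_factory=list)

    def to_dict(self):
        def clean(o):
            if isinstance(o, pd.DataFrame):
                return clean(o.to_dict(orient="list"))
            if isinstance(o, dict):
                return {str(k): clean(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [clean(v) for v in o]
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                o = o.item()
            if isinstance(o, float) and np.isnan(o):
                return None  # keep the JSON strictly valid
            if isinstance(o, (ConfusionMatrix, MetricReport)):
                return clean(vars(o))
            return o
        return clean(vars(self))


def confusion(y_true, y_pred, positive_label) -> ConfusionMatrix:
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label lists must have equal length")
    cm = ConfusionMatrix()
    for t, p in zip(y_true, y_pred):
        if t == positive_label:
            if p == positive_label:
                cm.tp += 1
            else:
                cm.fn += 1
        else:
            if p == positive_label:
                cm.fp += 1
            else:
                cm.tn += 1
    return cm


def _safe_div(num, den, name):
    if den == 0:
        logger.warning("zero denominator in %s; reporting 0", name)
        return 0.0
    return num / den


def macro_metrics(cm_per_class) -> MetricReport:
    """Per-class metrics and their unweighted (macro) mean.

    ``cm_per_class`` maps class label -> :class:`ConfusionMatrix` with
    that class as positive (a sequence is also accepted).
    """
    if not cm_per_class:
        raise ValueError("need at least one confusion matrix")
    if not isinstance(cm_per_class, dict):
        cm_per_class = {i: cm for i, cm in enumerate(cm_per_class)}
    report = MetricReport()
    for label, cm in cm_per_class.items():
        vals = {
            "se": _safe_div(cm.tp, cm.fn + cm.tp, f"se[{label}]"),
            "sp": _safe_div(cm.tn, cm.fp + cm.tn, f"sp[{label}]"),
            "pre": _safe_div(cm.tp, cm.fp + cm.tp, f"pre[{label}]"),
            "f_scr": _safe_div(2 * cm.tp, 2 * cm.tp + cm.fn + cm.fp,
                               f"f_scr[{label}]"),
            "acc": _safe_div(cm.tn + cm.tp, cm.total, f"acc[{label}]"),
        }
        report.per_class[label] = vals
        report.confusion[label] = cm
    report.macro = {m: float(np.mean([report.per_class[l][m]
                                      for l in report.per_class]))
                    for m in ("se", "sp", "pre", "f_scr", "acc")}
    return report


def _patient_table(cohort):
    """patient_id -> label mapping from CohortImage objects or a DataFrame."""
    if isinstance(cohort, pd.DataFrame):
        df = cohort[["image_id", "patient_id", "label"]]
    else:
        df = pd.DataFrame([(im.image_id, im.patient_id, im.label)
                           for im in cohort],
                          columns=["image_id", "patient_id", "label"])
    lab = df.groupby("patient_id")["label"].nunique()
    if (lab > 1).any():
        bad = lab[lab > 1].index.tolist()
        raise ValueError(f"patients with multiple labels: {bad[:5]}")
    return df


def grouped_split(cohort, mode="holdout", ratio_or_k=0.7,
                  seed=42) -> SplitPlan:
    """Patient-grouped, label-stratified split of image ids.

    holdout: per class, round(ratio * n_patients) patients go to train;
    kfold: per class, patients are shuffled and dealt into k folds.
    Deterministic given ``seed``; image ids follow their patient.
    """
    df = _patient_table(cohort)
    rng = np.random.default_rng(seed)
    by_patient = df.groupby("patient_id")["image_id"].apply(list)
    patients = df.drop_duplicates("patient_id")[["patient_id", "label"]]
    plan = SplitPlan(mode=mode, seed=seed)

    if mode == "holdout":
        ratio = float(ratio_or_k)
        if not 0 < ratio < 1:
            raise ValueError("holdout ratio must lie in (0, 1)")
        for label, grp in patients.groupby("label", sort=True):
            pids = sorted(grp["patient_id"])
            rng.shuffle(pids)
            n_train = int(round(ratio * len(pids)))
            n_train = min(max(n_train, 1), len(pids) - 1)
            for pid in pids[:n_train]:
                plan.train_ids.extend(by_patient[pid])
            for pid in pids[n_train:]:
                plan.test_ids.extend(by_patient[pid])
        return plan

    if mode == "kfold":
        k = int(ratio_or_k)
        fold_pids = [[] for _ in range(k)]
        for label, grp in patients.groupby("label", sort=True):
            pids = sorted(grp["patient_id"])
            if len(pids) < k:
                raise ValueError(
                    f"class {label!r} has {len(pids)} patients, fewer than "
                    f"k={k} folds")
            rng.shuffle(pids)
            for i, pid in enumerate(pids):
                fold_pids[i % k].append(pid)
        all_pids = set(patients["patient_id"])
        for f in range(k):
            test_p = set(fold_pids[f])
            train_p = all_pids - test_p
            train_ids = [i for p in sorted(train_p) for i in by_patient[p]]
            test_ids = [i for p in sorted(test_p) for i in by_patient[p]]
            plan.folds.append((train_ids, test_ids))
        return plan

    raise ValueError(f"unknown split mode {mode!r}")


def check_no_leakage(plan: SplitPlan, cohort):
    """Assert patient ids never straddle train/test or folds."""
    df = _patient_table(cohort)
    pat = dict(zip(df["image_id"], df["patient_id"]))
    pairs = [(plan.train_ids, plan.test_ids)] if plan.mode == "holdout" \
        else plan.folds
    for train_ids, test_ids in pairs:
        overlap = ({pat[i] for i in train_ids}
                   & {pat[i] for i in test_ids})
        if overlap:
            raise AssertionError(f"patient leakage: {sorted(overlap)[:5]}")


def roc_pr_curves(y_true, scores, positive_label=None):
    """ROC (trapezoidal AUC) and precision-recall curves.

    ``y_true`` may be 0/1 or labels with ``positive_label`` given.
    """
    y_true = np.asarray(y_true)
    if positive_label is not None:
        y = (y_true == positive_label).astype(int)
    else:
        y = y_true.astype(int)
    if len(set(y.tolist())) < 2:
        raise ValueError("ROC/PR need both classes present in y_true")
    scores = np.asarray(scores, dtype=float)
    fpr, tpr, roc_th = roc_curve(y, scores)
    prec, rec, pr_th = precision_recall_curve(y, scores)
    return {
        "fpr": fpr, "tpr": tpr, "roc_thresholds": roc_th,
        "auc": float(sk_auc(fpr, tpr)),
        "precision": prec, "recall": rec, "pr_thresholds": pr_th,
        "average_precision": float(average_precision_score(y, scores)),
    }


def calibration_bins(y_true, probs, n_bins=10) -> pd.DataFrame:
    """Equal-width reliability table: per bin, count, mean predicted
    probability and observed positive frequency; empty bins are flagged
    with count 0 and NaN means."""
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        rows.append({
            "bin_lo": edges[b], "bin_hi": edges[b + 1], "count": n,
            "mean_predicted": float(p[sel].mean()) if n else np.nan,
            "observed_frequency": float(y[sel].mean()) if n else np.nan,
            "empty": n == 0,
        })
    return pd.DataFrame(rows)


def decision_curve(y_true, probs, thresholds) -> pd.DataFrame:
    """Net benefit of the model vs treat-all and treat-none strategies.

    NB(pt) = TP/N - (FP/N) * pt/(1-pt) with predictions prob >= pt;
    treat-all: prevalence - (1-prevalence) * pt/(1-pt); treat-none: 0.
    Thresholds at 0 or 1 are excluded.
    """
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(probs, dtype=float)
    n = len(y)
    prevalence = y.mean()
    rows = []
    for pt in thresholds:
        if not 0.0 < pt < 1.0:
            continue
        pred = p >= pt
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        odds = pt / (1.0 - pt)
        rows.append({
            "threshold": pt,
            "net_benefit_model": tp / n - (fp / n) * odds,
            "net_benefit_treat_all": prevalence - (1 - prevalence) * odds,
            "net_benefit_treat_none": 0.0,
        })
    return pd.DataFrame(rows)


def bootstrap_ci(metric_fn, y_true, y_out, b=1000, level=0.95, seed=42):
    """Seeded percentile bootstrap over evaluation cases.

    ``metric_fn(y_true_resampled, y_out_resampled)`` is evaluated on B
    resamples; undefined resamples (exception or NaN) are redrawn and
    logged.  Returns (lo, hi) at the requested level.
    """
    if b < 100:
        raise ValueError("bootstrap needs B >= 100")
    y_true = np.asarray(y_true)
    y_out = np.asarray(y_out)
    rng = np.random.default_rng(seed)
    n = len(y_true)
    stats = []
    redraws = 0
    while len(stats) < b:
        idx = rng.integers(0, n, size=n)
        try:
            v = metric_fn(y_true[idx], y_out[idx])
        except Exception:  # noqa: BLE001 - contract: redraw and log
            v = np.nan
        if np.isnan(v):
            redraws += 1
            if redraws > 10 * b:
                raise RuntimeError("bootstrap metric undefined on nearly "
                                   "all resamples")
            continue
        stats.append(float(v))
    if redraws:
        logger.warning("bootstrap redrew %d undefined resamples", redraws)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def evaluate_predictions(y_true, y_pred, scores=None, probs=None,
                         positive_label=None, bootstrap=0,
                         seed=42) -> MetricReport:
    """Assemble a full MetricReport for one evaluation run.

    ``scores`` feed the ROC/PR curves; ``probs`` (probability of the
    positive class) feed calibration and decision curves.  With
    ``bootstrap`` > 0, percentile CIs for accuracy (and AUC when scores
    are given) are attached.
    """
    y_true, y_pred = list(y_true), list(y_pred)
    classes = sorted(set(y_true) | set(y_pred))
    if positive_label is None:
        positive_label = classes[-1]
    cms = {c: confusion(y_true, y_pred, c) for c in classes}
    report = macro_metrics(cms)
    y01 = np.array([1 if t == positive_label else 0 for t in y_true])
    if scores is not None and len(set(y01.tolist())) == 2:
        curves = roc_pr_curves(y01, scores)
        report.auc = curves["auc"]
        report.average_precision = curves["average_precision"]
        report.curves["roc"] = {k: curves[k] for k in ("fpr", "tpr")}
        report.curves["pr"] = {k: curves[k] for k in ("precision", "recall")}
    if probs is not None:
        report.curves["calibration"] = calibration_bins(y01, probs)
        report.curves["decision"] = decision_curve(
            y01, probs, np.linspace(0.05, 0.95, 19))
    if bootstrap:
        yp = np.asarray(y_pred)
        report.confidence_intervals["acc"] = bootstrap_ci(
            lambda t, p: float(np.mean(t == p)), np.asarray(y_true), yp,
            b=bootstrap, seed=seed)
        if scores is not None:
            def _auc(t, s):
                if len(set(t.tolist())) < 2:
                    return np.nan
                fpr, tpr, _ = roc_curve(t, s)
                return sk_auc(fpr, tpr)
            report.confidence_intervals["auc"] = bootstrap_ci(
                _auc, y01, np.asarray(scores, dtype=float), b=bootstrap,
                seed=seed + 1)
    return report
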