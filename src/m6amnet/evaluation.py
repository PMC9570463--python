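"""Threshold metrics, threshold-free curves, repeated stratified k-fold CV
and chromosome-level hold-out evaluation.

Conventions (documented because degenerate inputs are common in small
hold-out groups): predictions use ``p >= threshold``; MCC is 0 whenever
its denominator vanishes; AUROC/AUPR are ``None`` when the evaluated set
contains a single class.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .dataset import BenchmarkDataset, SplitPlan
from .encoding import DEFAULT_SCHEME, FeatureScheme, encode_batch


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class MetricsReport:
    sn: float
    sp: float
    acc: float
    mcc: float
    auroc: float | None = None
    aupr: float | None = None
    sd: dict = field(default_factory=dict)  # metric name -> SD over repeats

    def to_dict(self) -> dict:
        out = {"Sn": self.sn, "Sp": self.sp, "ACC": self.acc, "MCC": self.mcc,
               "AUROC": self.auroc, "AUPR": self.aupr}
        for k, v in self.sd.items():
            out[f"{k}_SD"] = v
        return out


def confusion_at_threshold(y_true, p_positive, threshold: float = 0.5) -> ConfusionCounts:
    """Tally the confusion table with positives predicted at ``p >= threshold``."""
    y = np.asarray(y_true)
    p = np.asarray(p_positive, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} scores")
    if y.size == 0:
        raise ValueError("empty input")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    pred = p >= threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        fn=int((~pred & pos).sum()),
        tn=int((~pred & ~pos).sum()),
        fp=int((pred & ~pos).sum()),
    )


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Sensitivity, specificity, accuracy and Matthews correlation.

    Degenerate denominators yield 0 (for MCC) or 0.0 rates, by convention.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    acc = (c.tp + c.tn) / c.total
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = ((c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)) if denom else 0.0
    return MetricsReport(sn=sn, sp=sp, acc=acc, mcc=mcc)


def roc_auc(y_true, p_positive) -> float:
    """AUROC via the Mann-Whitney rank statistic (ties mid-ranked)."""
    y = np.asarray(y_true)
    p = np.asarray(p_positive, dtype=float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC undefined: only one class present")
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def pr_auc(y_true, p_positive) -> float:
    """AUPR as average precision (step-wise sum over unique thresholds)."""
    y = np.asarray(y_true)
    p = np.asarray(p_positive, dtype=float)
    n1 = int((y == 1).sum())
    if n1 == 0 or n1 == y.size:
        raise ValueError("AUPR undefined: only one class present")
    order = np.argsort(-p, kind="mergesort")
    y_sorted = y[order]
    p_sorted = p[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # evaluate only at the last index of each tied score block
    last_of_block = np.r_[p_sorted[1:] != p_sorted[:-1], True]
    tps = tps[last_of_block]
    fps = fps[last_of_block]
    precision = tps / (tps + fps)
    recall = tps / n1
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def full_report(y_true, p_positive, threshold: float = 0.5) -> MetricsReport:
    """Threshold metrics plus AUROC/AUPR (None if single-class)."""
    report = compute_metrics(confusion_at_threshold(y_true, p_positive, threshold))
    y = np.asarray(y_true)
    if 0 < int((y == 1).sum()) < y.size:
        report.auroc = roc_auc(y_true, p_positive)
        report.aupr = pr_auc(y_true, p_positive)
    return report


# ---------------------------------------------------------------------------
# protocols


def stratified_fold_indices(y, k: int, seed: int) -> list[np.ndarray]:
    """Disjoint exhaustive label-stratified folds (test indices per fold)."""
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(y)), y)]


def repeated_kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    recipe,
    k: int = 5,
    repeats: int = 20,
    seed: int = 0,
    pooling: str = "pooled",
    threshold: float = 0.5,
) -> MetricsReport:
    """Repeated stratified k-fold cross-validation.

    `recipe(X_train, y_train, seed)` must return an object with a
    ``predict_proba(X) -> (n, 2)`` method.  With ``pooling='pooled'``
    (default) each repeat pools held-out predictions across its folds and
    computes one metric set; ``pooling='per_fold'`` averages per-fold
    metrics instead.  The report carries the mean over repeats, with SDs
    in ``report.sd`` when ``repeats > 1``.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < k:
        raise ValueError(f"need >= {k} records per class for {k}-fold CV")
    if pooling not in ("pooled", "per_fold"):
        raise ValueError("pooling must be 'pooled' or 'per_fold'")
    per_repeat: list[MetricsReport] = []
    for rep in range(repeats):
        rep_seed = seed + rep
        folds = stratified_fold_indices(y, k, rep_seed)
        fold_reports = []
        pooled_p = np.empty(len(y))
        for fold_i, test_idx in enumerate(folds):
            train_mask = np.ones(len(y), dtype=bool)
            train_mask[test_idx] = False
            model = recipe(X[train_mask], y[train_mask], seed=rep_seed * 1000 + fold_i)
            p = np.asarray(model.predict_proba(X[test_idx]))[:, 1]
            pooled_p[test_idx] = p
            if pooling == "per_fold":
                fold_reports.append(full_report(y[test_idx], p, threshold))
        if pooling == "pooled":
            per_repeat.append(full_report(y, pooled_p, threshold))
        else:
            per_repeat.append(_average_reports(fold_reports))
    return _average_reports(per_repeat, with_sd=repeats > 1)


def _average_reports(reports: list[MetricsReport], with_sd: bool = False) -> MetricsReport:
    def stat(name):
        vals = [getattr(r, name) for r in reports]
        if any(v is None for v in vals):
            return None, None
        return float(np.mean(vals)), float(np.std(vals))

    means, sds = {}, {}
    for name in ("sn", "sp", "acc", "mcc", "auroc", "aupr"):
        means[name], sds[name] = stat(name)
    out = MetricsReport(**{k: means[k] for k in ("sn", "sp", "acc", "mcc")},
                        auroc=means["auroc"], aupr=means["aupr"])
    if with_sd:
        out.sd = {k.upper(): v for k, v in sds.items() if v is not None}
    return out


def holdout_eval(
    plans: list[SplitPlan],
    dataset: BenchmarkDataset,
    recipe,
    scheme: FeatureScheme = DEFAULT_SCHEME,
    threshold: float = 0.5,
    seed: int = 0,
) -> dict[str, MetricsReport]:
    """Train/evaluate once per split plan with an identical recipe.

    Returns {plan name: MetricsReport}; per-group training failures are
    recorded as None so remaining groups still run.
    """
    X = encode_batch(dataset.windows(), scheme)
    y = dataset.labels()
    index = {rec.record_id: i for i, rec in enumerate(dataset.records)}
    results: dict[str, MetricsReport | None] = {}
    for plan in plans:
        tr = np.array([index[rid] for rid in plan.train_ids])
        te = np.array([index[rid] for rid in plan.test_ids])
        try:
            model = recipe(X[tr], y[tr], seed=seed)
            p = np.asarray(model.predict_proba(X[te]))[:, 1]
            results[plan.name] = full_report(y[te], p, threshold)
        except Exception as exc:  # keep evaluating other groups
            results[plan.name] = None
            import logging

            logging.getLogger(__name__).warning("group %s failed: %s", plan.name, exc)
    return results


# ---------------------------------------------------------------------------
# report I/O


def write_metrics_json(reports: dict[str, MetricsReport], path) -> None:
    doc = {name: (r.to_dict() if r is not None else None) for name, r in reports.items()}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def write_metrics_tsv(reports: dict[str, MetricsReport], path) -> None:
    cols = ["Sn", "Sp", "ACC", "MCC", "AUROC", "AUPR"]
    with open(path, "w") as fh:
        fh.write("group\t" + "\t".join(cols) + "\n")
        for name, r in reports.items():
            if r is None:
                fh.write(name + "\t" + "\t".join(["NA"] * len(cols)) + "\n")
                continue
            d = r.to_dict()
            fh.write(name + "\t" + "\t".join(
                "NA" if d[c] is None else f"{d[c]:.4f}" for c in cols) + "\n")


def write_predictions_tsv(ids, y_true, p_positive, path, threshold: float = 0.5) -> None:
    with open(path, "w") as fh:
        fh.write("record_id\tlabel\tp_positive\tprediction\n")
        for rid, yt, p in zip(ids, y_true, p_positive):
            fh.write(f"{rid}\t{yt}\t{p:.6f}\t{int(p >= threshold)}\n")
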