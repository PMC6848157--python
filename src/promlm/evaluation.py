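"""Cross-validation harness, confusion-count metrics, ROC/AUC, Wilcoxon.

Metrics follow the Chou-style confusion notation: with N+ positives and N-
negatives, N+- = FP (negatives called positive) and N-+ = FN (positives
called negative),

    Sens = 1 - N-+/N+          Spec = 1 - N+-/N-
    Acc  = 1 - (N-+ + N+-)/(N+ + N-)
    MCC  = (1 - (N-+/N+ + N+-/N-)) /
           sqrt((1 + (N+- - N-+)/N+) (1 + (N-+ - N+-)/N-))

which are algebraically identical to the standard TP/TN/FP/FN closed forms.
AUC is computed as the Mann-Whitney statistic (ties counted half), which the
trapezoidal integral of the ROC curve reproduces exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .data_io import Dataset


# ---------------------------------------------------------------------------
# Fold plans
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Per-sample validation-fold assignment for k-fold CV (4:1 at k=5)."""

    n_folds: int
    assignments: np.ndarray
    seed: int
    stratified: bool

    def split(self):
        for f in range(self.n_folds):
            yield self.assignments != f, self.assignments == f


def make_folds(labels, n_folds: int = 5, seed: int = 0,
               stratified: bool = True) -> FoldPlan:
    """Deterministic (seeded) fold assignment, stratified by default."""
    if isinstance(labels, Dataset):
        labels = labels.labels()
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if stratified and counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} member(s); need >= {n_folds}")
    if len(y) < n_folds:
        raise ValueError("fewer samples than folds")
    splitter = (StratifiedKFold if stratified else KFold)(
        n_splits=n_folds, shuffle=True, random_state=seed)
    assignments = np.empty(len(y), dtype=np.int64)
    for f, (_, val) in enumerate(splitter.split(np.zeros((len(y), 1)), y)):
        assignments[val] = f
    return FoldPlan(n_folds=n_folds, assignments=assignments, seed=seed,
                    stratified=stratified)


# ---------------------------------------------------------------------------
# Confusion counts and metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.tn, self.fp, self.fn):
            if v < 0:
                raise ValueError("counts must be non-negative")

    # Chou-notation aliases
    @property
    def n_pos(self) -> int:          # N+
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:          # N-
        return self.tn + self.fp

    @property
    def pos_as_neg(self) -> int:     # N-+ = FN
        return self.fn

    @property
    def neg_as_pos(self) -> int:     # N+- = FP
        return self.fp

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if not set(np.unique(y_true)) <= {0, 1} or not set(np.unique(y_pred)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _round_half_up(x: float, dp: int) -> float:
    q = Decimal(1).scaleb(-dp)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class MetricsReport:
    """Sens/Spec/Acc as fractions, MCC, optional AUC and ROC points."""

    sens: float
    spec: float
    acc: float
    mcc: float
    auc: float | None = None
    roc_points: np.ndarray | None = None
    mcc_degenerate: bool = False

    def as_percent(self, dp: int = 2) -> dict[str, float]:
        out = {
            "Sens": _round_half_up(100 * self.sens, dp),
            "Spec": _round_half_up(100 * self.spec, dp),
            "Acc": _round_half_up(100 * self.acc, dp),
            "MCC": _round_half_up(self.mcc, dp + 1),
        }
        if self.auc is not None:
            out["AUC"] = _round_half_up(self.auc, dp + 1)
        return out


def chou_metrics(c: ConfusionCounts) -> MetricsReport:
    """Metrics evaluated in the Chou confusion notation (see module docstring)."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    np_, nn = c.n_pos, c.n_neg
    if np_ == 0 or nn == 0:
        raise ValueError("Sens/Spec need both N+ > 0 and N- > 0")
    fn, fp = c.pos_as_neg, c.neg_as_pos
    sens = 1.0 - fn / np_
    spec = 1.0 - fp / nn
    acc = 1.0 - (fn + fp) / (np_ + nn)
    num = 1.0 - (fn / np_ + fp / nn)
    den_sq = (1.0 + (fp - fn) / np_) * (1.0 + (fn - fp) / nn)
    degenerate = den_sq <= 0
    mcc = 0.0 if degenerate else num / math.sqrt(den_sq)
    return MetricsReport(sens=sens, spec=spec, acc=acc, mcc=mcc,
                         mcc_degenerate=degenerate)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(y_true, scores) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) and the Mann-Whitney AUC (ties counted half)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC/AUC require both classes present")
    ranks = rankdata(scores)
    auc = (ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(y_true, scores, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    return points, float(auc)


# ---------------------------------------------------------------------------
# One-sided Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def wilcoxon_one_sided(a, b, exact_limit: int = 25) -> float:
    """P(a > b) signed-rank test; exact tail for n <= exact_limit.

    Zero differences are dropped.  Exact p-values come from the full null
    distribution of the positive-rank sum (a convolution over the midrank-
    tied ranks, equivalent to enumerating all 2^n sign patterns); larger n
    uses the tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; test undefined")
    ranks = rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()

    if n <= exact_limit:
        r2 = np.rint(2 * ranks).astype(np.int64)   # doubled ranks are integers
        total = int(r2.sum())
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in r2:
            counts[r:] += counts[:-r] if r > 0 else counts
        obs = int(np.rint(2 * w_pos))
        return float(counts[obs:].sum() / 2.0 ** n)

    mean = n * (n + 1) / 4.0
    _, t = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((t ** 3 - t).sum()) / 48.0
    z = (w_pos - mean - 0.5) / math.sqrt(var)
    return float(norm.sf(z))


# ---------------------------------------------------------------------------
# CV harnesses
# ---------------------------------------------------------------------------

def _fold_metrics(y_va, pred, scores) -> dict:
    c = confusion(y_va, pred)
    rep = chou_metrics(c)
    _, auc = roc_auc(y_va, scores)
    return {
        "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn,
        "sens": rep.sens, "spec": rep.spec, "acc": rep.acc,
        "mcc": rep.mcc, "auc": auc,
    }


def cross_validate(estimator_factory, X, y, plan: FoldPlan,
                   standardize: bool = True) -> pd.DataFrame:
    """One CV pass on a feature matrix; estimators are refit per fold.

    Standardization statistics, when enabled, come from the training fold
    only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    rows = []
    for f, (tr, va) in enumerate(plan.split()):
        Xtr, Xva = X[tr], X[va]
        if standardize:
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            Xtr, Xva = (Xtr - mu) / sd, (Xva - mu) / sd
        est = estimator_factory()
        est.fit(Xtr, y[tr])
        pred = est.predict(Xva)
        scores = (est.decision_scores(Xva) if hasattr(est, "decision_scores")
                  else est.predict_proba(Xva)[:, 1])
        rows.append({"fold": f, **_fold_metrics(y[va], pred, scores)})
    return pd.DataFrame(rows)


def repeated_cv(pipeline_factory, dataset: Dataset, n_repeats: int = 10,
                seeds: list[int] | None = None, n_folds: int = 5,
                base_seed: int = 0) -> pd.DataFrame:
    """Repeated k-fold CV of a sequence-level pipeline.

    ``pipeline_factory(seed)`` must return an object with
    ``fit(records, y)``, ``predict(records)`` and ``decision_scores(records)``;
    anything fit inside (embeddings, feature selection, the classifier) sees
    the training fold only unless the pipeline itself was pre-fit in
    paper-mode.  Returns one row per (repeat, fold).
    """
    if seeds is None:
        seeds = [base_seed + r for r in range(n_repeats)]
    if len(seeds) != n_repeats:
        raise ValueError("need one seed per repeat")
    y = dataset.labels()
    records = dataset.records
    rows = []
    for r, seed in enumerate(seeds):
        plan = make_folds(y, n_folds=n_folds, seed=seed)
        for f, (tr, va) in enumerate(plan.split()):
            rec_tr = [records[i] for i in np.flatnonzero(tr)]
            rec_va = [records[i] for i in np.flatnonzero(va)]
            pipe = pipeline_factory(seed * 101 + f)
            pipe.fit(rec_tr, y[tr])
            pred = pipe.predict(rec_va)
            scores = pipe.decision_scores(rec_va)
            rows.append({"repeat": r, "seed": seed, "fold": f,
                         **_fold_metrics(y[va], pred, scores)})
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd of each metric over all result rows."""
    metrics = ["sens", "spec", "acc", "mcc", "auc"]
    return pd.DataFrame({
        "mean": results[metrics].mean(),
        "sd": results[metrics].std(ddof=1),
    })
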