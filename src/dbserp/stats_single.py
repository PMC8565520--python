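"""Single-feature biomarker statistics: t-tests, ROC cutoff model, 5-fold CV.

A single engineered feature is treated as a one-dimensional classifier: the
ROC curve over thresholds gives an AUC, and the Youden-optimal cutoff fitted on
a training fold classifies held-out sessions.  Metrics are reported as
mean +/- SD over stratified folds, for both the training and test sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn import metrics as skm
from sklearn.model_selection import GroupKFold, StratifiedKFold

from .core import ValidationError

METRICS = ("precision", "recall", "accuracy", "auc")


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float


def ttest_independent(a, b, welch: bool = False) -> TTestResult:
    """Two-sided independent-samples t-test (pooled variance by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n >= 2")
    res = sstats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), df=df)


@dataclass
class ROCResult:
    """ROC sweep of a single feature, oriented so that AUC >= 0.5.

    ``direction`` is +1 if larger values indicate the positive class, else -1.
    ``cutoff`` is in original feature units; a sample is classified positive
    when ``direction * value >= direction * cutoff``.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    cutoff: float
    direction: int
    positive_class: str

    def predict(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return self.direction * v >= self.direction * self.cutoff


def roc_analysis(values, labels, positive_class: str) -> ROCResult:
    """Threshold sweep with trapezoidal AUC and Youden-J cutoff.

    Orientation is chosen so the reported AUC is >= 0.5; among cutoff ties the
    lower threshold (in original units) wins.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    pos = y == positive_class
    if pos.all() or not pos.any():
        raise ValidationError("both classes must be present")
    direction = 1
    fpr, tpr, thr = skm.roc_curve(pos, v)
    auc = float(np.trapezoid(tpr, fpr))
    if auc < 0.5:
        direction = -1
        fpr, tpr, thr = skm.roc_curve(pos, -v)
        auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = j == j.max()
    # thresholds from roc_curve are in score units (= direction * value);
    # pick the lowest original-unit cutoff among ties
    cand = thr[best] * direction
    cand = cand[np.isfinite(cand)]
    if cand.size == 0:  # degenerate single-threshold sweep
        cand = np.array([v.min()])
    cutoff = float(cand.min())
    return ROCResult(
        thresholds=thr * direction,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        cutoff=cutoff,
        direction=direction,
        positive_class=str(positive_class),
    )


@dataclass
class CVReport:
    """Fold-wise classification metrics with mean +/- SD summaries."""

    folds: pd.DataFrame  # one row per fold; columns like "test_accuracy"
    fold_assignments: np.ndarray
    seed: int
    positive_class: str | None = None
    extra: dict = field(default_factory=dict)

    def mean(self) -> pd.Series:
        return self.folds.mean()

    def sd(self) -> pd.Series:
        return self.folds.std(ddof=1)

    def summary(self) -> str:
        lines = ["Cross-validated single-feature / classifier report"]
        if self.positive_class is not None:
            lines.append(f"positive class: {self.positive_class}")
        m, s = self.mean(), self.sd()
        for col in self.folds.columns:
            lines.append(f"  {col:<18s} {m[col]:.3f} (+/-{s[col]:.2f})")
        return "\n".join(lines)


def _fold_iter(y, k, seed, groups=None):
    if groups is not None:
        splitter = GroupKFold(n_splits=k)
        return splitter.split(np.zeros_like(y), y, groups)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return splitter.split(np.zeros_like(y), y)


def cv_single_feature(
    values,
    labels,
    positive_class: str,
    k: int = 5,
    seed: int = 0,
    groups=None,
) -> CVReport:
    """Stratified k-fold evaluation of the one-feature cutoff classifier.

    Per fold the ROC cutoff is fitted on the training part and applied to the
    held-out part; precision, recall, accuracy and AUC are reported for both
    sides.  If a class has fewer members than ``k`` the fold count is reduced
    (with a warning).
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    min_class = min(np.sum(y == c) for c in np.unique(y))
    if min_class < k:
        import warnings

        warnings.warn(f"reducing folds from {k} to {min_class}", stacklevel=2)
        k = int(min_class)
    if k < 2:
        raise ValidationError("need at least 2 folds")
    assign = np.full(y.size, -1)
    rows = []
    for fold, (tr, te) in enumerate(_fold_iter(y, k, seed, groups)):
        assign[te] = fold
        roc = roc_analysis(v[tr], y[tr], positive_class)
        row = {}
        for part, sel in (("train", tr), ("test", te)):
            y_true = y[sel] == positive_class
            y_pred = roc.predict(v[sel])
            row[f"{part}_precision"] = skm.precision_score(y_true, y_pred, zero_division=0)
            row[f"{part}_recall"] = skm.recall_score(y_true, y_pred, zero_division=0)
            row[f"{part}_accuracy"] = skm.accuracy_score(y_true, y_pred)
            if y_true.all() or not y_true.any():
                row[f"{part}_auc"] = np.nan
            else:
                row[f"{part}_auc"] = skm.roc_auc_score(y_true, roc.direction * v[sel])
        rows.append(row)
    return CVReport(
        folds=pd.DataFrame(rows),
        fold_assignments=assign,
        seed=seed,
        positive_class=str(positive_class),
    )


def biomarker_cv_report(report: CVReport) -> dict:
    """Mean (SD) train/test metrics in the standard single-feature report layout."""
    m, s = report.mean(), report.sd()
    out = {}
    for part in ("train", "test"):
        for metric in METRICS:
            col = f"{part}_{metric}"
            out[col] = {"mean": float(m[col]), "sd": float(s[col])}
    return out


def screen_features(table, positive: str, negative: str, welch: bool = False) -> pd.DataFrame:
    """Exhaustive single-feature screen over every feature column of a table.

    Complements the targeted analysis: for each feature, the two-sided
    independent t-test and the full-sample (oriented) ROC AUC for
    ``positive`` vs ``negative``, sorted by p-value.  No multiplicity
    correction is applied.
    """
    from .features import feature_columns

    cols = feature_columns(table)
    sub = table[table["region"].isin([positive, negative])]
    labels = sub["region"].to_numpy()
    rows = []
    for col in cols:
        v = sub[col].to_numpy()
        tt = ttest_independent(v[labels == positive], v[labels == negative], welch)
        try:
            auc = roc_analysis(v, labels, positive).auc
        except ValidationError:
            auc = np.nan
        rows.append({"feature": col, "t": tt.t, "p": tt.p, "df": tt.df, "auc": auc})
    return pd.DataFrame(rows).sort_values("p", ignore_index=True)
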