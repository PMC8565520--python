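"""MRMR feature selection and linear-SVM classification of stimulation site.

MRMR (minimum redundancy, maximum relevance) greedily picks features with high
mutual information (MI) with the region label while penalizing MI with the
already-selected set; MI is estimated plug-in style on equal-frequency 3-bin
discretizations, which makes the ranking invariant to monotone feature
transforms.  The default criterion is the mutual-information difference (MID);
the quotient (MIQ) form is available.

Classification is a linear SVM over the selected features, standardized on
training-fold statistics, evaluated with stratified 5-fold CV over a fixed C
grid; one C (the one with best mean validation accuracy) is reported per
analysis.  Feature selection runs inside each training fold by default
(leakage-safe); selection on the full table is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.multiclass import OneVsRestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import PipelineConfig, ValidationError
from .features import feature_columns
from .stats_single import CVReport, _fold_iter

DEFAULT_C_GRID = (0.001, 0.01, 0.1, 0.5, 1.0, 2.0)
N_BINS = 3


def discretize_equal_frequency(x: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    """Equal-frequency bin codes (0..n_bins-1); ties can merge bins."""
    x = np.asarray(x, dtype=float)
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    # side='left': a value exactly at a bin edge belongs to the lower bin
    return np.searchsorted(qs, x, side="left")


def mutual_information(codes_a: np.ndarray, codes_b: np.ndarray) -> float:
    """Plug-in MI (nats) between two integer-coded variables."""
    a = np.asarray(codes_a)
    b = np.asarray(codes_b)
    n = a.size
    na, nb = a.max() + 1, b.max() + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb) / n
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])).sum())


@dataclass
class MrmrRanking:
    """Greedy MRMR selection path."""

    features: list[str]
    relevance: dict[str, float]
    scores: list[float]  # criterion value at each greedy step
    k: int
    criterion: str = "MID"

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValidationError("ranking contains repeats")


def mrmr_select(
    table: pd.DataFrame, labels, k: int, criterion: str = "MID"
) -> MrmrRanking:
    """Rank the top-``k`` feature columns of ``table`` by greedy MRMR.

    Step 1 picks the most label-relevant feature; step j maximizes
    relevance(f) - mean_redundancy(f, selected) (MID) or the ratio (MIQ).
    Deterministic given the table: ties break toward the earlier column.
    """
    cols = feature_columns(table)
    if not cols:
        cols = list(table.columns)
    if k < 1 or k > len(cols):
        raise ValidationError(f"k={k} outside [1, {len(cols)}]")
    y = pd.Categorical(np.asarray(labels)).codes
    X = np.stack([discretize_equal_frequency(table[c].to_numpy()) for c in cols])
    relevance = np.array([mutual_information(X[i], y) for i in range(len(cols))])
    selected: list[int] = []
    scores: list[float] = []
    red_cache = np.zeros((0, len(cols)))
    remaining = np.ones(len(cols), dtype=bool)
    for _step in range(k):
        if not selected:
            crit = relevance.copy()
        else:
            mean_red = red_cache.mean(axis=0)
            if criterion == "MID":
                crit = relevance - mean_red
            elif criterion == "MIQ":
                crit = relevance / np.maximum(mean_red, 1e-12)
            else:
                raise ValidationError(f"unknown criterion {criterion!r}")
        crit = np.where(remaining, crit, -np.inf)
        # earliest column among ties (within float tolerance: exact ties occur
        # for features with identical contingency shapes)
        best = int(np.flatnonzero(crit >= crit.max() - 1e-10)[0])
        selected.append(best)
        scores.append(float(crit[best]))
        remaining[best] = False
        new_red = np.array(
            [mutual_information(X[best], X[j]) for j in range(len(cols))]
        )
        red_cache = np.vstack([red_cache, new_red])
    return MrmrRanking(
        features=[cols[i] for i in selected],
        relevance={cols[i]: float(relevance[i]) for i in range(len(cols))},
        scores=scores,
        k=k,
        criterion=criterion,
    )


@dataclass
class SvmSpec:
    """Linear-SVM analysis specification."""

    mode: str = "two_class"  # "two_class" | "ovr" | "ovo"
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    standardize: bool = True
    classes: tuple[str, ...] | None = None  # restrict to these labels

    def __post_init__(self) -> None:
        if self.mode not in ("two_class", "ovr", "ovo"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if any(c <= 0 for c in self.c_grid):
            raise ValidationError("C values must be positive")


def _make_svm(mode: str, c: float):
    base = SVC(kernel="linear", C=c)
    if mode == "ovr":
        return OneVsRestClassifier(base)
    return base  # SVC is one-vs-one natively; fine for two_class too


@dataclass
class ClassifierReport(CVReport):
    """CV report for an SVM analysis: adds chosen C, the per-C accuracy curve,
    the selected features per fold, and (multiclass) a pooled confusion
    matrix."""

    chosen_c: float = np.nan
    c_curve: pd.DataFrame | None = None
    selected_features: list[list[str]] = field(default_factory=list)
    confusion: np.ndarray | None = None
    classes: list[str] = field(default_factory=list)
    mode: str = "two_class"

    def summary(self) -> str:  # noqa: D102
        lines = [
            f"Linear SVM ({self.mode}), classes: {' vs '.join(self.classes)}",
            f"chosen C = {self.chosen_c}",
        ]
        m, s = self.mean(), self.sd()
        for col in self.folds.columns:
            lines.append(f"  {col:<18s} {m[col]:.3f} (+/-{s[col]:.2f})")
        if self.confusion is not None:
            lines.append("confusion matrix (rows = true):")
            lines.append(str(pd.DataFrame(self.confusion, index=self.classes, columns=self.classes)))
        return "\n".join(lines)


def train_eval_svm(
    table: pd.DataFrame,
    labels,
    spec: SvmSpec | None = None,
    k_folds: int = 5,
    seed: int = 0,
    mrmr_k: int | None = 25,
    select_within_folds: bool = True,
    mrmr_criterion: str = "MID",
    groups=None,
    nested_cv: bool = False,
) -> ClassifierReport:
    """Fit and evaluate a linear SVM with stratified k-fold CV over a C grid.

    One C — the grid value with the highest mean validation accuracy (ties to
    the smaller C) — is chosen for the whole analysis and its fold metrics are
    reported.  Multiclass precision/recall are macro-averaged.  With
    ``nested_cv`` each outer fold instead picks its own C by an inner CV on
    its training part (the reported ``chosen_c`` is then the modal fold C).
    """
    spec = spec or SvmSpec()
    y = np.asarray(labels)
    if spec.classes is not None:
        keep = np.isin(y, spec.classes)
        table = table.loc[keep]
        y = y[keep]
        if groups is not None:
            groups = np.asarray(groups)[keep]
    classes = sorted(np.unique(y))
    if len(classes) < 2:
        raise ValidationError("need at least two classes")
    if spec.mode == "two_class" and len(classes) != 2:
        raise ValidationError("two_class mode needs exactly two labels")
    cols = feature_columns(table)
    if not cols:
        cols = list(table.columns)
    Xfull = table[cols]
    min_class = min(np.sum(y == c) for c in classes)
    if min_class < k_folds:
        warnings.warn(f"reducing folds from {k_folds} to {min_class}", stacklevel=2)
        k_folds = int(min_class)
    if k_folds < 2:
        raise ValidationError("a class is too small even for 2 folds; enlarge the cohort")

    folds = list(_fold_iter(y, k_folds, seed, groups))
    # per-fold feature selection and scaling (selection is C-independent)
    fold_cols: list[list[str]] = []
    for tr, _te in folds:
        if mrmr_k is None:
            fold_cols.append(cols)
        elif select_within_folds:
            rank = mrmr_select(Xfull.iloc[tr], y[tr], min(mrmr_k, len(cols)), mrmr_criterion)
            fold_cols.append(rank.features)
        else:
            rank = mrmr_select(Xfull, y, min(mrmr_k, len(cols)), mrmr_criterion)
            fold_cols.append(rank.features)

    average = "binary" if len(classes) == 2 else "macro"
    pos_label = classes[0] if len(classes) == 2 else 1

    def _metrics(y_true, y_pred, prefix):
        kw = dict(zero_division=0)
        if average == "binary":
            kw["pos_label"] = pos_label
        return {
            f"{prefix}_precision": skm.precision_score(y_true, y_pred, average=average, **kw),
            f"{prefix}_recall": skm.recall_score(y_true, y_pred, average=average, **kw),
            f"{prefix}_accuracy": skm.accuracy_score(y_true, y_pred),
        }

    per_c_rows: dict[float, list[dict]] = {c: [] for c in spec.c_grid}
    per_c_conf: dict[float, np.ndarray] = {
        c: np.zeros((len(classes), len(classes)), dtype=int) for c in spec.c_grid
    }
    fold_data = []
    for (tr, te), sel in zip(folds, fold_cols):
        Xtr = Xfull.iloc[tr][sel].to_numpy(dtype=float)
        Xte = Xfull.iloc[te][sel].to_numpy(dtype=float)
        if spec.standardize:
            scaler = StandardScaler().fit(Xtr)
            Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        fold_data.append((tr, te, Xtr, Xte))
    if nested_cv:
        return _nested_report(
            spec, y, classes, fold_data, fold_cols, _metrics, k_folds, seed
        )
    for tr, te, Xtr, Xte in fold_data:
        for c in spec.c_grid:
            clf = _make_svm(spec.mode, c)
            clf.fit(Xtr, y[tr])
            row = _metrics(y[tr], clf.predict(Xtr), "train")
            pred_te = clf.predict(Xte)
            row.update(_metrics(y[te], pred_te, "test"))
            per_c_rows[c].append(row)
            per_c_conf[c] += skm.confusion_matrix(y[te], pred_te, labels=classes)

    cs = sorted(spec.c_grid)
    accs = [float(np.mean([r["test_accuracy"] for r in per_c_rows[c]])) for c in cs]
    c_curve = pd.DataFrame({"C": cs, "mean_test_accuracy": accs})
    chosen_c = float(cs[int(np.argmax(accs))])  # ties break toward smaller C
    assign = np.full(y.size, -1)
    for fold, (_tr, te) in enumerate(folds):
        assign[te] = fold
    return ClassifierReport(
        folds=pd.DataFrame(per_c_rows[chosen_c]),
        fold_assignments=assign,
        seed=seed,
        chosen_c=chosen_c,
        c_curve=c_curve,
        selected_features=fold_cols,
        confusion=per_c_conf[chosen_c] if len(classes) > 2 else None,
        classes=[str(c) for c in classes],
        mode=spec.mode,
    )


def _nested_report(spec, y, classes, fold_data, fold_cols, metrics_fn, k_folds, seed):
    """Outer-fold metrics with per-fold C chosen by an inner CV on the
    training part (leakage-free C selection)."""
    rows, fold_cs = [], []
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for tr, te, Xtr, Xte in fold_data:
        inner_k = min(k_folds, min(np.sum(y[tr] == c) for c in classes))
        inner_accs = {c: [] for c in spec.c_grid}
        for itr, ival in _fold_iter(y[tr], max(inner_k, 2), seed):
            for c in spec.c_grid:
                clf = _make_svm(spec.mode, c)
                clf.fit(Xtr[itr], y[tr][itr])
                inner_accs[c].append(skm.accuracy_score(y[tr][ival], clf.predict(Xtr[ival])))
        cs = sorted(spec.c_grid)
        best_c = cs[int(np.argmax([np.mean(inner_accs[c]) for c in cs]))]
        fold_cs.append(best_c)
        clf = _make_svm(spec.mode, best_c)
        clf.fit(Xtr, y[tr])
        row = metrics_fn(y[tr], clf.predict(Xtr), "train")
        pred_te = clf.predict(Xte)
        row.update(metrics_fn(y[te], pred_te, "test"))
        rows.append(row)
        conf += skm.confusion_matrix(y[te], pred_te, labels=classes)
    assign = np.full(y.size, -1)
    for fold, (_tr, te, _x, _z) in enumerate(fold_data):
        assign[te] = fold
    modal_c = float(pd.Series(fold_cs).mode().iloc[0])
    return ClassifierReport(
        folds=pd.DataFrame(rows),
        fold_assignments=assign,
        seed=seed,
        chosen_c=modal_c,
        c_curve=None,
        selected_features=fold_cols,
        confusion=conf if len(classes) > 2 else None,
        classes=[str(c) for c in classes],
        mode=spec.mode,
        extra={"fold_cs": fold_cs},
    )


STANDARD_ANALYSES = (
    ("ZI_vs_VMR", "two_class", ("ZI", "VMR")),
    ("ZI_vs_DLR", "two_class", ("ZI", "DLR")),
    ("DLR_vs_VMR", "two_class", ("DLR", "VMR")),
    ("multiclass_ovr", "ovr", ("ZI", "DLR", "VMR")),
    ("multiclass_ovo", "ovo", ("ZI", "DLR", "VMR")),
)


@dataclass
class LocalizationReport:
    """The five-analysis classification report (three pairwise + OvR + OvO)."""

    runs: dict[str, ClassifierReport]

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for name, rep in self.runs.items():
            m, s = rep.mean(), rep.sd()
            rows[name] = {
                "model": f"linear SVM {rep.mode}",
                "n_features": len(rep.selected_features[0]),
                "C": rep.chosen_c,
                **{
                    f"{col}_mean": float(m[col]) for col in rep.folds.columns
                },
                **{f"{col}_sd": float(s[col]) for col in rep.folds.columns},
            }
        return pd.DataFrame(rows).T

    def summary(self) -> str:
        return "\n\n".join(rep.summary() for rep in self.runs.values())


def full_pipeline_classification(
    table: pd.DataFrame, config: PipelineConfig | None = None
) -> LocalizationReport:
    """Run the five standard analyses on a labelled feature table.

    The table must carry a ``region`` column; features are the MRMR top-k
    (default 25).  Emits pairwise ZI/VMR, ZI/DLR, DLR/VMR linear SVMs plus
    one-vs-rest and one-vs-one multiclass models.
    """
    config = config or PipelineConfig()
    if "region" not in table.columns:
        raise ValidationError("feature table lacks a 'region' column")
    y = table["region"].to_numpy()
    groups = table["patient_id"].to_numpy() if config.group_by_patient else None
    runs = {}
    for name, mode, cls in STANDARD_ANALYSES:
        spec = SvmSpec(mode=mode, c_grid=config.svm_c_grid, classes=cls)
        runs[name] = train_eval_svm(
            table,
            y,
            spec,
            k_folds=config.cv_folds,
            seed=config.rng_seed,
            mrmr_k=config.mrmr_k,
            select_within_folds=config.select_within_folds,
            mrmr_criterion=config.mrmr_criterion,
            groups=groups,
        )
    return LocalizationReport(runs=runs)
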