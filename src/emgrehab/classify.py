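"""Per-patient movement classification and longitudinal progression summaries.

Three classifiers — k-nearest neighbours (Euclidean), random forest, and an
RBF-kernel support vector machine — are trained per patient per assessment
week on the window feature table and evaluated by grouped cross-validation.
Folds are grouped by contraction repetition by default: overlapping windows
from one repetition share signal, so window-level folds would leak between
train and test. Feature standardization is fitted on the training folds only.

Longitudinal outputs mirror the study's reporting: per-classifier week-pair
progression cells (within-group mean accuracy change averaged over the two
groups, with paired-t and between-group ANOVA p-values) and the mean/SD of
the three classifiers' group-level accuracies per week.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import ConfigurationError, DataError
from .features import feature_columns

CLASSIFIER_KINDS = ("knn", "random_forest", "svm")


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "knn"
    knn_k: int = 5
    rf_trees: int = 100
    svm_kernel: str = "rbf"
    svm_c: float = 1.0
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ConfigurationError(f"unknown classifier kind {self.kind!r}")
        if self.knn_k < 1 or self.rf_trees < 1 or self.svm_c <= 0:
            raise ConfigurationError("classifier hyperparameters must be positive")

    def build(self):
        if self.kind == "knn":
            return KNeighborsClassifier(n_neighbors=self.knn_k, metric="euclidean")
        if self.kind == "random_forest":
            return RandomForestClassifier(n_estimators=self.rf_trees,
                                          random_state=self.seed, n_jobs=1)
        return SVC(kernel=self.svm_kernel, C=self.svm_c, random_state=self.seed)


@dataclass(frozen=True)
class CvSpec:
    folds: int = 5
    grouping: str = "repetition"  # or "window"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")
        if self.grouping not in ("repetition", "window"):
            raise ConfigurationError("grouping must be 'repetition' or 'window'")


@dataclass
class ClassifierReport:
    patient_id: str
    week: float
    kind: str
    accuracy: float  # mean fold accuracy, fraction in [0, 1]
    confusion: np.ndarray  # (n_classes, n_classes), rows = true class
    classes: tuple[str, ...]
    fold_accuracies: list[float] = field(default_factory=list)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "week": self.week,
            "classifier": self.kind,
            "accuracy": self.accuracy,
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "fold_accuracies": self.fold_accuracies,
            "seed": self.seed,
        }


def _grouped_folds(y: np.ndarray, groups: np.ndarray, folds: int,
                   seed: int) -> list[np.ndarray]:
    """Deterministic fold assignment of whole groups, class-balanced.

    With repetition grouping each group (repetition index) contains every
    movement, so assigning whole repetitions to folds keeps every class in
    every training fold.
    """
    uniq = np.unique(groups)
    if folds > uniq.size:
        raise ConfigurationError(
            f"{folds} folds requested but only {uniq.size} repetition groups "
            "are available")
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq.size)
    assignment = {g: order[i] % folds for i, g in enumerate(uniq)}
    return [np.flatnonzero(np.isin(groups, [g for g, f in assignment.items() if f == k]))
            for k in range(folds)]


def _window_folds(y: np.ndarray, folds: int, seed: int) -> list[np.ndarray]:
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros_like(y), y)]


def crossval_accuracy(table: pd.DataFrame, clf: ClassifierSpec,
                      cv: CvSpec) -> ClassifierReport:
    """Cross-validated movement accuracy for one patient-week feature table.

    Standardization (when enabled) is fitted on training folds only; the
    report carries the mean fold accuracy, per-fold accuracies, and the
    confusion matrix accumulated over test folds.
    """
    patients = table["patient_id"].unique()
    weeks = table["week"].unique()
    if len(patients) != 1 or len(weeks) != 1:
        raise DataError("crossval_accuracy expects a single patient-week table")
    classes = tuple(sorted(table["movement"].unique()))
    if len(classes) < 2:
        raise DataError(f"patient {patients[0]} has fewer than 2 movement classes")

    cols = feature_columns(table)
    X = table[cols].to_numpy(dtype=float)
    y = table["movement"].to_numpy()

    if cv.grouping == "repetition":
        groups = table["repetition"].to_numpy()
        test_folds = _grouped_folds(y, groups, cv.folds, cv.seed)
    else:
        test_folds = _window_folds(y, cv.folds, cv.seed)

    n_cls = len(classes)
    cls_index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((n_cls, n_cls), dtype=int)
    fold_acc: list[float] = []
    all_idx = np.arange(len(y))
    for test_idx in test_folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        y_tr = y[train_idx]
        missing = set(classes) - set(y_tr)
        if missing:
            raise DataError(f"classes {sorted(missing)} absent from a training fold "
                            f"for patient {patients[0]}")
        X_tr, X_te = X[train_idx], X[test_idx]
        if clf.standardize:
            scaler = StandardScaler().fit(X_tr)
            X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
        model = clf.build()
        model.fit(X_tr, y_tr)
        pred = model.predict(X_te)
        y_te = y[test_idx]
        fold_acc.append(float(np.mean(pred == y_te)))
        for t, p in zip(y_te, pred):
            confusion[cls_index[t], cls_index[p]] += 1

    return ClassifierReport(
        patient_id=str(patients[0]), week=float(weeks[0]), kind=clf.kind,
        accuracy=float(np.mean(fold_acc)), confusion=confusion,
        classes=classes, fold_accuracies=fold_acc, seed=clf.seed,
    )


def reports_frame(reports: Sequence[ClassifierReport]) -> pd.DataFrame:
    """Long-format accuracy frame: patient_id, group-less report columns."""
    return pd.DataFrame([
        {"patient_id": r.patient_id, "week": r.week, "classifier": r.kind,
         "accuracy": r.accuracy}
        for r in reports
    ])


def _week_pairs(weeks: Sequence[float]) -> list[tuple[float, float]]:
    """Consecutive week pairs plus the follow-up-vs-baseline span."""
    w = list(weeks)
    pairs = list(zip(w[:-1], w[1:]))
    pairs.append((w[0], w[-1]))
    return pairs


def progression_table(acc: pd.DataFrame, weeks: Sequence[float],
                      groups: Sequence[str]) -> pd.DataFrame:
    """Week-pair progression cells per classifier (accuracy in percent).

    ``acc`` is a long frame with columns ``patient_id, group, week,
    classifier, accuracy`` (fractions). For each classifier and week pair the
    cell value is the mean over the two groups of the within-group mean
    per-patient accuracy difference, in percentage points, with its SD over
    all patients' difference scores. Attached p-values: paired two-tailed t
    per group, one-way ANOVA between groups on the per-patient difference
    scores, and Shapiro-Wilk normality p of the pooled differences.

    The follow-up-vs-baseline cell telescopes exactly: it equals the sum of
    the consecutive-pair cells per group.
    """
    required = {"patient_id", "group", "week", "classifier", "accuracy"}
    if not required <= set(acc.columns):
        raise DataError(f"accuracy frame must have columns {sorted(required)}")
    for w in weeks:
        missing = acc[acc["week"] == w]
        if missing.empty:
            raise DataError(f"no reports at week {w}")
    wide = acc.pivot_table(index=["patient_id", "group", "classifier"],
                           columns="week", values="accuracy")
    incomplete = wide[wide[list(weeks)].isna().any(axis=1)]
    if not incomplete.empty:
        names = sorted({i[0] for i in incomplete.index})
        raise DataError(f"patients missing weeks: {names}")

    rows = []
    for kind in sorted(acc["classifier"].unique()):
        sub = wide.xs(kind, level="classifier")
        for w_a, w_b in _week_pairs(weeks):
            diffs = (sub[w_b] - sub[w_a]) * 100.0
            group_means = {}
            p_paired = {}
            for g in groups:
                d = diffs.xs(g, level="group")
                group_means[g] = float(d.mean())
                t = spstats.ttest_rel(sub[w_b].xs(g, level="group") * 100.0,
                                      sub[w_a].xs(g, level="group") * 100.0)
                p_paired[g] = float(t.pvalue)
            d_groups = [diffs.xs(g, level="group").to_numpy() for g in groups]
            anova_p = float(spstats.f_oneway(*d_groups).pvalue) if all(
                len(d) > 1 for d in d_groups) else float("nan")
            pooled = diffs.to_numpy()
            shapiro_p = float(spstats.shapiro(pooled).pvalue) if (
                3 <= pooled.size <= 5000 and np.ptp(pooled) > 0) else float("nan")
            rows.append({
                "classifier": kind,
                "week_a": w_a,
                "week_b": w_b,
                "value": float(np.mean([group_means[g] for g in groups])),
                "sd": float(np.std(pooled, ddof=1)) if pooled.size > 1 else 0.0,
                **{f"mean_{g}": group_means[g] for g in groups},
                **{f"p_paired_{g}": p_paired[g] for g in groups},
                "p_between_groups": anova_p,
                "shapiro_p": shapiro_p,
            })
    return pd.DataFrame(rows)


def progression_from_group_means(
    group_means: Mapping[str, Mapping[float, float]],
    weeks: Sequence[float],
) -> dict[tuple[float, float], float]:
    """Week-pair cells recomputed from group-level mean accuracies.

    ``group_means[group][week]`` is the group's mean accuracy (any fixed
    scale). Each cell is the mean over groups of the within-group week-pair
    difference — the deterministic arithmetic behind the progression table
    when only group means are available.
    """
    cells = {}
    for w_a, w_b in _week_pairs(weeks):
        per_group = [group_means[g][w_b] - group_means[g][w_a] for g in group_means]
        cells[(w_a, w_b)] = float(np.mean(per_group))
    return cells


def mean_sd_across_classifiers(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample SD across the per-classifier group accuracies."""
    if len(values) < 1:
        raise DataError("no classifier accuracies supplied")
    v = np.asarray(values, dtype=float)
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return float(np.mean(v)), sd


def classifier_mean_summary(acc: pd.DataFrame) -> pd.DataFrame:
    """Per (group, week): mean and SD across classifiers of group accuracies.

    ``acc`` is the long accuracy frame (fractions). Patient accuracies are
    first averaged within (group, week, classifier); the summary is then the
    arithmetic mean and sample SD of the three classifier-level means, in
    percent.
    """
    grp = (acc.groupby(["group", "week", "classifier"])["accuracy"]
           .mean().reset_index())
    rows = []
    for (g, w), sub in grp.groupby(["group", "week"]):
        expected = set(acc["classifier"].unique())
        present = set(sub["classifier"])
        if present != expected:
            raise DataError(f"group {g} week {w} missing classifiers "
                            f"{sorted(expected - present)}")
        mean, sd = mean_sd_across_classifiers((sub["accuracy"] * 100.0).tolist())
        rows.append({"group": g, "week": w, "mean_acc": mean, "sd_acc": sd})
    return pd.DataFrame(rows)
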