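"""Validation and screening of per-recording indices against apnea severity.

A cohort is summarised as an index table — one row per recording with the
computed indices, the apnea–hypopnea index (AHI, events/hour) and the derived
severity group (N: AHI < 5; OSA-m: 5 <= AHI <= 30; OSA-s: AHI > 30).  The
module provides Pearson correlation of an index with AHI (with the
conventional verbal strength categories), pairwise Welch t-tests plus one-way
ANOVA across the three groups, and severe-vs-non-severe screening with
stratified k-fold cross-validated classifiers, the severe class positive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "GROUPS",
    "POSITIVE_GROUP",
    "ScreenResult",
    "group_from_ahi",
    "correlation_category",
    "validate_index_table",
    "correlate",
    "group_tests",
    "metrics_from_confusion",
    "screen_cv",
]

GROUPS = ("N", "OSA-m", "OSA-s")
POSITIVE_GROUP = "OSA-s"

#: |R| bins -> verbal correlation strength, half-open [lo, hi) except the last.
_CATEGORIES = [
    (0.0, 0.2, "very weak"),
    (0.2, 0.4, "weak"),
    (0.4, 0.6, "moderate"),
    (0.6, 0.8, "strong"),
    (0.8, 1.0 + 1e-12, "very strong"),
]


def correlation_category(r: float) -> str:
    """Verbal strength of a Pearson R: |R| binned at 0.2-wide intervals."""
    a = abs(r)
    if not 0 <= a <= 1:
        raise ValueError(f"|R| must lie in [0, 1], got {a}")
    return next(c for lo, hi, c in _CATEGORIES if lo <= a < hi)


def group_from_ahi(ahi: float) -> str:
    if ahi < 5:
        return "N"
    if ahi <= 30:
        return "OSA-m"
    return "OSA-s"


def validate_index_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check required columns and AHI/group consistency; fills a missing
    ``group`` column from AHI."""
    if "ahi" not in table.columns:
        raise ValueError("index table must have an 'ahi' column")
    table = table.copy()
    if "group" not in table.columns:
        table["group"] = table["ahi"].map(group_from_ahi)
    else:
        expected = table["ahi"].map(group_from_ahi)
        bad = table["group"] != expected
        if bad.any():
            raise ValueError(
                f"group labels inconsistent with AHI thresholds in rows "
                f"{list(table.index[bad])}"
            )
    return table


@dataclass
class ScreenResult:
    """Pooled cross-validation outcome of one feature set / classifier."""

    acc: float
    sen: float
    spe: float
    precision: float
    recall: float
    f1: float
    confusion: tuple[int, int, int, int]  # TP, FP, FN, TN
    fold_assignments: dict = field(default_factory=dict)


def correlate(table: pd.DataFrame, index_name: str):
    """Pearson R of an index against AHI with verbal strength category.

    Returns ``(R, p, category)``; the category bins |R| into very weak / weak
    / moderate / strong / very strong at 0.2-wide half-open intervals.
    """
    table = validate_index_table(table)
    x = table[index_name].to_numpy(dtype=float)
    y = table["ahi"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 recordings for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(f"zero variance in {index_name!r} or AHI")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), correlation_category(r)


def group_tests(table: pd.DataFrame, index_name: str) -> dict[str, float]:
    """Pairwise Welch t-tests and one-way ANOVA of an index across N / OSA-m /
    OSA-s.

    Returns p-values keyed ``"N|OSA-m"``, ``"N|OSA-s"``, ``"OSA-m|OSA-s"`` and
    ``"anova"``.  Degenerate input (all groups constant) yields NaNs with a
    warning rather than an exception.
    """
    table = validate_index_table(table)
    samples = {}
    for g in GROUPS:
        v = table.loc[table["group"] == g, index_name].to_numpy(dtype=float)
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 recordings")
        samples[g] = v
    if all(np.ptp(v) == 0 for v in samples.values()):
        warnings.warn(
            f"{index_name!r} is constant within every group; tests undefined"
        )
        return {"N|OSA-m": math.nan, "N|OSA-s": math.nan,
                "OSA-m|OSA-s": math.nan, "anova": math.nan}
    out = {}
    for a, b in (("N", "OSA-m"), ("N", "OSA-s"), ("OSA-m", "OSA-s")):
        out[f"{a}|{b}"] = float(
            stats.ttest_ind(samples[a], samples[b], equal_var=False).pvalue
        )
    out["anova"] = float(stats.f_oneway(*samples.values()).pvalue)
    return out


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def metrics_from_confusion(TP: int, FP: int, FN: int, TN: int):
    """Accuracy, sensitivity, specificity, precision, recall and F1 (percent).

    Ratios with a zero denominator are NaN (undefined), never silently 0; F1
    is 0 when precision and recall are defined but both vanish.
    """
    if min(TP, FP, FN, TN) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = TP + FP + FN + TN
    if total == 0:
        raise ValueError("confusion matrix is empty")
    acc = (TP + TN) / total
    sen = _ratio(TP, TP + FN)
    spe = _ratio(TN, TN + FP)
    precision = _ratio(TP, TP + FP)
    recall = sen
    if math.isnan(precision) or math.isnan(recall):
        f1 = math.nan
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return tuple(100.0 * v for v in (acc, sen, spe, precision, recall, f1))


_CLASSIFIERS = {
    "decision_tree": lambda seed: DecisionTreeClassifier(random_state=seed),
    "knn": lambda seed: KNeighborsClassifier(n_neighbors=5),
    "random_forest": lambda seed: RandomForestClassifier(
        n_estimators=100, random_state=seed
    ),
    "naive_bayes": lambda seed: GaussianNB(),
}


def screen_cv(
    table: pd.DataFrame,
    feature_names: list[str],
    classifier_name: str = "decision_tree",
    k_folds: int = 5,
    seed: int = 0,
) -> ScreenResult:
    """Severe-OSA screening with stratified k-fold cross-validation.

    One feature vector per recording; the severe group is positive.  Confusion
    counts are pooled over the test folds and the metrics computed from the
    pooled counts.
    """
    if classifier_name not in _CLASSIFIERS:
        raise ValueError(
            f"unknown classifier {classifier_name!r}; "
            f"choose from {sorted(_CLASSIFIERS)}"
        )
    table = validate_index_table(table)
    missing = [f for f in feature_names if f not in table.columns]
    if missing:
        raise ValueError(f"features not in table: {missing}")
    X = table[feature_names].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing index values in rows entering classification")
    y = (table["group"] == POSITIVE_GROUP).to_numpy()
    if y.all() or not y.any():
        raise ValueError("both severe and non-severe recordings are required")
    if k_folds > min(y.sum(), (~y).sum()):
        raise ValueError("k_folds exceeds the size of the smaller class")

    ids = (
        table["recording_id"].tolist()
        if "recording_id" in table.columns
        else list(table.index)
    )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    TP = FP = FN = TN = 0
    folds: dict = {}
    for fold, (train, test) in enumerate(skf.split(X, y)):
        clf = _CLASSIFIERS[classifier_name](seed)
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        truth = y[test]
        TP += int(np.sum(pred & truth))
        FP += int(np.sum(pred & ~truth))
        FN += int(np.sum(~pred & truth))
        TN += int(np.sum(~pred & ~truth))
        for i in test:
            folds[ids[i]] = fold
    acc, sen, spe, precision, recall, f1 = metrics_from_confusion(TP, FP, FN, TN)
    return ScreenResult(
        acc=acc, sen=sen, spe=spe, precision=precision, recall=recall, f1=f1,
        confusion=(TP, FP, FN, TN), fold_assignments=folds,
    )
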