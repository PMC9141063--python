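"""Classification metrics and endophenotype probability comparisons.

Threshold metrics (accuracy, sensitivity, specificity, balanced accuracy,
F1) come straight from the confusion counts; AUC is computed by concordant
pair counting (ties count one half), which equals the trapezoidal area
under the ROC curve. The endophenotype analysis compares per-subject mean
predicted probabilities between clinically defined case subgroups with a
two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self):
        return self.tp + self.fp + self.tn + self.fn


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Mean of sensitivity and specificity (robust under class imbalance)."""
    return (sensitivity + specificity) / 2.0


def confusion_metrics(labels, probabilities, threshold: float = 0.5):
    """Threshold the probabilities and compute the five confusion metrics.

    Positive class = case (label 1). Metrics with a zero denominator are
    reported as NaN with a warning. Returns ``(ConfusionCounts, dict)``.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    pred = (p >= threshold).astype(int)
    cc = ConfusionCounts(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
    )

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)")
            return np.nan
        return num / den

    sens = ratio(cc.tp, cc.tp + cc.fn, "sensitivity")
    spec = ratio(cc.tn, cc.tn + cc.fp, "specificity")
    metrics = {
        "accuracy": ratio(cc.tp + cc.tn, cc.total, "accuracy"),
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": balanced_accuracy(sens, spec),
        "f1": ratio(2 * cc.tp, 2 * cc.tp + cc.fp + cc.fn, "f1"),
        "decision_threshold": threshold,
    }
    return cc, metrics


def roc_auc(labels, probabilities) -> float:
    """AUC by pair counting: (concordant + 0.5 * tied) / (n1 * n0).

    Implemented through midranks (the Mann–Whitney identity), so tied
    scores contribute one half per pair.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(probabilities, dtype=float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    r = stats.rankdata(s)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def wilcoxon_rank_sum(x, y):
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null when the combined sample size is at most 25 and there are
    no ties; tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return 1.0  # all observations tied: the null is symmetric
    exact = (combined.size <= 25
             and np.unique(combined).size == combined.size)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return float(res.pvalue)


GROUPINGS = {
    "moca": ("moca_class", "CI"),
    "rbd": ("rbd", "yes"),
    "motor": ("motor_class", "TD"),
    "smell": ("smell_class", "normosmia"),
    "age": ("age_class", ">=56"),
}


@dataclass
class EndophenotypeResult:
    grouping: str
    group_in: str
    n_in: int
    n_out: int
    mean_in: float
    mean_out: float
    p_value: float | None
    n_missing: int = 0


def subject_probabilities(records: pd.DataFrame, C: int) -> pd.Series:
    """Per-subject predicted probability at feature-set size C, averaged
    over repetitions (each subject is validated once per repetition)."""
    at_c = records[records["C"] == C]
    if at_c.empty:
        raise ValueError(f"no prediction records at C={C}")
    return at_c.groupby("sample_id")["probability"].mean()


def endophenotype_test(records: pd.DataFrame, metadata: pd.DataFrame,
                       grouping: str, C: int) -> EndophenotypeResult:
    """Compare mean predicted probability between case subgroups.

    ``grouping`` is one of moca / rbd / motor / smell / age; cases only.
    Missing endophenotype values are dropped (count reported). Groups with
    fewer than two subjects skip the test (p = None) with a warning.
    """
    if grouping not in GROUPINGS:
        raise KeyError(f"unknown grouping {grouping!r}")
    col, in_level = GROUPINGS[grouping]
    probs = subject_probabilities(records, C)
    cases = metadata[metadata["label"] == "case"]
    probs = probs[probs.index.isin(cases.index)]
    vals = cases.loc[probs.index, col]
    missing = vals.isna()
    n_missing = int(missing.sum())
    probs, vals = probs[~missing], vals[~missing]
    mask_in = (vals == in_level).to_numpy()
    a, b = probs[mask_in], probs[~mask_in]
    result = EndophenotypeResult(
        grouping=grouping, group_in=in_level, n_in=len(a), n_out=len(b),
        mean_in=float(a.mean()) if len(a) else np.nan,
        mean_out=float(b.mean()) if len(b) else np.nan,
        p_value=None, n_missing=n_missing)
    if len(a) < 2 or len(b) < 2:
        warnings.warn(f"grouping {grouping}: a group has <2 subjects; "
                      "test skipped")
        return result
    result.p_value = wilcoxon_rank_sum(a.to_numpy(), b.to_numpy())
    return result


def endophenotype_report(records, metadata, C,
                         groupings=tuple(GROUPINGS)) -> pd.DataFrame:
    rows = []
    for g in groupings:
        r = endophenotype_test(records, metadata, g, C)
        rows.append({"grouping": r.grouping, "group": r.group_in,
                     "n_in": r.n_in, "n_out": r.n_out,
                     "mean_prob_in": r.mean_in, "mean_prob_out": r.mean_out,
                     "p_value": r.p_value, "n_missing": r.n_missing})
    return pd.DataFrame(rows)
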