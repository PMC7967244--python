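"""Clinical indexes, ROC/AUC, and Mann-Whitney U model comparison.

Binary confusion matrices follow the convention rows = true class, columns =
predicted class, with the positive (MI) class at index 1:

    ACC% = (TP + TN) / (TP + TN + FP + FN) * 100
    SEN% = TP / (TP + FN) * 100
    SPE% = TN / (TN + FP) * 100
    F1%  = 2 TP / (2 TP + FP + FN) * 100

Zero denominators yield ``None`` (an explicit undefined marker), never an
exception.  The AUC is computed as the rank statistic (the probability that
a random positive outscores a random negative, ties counted 1/2), which
makes the identity AUC = U / (n+ n-) with the Mann-Whitney statistic exact.

The U test uses midranks for ties, the exact null distribution of U (dynamic
programming over rank arrangements) for small tie-free samples, and a
tie-corrected, continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

EXACT_MAX_N = 20


@dataclass(frozen=True)
class MetricSet:
    """Clinical index set in percent; ``None`` marks an undefined index."""

    acc: float | None
    sen: float | None = None
    spe: float | None = None
    f1: float | None = None
    auc: float | None = None  # fraction in [0, 1], not percent

    def as_dict(self) -> dict[str, float | None]:
        return {"ACC": self.acc, "SEN": self.sen, "SPE": self.spe,
                "F1": self.f1, "AUC": self.auc}


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def clinical_indexes(cm: np.ndarray, positive_index: int = 1) -> MetricSet:
    """ACC/SEN/SPE/F1 from a 2x2 confusion matrix (rows true, cols predicted)."""
    cm = np.asarray(cm)
    if cm.shape != (2, 2):
        raise ValueError(f"need a 2x2 confusion matrix, got {cm.shape}")
    if np.any(cm < 0) or cm.sum() == 0:
        raise ValueError("confusion matrix must be non-negative with positive total")
    pos, neg = positive_index, 1 - positive_index
    tp, fn = cm[pos, pos], cm[pos, neg]
    tn, fp = cm[neg, neg], cm[neg, pos]
    return MetricSet(
        acc=_ratio(tp + tn, cm.sum()),
        sen=_ratio(tp, tp + fn),
        spe=_ratio(tn, tn + fp),
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
    )


def multiclass_accuracy(cm: np.ndarray) -> float:
    """Trace over total, in percent."""
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.size == 0:
        raise ValueError(f"need a square non-empty confusion matrix, got {cm.shape}")
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * np.trace(cm) / total


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted class."""
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (np.asarray(y_true, dtype=int), np.asarray(y_pred, dtype=int)), 1)
    return cm


# ---------------------------------------------------------------------------
# ROC / AUC


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic with midranks for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative samples")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Stepwise ROC path over score thresholds plus the rank-statistic AUC.

    Returns (fpr, tpr, thresholds, auc).
    """
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("labels are all one class; ROC undefined")
    fpr, tpr, thresholds = _sk_roc_curve(labels.astype(int), scores)
    return fpr, tpr, thresholds, rank_auc(scores, labels)


# ---------------------------------------------------------------------------
# Mann-Whitney U


@lru_cache(maxsize=None)
def _u_distribution(n1: int, n2: int) -> np.ndarray:
    """Exact null counts of arrangements per U value, by dynamic programming.

    ``out[u]`` is the number of the C(n1+n2, n1) equally likely rank
    arrangements with Mann-Whitney statistic exactly u.
    """
    # N(u; m, n) = N(u; m, n-1) + N(u - n; m - 1, n): the largest of the
    # m + n ranks is either a sample-two value (U unchanged) or a sample-one
    # value (it outranks all n sample-two values).
    max_u = n1 * n2
    delta = np.zeros(max_u + 1)
    delta[0] = 1.0
    table = [delta.copy() for _ in range(n1 + 1)]  # n = 0 column
    for n in range(1, n2 + 1):
        new = [delta.copy()]
        for m in range(1, n1 + 1):
            arr = table[m].copy()
            arr[n:] += new[m - 1][: max_u + 1 - n]
            new.append(arr)
        table = new
    return table[n1]


def mann_whitney_u(
    sample_a, sample_b, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U (for sample_a) and its p-value.

    Exact p by enumerating the null distribution when both samples have at
    most 20 observations and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    u_a = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    u_b = n1 * n2 - u_a

    has_ties = np.unique(combined).size < combined.size
    if not has_ties and n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        counts = _u_distribution(n1, n2)
        total = counts.sum()
        cdf = np.cumsum(counts) / total
        sf = np.cumsum(counts[::-1])[::-1] / total  # P(U >= u)
        if alternative == "two-sided":
            p = 2.0 * min(cdf[int(u_a)], sf[int(u_a)])
        elif alternative == "greater":  # a tends larger than b
            p = sf[int(u_a)]
        else:
            p = cdf[int(u_a)]
        return u_a, float(min(p, 1.0))

    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # all observations identical
        return u_a, 1.0
    mean = n1 * n2 / 2.0
    sigma = np.sqrt(sigma2)
    if alternative == "two-sided":
        z = (abs(u_a - mean) - 0.5) / sigma
        p = 2.0 * stats.norm.sf(max(z, 0.0))
    elif alternative == "greater":
        z = (u_a - mean - 0.5) / sigma
        p = stats.norm.sf(z)
    else:
        z = (u_a - mean + 0.5) / sigma
        p = stats.norm.cdf(z)
    return u_a, float(min(p, 1.0))


def significance_stars(p: float) -> str:
    """Star rating: * p<0.05, ** p<0.01, *** p<0.001, 'ns' otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# model comparison


DETECTION_INDEXES = ("ACC", "SEN", "SPE", "F1", "AUC")
LOCATING_INDEXES = ("ACC",)


def five_number_summary(values: np.ndarray) -> dict[str, float]:
    q = np.percentile(values, [0, 25, 50, 75, 100])
    return {"min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4]}


def compare_models(
    per_repeat_a: dict[str, np.ndarray],
    per_repeat_b: dict[str, np.ndarray],
    task: str = "detection",
    alternative: str = "two-sided",
) -> dict[str, dict]:
    """Index-by-index comparison of two models' per-repeat metric vectors.

    Accepts externally produced vectors, so published models can be compared
    without re-implementation.  Both inputs must cover the task's index list
    with equal repeat counts.
    """
    indexes = DETECTION_INDEXES if task == "detection" else LOCATING_INDEXES
    report: dict[str, dict] = {}
    for index in indexes:
        if index not in per_repeat_a or index not in per_repeat_b:
            raise ValueError(f"both models must provide per-repeat {index} values")
        va = np.asarray(per_repeat_a[index], dtype=float)
        vb = np.asarray(per_repeat_b[index], dtype=float)
        if va.shape != vb.shape:
            raise ValueError(
                f"{index}: mismatched repeat counts ({va.size} vs {vb.size})"
            )
        u, p = mann_whitney_u(va, vb, alternative=alternative)
        report[index] = {
            "mean_a": float(va.mean()), "sd_a": float(va.std(ddof=1)) if va.size > 1 else 0.0,
            "mean_b": float(vb.mean()), "sd_b": float(vb.std(ddof=1)) if vb.size > 1 else 0.0,
            "summary_a": five_number_summary(va),
            "summary_b": five_number_summary(vb),
            "mean_difference": float(va.mean() - vb.mean()),
            "U": u,
            "p": p,
            "stars": significance_stars(p),
        }
    return report
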