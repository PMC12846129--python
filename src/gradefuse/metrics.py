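"""Evaluation metrics: classification agreement, ranking, clustering
stability and survival.

Accuracy, Cohen's kappa, precision/recall, ROC-AUC and the concordance index
are implemented directly from their definitions (AUC as the normalised
Mann–Whitney statistic with half-credit ties, the C-index over comparable
pairs ``t_i < t_j`` with ``event_i = 1``).  Clustering consistency is the
mean pairwise adjusted Rand index.  Kaplan–Meier estimation and the log-rank
test delegate to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score

from .exceptions import ConfigurationError, UndefinedMetricError

__all__ = [
    "ConfusionCounts", "AgreementStats", "PrecisionRecall", "SurvivalSummary",
    "ConsistencyStats", "confusion_counts", "accuracy", "multiclass_accuracy",
    "cohen_kappa", "precision_recall", "auc", "c_index",
    "clustering_consistency", "km_logrank",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(y_true, y_pred, positive=1) -> ConfusionCounts:
    yt = np.asarray(y_true) == positive
    yp = np.asarray(y_pred) == positive
    return ConfusionCounts(
        tp=int(np.sum(yt & yp)),
        tn=int(np.sum(~yt & ~yp)),
        fp=int(np.sum(~yt & yp)),
        fn=int(np.sum(yt & ~yp)),
    )


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if counts.total == 0:
        raise UndefinedMetricError("accuracy undefined on empty counts")
    return (counts.tp + counts.tn) / counts.total


def multiclass_accuracy(y_true, y_pred) -> float:
    """Trace-over-total accuracy for multi-class labels."""
    yt, yp = np.asarray(y_true), np.asarray(y_pred)
    if yt.size == 0:
        raise UndefinedMetricError("accuracy undefined on empty input")
    return float(np.mean(yt == yp))


@dataclass(frozen=True)
class AgreementStats:
    p_o: float
    p_e: float
    kappa: float


def cohen_kappa(y1, y2) -> AgreementStats:
    """Cohen's kappa = (p_o - p_e) / (1 - p_e) with multinomial chance p_e."""
    y1, y2 = np.asarray(y1), np.asarray(y2)
    if y1.shape != y2.shape or y1.size < 2:
        raise UndefinedMetricError("kappa needs >= 2 paired labels")
    n = y1.size
    labels = np.union1d(y1, y2)
    p_o = float(np.mean(y1 == y2))
    p_e = float(sum(np.mean(y1 == c) * np.mean(y2 == c) for c in labels))
    if np.isclose(p_e, 1.0):
        raise UndefinedMetricError("kappa undefined: chance agreement is 1 (single class)")
    return AgreementStats(p_o=p_o, p_e=p_e, kappa=(p_o - p_e) / (1.0 - p_e))


@dataclass(frozen=True)
class PrecisionRecall:
    precision: float | None
    recall: float | None

    @property
    def defined(self) -> bool:
        return self.precision is not None and self.recall is not None


def precision_recall(counts: ConfusionCounts) -> PrecisionRecall:
    """Precision = TP/(TP+FP), Recall = TP/(TP+FN); zero denominators yield
    an explicit ``None`` rather than a silent 0."""
    prec = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp > 0 else None
    rec = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else None
    return PrecisionRecall(precision=prec, recall=rec)


def auc(scores, labels) -> float:
    """Area under the ROC curve.

    Computed as the normalised Mann–Whitney U statistic with half credit for
    ties, which equals the trapezoidal integral of TPR over FPR.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == np.max(labels)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0 or np.unique(labels).size != 2:
        raise UndefinedMetricError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks give the half-credit tie policy
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def c_index(risks, times, events) -> float:
    """Concordance index over comparable pairs.

    A pair (i, j) is comparable when t_i < t_j and the earlier subject had an
    event; concordant when the earlier subject carries the higher predicted
    risk, with ties in risk receiving half credit.
    """
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    n = len(risks)
    num = 0.0
    n_pairs = 0
    for i in range(n):
        if not events[i]:
            continue
        earlier = times[i] < times
        n_pairs += int(earlier.sum())
        num += np.sum(risks[i] > risks[earlier]) + 0.5 * np.sum(risks[i] == risks[earlier])
    if n_pairs == 0:
        raise UndefinedMetricError("no comparable pairs for the C-index")
    return float(num / n_pairs)


@dataclass(frozen=True)
class ConsistencyStats:
    pairwise_ari: tuple[float, ...]
    mean_consistency: float


def clustering_consistency(runs, rng: np.random.Generator | None = None,
                           bootstrap_fraction: float | None = None) -> ConsistencyStats:
    """Mean pairwise adjusted Rand index across repeated cluster assignments.

    ``runs`` is a sequence of equal-length label vectors over a common
    patient set.  With ``bootstrap_fraction`` set, each pairwise comparison
    is restricted to a random common subsample.
    """
    runs = [np.asarray(r) for r in runs]
    if len(runs) < 2:
        raise ConfigurationError("consistency needs >= 2 assignment runs")
    n = len(runs[0])
    if any(len(r) != n for r in runs):
        raise ConfigurationError("assignment runs must cover the same patients")
    aris = []
    for a, b in combinations(range(len(runs)), 2):
        idx = np.arange(n)
        if bootstrap_fraction is not None:
            if rng is None:
                raise ConfigurationError("bootstrap mode needs an rng")
            idx = rng.choice(n, size=max(2, int(round(bootstrap_fraction * n))), replace=False)
        aris.append(float(adjusted_rand_score(runs[a][idx], runs[b][idx])))
    return ConsistencyStats(pairwise_ari=tuple(aris), mean_consistency=float(np.mean(aris)))


@dataclass
class SurvivalSummary:
    curves: dict = field(default_factory=dict)       # group -> DataFrame(time, survival, at_risk)
    medians: dict = field(default_factory=dict)      # group -> median time (may be nan)
    median_ci: dict = field(default_factory=dict)    # group -> (lo, hi)
    logrank_stat: float | None = None
    logrank_p: float | None = None


def km_logrank(times, events, groups) -> SurvivalSummary:
    """Kaplan–Meier curves per group plus the log-rank test across groups."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ConfigurationError("km_logrank needs >= 2 groups")
    if events.sum() == 0:
        raise UndefinedMetricError("no events observed")
    out = SurvivalSummary()
    for g in uniq:
        sel = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel], label=str(g))
        surv = kmf.survival_function_
        table = kmf.event_table
        out.curves[g] = pd.DataFrame({
            "time": surv.index.to_numpy(dtype=float),
            "survival": surv.iloc[:, 0].to_numpy(dtype=float),
            "at_risk": table["at_risk"].reindex(surv.index).to_numpy(dtype=float),
        })
        med = kmf.median_survival_time_
        out.medians[g] = float(med) if np.isfinite(med) else float("nan")
        try:
            from lifelines.utils import median_survival_times
            ci = median_survival_times(kmf.confidence_interval_)
            out.median_ci[g] = (float(ci.iloc[0, 0]), float(ci.iloc[0, 1]))
        except Exception:  # pragma: no cover - CI may be undefined at tiny n
            out.median_ci[g] = (float("nan"), float("nan"))
    if uniq.size == 2:
        a, b = uniq
        res = logrank_test(times[groups == a], times[groups == b],
                           events[groups == a], events[groups == b])
    else:
        res = multivariate_logrank_test(times, groups, events)
    out.logrank_stat = float(res.test_statistic)
    out.logrank_p = float(res.p_value)
    return out
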