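"""Evaluation statistics: ROC/PR AUC, bootstrap CIs, paired comparison,
sensitivity-matched thresholds and confusion counts.

Conventions used throughout: the decision rule is ``score >= threshold``
(ties positive); ROC AUC is the Mann-Whitney pair statistic (ties get half
credit); PR AUC is step-wise average precision; bootstrap CIs resample
volumes with replacement and take order statistics (the 125th and 4875th of
5000 sorted replicate values for a 95% interval).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .volume_data import BIOMARKERS

logger = logging.getLogger(__name__)


@dataclass
class ScoredSet:
    """Per-volume prediction scores and binary labels for the 5 biomarkers."""

    scores: np.ndarray  # (N, 5) in [0, 1]
    labels: np.ndarray  # (N, 5) binary
    volume_ids: list | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.scores.shape != self.labels.shape or self.scores.ndim != 2:
            raise ValueError("scores and labels must both be (N, K)")
        if self.scores.min() < 0 or self.scores.max() > 1:
            raise ValueError("scores must lie in [0, 1]")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        if self.volume_ids is None:
            self.volume_ids = [f"V{i:05d}" for i in range(len(self.scores))]
        if len(set(self.volume_ids)) != len(self.scores):
            raise ValueError("volume ids must be unique")

    def __len__(self) -> int:
        return len(self.scores)

    def resample(self, indices) -> "ScoredSet":
        idx = np.asarray(indices)
        return ScoredSet(
            scores=self.scores[idx],
            labels=self.labels[idx],
            volume_ids=[f"R{i:05d}" for i in range(len(idx))],
        )


@dataclass
class BootstrapCI:
    point: float
    lower: float
    upper: float
    n_boot: int
    seed: int


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


class SingleClassError(ValueError):
    """A metric was requested on labels containing only one class."""


# ---------------------------------------------------------------------------
# Core metrics
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUROC: P(score+ > score-) + 0.5 P(tie)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise SingleClassError("ROC AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, np.asarray(scores)))


def pr_auc(scores, labels) -> float:
    """Average precision (step-wise integration of the PR curve)."""
    labels = np.asarray(labels)
    if labels.sum() < 1:
        raise SingleClassError("PR AUC undefined without positive examples")
    return float(average_precision_score(labels, np.asarray(scores)))


def mean_metric_over_labels(per_label_values) -> float:
    """Unweighted arithmetic mean across biomarkers."""
    vals = [v for v in per_label_values if v is not None and np.isfinite(v)]
    if not vals:
        raise ValueError("no computable per-label metric")
    return float(np.mean(vals))


def computable_labels(metric, ss: ScoredSet) -> list:
    """Indices of the biomarkers on which ``metric`` is defined for this set."""
    out = []
    for k in range(ss.labels.shape[1]):
        try:
            metric(ss.scores[:, k], ss.labels[:, k])
            out.append(k)
        except SingleClassError:
            pass
    return out


def mean_auroc(ss: ScoredSet, labels: list | None = None) -> float:
    """Unweighted mean AUROC over biomarkers (optionally a fixed subset).

    Raises SingleClassError if any requested biomarker lacks both classes —
    so bootstrap resamples that lose a class get redrawn rather than silently
    averaging over fewer labels.
    """
    ks = range(ss.labels.shape[1]) if labels is None else labels
    return mean_metric_over_labels(
        [roc_auc(ss.scores[:, k], ss.labels[:, k]) for k in ks]
    )


def mean_aupr(ss: ScoredSet, labels: list | None = None) -> float:
    ks = range(ss.labels.shape[1]) if labels is None else labels
    return mean_metric_over_labels(
        [pr_auc(ss.scores[:, k], ss.labels[:, k]) for k in ks]
    )


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_indices(n: int, n_boot: int, seed: int) -> np.ndarray:
    """The (n_boot, n) resample index matrix; shared across models for pairing."""
    rng = np.random.default_rng(seed)
    return rng.integers(0, n, size=(n_boot, n))


def bootstrap_ci(
    metric,
    data: ScoredSet,
    n_boot: int = 5000,
    seed: int = 0,
    indices: np.ndarray | None = None,
    return_replicates: bool = False,
):
    """Resampling-unit bootstrap percentile CI via order statistics.

    The interval is (sorted[ceil(0.025 B)], sorted[floor(0.975 B)]) with
    1-based ranks — the 125th and 4875th of 5000 sorted replicate values.
    ``data`` is a ScoredSet (resampled volume-wise) or any indexable array.
    Resamples on which the metric is undefined (a class vanished) are
    redrawn and logged.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    def _take(idx):
        return data.resample(idx) if hasattr(data, "resample") else np.asarray(data)[idx]

    point = metric(data)
    if indices is None:
        indices = bootstrap_indices(len(data), n_boot, seed)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    values = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        idx = indices[b]
        for _ in range(1000):
            try:
                values[b] = metric(_take(idx))
                break
            except SingleClassError:
                redraws += 1
                idx = rng.integers(0, len(data), size=len(data))
        else:  # pragma: no cover - pathological inputs
            raise SingleClassError("metric undefined on 1000 consecutive redraws")
    if redraws:
        logger.info("bootstrap_ci: redrew %d degenerate resamples", redraws)
    srt = np.sort(values)  # replicates stay in draw order for pairing
    lo_rank = int(np.ceil(0.025 * n_boot))  # 125 at B=5000
    hi_rank = int(np.floor(0.975 * n_boot))  # 4875 at B=5000
    ci = BootstrapCI(
        point=float(point),
        lower=float(srt[max(lo_rank - 1, 0)]),
        upper=float(srt[hi_rank - 1]),
        n_boot=n_boot,
        seed=seed,
    )
    return (ci, values) if return_replicates else ci


def compare_models(
    metric, data_a: ScoredSet, data_b: ScoredSet, n_boot: int = 5000, seed: int = 0
) -> float:
    """Paired comparison p-value: the same bootstrap resample indices are
    applied to both models' scored sets and the per-resample metric values
    are compared with a Wilcoxon signed-rank test."""
    if len(data_a) != len(data_b):
        raise ValueError("paired comparison needs equally sized scored sets")
    idx = bootstrap_indices(len(data_a), n_boot, seed)
    _, va = bootstrap_ci(metric, data_a, n_boot, seed, indices=idx, return_replicates=True)
    _, vb = bootstrap_ci(metric, data_b, n_boot, seed, indices=idx, return_replicates=True)
    return wilcoxon_signed_rank(va, vb)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(a, b=None) -> float:
    """Two-sided signed-rank p-value on paired values (or differences).

    Zero differences are dropped. Exact null enumeration for n <= 25 tie-free
    differences; normal approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    d = a - np.asarray(b, dtype=float) if b is not None else a
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    ranks_tied = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 25 and not ranks_tied) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method, correction=False)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Thresholds and confusion counts
# ---------------------------------------------------------------------------

def sensitivity_matched_threshold(scores, labels, target_sensitivity: float) -> float:
    """Largest threshold t (rule: score >= t is positive) whose sensitivity on
    the tuning set reaches the target — i.e., maximal specificity subject to
    the sensitivity constraint. ``target=0`` returns a value above the
    maximum score (nothing classified positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.sum() < 1:
        raise ValueError("need at least one positive to match sensitivity")
    if not 0 <= target_sensitivity <= 1:
        raise ValueError("target sensitivity must lie in [0, 1]")
    pos = scores[labels == 1]
    above_max = float(np.nextafter(scores.max(), np.inf))
    candidates = [above_max] + sorted(np.unique(scores), reverse=True)
    for t in candidates:
        sens = float((pos >= t).mean())
        if sens >= target_sensitivity:
            return float(t)
    return float(pos.min())  # target 1.0 fallback: capture every positive


def confusion_at_threshold(scores, labels, threshold: float) -> ConfusionCounts:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (labels == 1))),
        fp=int(np.sum(pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
        tn=int(np.sum(~pred & (labels == 0))),
    )


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def evaluate_scored_set(ss: ScoredSet, n_boot: int = 1000, seed: int = 0) -> dict:
    """Per-biomarker and mean AUROC/AUPRC with bootstrap 95% CIs, as a dict
    matching the metrics-report JSON layout."""
    report = {"per_biomarker": {}, "n_boot": n_boot, "seed": seed}
    for k, name in enumerate(BIOMARKERS):
        entry = {}
        for label_metric, key in ((roc_auc, "auroc"), (pr_auc, "auprc")):
            try:
                ci = bootstrap_ci(
                    lambda s, k=k, m=label_metric: m(s.scores[:, k], s.labels[:, k]),
                    ss,
                    n_boot=n_boot,
                    seed=seed,
                )
                entry[key] = ci.point
                entry[f"{key}_ci"] = [ci.lower, ci.upper]
            except SingleClassError:
                entry[key] = None
                entry[f"{key}_ci"] = None
        report["per_biomarker"][name] = entry
    for mean_fn, base_metric, key in (
        (mean_auroc, roc_auc, "mean_auroc"),
        (mean_aupr, pr_auc, "mean_auprc"),
    ):
        ks = computable_labels(base_metric, ss)
        if not ks:
            report[key] = None
            continue
        ci = bootstrap_ci(lambda d, f=mean_fn, ks=ks: f(d, ks), ss,
                          n_boot=n_boot, seed=seed)
        report[key] = {"point": ci.point, "ci": [ci.lower, ci.upper],
                       "labels_used": [BIOMARKERS[k] for k in ks]}
    return report
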