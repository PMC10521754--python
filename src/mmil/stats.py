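"""Evaluation statistics: ROC/AUC, Youden-optimal cutoff, bootstrap CIs,
and the Wilcoxon rank-sum test.

AUC is the tie-corrected Mann-Whitney pair-counting statistic computed from
midranks. The Youden cutoff maximizes J = sensitivity + specificity - 1 over
observed-score thresholds (rule: score >= cutoff predicts positive), with
ties broken toward the lower cutoff (higher sensitivity); the reported
cutoff is the midpoint of the gap below the winning threshold. Bootstrap
intervals are percentile intervals from class-stratified resamples. The
rank-sum test enumerates all rank assignments exactly for combined n <= 20
(midranks under ties) and otherwise uses the tie-corrected normal
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as _sps

__all__ = [
    "EvalReport",
    "roc_auc",
    "youden_cutoff",
    "bootstrap_ci",
    "wilcoxon_rank_sum",
    "evaluate_scores",
]


def _validate_two_class(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not ((labels == 0).any() and (labels == 1).any()):
        raise ValueError("both classes must be present")
    return scores, labels


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC with midrank tie correction."""
    scores, labels = _validate_two_class(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = _sps.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc)


def youden_cutoff(scores, labels) -> tuple[float, float, float]:
    """(cutoff, sensitivity, specificity) maximizing J over observed thresholds."""
    scores, labels = _validate_two_class(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    uniq = np.unique(scores)
    best = None
    for t in uniq:  # ascending; strict improvement keeps the lowest maximizer
        sens = float((pos >= t).mean())
        spec = float((neg < t).mean())
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    _, t, sens, spec = best
    below = uniq[uniq < t]
    cutoff = float((t + below[-1]) / 2.0) if len(below) else float(t)
    return cutoff, sens, spec


def bootstrap_ci(
    metric,
    scores,
    labels,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile interval from B class-stratified bootstrap resamples."""
    if B < 100:
        raise ValueError("B must be at least 100")
    scores, labels = _validate_two_class(scores, labels)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    vals = np.empty(B)
    for b in range(B):
        idx = np.concatenate(
            [
                rng.choice(pos_idx, size=len(pos_idx), replace=True),
                rng.choice(neg_idx, size=len(neg_idx), replace=True),
            ]
        )
        vals[b] = metric(scores[idx], labels[idx])
    alpha = (1.0 - level) / 2.0
    return (
        float(np.quantile(vals, alpha)),
        float(np.quantile(vals, 1.0 - alpha)),
    )


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p by full enumeration of rank assignments (midranks)."""
    pooled = np.concatenate([a, b])
    ranks = _sps.rankdata(pooled)
    n1 = len(a)
    w_obs = ranks[:n1].sum()
    mean_w = ranks.sum() * n1 / len(pooled)
    dev = abs(w_obs - mean_w)
    count = 0
    total = comb(len(pooled), n1)
    for subset in combinations(range(len(pooled)), n1):
        if abs(ranks[list(subset)].sum() - mean_w) >= dev - 1e-9:
            count += 1
    return count / total


def wilcoxon_rank_sum(sample_a, sample_b) -> tuple[float, float]:
    """(rank-sum statistic of sample_a, two-sided p).

    Exact enumeration for combined n <= 20; tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    ranks = _sps.rankdata(np.concatenate([a, b]))
    w = float(ranks[: len(a)].sum())
    if len(a) + len(b) <= 20:
        return w, float(_exact_rank_sum_p(a, b))
    res = _sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return w, float(res.pvalue)


@dataclass
class EvalReport:
    """Pooled (and optionally per-fold) discrimination summary."""

    auc: float
    ci: tuple
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    n: int
    bootstrap_B: int
    ci_level: float
    seed: int
    per_fold_auc: list | None = None

    def __post_init__(self):
        lo, hi = self.ci
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC out of [0, 1]")
        if lo > self.auc + 1e-12 or hi < self.auc - 1e-12:
            raise ValueError("CI must bracket the point estimate")

    def to_dict(self) -> dict:
        d = {
            "auc": self.auc,
            "ci": list(self.ci),
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "n": self.n,
            "bootstrap_B": self.bootstrap_B,
            "ci_level": self.ci_level,
            "seed": self.seed,
        }
        if self.per_fold_auc is not None:
            d["per_fold_auc"] = list(self.per_fold_auc)
        return d


def evaluate_scores(
    scores,
    labels,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    per_fold_auc: list | None = None,
) -> EvalReport:
    """Full report: AUC + bootstrap CI + Youden cutoff metrics."""
    scores, labels = _validate_two_class(scores, labels)
    auc = roc_auc(scores, labels)
    lo, hi = bootstrap_ci(roc_auc, scores, labels, B=B, level=level, seed=seed)
    ci = (min(lo, auc), max(hi, auc))
    cutoff, sens, spec = youden_cutoff(scores, labels)
    pred = (scores >= cutoff).astype(int)
    acc = float((pred == labels).mean())
    return EvalReport(
        auc=auc,
        ci=ci,
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        n=len(labels),
        bootstrap_B=B,
        ci_level=level,
        seed=seed,
        per_fold_auc=per_fold_auc,
    )
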