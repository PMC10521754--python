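"""ROC/AUC, Youden cutoff, bootstrap CI and rank-sum oracles."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score, roc_curve

from mmil.stats import (
    bootstrap_ci,
    evaluate_scores,
    roc_auc,
    wilcoxon_rank_sum,
    youden_cutoff,
)


def _brute_force_auc(scores, labels):
    """Pair-counting oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auc_printed_toy_case():
    labels = np.array([1, 0, 1, 0])
    scores = np.array([0.9, 0.8, 0.7, 0.1])
    assert roc_auc(scores, labels) == 0.75
    assert _brute_force_auc(scores, labels) == 0.75


def test_auc_edge_cases():
    assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert roc_auc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1]) == 0.5


@pytest.mark.parametrize("seed", range(10))
def test_auc_agrees_with_sklearn_and_pair_counting(seed):
    rng = np.random.default_rng(seed)
    n = 50
    labels = rng.integers(0, 2, n)
    if labels.sum() in (0, n):
        labels[0] = 1 - labels[0]
    scores = np.round(rng.random(n), 2)  # ties likely
    ours = roc_auc(scores, labels)
    assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-10)
    assert ours == pytest.approx(_brute_force_auc(scores, labels), abs=1e-10)


def test_auc_requires_both_classes():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.9], [1, 1])


def _exhaustive_youden(scores, labels):
    pos, neg = scores[labels == 1], scores[labels == 0]
    best = None
    for t in np.unique(scores):
        sens = (pos >= t).mean()
        spec = (neg < t).mean()
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    return best


def test_youden_matches_exhaustive_enumeration():
    labels = np.array([1, 0, 1, 0])
    scores = np.array([0.9, 0.8, 0.7, 0.1])
    cutoff, sens, spec = youden_cutoff(scores, labels)
    j_best, t_best, sens_o, spec_o = _exhaustive_youden(scores, labels)
    assert (sens, spec) == (sens_o, spec_o)
    assert sens + spec - 1 == pytest.approx(j_best)
    # reported cutoff sits in the gap just below the winning threshold
    assert cutoff < t_best
    assert (scores >= cutoff).sum() == (scores >= t_best).sum()


def test_youden_perfect_separation_midpoint():
    labels = np.array([0, 0, 1, 1])
    scores = np.array([0.1, 0.2, 0.8, 0.9])
    cutoff, sens, spec = youden_cutoff(scores, labels)
    assert (sens, spec) == (1.0, 1.0)
    assert cutoff == pytest.approx(0.5)  # midpoint of the separating gap


def test_youden_degenerate_equal_scores():
    cutoff, sens, spec = youden_cutoff(np.full(6, 0.3), np.array([0, 1, 0, 1, 0, 1]))
    assert sens + spec - 1 == pytest.approx(0.0)


def test_bootstrap_deterministic_and_degenerate():
    rng = np.random.default_rng(0)
    labels = np.r_[np.ones(20, int), np.zeros(20, int)]
    scores = np.r_[rng.normal(1, 1, 20), rng.normal(0, 1, 20)]
    a = bootstrap_ci(roc_auc, scores, labels, B=200, seed=7)
    b = bootstrap_ci(roc_auc, scores, labels, B=200, seed=7)
    assert a == b
    # metric constant under resampling -> zero-width interval
    sep = np.r_[np.full(10, 0.9), np.full(10, 0.1)]
    lab = np.r_[np.ones(10, int), np.zeros(10, int)]
    lo, hi = bootstrap_ci(roc_auc, sep, lab, B=200, seed=1)
    assert lo == hi == 1.0


def test_bootstrap_requires_minimum_replicates():
    with pytest.raises(ValueError):
        bootstrap_ci(roc_auc, np.array([0.1, 0.9]), np.array([0, 1]), B=10)


def test_bootstrap_coverage_of_known_auc():
    """95% percentile intervals cover the large-sample binormal AUC in
    >= 90% of replicates (n = 200 per replicate)."""
    from scipy.stats import norm

    mu = 1.0
    truth = norm.cdf(mu / np.sqrt(2))
    cover = 0
    reps = 200
    for rep in range(reps):
        rng = np.random.default_rng(rep)
        scores = np.r_[rng.normal(mu, 1, 100), rng.normal(0, 1, 100)]
        labels = np.r_[np.ones(100, int), np.zeros(100, int)]
        lo, hi = bootstrap_ci(roc_auc, scores, labels, B=300, seed=rep)
        cover += lo <= truth <= hi
    assert cover / reps >= 0.90


def test_rank_sum_identical_samples_p_one():
    a = np.array([1.0, 2.0, 3.0])
    _, p = wilcoxon_rank_sum(a, a.copy())
    assert p == 1.0


def test_rank_sum_exact_enumeration_small_case():
    _, p = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
    assert p == pytest.approx(2 / 6)


def test_rank_sum_exact_and_asymptotic_agree():
    rng = np.random.default_rng(3)
    for _ in range(10):
        a = rng.normal(size=10)
        b = rng.normal(0.5, 1, size=10)
        _, p_exact = wilcoxon_rank_sum(a, b)  # combined n = 20 -> exact
        from scipy.stats import mannwhitneyu

        p_asym = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert abs(p_exact - p_asym) < 0.02


def test_rank_sum_empty_sample_raises():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0])


def test_auc_equals_trapezoidal_roc_area():
    rng = np.random.default_rng(8)
    labels = np.r_[np.ones(30, int), np.zeros(30, int)]
    scores = np.round(rng.random(60), 2)
    fpr, tpr, _ = roc_curve(labels, scores)
    assert roc_auc(scores, labels) == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-10)


def test_evaluate_scores_report_invariants():
    rng = np.random.default_rng(1)
    labels = np.r_[np.ones(25, int), np.zeros(25, int)]
    scores = np.r_[rng.normal(1, 1, 25), rng.normal(0, 1, 25)]
    rep = evaluate_scores(scores, labels, B=200, seed=0)
    assert 0 <= rep.auc <= 1
    assert rep.ci[0] <= rep.auc <= rep.ci[1]
    for v in (rep.sensitivity, rep.specificity, rep.accuracy):
        assert 0 <= v <= 1
    d = rep.to_dict()
    assert d["n"] == 50 and d["bootstrap_B"] == 200
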