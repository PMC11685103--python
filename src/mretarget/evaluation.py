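"""Metrics, threshold selection, and functional-efficacy statistics.

AUC is rank-based with ties averaged; AUPRC uses step interpolation
(average precision).  The operating-point metrics are computed at a caller
threshold (default 0.5), with the Youden-index maximizer reported as the
data-driven alternative.  The rank-sum test is exact (full enumeration)
for small samples and a tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from mretarget.errors import DataError

#: Combined-sample-size cap for the exact rank-sum enumeration.
EXACT_RANKSUM_MAX_N = 18


def _check_two_classes(labels: np.ndarray) -> None:
    classes = np.unique(labels)
    if len(classes) < 2:
        raise DataError(f"need both classes, got only {classes.tolist()}")


def auc_score(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC (ties averaged): P(s_pos > s_neg) + 0.5 P(equal)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auprc_score(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve by step interpolation."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    tp = np.cumsum(y)
    precision = tp / np.arange(1, len(y) + 1)
    n_pos = labels.sum()
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


@dataclass(frozen=True)
class MetricReport:
    auc: float
    auprc: float
    accuracy: float
    f1: float
    sensitivity: float
    specificity: float
    precision: float
    recall: float
    threshold_used: float
    ci_auc: Optional[tuple[float, float]] = None

    def as_dict(self) -> dict:
        d = {
            "auc": self.auc, "auprc": self.auprc, "accuracy": self.accuracy,
            "f1": self.f1, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "precision": self.precision,
            "recall": self.recall, "threshold_used": self.threshold_used,
        }
        if self.ci_auc is not None:
            d["ci_auc_lo"], d["ci_auc_hi"] = self.ci_auc
        return d


def binary_metrics(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
    bootstrap_ci: bool = False,
    n_boot: int = 2000,
    seed: int = 0,
) -> MetricReport:
    """Full metric report at one operating threshold (predict positive when
    score >= threshold); optional bootstrap CI on the AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    pred = scores >= threshold
    pos, neg = labels == 1, labels == 0
    tp = int(np.sum(pred & pos))
    tn = int(np.sum(~pred & neg))
    fp = int(np.sum(pred & neg))
    fn = int(np.sum(~pred & pos))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    ci = bootstrap_auc_ci(scores, labels, n_boot=n_boot, seed=seed) if bootstrap_ci else None
    return MetricReport(
        auc=auc_score(scores, labels),
        auprc=auprc_score(scores, labels),
        accuracy=(tp + tn) / len(labels),
        f1=f1,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        recall=sens,
        threshold_used=threshold,
        ci_auc=ci,
    )


def bootstrap_auc_ci(scores, labels, n_boot=2000, seed=0, alpha=0.05):
    """Percentile bootstrap CI on the AUC, resampling within each class."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, len(pos), replace=True), rng.choice(neg, len(neg), replace=True)]
        )
        aucs[b] = auc_score(scores[idx], labels[idx])
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return (float(lo), float(hi))


def youden_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Observed score maximizing J = sensitivity + specificity - 1.

    Candidate thresholds are the observed score values (predict positive
    when score >= threshold); ties resolved toward the smallest score.
    Warns when even the best J is <= 0 (anti-predictive scores).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    best_j, best_t = -np.inf, None
    for t in np.unique(scores):  # ascending
        pred = scores >= t
        sens = np.sum(pred & (labels == 1)) / n_pos
        spec = np.sum(~pred & (labels == 0)) / n_neg
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_t = j, float(t)
    if best_j <= 0:
        warnings.warn(
            f"youden_threshold: maximal J = {best_j:.3f} <= 0; scores are "
            "non-predictive or anti-predictive"
        )
    return best_t


# ---------------------------------------------------------------------------
# Rank-sum and KS comparisons
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-tailed two-sample rank-sum test of x vs y.

    Returns ``(W, p)`` where W is the rank sum of ``x``.  For combined
    sample sizes up to ``EXACT_RANKSUM_MAX_N`` the p-value is exact (all
    label assignments enumerated, ties handled through midranks); larger
    samples use the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DataError("rank-sum test requires two non-empty samples")
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w_obs = float(ranks[:n1].sum())
    mean_w = n1 * (n1 + n2 + 1) / 2.0

    if n1 + n2 <= EXACT_RANKSUM_MAX_N:
        dev_obs = abs(w_obs - mean_w)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            w = ranks[list(combo)].sum()
            if abs(w - mean_w) >= dev_obs - 1e-9:
                count += 1
            total += 1
        return w_obs, count / total

    # normal approximation with tie correction
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return w_obs, 1.0
    z = (w_obs - mean_w) / np.sqrt(var_w)
    return w_obs, float(2 * stats.norm.sf(abs(z)))


def ks_comparison(x, y, alternative: str = "greater") -> tuple[float, float]:
    """One-sided two-sample Kolmogorov-Smirnov test (model-vs-model style).

    ``alternative='greater'`` tests whether the empirical CDF of x lies
    above that of y, i.e. x is stochastically smaller — the usual direction
    for repression fold changes.
    """
    res = stats.ks_2samp(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def functional_efficacy(
    log2_fc: Mapping[str, float],
    groups: Mapping[str, set],
    scores: Optional[Mapping[str, float]] = None,
    top_n: Optional[int] = 100,
    method: str = "wilcoxon",
) -> dict[str, dict]:
    """Compare perturbation responses of predicted-target groups vs no-site genes.

    ``log2_fc`` maps gene -> log2 fold change; ``groups`` maps group name
    (must include ``"no_site"``) -> gene set, with all groups disjoint.
    Target groups are optionally restricted to their ``top_n`` genes by
    ``scores`` before testing.  Each target group is tested against the
    no-site genes with the two-tailed rank-sum test (``method="wilcoxon"``)
    or the one-sided KS test (``method="ks"``).
    """
    if "no_site" not in groups:
        raise DataError("functional_efficacy: groups must include 'no_site'")
    names = list(groups)
    for i, a in enumerate(names):
        if not groups[a]:
            raise DataError(f"functional_efficacy: group {a!r} is empty")
        for b in names[i + 1 :]:
            overlap = groups[a] & groups[b]
            if overlap:
                raise DataError(
                    f"functional_efficacy: groups {a!r} and {b!r} overlap "
                    f"({len(overlap)} genes)"
                )
    if method not in ("wilcoxon", "ks"):
        raise DataError(f"unknown method {method!r}")

    ref = np.array([log2_fc[g] for g in groups["no_site"] if g in log2_fc])
    if len(ref) == 0:
        raise DataError("functional_efficacy: no fold changes for 'no_site' genes")

    out: dict[str, dict] = {}
    for name, genes in groups.items():
        if name == "no_site":
            continue
        members = [g for g in genes if g in log2_fc]
        if scores is not None and top_n is not None:
            members = sorted(members, key=lambda g: -scores.get(g, -np.inf))[:top_n]
        vals = np.array([log2_fc[g] for g in members])
        if len(vals) == 0:
            raise DataError(f"functional_efficacy: no fold changes for group {name!r}")
        if method == "wilcoxon":
            stat, p = wilcoxon_rank_sum(vals, ref)
        else:
            stat, p = ks_comparison(vals, ref, alternative="greater")
        out[name] = {
            "n": len(vals),
            "n_no_site": len(ref),
            "statistic": stat,
            "p_value": p,
            "median_log2_fc": float(np.median(vals)),
            "median_no_site": float(np.median(ref)),
        }
    return out
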