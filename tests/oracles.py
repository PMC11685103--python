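"""Independent brute-force oracles used only by the tests.

Everything here is deliberately written from the definitions, in a
different style from the package implementation, so agreement between the
two is meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE_PAIRS = {("G", "U"), ("U", "G")}


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def oracle_scan(mirna: str, tseq: str, lo: int, hi: int):
    """Naive all-anchors, all-definitions scan.

    Tests every category definition independently at every anchor via
    substring comparison, applies category precedence per anchor, then
    keeps one strongest site per match_start.  Returns a sorted list of
    (match_start, match_end, category, anchor) tuples.
    """
    per_anchor = []
    for a in range(lo, hi + 3):
        cats = []
        # canonical definitions, tested independently by substring equality
        seed6_ok = a - 6 >= lo and a <= hi and tseq[a - 6 : a] == revcomp(mirna[1:7])
        seed7_ok = a - 7 >= lo and a <= hi and tseq[a - 7 : a] == revcomp(mirna[1:8])
        nine_ok = a - 9 >= lo and a <= hi and tseq[a - 9 : a] == revcomp(mirna[1:10])
        a_ok = a < hi and tseq[a] == "A"
        if nine_ok:
            cats.append(("9mer", a - 9, a))
        if seed7_ok and a_ok:
            cats.append(("8mer", a - 7, a + 1))
        if seed7_ok:
            cats.append(("7mer-m8", a - 7, a))
        if seed6_ok and a_ok:
            cats.append(("7mer-A1", a - 6, a + 1))
        if seed6_ok:
            cats.append(("6mer", a - 6, a))
        canonical = bool(cats)

        # centered: miRNA 4-14 fully WC-paired, footprint inside the region
        if (
            not canonical
            and a - 13 >= lo
            and a - 2 <= hi
            and tseq[a - 13 : a - 2] == revcomp(mirna[3:14])
        ):
            pmin, pmax = 4, 14
            while pmin > 1:
                i = a - (pmin - 2)
                if lo <= i < hi and tseq[i] == _COMP[mirna[pmin - 2]]:
                    pmin -= 1
                else:
                    break
            while pmax < len(mirna):
                i = a - pmax
                if lo <= i < hi and tseq[i] == _COMP[mirna[pmax]]:
                    pmax += 1
                else:
                    break
            cats.append(("centered", a - pmax + 1, a - pmin + 2))

        # compensatory: exactly one non-WC seed position + a 4-run in 13-17
        if not cats and a - 6 >= lo and a <= hi:
            want = revcomp(mirna[1:7])
            got = tseq[a - 6 : a]
            bad = [k for k in range(6) if got[k] != want[k]]
            if len(bad) == 1:
                run_a = a - 15 >= lo and tseq[a - 15 : a - 11] == revcomp(mirna[12:16])
                run_b = a - 16 >= lo and tseq[a - 16 : a - 12] == revcomp(mirna[13:17])
                if run_a or run_b:
                    cats.append(("compensatory", a - 6, a))

        if cats:
            per_anchor.append((a, cats[0]))  # first = strongest by order above

    order = {c: i for i, c in enumerate(
        ["9mer", "8mer", "7mer-m8", "7mer-A1", "6mer", "centered", "compensatory"]
    )}
    best_by_start: dict[int, tuple] = {}
    for a, (cat, ms, me) in per_anchor:
        key = (order[cat], a)
        cur = best_by_start.get(ms)
        if cur is None or key < (order[cur[2]], cur[3]):
            best_by_start[ms] = (ms, me, cat, a)
    return sorted(best_by_start.values(), key=lambda r: (r[0], order[r[2]]))


def brute_auc(scores, labels) -> float:
    """AUC as the literal pairwise count P(s+ > s-) + 0.5 P(equal)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def exhaustive_youden(scores, labels):
    """Best (smallest) observed score threshold by exhaustive J search."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    best = None
    for t in sorted(set(scores.tolist())):
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
        fn = sum(1 for s, y in zip(scores, labels) if s < t and y == 1)
        tn = sum(1 for s, y in zip(scores, labels) if s < t and y == 0)
        fp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 0)
        j = tp / (tp + fn) + tn / (tn + fp) - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, t)
    return best[1]


def exact_ranksum_p(x, y) -> float:
    """Exact two-tailed rank-sum p-value via the Mann-Whitney U statistic.

    Enumerates every assignment of the pooled values to the two groups and
    counts assignments whose U deviates from its mean at least as much as
    the observed one.  Ties contribute 0.5 per pair, so this agrees with
    midrank-based statistics.
    """
    x, y = list(x), list(y)
    pooled = x + y
    n1, n2 = len(x), len(y)

    def u_stat(a, b):
        u = 0.0
        for va in a:
            for vb in b:
                if va > vb:
                    u += 1.0
                elif va == vb:
                    u += 0.5
        return u

    mean_u = n1 * n2 / 2.0
    dev_obs = abs(u_stat(x, y) - mean_u)
    count = total = 0
    idx = range(n1 + n2)
    for combo in itertools.combinations(idx, n1):
        sel = set(combo)
        a = [pooled[i] for i in idx if i in sel]
        b = [pooled[i] for i in idx if i not in sel]
        if abs(u_stat(a, b) - mean_u) >= dev_obs - 1e-9:
            count += 1
        total += 1
    return count / total


def beta_bayes_auc(pos_beta, neg_beta, n=200_000, seed=123) -> float:
    """Monte-Carlo AUC of the Bayes-optimal score for two-feature data with
    both features iid Beta(pos) in class 1 and Beta(neg) in class 0."""
    from scipy.stats import beta as beta_dist

    rng = np.random.default_rng(seed)
    ap, bp = pos_beta
    an, bn = neg_beta

    def llr(x):
        return (
            beta_dist.logpdf(x, ap, bp) - beta_dist.logpdf(x, an, bn)
        ).sum(axis=1)

    xp = rng.beta(ap, bp, size=(n, 2))
    xn = rng.beta(an, bn, size=(n, 2))
    sp, sn = llr(xp), llr(xn)
    # pairwise AUC by rank trick on the pooled sample (exact for continuous)
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([sp, sn]))
    return float((ranks[:n].sum() - n * (n + 1) / 2) / (n * n))


def conv_chain_lengths(input_len, conv_layers, pool_size, pool_after_each_but_last=True):
    """Closed-form per-layer lengths: floor((L-k)/s)+1 per conv, floor(L/p) per pool."""
    out = []
    L = input_len
    for i, (_f, k, s) in enumerate(conv_layers):
        L = (L - k) // s + 1
        out.append(("conv", L))
        if pool_after_each_but_last and i < len(conv_layers) - 1:
            L = L // pool_size
            out.append(("pool", L))
    return out
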