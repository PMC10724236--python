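"""Naive reference implementations used as independent oracles in tests.

These deliberately use plain-Python loops, direct slice arithmetic and
recursion — no prefix sums, no vectorisation — so they share no code path
with the package implementations they check.
"""

from scipy.stats import mannwhitneyu


def naive_test(a, b):
    """Reference Mann-Whitney candidate test (mirrors the documented rule)."""
    if len(a) < 2 or len(b) < 2:
        return 1.0
    vals = list(a) + list(b)
    if all(v == vals[0] for v in vals):
        return 1.0
    p = float(mannwhitneyu(list(a), list(b), alternative="two-sided",
                           method="auto").pvalue)
    return min(max(p, 5e-324), 1.0)


def naive_segment(a, b, min_size):
    """Exhaustive recursive segmentation by direct evaluation of every
    breakpoint: score = |mean(dL) - mean(dR)| computed from raw slices,
    leftmost maximum; split while a sub-segment is more significant than
    its parent. Returns sorted (lo, hi, p) triples."""
    d = [x - y for x, y in zip(a, b)]

    def mean(seg):
        return sum(seg) / len(seg)

    def rec(lo, hi):
        p = naive_test(a[lo:hi], b[lo:hi])
        n = hi - lo
        if n >= 2 * min_size:
            best_k, best_score = None, None
            for k in range(lo + min_size, hi - min_size + 1):
                score = abs(mean(d[lo:k]) - mean(d[k:hi]))
                if best_score is None or score > best_score:
                    best_k, best_score = k, score
            p_left = naive_test(a[lo:best_k], b[lo:best_k])
            p_right = naive_test(a[best_k:hi], b[best_k:hi])
            if min(p_left, p_right) < p - 1e-12:
                return rec(lo, best_k) + rec(best_k, hi)
        return [(lo, hi, p)]

    return sorted(rec(0, len(d)))


def naive_retention(candidates, min_cpgs, q_threshold, min_diff):
    """Brute-force application of the published retention rule."""
    kept = []
    for c in candidates:
        if c.n_cpgs < min_cpgs:
            continue
        if not c.q_value < q_threshold:
            continue
        if not abs(c.mean_diff) > min_diff:
            continue
        kept.append(c)
    return kept
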