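"""Independent brute-force oracles used to cross-check the package.

These deliberately use different algorithms from the implementations they
verify (fixpoint merging, dynamic-programming reachability, exhaustive tail
sums) and must stay free of rg4i imports.
"""

from __future__ import annotations

from math import comb

from scipy.stats import chi2 as chi2_dist


def brute_force_peaks(counts, min_cov=10, merge_gap=30, min_width=30):
    """Literal reading of the peak rules via fixpoint interval merging."""
    positions = [i for i, c in enumerate(counts) if c > min_cov]
    runs = []
    for pos in positions:
        if runs and pos == runs[-1][1]:
            runs[-1][1] = pos + 1
        else:
            runs.append([pos, pos + 1])
    # merge any pair with gap < merge_gap until nothing changes
    changed = True
    while changed:
        changed = False
        for i in range(len(runs) - 1):
            if runs[i + 1][0] - runs[i][1] < merge_gap:
                runs[i][1] = runs[i + 1][1]
                del runs[i + 1]
                changed = True
                break
    return [(s, e) for s, e in runs if e - s >= min_width]


def g4_presence_bruteforce(sequence, min_run=2, max_loop=12, n_runs=4):
    """DP reachability over (run index, run-end position) decompositions."""
    seq = sequence.upper().replace("U", "T")
    n = len(seq)

    def run_ends_from(start):
        """Exclusive end positions of all-G runs of length >= min_run at start."""
        ends = []
        j = start
        while j < n and seq[j] == "G":
            j += 1
            if j - start >= min_run:
                ends.append(j)
        return ends

    ends = set()
    for i in range(n):
        ends.update(run_ends_from(i))
    for _ in range(n_runs - 1):
        nxt = set()
        for j in ends:
            for loop in range(1, max_loop + 1):
                nxt.update(run_ends_from(j + loop))
        ends = nxt
        if not ends:
            return False
    return bool(ends)


def bh_bruteforce(pvals):
    """Step-up BH adjusted p-values, computed from the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, m * pvals[i] / rank)
        adjusted[i] = running_min
    return adjusted


def yates_chi2(k1, n1, k2, n2):
    """Textbook 2x2 chi-square with Yates continuity correction."""
    a, b = k1, n1 - k1
    c, d = k2, n2 - k2
    n = a + b + c + d
    num = n * (max(abs(a * d - b * c) - n / 2, 0.0)) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    if den == 0:
        return 0.0, 1.0
    stat = num / den
    return stat, float(chi2_dist.sf(stat, 1))


def hypergeom_right_tail(k, M, K, n):
    """P(X >= k) for X ~ Hypergeom(M, K, n), by exhaustive summation."""
    total = 0
    for kk in range(k, min(K, n) + 1):
        if n - kk <= M - K:
            total += comb(K, kk) * comb(M - K, n - kk)
    return total / comb(M, n)


def fisher_two_sided(a, b, c, d):
    """Two-sided Fisher exact p by summing tables as or less probable."""
    M, K, n = a + b + c + d, a + b, a + c
    denom = comb(M, n)

    def pmf(x):
        if x < 0 or x > K or n - x < 0 or n - x > M - K:
            return 0.0
        return comb(K, x) * comb(M - K, n - x) / denom

    p_obs = pmf(a)
    return min(1.0, sum(pmf(x) for x in range(min(K, n) + 1) if pmf(x) <= p_obs * (1 + 1e-9)))


def gar_class_bruteforce(sequence):
    """Classify by testing every substring against the four repeat strings."""
    subs = {
        sequence[i:j]
        for i in range(len(sequence))
        for j in range(i + 4, min(i + 10, len(sequence)) + 1)
    }
    if {"RGGRGG", "RGRGRG", "RGGRGGRGG"} & subs:
        return "CLASS_A"
    if "RGRG" in subs:
        return "CLASS_B"
    return "NONE"
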