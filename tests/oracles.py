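"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the code paths they check: the matching oracle
enumerates every one-to-one assignment (including crossing ones), and the
edit-distance oracle enumerates every (deletion set, insertion set,
shift pairing) decomposition.
"""

from itertools import combinations, permutations

import numpy as np


def optimal_matching(truth, estimate, window):
    """(max hits, min total |dt| among max-hit matchings) by enumeration."""
    t = list(truth)
    e = list(estimate)
    best_hits, best_cost = 0, 0.0
    for k in range(min(len(t), len(e)), -1, -1):
        if k < best_hits:
            break
        found = False
        for ti in combinations(range(len(t)), k):
            for ej in permutations(range(len(e)), k):
                ds = [abs(t[i] - e[j]) for i, j in zip(ti, ej)]
                if all(d < window for d in ds):
                    cost = sum(ds)
                    if not found or cost < best_cost:
                        best_hits, best_cost = k, cost
                        found = True
        if found:
            break
    return best_hits, best_cost


def edit_distance(truth, estimate, q):
    """Victor-Purpura cost by enumeration over all pairings."""
    t = list(truth)
    e = list(estimate)
    best = float("inf")
    for k in range(min(len(t), len(e)) + 1):
        for ti in combinations(range(len(t)), k):
            for ej in permutations(range(len(e)), k):
                cost = (len(t) - k) + (len(e) - k) \
                    + sum(min(q * abs(t[i] - e[j]), 2.0)
                          for i, j in zip(ti, ej))
                best = min(best, cost)
    return best


def triangle_overlap_score(truth, estimate, e, n_points=10_000):
    """CosMIC by direct numeric integration of the membership functions."""
    t = np.asarray(truth, dtype=float)
    s = np.asarray(estimate, dtype=float)
    if t.size == 0 and s.size == 0:
        return 1.0
    if t.size == 0 or s.size == 0:
        return 0.0
    lo = min(t.min(), s.min()) - 2 * e
    hi = max(t.max(), s.max()) + 2 * e
    grid = np.linspace(lo, hi, n_points)

    def member(times):
        return sum(np.clip((e - np.abs(grid - T)) / e, 0.0, None)
                   for T in times)

    y, ye = member(t), member(s)
    num = 2.0 * np.trapezoid(np.minimum(y, ye), grid)
    den = np.trapezoid(y, grid) + np.trapezoid(ye, grid)
    return float(num / den)
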