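"""Independent brute-force oracles used only by the tests."""

from itertools import combinations
from math import comb

import numpy as np


def fisher_exact_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact integer hypergeometric enumeration.

    With margins fixed, every table is weighted C(r1,k)·C(r2,c1−k); the
    two-sided p sums the weights of all tables no more probable than the
    observed one.  Integer arithmetic throughout — no rounding until the
    final division.
    """
    r1, r2, c1 = a + b, c + d, a + c
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    w_obs = comb(r1, a) * comb(r2, c1 - a)
    total = comb(r1 + r2, c1)
    s = sum(
        w
        for k in range(kmin, kmax + 1)
        if (w := comb(r1, k) * comb(r2, c1 - k)) <= w_obs
    )
    return s / total


def logrank_permutation_p(times, events, group_a_indices, statistic_fn) -> float:
    """Exact permutation p for a two-group statistic: enumerate every
    relabelling that keeps the group sizes, p = fraction of statistics at
    least as large as the observed one (observed split included)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    n = times.size
    size_a = len(group_a_indices)
    observed = statistic_fn(times, events, np.asarray(group_a_indices))
    count = 0
    total = 0
    for subset in combinations(range(n), size_a):
        stat = statistic_fn(times, events, np.asarray(subset))
        total += 1
        if stat >= observed - 1e-12:
            count += 1
    return count / total


def auc_brute_force(scores, outcome) -> float:
    """AUC as the probability a random positive outranks a random negative,
    counting ties as 1/2 — direct O(n²) pair enumeration."""
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome, dtype=bool)
    pos = scores[outcome]
    neg = scores[~outcome]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins) / (len(pos) * len(neg))
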