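"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the code paths they check: the Mann-Whitney oracle
enumerates every group assignment with itertools, and the elimination oracle
simulates the refill process one spine at a time.
"""
from itertools import combinations

import numpy as np


def mann_whitney_p_bruteforce(x, y) -> float:
    """Two-tailed exact u-test p by enumerating all C(n1+n2, n1) assignments."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = np.array(x + y)
    n1 = len(x)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)

    def u_of(idx):
        r1 = ranks[list(idx)].sum()
        return r1 - n1 * (n1 + 1) / 2.0

    u_obs = u_of(range(n1))
    us = np.array([u_of(c) for c in combinations(range(len(pooled)), n1)])
    total = us.size
    cdf = (us <= u_obs).sum() / total
    sf = (us >= u_obs).sum() / total
    return min(1.0, 2.0 * min(cdf, sf))


def min_attainable_p_bruteforce(n: int) -> float:
    """Smallest two-tailed u-test p for equal groups of size n, by enumeration."""
    x = list(range(n))            # fully separated tie-free configuration
    y = list(range(n, 2 * n))
    return mann_whitney_p_bruteforce(x, y)


def eliminate_and_refill_once(lengths, source_lengths, threshold, p_elim, rng):
    """One-spine-at-a-time simulation of the elimination/refill process."""
    out = []
    for L in lengths:
        if L > threshold and rng.random() < p_elim:
            # refill with fresh draws passing the same rule
            while True:
                cand = source_lengths[rng.integers(0, len(source_lengths))]
                if cand > threshold and rng.random() < p_elim:
                    continue
                out.append(cand)
                break
        else:
            out.append(L)
    return np.array(out)
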