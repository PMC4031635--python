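"""Independent brute-force oracles used across the test suite.

These deliberately avoid the code paths they check: Fisher p-values are
enumerated from binomial coefficients, interval overlap is an all-pairs
scan, and burden scores are a double loop.
"""
from __future__ import annotations

from math import comb

import numpy as np


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration: sum of
    point probabilities not exceeding the observed one (with the usual
    1e-7 relative slack for float ties)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    k_min, k_max = max(0, c1 - r2), min(r1, c1)
    probs = {k: comb(r1, k) * comb(r2, c1 - k) / denom for k in range(k_min, k_max + 1)}
    p_obs = probs[a]
    return min(sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7)), 1.0)


def overlap_flags_oracle(positions, chroms, intervals) -> np.ndarray:
    """All-pairs interval overlap: 1-based pos p is inside (chrom, start,
    end) iff start < p <= end."""
    out = np.zeros(len(positions), dtype=bool)
    for i, (p, ch) in enumerate(zip(positions, chroms)):
        for ich, start, end in intervals:
            if ich == ch and start < p <= end:
                out[i] = True
                break
    return out


def burden_score_oracle(dosages, mafs, in_subset, threshold) -> np.ndarray:
    """Double-loop burden score; missing (nan) dosages contribute 0."""
    n, v = dosages.shape
    out = np.zeros(n)
    for i in range(n):
        for j in range(v):
            if in_subset[j] and mafs[j] <= threshold and not np.isnan(dosages[i, j]):
                out[i] += dosages[i, j]
    return out
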