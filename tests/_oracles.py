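"""Brute-force oracles shared across test modules."""

import itertools

import numpy as np


def exact_mw_pvalue(a, b):
    """Brute-force two-sided Mann-Whitney p by enumerating all labelings."""
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    m = n1 * n2 / 2

    def u_stat(idx_a):
        x = pooled[list(idx_a)]
        y = np.delete(pooled, list(idx_a))
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)

    u_obs = sum((xi > yj) + 0.5 * (xi == yj) for xi in a for yj in b)
    us = [u_stat(c) for c in itertools.combinations(range(n1 + n2), n1)]
    return float(np.mean([abs(u - m) >= abs(u_obs - m) - 1e-12 for u in us]))
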