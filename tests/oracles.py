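"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths under test: pmf values come from
explicit outcome enumeration, and mixture likelihood maximization from
exhaustive subset enumeration with scipy scalar optimization of the single
free weight (g <= 2).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import minimize_scalar


def ztb_pmf_enumerated(x: int, m: int, p: float) -> float:
    """P(X = x | X > 0) for X = number of active molecules out of m, by
    summing over all 2^m activity patterns."""
    total = 0.0
    p_pos = 0.0
    for pattern in itertools.product([0, 1], repeat=m):
        k = sum(pattern)
        prob = (p ** k) * ((1 - p) ** (m - k))
        if k > 0:
            p_pos += prob
            if k == x:
                total += prob
    return total / p_pos if p_pos > 0 else 0.0


def ztb_pmf_closed(x: int, m: int, p: float) -> float:
    if not (1 <= x <= m):
        return 0.0
    return (math.comb(m, x) * p ** x * (1 - p) ** (m - x)
            / (1.0 - (1.0 - p) ** m))


def _loglik(counts, sizes, weights, p) -> float:
    ll = 0.0
    for x in counts:
        px = sum(w * ztb_pmf_closed(int(x), int(m), p)
                 for m, w in zip(sizes, weights))
        if px <= 0:
            return -math.inf
        ll += math.log(px)
    return ll


def brute_force_fit(counts, p: float, g: int, m_max: int = 8):
    """Globally maximize the g-component zero-truncated binomial mixture
    likelihood by enumerating every size subset; for g = 2 the single free
    weight is optimized by bounded scalar minimization.

    Returns (best_loglik, best_sizes, best_weights).
    """
    counts = np.asarray(counts, dtype=int)
    x_max = int(counts.max())
    grid = [m for m in range(1, m_max + 1)]
    best = (-math.inf, None, None)
    if g == 1:
        for m in grid:
            if m < x_max:
                continue
            ll = _loglik(counts, (m,), (1.0,), p)
            if ll > best[0]:
                best = (ll, (m,), (1.0,))
        return best
    if g != 2:
        raise ValueError("oracle supports g <= 2 only")
    for m1, m2 in itertools.combinations(grid, 2):
        if max(m1, m2) < x_max:
            continue

        def neg(w1, _sizes=(m1, m2)):
            return -_loglik(counts, _sizes, (w1, 1.0 - w1), p)

        res = minimize_scalar(neg, bounds=(1e-12, 1.0 - 1e-12),
                              method="bounded",
                              options={"xatol": 1e-13})
        # guard the scalar optimizer with a coarse grid refinement
        ws = np.linspace(1e-9, 1.0 - 1e-9, 201)
        lls = np.array([-neg(w) for w in ws])
        w_best = ws[int(np.argmax(lls))]
        cand = max(-res.fun, lls.max())
        if cand > best[0]:
            w = float(res.x) if -res.fun >= lls.max() else float(w_best)
            best = (float(cand), (m1, m2), (w, 1.0 - w))
    return best


def ks_statistic_double_loop(a, b) -> float:
    """KS statistic by brute force over every integer in the joint range."""
    a = np.asarray(a)
    b = np.asarray(b)
    d = 0.0
    for x in range(int(min(a.min(), b.min())), int(max(a.max(), b.max())) + 1):
        d = max(d, abs((a <= x).mean() - (b <= x).mean()))
    return d
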