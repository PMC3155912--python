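"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each statistic from its definition with the
slowest, most literal code possible, sharing nothing with the package
implementations they check.
"""

from __future__ import annotations

import numpy as np


def brute_force_max_t(x: np.ndarray) -> tuple[int, int, float]:
    """Exhaustive scan of every circular arc boundary 0 <= i < j <= n.

    T(i, j) = |mean(arc) - mean(complement)| / (s * sqrt(1/k + 1/(n-k)))
    with s the pooled two-group SD.  Ties broken toward smallest (i, j).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    best = (-1.0, 0, 1)
    for i in range(n):
        for j in range(i + 1, n + 1):
            k = j - i
            if k == n:
                continue
            arc = x[i:j]
            comp = np.concatenate([x[:i], x[j:]])
            m1, m2 = arc.mean(), comp.mean()
            ss = ((arc - m1) ** 2).sum() + ((comp - m2) ** 2).sum()
            s2 = ss / (n - 2)
            denom = s2 * (1.0 / k + 1.0 / (n - k))
            if denom <= 0:
                t = 0.0 if m1 == m2 else np.inf
            else:
                t = abs(m1 - m2) / np.sqrt(denom)
            if t > best[0] or (t == best[0] and (i, j) < (best[1], best[2])):
                best = (t, i, j)
    return best[1], best[2], best[0]


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values straight from the definition:
    q_i = min over {j : p_j >= p_i} of (m * p_j / rank_j), capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        candidates = [
            m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i]
        ]
        q[i] = min(1.0, min(candidates))
    return q


def brute_force_es(metric: np.ndarray, hit_mask: np.ndarray,
                   weight_exponent: float = 1.0) -> tuple[float, np.ndarray]:
    """Literal step-by-step running-sum walk over a ranking.

    ``metric`` is the ranking metric in rank order; ``hit_mask`` marks set
    members.  Returns (es, running_sum) with es the extremum by absolute
    value (positive preferred on an exact tie).
    """
    metric = np.asarray(metric, dtype=float)
    hit_mask = np.asarray(hit_mask, dtype=bool)
    n = len(metric)
    k = int(hit_mask.sum())
    w = np.abs(metric) ** weight_exponent
    nr = w[hit_mask].sum()
    running = np.empty(n)
    total = 0.0
    for idx in range(n):
        if hit_mask[idx]:
            total += (w[idx] / nr) if nr > 0 else 1.0 / k
        else:
            total -= 1.0 / (n - k)
        running[idx] = total
    hi = running.max()
    lo = running.min()
    # extremes can also be the 0 start, but |0| never beats a nonzero extreme
    es = hi if abs(hi) >= abs(lo) else lo
    return float(es), running


def assert_es_matches(got_es: float, metric, hit_mask,
                      weight_exponent: float = 1.0, tol: float = 1e-9) -> None:
    """Check an ES against the brute-force walk.

    When the positive and negative extremes tie in magnitude (to within
    float noise) the chosen sign depends on summation order, so only the
    magnitude is compared; otherwise value and sign must agree.
    """
    es_ref, running = brute_force_es(metric, hit_mask, weight_exponent)
    hi, lo = running.max(), running.min()
    if abs(abs(hi) - abs(lo)) < tol:
        assert abs(abs(got_es) - abs(es_ref)) < tol, (got_es, es_ref)
    else:
        assert abs(got_es - es_ref) < tol, (got_es, es_ref)
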