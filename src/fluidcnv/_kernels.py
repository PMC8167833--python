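"""Numeric kernels for circular binary segmentation.

The split statistic is the two-sample t between an arc ``x[i:j]`` and its
complement on the circularized series (wrapping arcs are complements of
plain ones, so scanning all ``0 <= i < j <= n`` with the complement covers
the circle).  Zero pooled variance with unequal means scores +inf; ties in
the maximum are broken toward the leftmost, then shortest, arc by scan
order.  Kernels are numba-compiled when numba is available and fall back
to pure Python otherwise.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]

_VAR_EPS = 1e-12


@njit(cache=False)
def max_arc_t2(x):
    """Maximum squared circular two-sample t over all arcs of ``x``.

    Returns ``(t2, i, j)`` for the maximizing arc ``x[i:j]``; ``t2`` is
    0.0 when no arc separates the series (constant input or n < 2).
    """
    n = x.shape[0]
    cs = np.empty(n + 1)
    css = np.empty(n + 1)
    cs[0] = 0.0
    css[0] = 0.0
    for k in range(n):
        cs[k + 1] = cs[k] + x[k]
        css[k + 1] = css[k] + x[k] * x[k]
    tot = cs[n]
    tot2 = css[n]
    best = 0.0
    bi = 0
    bj = 0
    df = n - 2
    for i in range(n):
        for j in range(i + 1, n + 1):
            l = j - i
            m = n - l
            if m == 0:
                continue
            s_in = cs[j] - cs[i]
            mean_in = s_in / l
            s_out = tot - s_in
            mean_out = s_out / m
            d = mean_in - mean_out
            ssd = (css[j] - css[i] - s_in * mean_in) + (tot2 - css[j] + css[i] - s_out * mean_out)
            if df <= 0 or ssd < _VAR_EPS * n:
                t2 = np.inf if d != 0.0 else 0.0
            else:
                t2 = d * d / ((ssd / df) * (1.0 / l + 1.0 / m))
            if t2 > best:
                best = t2
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=False)
def perm_exceed_count(perms, t2_obs, stop_at):
    """Count permutation rows whose max arc t^2 reaches ``t2_obs``.

    Each row short-circuits at the first qualifying arc; the whole scan
    stops once the count exceeds ``stop_at`` (the caller's evidence bound
    for non-significance).  Returns ``(count, rows_processed)``.
    """
    B, n = perms.shape
    cs = np.empty(n + 1)
    css = np.empty(n + 1)
    e = 0
    rows = 0
    df = n - 2
    for b in range(B):
        rows += 1
        cs[0] = 0.0
        css[0] = 0.0
        for k in range(n):
            v = perms[b, k]
            cs[k + 1] = cs[k] + v
            css[k + 1] = css[k] + v * v
        tot = cs[n]
        tot2 = css[n]
        hit = False
        for i in range(n):
            if hit:
                break
            for j in range(i + 1, n + 1):
                l = j - i
                m = n - l
                if m == 0:
                    continue
                s_in = cs[j] - cs[i]
                mean_in = s_in / l
                s_out = tot - s_in
                mean_out = s_out / m
                d = mean_in - mean_out
                ssd = (css[j] - css[i] - s_in * mean_in) + (
                    tot2 - css[j] + css[i] - s_out * mean_out
                )
                if df <= 0 or ssd < _VAR_EPS * n:
                    t2 = np.inf if d != 0.0 else 0.0
                else:
                    t2 = d * d / ((ssd / df) * (1.0 / l + 1.0 / m))
                if t2 >= t2_obs:
                    hit = True
                    break
        if hit:
            e += 1
            if e > stop_at:
                break
    return e, rows
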