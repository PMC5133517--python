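"""Independent brute-force oracles used to verify the package's numerics.

Each oracle re-derives a quantity by the most transparent route available
(normal equations, explicit enumeration, numerical integration, naive double
loops) so that agreement with the package is a genuine cross-check, not a
tautology.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy.integrate import quad


def ols_slope_and_rss(y, x):
    """Slope and RSS of y on [1, x] solved via the normal equations."""
    X = np.column_stack([np.ones(len(x)), np.asarray(x, dtype=float)])
    beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(y, dtype=float))
    resid = y - X @ beta
    return float(beta[1]), float(resid @ resid)


def ols_residuals(y, X):
    """Residuals of y on a design matrix (with intercept prepended)."""
    D = np.column_stack([np.ones(len(y)), np.asarray(X, dtype=float)])
    beta = np.linalg.solve(D.T @ D, D.T @ np.asarray(y, dtype=float))
    return np.asarray(y, dtype=float) - D @ beta


def interval_union(intervals, gap=1):
    """Union of closed integer intervals, coalescing gaps <= ``gap``.

    Implemented by explicit membership over the covered integer range, so it
    is independent of any sort-and-sweep logic.
    """
    if not intervals:
        return []
    covered = set()
    for a, b in intervals:
        covered.update(range(a, b + 1))
    out = []
    for x in sorted(covered):
        if out and x <= out[-1][1] + gap:
            out[-1][1] = x
        else:
            out.append([x, x])
    return [tuple(iv) for iv in out]


def piecewise_linear(anchors, q):
    """Scalar piecewise-linear interpolation/extrapolation over (x, y) anchors."""
    xs = [a[0] for a in anchors]
    ys = [a[1] for a in anchors]
    if q <= xs[0]:
        i = 0
    elif q >= xs[-1]:
        i = len(xs) - 2
    else:
        i = max(k for k in range(len(xs) - 1) if xs[k] <= q)
    slope = (ys[i + 1] - ys[i]) / (xs[i + 1] - xs[i])
    return ys[i] + (q - xs[i]) * slope


def membership_matrix(segments, markers, pairs):
    """Naive double-loop pairs x markers closed-interval membership matrix."""
    mat = np.zeros((len(pairs), len(markers)), dtype=int)
    index = {p: i for i, p in enumerate(pairs)}
    for seg in segments:
        key = tuple(sorted((seg.id1, seg.id2)))
        if key not in index:
            continue
        for j, m in enumerate(markers):
            if seg.start_bp <= m <= seg.end_bp:
                mat[index[key], j] = 1
    return mat


def hwe_enumeration_p(n_hom_ref, n_het, n_hom_alt):
    """Exact HWE p-value by full enumeration with rational arithmetic.

    P(het = h | n, allele counts) = 2^h * n! / (h! n_rh! n_ch!) normalised
    over all heterozygote counts consistent with the allele counts.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    weights = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        n_rh = (n_rare - h) // 2
        n_ch = n - h - n_rh
        if n_ch < 0:
            continue
        weights[h] = Fraction(2**h * math.factorial(n)) / (
            math.factorial(h) * math.factorial(n_rh) * math.factorial(n_ch)
        )
    total = sum(weights.values())
    observed = weights[n_het]
    p = sum(w for w in weights.values() if w <= observed) / total
    return float(p)


def t_lower_tail_quad(t, df):
    """Lower-tail t probability by numerical integration of the density."""

    def density(x):
        c = math.exp(
            math.lgamma((df + 1) / 2) - math.lgamma(df / 2)
        ) / math.sqrt(df * math.pi)
        return c * (1 + x * x / df) ** (-(df + 1) / 2)

    if t <= 0:
        val, _ = quad(density, -np.inf, t)
        return val
    val, _ = quad(density, t, np.inf)
    return 1 - val
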