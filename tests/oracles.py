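"""Independent oracles for cross-checking the implementation.

These deliberately avoid the code paths (and where possible the library
calls) used by the package: the slope comes from an iteratively refined grid
search over the residual sum of squares, the t-tail probability from direct
numerical integration of the t density written out via gamma functions, and
the scalar clustering from a brute-force all-pairs agglomeration.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad


def sse_at_slope(b: float, x, y) -> float:
    """Residual SS at slope b with the intercept profiled out."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    a = (y - b * x).mean()
    return float(((y - a - b * x) ** 2).sum())


def grid_search_slope(x, y, lo: float = -10.0, hi: float = 10.0, iters: int = 60, pts: int = 41) -> float:
    """Least-squares slope by shrinking-grid search on the (convex) SSE."""
    for _ in range(iters):
        grid = np.linspace(lo, hi, pts)
        errs = [sse_at_slope(b, x, y) for b in grid]
        i = int(np.argmin(errs))
        lo, hi = grid[max(0, i - 1)], grid[min(pts - 1, i + 1)]
    return 0.5 * (lo + hi)


def t_density(u: float, df: int) -> float:
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    return c * (1.0 + u * u / df) ** (-(df + 1) / 2)


def p_two_sided_by_integration(t: float, df: int) -> float:
    """2 * integral of the t density from |t| to infinity."""
    tail, _ = quad(t_density, abs(t), np.inf, args=(df,), epsabs=1e-14, epsrel=1e-12)
    return 2.0 * tail


def ols_by_oracle(x, y) -> tuple[float, float, float, float]:
    """(slope, se, t, p) assembled entirely from the oracle primitives."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    b = grid_search_slope(x, y)
    n = x.size
    df = n - 2
    s2 = sse_at_slope(b, x, y) / df
    se = math.sqrt(s2 / float(((x - x.mean()) ** 2).sum()))
    t = b / se
    return b, se, t, p_two_sided_by_integration(t, df)


def brute_force_average_linkage(scores: dict[str, float]) -> list[tuple[frozenset, frozenset, float]]:
    """All-pairs UPGMA agglomeration of scalars, merge by merge."""
    clusters: list[frozenset] = [frozenset([k]) for k in scores]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = float(
                    np.mean(
                        [abs(scores[a] - scores[b]) for a in clusters[i] for b in clusters[j]]
                    )
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        a, b = clusters[i], clusters[j]
        merges.append((a, b, d))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [a | b]
    return merges
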