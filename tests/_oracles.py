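"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity by a different route than the library:
lattice searches for the exponential fits, ray casting for polygon
membership, the shoelace formula for areas, long-double normal equations
for OLS, and direct summation for means.  They are deliberately slow and
simple.
"""

import math

import numpy as np


def t1_grid_search(signal, delays, n_pass: int = 12, n_grid: int = 21):
    """Coarse-to-fine lattice search over (A, B, T1) minimizing SSR.

    Returns (A, B, T1, final grid steps).
    """
    signal = np.asarray(signal, float)
    delays = np.asarray(delays, float)
    lo = np.array([0.5 * signal.max(), 0.1 * signal.max(), 50.0])
    hi = np.array([2.0 * signal.max() + 1.0, 2.0 * signal.max() + 1.0, 8000.0])
    best = None
    for _ in range(n_pass):
        a_g = np.linspace(lo[0], hi[0], n_grid)
        b_g = np.linspace(lo[1], hi[1], n_grid)
        t_g = np.linspace(lo[2], hi[2], n_grid)
        model = (
            a_g[:, None, None, None]
            - b_g[None, :, None, None]
            * np.exp(-delays[None, None, None, :] / t_g[None, None, :, None])
        )
        ssr = np.sum((model - signal) ** 2, axis=-1)
        i, j, k = np.unravel_index(np.argmin(ssr), ssr.shape)
        best = (a_g[i], b_g[j], t_g[k])
        step = (hi - lo) / (n_grid - 1)
        center = np.array(best)
        lo = center - 5.0 * step
        hi = center + 5.0 * step
        lo[2] = max(lo[2], 1.0)
    return (*best, (hi - lo) / (n_grid - 1))


def t2_grid_search(signal, echoes, n_pass: int = 10, n_grid: int = 41):
    """Coarse-to-fine lattice search over (S0, T2)."""
    signal = np.asarray(signal, float)
    echoes = np.asarray(echoes, float)
    lo = np.array([0.5 * signal.max(), 1.0])
    hi = np.array([5.0 * signal.max(), 200.0])
    best = None
    for _ in range(n_pass):
        s_g = np.linspace(lo[0], hi[0], n_grid)
        t_g = np.linspace(lo[1], hi[1], n_grid)
        model = s_g[:, None, None] * np.exp(-echoes[None, None, :] / t_g[None, :, None])
        ssr = np.sum((model - signal) ** 2, axis=-1)
        i, j = np.unravel_index(np.argmin(ssr), ssr.shape)
        best = (s_g[i], t_g[j])
        step = (hi - lo) / (n_grid - 1)
        center = np.array(best)
        lo = np.maximum(center - 10.0 * step, [1e-9, 0.5])
        hi = center + 10.0 * step
    return (*best, (hi - lo) / (n_grid - 1))


def point_in_polygon(point, vertices) -> bool:
    """Ray-casting (even-odd) point-in-polygon test."""
    x, y = point
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x_cross > x:
                inside = not inside
    return inside


def shoelace(vertices) -> float:
    """Polygon area by direct pairwise summation."""
    v = list(vertices)
    total = 0.0
    for i in range(len(v)):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % len(v)]
        total += x1 * y2 - x2 * y1
    return abs(total) / 2.0


def ols_normal_equations(X, y):
    """OLS coefficients: normal equations solved by long-double Gaussian
    elimination with partial pivoting (numpy.linalg rejects float128)."""
    Xl = np.asarray(X, dtype=np.longdouble)
    yl = np.asarray(y, dtype=np.longdouble)
    A = Xl.T @ Xl
    b = Xl.T @ yl
    n = A.shape[0]
    M = np.hstack([A, b[:, None]])
    for col in range(n):
        pivot = col + int(np.argmax(np.abs(M[col:, col])))
        M[[col, pivot]] = M[[pivot, col]]
        M[col] = M[col] / M[col, col]
        for row in range(n):
            if row != col:
                M[row] = M[row] - M[row, col] * M[col]
    return M[:, -1].astype(float)


def pooled_t_statistic(x, y):
    """Hand-computed pooled-variance two-sample t statistic."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    return (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))


def kmeans_wcss(points, labels, k=3):
    """Within-cluster sum of squares for a given assignment."""
    points = np.asarray(points, float)
    total = 0.0
    for c in range(k):
        sel = points[labels == c]
        if len(sel):
            total += float(((sel - sel.mean(axis=0)) ** 2).sum())
    return total


def exhaustive_kmeans_wcss(points, k=3):
    """Global optimum WCSS by enumerating every assignment (tiny n only)."""
    import itertools

    points = np.asarray(points, float)
    n = len(points)
    best = math.inf
    for labels in itertools.product(range(k), repeat=n):
        best = min(best, kmeans_wcss(points, np.asarray(labels), k))
    return best
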